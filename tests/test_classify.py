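"""Label assignment from fitted parameters and summary statistics."""

import math

import numpy as np
import pandas as pd
import pytest

from gausspower.classify import (GAUSSIAN, INTERMEDIATE, POWER, UNCLASSIFIED,
                                 classify_cluster, compare_group_means,
                                 log10_K_over_g, summarize)
from gausspower.distributions import GPParams
from gausspower.fit import FitResult


def _gp_fit(g, K, f=1.0, converged=True):
    params = GPParams(g=g, f=f, K=K, A=1.0) if converged else None
    return FitResult(family="GP", params=params, lse=0.01, branch="linear",
                     n_starts=1, converged=converged)


class TestThresholds:
    @pytest.mark.parametrize("g,K,expected", [
        (1.0, 0.01, GAUSSIAN),      # r = -2
        (1.0, 1.0, INTERMEDIATE),   # r = 0
        (1.0, 10.0, POWER),         # r = 1
        (1.0, 0.1, UNCLASSIFIED),   # r = -1, in the gap
        (1.0, 2.0, UNCLASSIFIED),   # r = 0.3, in the gap
        (1.0, 0.0, GAUSSIAN),       # K = 0 boundary
    ])
    def test_label_regions(self, g, K, expected):
        assert classify_cluster(_gp_fit(g, K)).label == expected

    def test_K_zero_plotting_convention(self):
        lab = classify_cluster(_gp_fit(g=2.0, K=0.0))
        assert lab.log10_K_over_g == pytest.approx(math.log10(1e-4 / 2.0))
        assert log10_K_over_g(2.0, 0.0) == lab.log10_K_over_g

    def test_partition_is_disjoint(self):
        # no r value satisfies two label regions
        for r in np.linspace(-3, 2, 501):
            fit = _gp_fit(1.0, 10.0 ** r)
            labels = [classify_cluster(fit).label]
            assert len(labels) == 1
            regions = [r < -1.3, -0.6 < r < 0.1, r > 0.4]
            assert sum(regions) <= 1
            if not any(regions):
                assert labels[0] == UNCLASSIFIED

    def test_gap_to_nearest_assignment(self):
        assert classify_cluster(_gp_fit(1.0, 10 ** -1.2),
                                gap_to_nearest=True).label == GAUSSIAN
        assert classify_cluster(_gp_fit(1.0, 10 ** -0.7),
                                gap_to_nearest=True).label == INTERMEDIATE
        assert classify_cluster(_gp_fit(1.0, 10 ** 0.35),
                                gap_to_nearest=True).label == POWER

    def test_non_converged_is_unclassified(self):
        lab = classify_cluster(_gp_fit(1.0, 1.0, converged=False))
        assert lab.label == UNCLASSIFIED

    def test_nb_fit_rejected(self):
        fit = FitResult(family="NB", params=None, lse=0.1, branch="linear",
                        n_starts=1, converged=True)
        with pytest.raises(ValueError):
            classify_cluster(fit)


def _table(labels, condition="7-13", age=7, expr=100.0, category="other"):
    return pd.DataFrame({
        "gene_id": [f"g{i}" for i in range(len(labels))],
        "condition": condition, "age_days": age, "time_h": 13,
        "cluster_id": 0, "label": labels,
        "mean_expression": expr if np.ndim(expr) else [expr] * len(labels),
        "category": category,
    })


class TestSummarize:
    def test_all_gaussian(self):
        out = summarize(_table([GAUSSIAN] * 10), "condition")
        row = out.iloc[0]
        assert (row[POWER], row[INTERMEDIATE], row[GAUSSIAN]) == (0, 0, 1)

    def test_rows_sum_to_one_and_unclassified_separate(self):
        labels = [GAUSSIAN] * 4 + [INTERMEDIATE] * 3 + [POWER] * 2 + [
            UNCLASSIFIED]
        out = summarize(_table(labels), "condition")
        row = out.iloc[0]
        assert row[POWER] + row[INTERMEDIATE] + row[GAUSSIAN] == (
            pytest.approx(1.0, abs=1e-12))
        assert row["unclassified_fraction"] == pytest.approx(0.1)
        assert row["n_classified"] == 9

    def test_grouping_by_category(self):
        t = pd.concat([_table([GAUSSIAN] * 4, category="ribosome"),
                       _table([POWER] * 4, category="transcription_factor")])
        out = summarize(t, "category").set_index("category")
        assert out.loc["ribosome", GAUSSIAN] == 1.0
        assert out.loc["transcription_factor", POWER] == 1.0

    def test_unknown_grouping_rejected(self):
        with pytest.raises(ValueError):
            summarize(_table([GAUSSIAN]), "chromosome")
        with pytest.raises(ValueError):
            summarize(_table([]).iloc[0:0], "condition")


class TestGroupMeans:
    def test_planted_expression_difference_detected(self):
        rng = np.random.default_rng(5)
        n = 300
        t = pd.concat([
            _table([GAUSSIAN] * n, expr=rng.lognormal(5, 0.5, n)),
            _table([INTERMEDIATE] * n, expr=rng.lognormal(4, 0.5, n)),
            _table([POWER] * n, expr=rng.lognormal(3, 0.5, n)),
        ])
        out = compare_group_means(t).set_index(["group_a", "group_b"])
        row = out.loc[(GAUSSIAN, INTERMEDIATE)]
        assert row["mean_a"] > row["mean_b"] and row["pvalue"] < 0.01
        row2 = out.loc[(INTERMEDIATE, POWER)]
        assert row2["mean_a"] > row2["mean_b"] and row2["pvalue"] < 0.01

    def test_identical_means_not_significant(self):
        rng = np.random.default_rng(6)
        vals = rng.lognormal(4, 0.3, 50)
        t = pd.concat([_table([GAUSSIAN] * 50, expr=vals),
                       _table([INTERMEDIATE] * 50, expr=vals)])
        out = compare_group_means(t)
        assert out.iloc[0]["pvalue"] > 0.9

    def test_t_statistic_antisymmetry(self):
        rng = np.random.default_rng(7)
        a, b = rng.lognormal(5, 0.4, 40), rng.lognormal(4, 0.4, 40)
        t1 = pd.concat([_table([GAUSSIAN] * 40, expr=a),
                        _table([INTERMEDIATE] * 40, expr=b)])
        t2 = pd.concat([_table([GAUSSIAN] * 40, expr=b),
                        _table([INTERMEDIATE] * 40, expr=a)])
        s1 = compare_group_means(t1).iloc[0]["t"]
        s2 = compare_group_means(t2).iloc[0]["t"]
        assert s1 == pytest.approx(-s2)

    def test_small_groups_skipped(self):
        t = pd.concat([_table([GAUSSIAN] * 5), _table([INTERMEDIATE])])
        out = compare_group_means(t)
        assert len(out) == 0
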