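"""Classification of fitted ePDF profiles along the Gaussian-power spectrum.

Fitted Gauss-power parameters separate into three groups along
r = log10(K/g): Gaussian (K = 0 or r < -1.3), intermediate
(-0.6 < r < 0.1) and power law-like (r > 0.4).  Values falling in the
gaps between groups are reported as Unclassified rather than snapped to
the nearest group (``gap_to_nearest=True`` enables nearest-boundary
assignment for full accounting).  Genes inherit the label of the cluster
whose average profile was fitted.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats

from .fit import FitResult

__all__ = [
    "ClassLabel",
    "GAUSSIAN",
    "INTERMEDIATE",
    "POWER",
    "UNCLASSIFIED",
    "LABELS",
    "K_ZERO_PSEUDO",
    "classify_cluster",
    "log10_K_over_g",
    "summarize",
    "compare_group_means",
]

GAUSSIAN = "Gaussian"
INTERMEDIATE = "Intermediate"
POWER = "PowerLawLike"
UNCLASSIFIED = "Unclassified"
LABELS = (POWER, INTERMEDIATE, GAUSSIAN)

#: pseudo-K used to place K = 0 fits on the log10(K/g) axis
K_ZERO_PSEUDO = 1e-4


@dataclass(frozen=True)
class ClassLabel:
    label: str
    log10_K_over_g: float


def log10_K_over_g(g: float, K: float) -> float:
    """r = log10(K/g), with K = 0 mapped to log10(1e-4 / g) by convention."""
    if K == 0:
        return math.log10(K_ZERO_PSEUDO / g)
    return math.log10(K / g)


def classify_cluster(fit: FitResult, gap_to_nearest: bool = False) -> ClassLabel:
    """Label one GP fit as Gaussian / Intermediate / PowerLawLike.

    Threshold-gap values ([-1.3, -0.6] and [0.1, 0.4]) are Unclassified
    unless ``gap_to_nearest`` snaps them to the nearest boundary's label.
    Non-converged fits are Unclassified.
    """
    if fit.family != "GP":
        raise ValueError(f"classification requires a GP fit, got {fit.family}")
    if not fit.converged or fit.params is None:
        return ClassLabel(label=UNCLASSIFIED, log10_K_over_g=math.nan)
    g, K = fit.params.g, fit.params.K
    r = log10_K_over_g(g, K)
    if K == 0 or r < -1.3:
        return ClassLabel(GAUSSIAN, r)
    if -0.6 < r < 0.1:
        return ClassLabel(INTERMEDIATE, r)
    if r > 0.4:
        return ClassLabel(POWER, r)
    if gap_to_nearest:
        if r <= -0.6:  # gap [-1.3, -0.6]
            lbl = GAUSSIAN if abs(r + 1.3) < abs(r + 0.6) else INTERMEDIATE
        else:          # gap [0.1, 0.4]
            lbl = INTERMEDIATE if abs(r - 0.1) < abs(r - 0.4) else POWER
        return ClassLabel(lbl, r)
    return ClassLabel(UNCLASSIFIED, r)


def summarize(table: pd.DataFrame, grouping: str = "condition") -> pd.DataFrame:
    """Occurrence ratios of the three labels per group.

    ``table`` is a gene-class table with columns label, condition,
    age_days and (optionally) category.  Ratios are computed among
    classified rows; the unclassified fraction of all rows is reported in
    its own column.  Label columns are ordered Power, Intermediate,
    Gaussian.
    """
    if table.empty:
        raise ValueError("empty gene-class table")
    key = {"condition": "condition", "age": "age_days",
           "category": "category"}.get(grouping)
    if key is None or key not in table.columns:
        raise ValueError(f"unknown or unavailable grouping {grouping!r}")
    rows = []
    for grp, sub in table.groupby(key, sort=True):
        classified = sub[sub["label"] != UNCLASSIFIED]
        n_cls = len(classified)
        counts = classified["label"].value_counts()
        row = {key: grp, "n_genes": len(sub), "n_classified": n_cls,
               "unclassified_fraction": 1.0 - n_cls / len(sub)}
        for lbl in LABELS:
            row[lbl] = counts.get(lbl, 0) / n_cls if n_cls else math.nan
        rows.append(row)
    return pd.DataFrame(rows)


def compare_group_means(table: pd.DataFrame,
                        expression_col: str = "mean_expression") -> pd.DataFrame:
    """t-tests on average log10 expression between adjacent label groups.

    Per age group: Gaussian vs Intermediate and Intermediate vs
    PowerLawLike, on log10 of each gene's mean (unstandardized)
    expression.  Groups with < 2 genes are skipped.
    """
    out = []
    for age, sub in table.groupby("age_days", sort=True):
        logx = {}
        for lbl in (GAUSSIAN, INTERMEDIATE, POWER):
            vals = sub.loc[sub["label"] == lbl, expression_col].to_numpy()
            vals = vals[vals > 0]
            logx[lbl] = np.log10(vals)
        for a, b in ((GAUSSIAN, INTERMEDIATE), (INTERMEDIATE, POWER)):
            if len(logx[a]) < 2 or len(logx[b]) < 2:
                continue
            t, p = stats.ttest_ind(logx[a], logx[b], equal_var=False)
            out.append({"age_days": age, "group_a": a, "group_b": b,
                        "mean_a": float(np.mean(logx[a])),
                        "mean_b": float(np.mean(logx[b])),
                        "t": float(t), "pvalue": float(p)})
    return pd.DataFrame(out)
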