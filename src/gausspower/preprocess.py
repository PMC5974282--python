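"""Expression-matrix I/O and the harvest-order stationarity filter.

Replicates within a condition are harvested over a short window, so genes
responding on that timescale show a systematic trend across harvest order.
The filter splits each condition's samples into an early and a late half
by harvest order, runs a two-sample t-test on each gene, and keeps the
gene only if P > alpha (default 0.2): a deliberately permissive test that
discards anything with even weak evidence of a harvest-time trend.
"""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path

import numpy as np
import pandas as pd
from scipy import stats

__all__ = [
    "ConditionKey",
    "read_matrix",
    "read_metadata",
    "read_annotation",
    "condition_samples",
    "list_conditions",
    "stationarity_filter",
]


@dataclass(frozen=True, order=True)
class ConditionKey:
    """One experimental condition: plant age x harvest time."""

    age_days: int
    time_h: int

    def __str__(self) -> str:
        return f"{self.age_days}:{self.time_h}"

    @classmethod
    def parse(cls, text: str) -> "ConditionKey":
        age, _, time = str(text).partition(":")
        return cls(age_days=int(age), time_h=int(time))


def read_matrix(path) -> pd.DataFrame:
    """Read a genes x samples expression TSV (first column = gene IDs)."""
    mat = pd.read_csv(path, sep="\t", index_col=0)
    if mat.index.has_duplicates:
        raise ValueError(f"duplicate gene IDs in {path}")
    if mat.columns.has_duplicates:
        raise ValueError(f"duplicate sample IDs in {path}")
    if (mat.to_numpy() < 0).any():
        raise ValueError(f"negative expression values in {path}")
    return mat


def read_metadata(path) -> pd.DataFrame:
    meta = pd.read_csv(path, sep="\t")
    required = {"sample_id", "age_days", "time_h", "harvest_order"}
    missing = required - set(meta.columns)
    if missing:
        raise ValueError(f"metadata {path} missing columns {sorted(missing)}")
    return meta


def read_annotation(path) -> pd.DataFrame:
    ann = pd.read_csv(path, sep="\t")
    if "gene_id" not in ann.columns:
        raise ValueError(f"annotation {path} missing gene_id column")
    return ann


def list_conditions(meta: pd.DataFrame) -> list[ConditionKey]:
    keys = meta[["age_days", "time_h"]].drop_duplicates().sort_values(
        ["age_days", "time_h"])
    return [ConditionKey(int(a), int(t)) for a, t in keys.to_numpy()]


def condition_samples(meta: pd.DataFrame, condition: ConditionKey) -> pd.DataFrame:
    """Metadata rows for one condition, sorted by harvest order."""
    sel = meta[(meta["age_days"] == condition.age_days)
               & (meta["time_h"] == condition.time_h)]
    if len(sel) < 2:
        raise ValueError(f"condition {condition} identifies < 2 samples")
    return sel.sort_values("harvest_order")


def _split_halves(n: int) -> int:
    """Index splitting n ordered samples into early/late halves.

    For odd n the median sample joins the early half (deterministic rule).
    """
    return (n + 1) // 2


def stationarity_filter(matrix: pd.DataFrame, meta: pd.DataFrame,
                        condition: ConditionKey, alpha: float = 0.2,
                        variant: str = "welch"):
    """Early-vs-late harvest t-test per gene; retain genes with P > alpha.

    Returns ``(retained, pvalues)``: a pandas Index of retained gene IDs
    and a Series of per-gene P values.  ``variant`` selects Welch's
    (unequal-variance, default) or Student's pooled t-test.  Degenerate
    genes whose halves are constant and equal get P = 1 (retained);
    constant but unequal halves get P = 0 (removed).
    """
    if variant not in ("welch", "student"):
        raise ValueError(f"unknown t-test variant {variant!r}")
    sel = condition_samples(meta, condition)
    if len(sel) < 4:
        raise ValueError(
            f"condition {condition} needs >= 4 samples, has {len(sel)}")
    cols = sel["sample_id"].to_numpy()
    missing = [c for c in cols if c not in matrix.columns]
    if missing:
        raise ValueError(f"samples missing from matrix: {missing}")
    n_early = _split_halves(len(cols))
    early = matrix[cols[:n_early]].to_numpy(dtype=float)
    late = matrix[cols[n_early:]].to_numpy(dtype=float)
    with np.errstate(invalid="ignore", divide="ignore"):
        _, pvals = stats.ttest_ind(early, late, axis=1,
                                   equal_var=(variant == "student"))
    pvals = np.asarray(pvals, dtype=float)
    # zero variance in both halves: equal means -> P=1, unequal -> P=0
    bad = ~np.isfinite(pvals)
    if bad.any():
        eq = np.isclose(early.mean(axis=1), late.mean(axis=1))
        pvals[bad & eq] = 1.0
        pvals[bad & ~eq] = 0.0
    pvalues = pd.Series(pvals, index=matrix.index, name="pvalue")
    retained = matrix.index[pvals > alpha]
    return retained, pvalues
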