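"""Langevin simulation of feedback-regulated expression and synthetic cohorts.

The single-gene model is

    dx/dt = G + R(t) + F x / (K + x) * eta(t) - C x

with independent Gaussian white noises, <R R'> = 2 D delta and
<eta eta'> = 2 delta.  ``G`` is the mean activation rate by upstream genes,
``C`` the degradation rate, and the saturating multiplicative term models
noisy feedback with magnitude ``F`` and half-saturation ``K``.  The
multiplicative noise is integrated in the Stratonovich sense with a Heun
predictor-corrector: in that convention (and for D/C -> 0) the stationary
Fokker-Planck solution is exactly the Gauss-power density with g = G/C and
f = F/C, which the test suite checks against brute-force quadrature.

Cohort generation draws replicate expression values directly from that
stationary law, gene by gene, and emulates the design of a multi-condition
plant RNA-seq experiment: several (age, harvest-time) conditions with
~20-27 biological replicates each, ~10^3-10^4 genes spread over three
feedback regimes (K << g, K ~ g, K >> g), and a configurable fraction of
genes carrying a harvest-order drift that the stationarity filter is meant
to remove.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .distributions import GPParams, gp_sample

__all__ = [
    "SDEParams",
    "CohortSpec",
    "Cohort",
    "simulate_stationary",
    "simulate_trajectory",
    "generate_cohort",
    "DEFAULT_REGIME_PRIORS",
    "REGIMES",
]

REGIMES = ("gaussian", "intermediate", "power")

#: Per-regime parameter priors.  A regime is defined by where the
#: standard profile transform (per-gene standardization, sorted-vector
#: averaging, min-shift) places the *fitted* log10(K/g) of the resulting
#: curve: the ranges below were calibrated by forward-mapping noiseless
#: regime-pure average profiles through that transform so each regime
#: reproduces one of the three observed fitted groups (r < -1.3,
#: -0.6 < r < 0.1, r > 0.4).  Self-standardization of 24 replicates
#: compresses heavy tails, so the generating K/g and f/g of the upper
#: regimes sit well above the fitted thresholds; f/g is co-scaled with
#: K/g (the two are strongly positively correlated in fits), and the
#: mean drive g is higher for Gaussian-regime genes, mirroring the
#: association of Gaussian profiles with high average expression.
DEFAULT_REGIME_PRIORS: dict[str, dict] = {
    "gaussian": {"K_over_g": (0.0, 0.05), "f_over_g": (0.2, 0.6),
                 "g": (50.0, 2000.0)},
    "intermediate": {"K_over_g": (1.0, 2.0), "f_over_K": (2.0, 3.0),
                     "g": (20.0, 1000.0)},
    "power": {"K_over_g": (10.0, 60.0), "f_over_K": (2.0, 3.0),
              "g": (10.0, 500.0)},
}


@dataclass(frozen=True)
class SDEParams:
    """Langevin model parameters (rates in units of 1/time)."""

    G: float
    C: float
    F: float = 0.0
    K: float = 0.0
    D: float = 0.0

    def __post_init__(self) -> None:
        vals = (self.G, self.C, self.F, self.K, self.D)
        if not all(math.isfinite(v) for v in vals):
            raise ValueError(f"SDE parameters must be finite, got {vals}")
        if self.C <= 0:
            raise ValueError(f"degradation rate C must be > 0, got {self.C}")
        if min(self.G, self.F, self.K, self.D) < 0:
            raise ValueError("G, F, K, D must be >= 0")

    @property
    def g(self) -> float:
        return self.G / self.C

    @property
    def f(self) -> float:
        return self.F / self.C

    def stationary_gp(self) -> GPParams:
        """G-P parameters of the D/C -> 0 stationary law."""
        return GPParams(g=self.g, f=self.f, K=self.K)


def _heun_steps(x: np.ndarray, params: SDEParams, dt: float, n_steps: int,
                rng: np.random.Generator, floor: float) -> np.ndarray:
    """Advance all chains n_steps with the Stratonovich Heun scheme."""
    G, C, F, K, D = params.G, params.C, params.F, params.K, params.D
    sqdt = math.sqrt(dt)
    add_amp = math.sqrt(2.0 * D)
    mul_amp = math.sqrt(2.0) * F
    for step in range(n_steps):
        dw_add = rng.standard_normal(x.shape) * sqdt
        dw_mul = rng.standard_normal(x.shape) * sqdt
        drift = G - C * x
        diff = mul_amp * x / (K + x)
        xp = x + drift * dt + add_amp * dw_add + diff * dw_mul
        xp = np.abs(xp - floor) + floor
        drift_p = G - C * xp
        diff_p = mul_amp * xp / (K + xp)
        x = (x + 0.5 * (drift + drift_p) * dt + add_amp * dw_add
             + 0.5 * (diff + diff_p) * dw_mul)
        x = np.abs(x - floor) + floor
        if not np.all(np.isfinite(x)):
            raise FloatingPointError(
                f"trajectory diverged (non-finite x) at step {step}")
    return x


def simulate_stationary(params: SDEParams, dt: float, burn_in: float,
                        n_samples: int, spacing: float, seed: int,
                        n_chains: int | None = None) -> np.ndarray:
    """Draw approximately independent stationary samples of the SDE.

    Many independent chains are integrated in parallel; after ``burn_in``
    time units each chain is sampled every ``spacing`` time units until
    ``n_samples`` values are collected.  ``spacing`` should be a few
    relaxation times 1/C.  x is kept positive by reflection at a floor
    eps = 1e-6 * g (the stationary density vanishes at 0 for K > 0).
    """
    if dt <= 0:
        raise ValueError(f"dt must be > 0, got {dt}")
    if n_samples <= 0:
        raise ValueError(f"n_samples must be >= 1, got {n_samples}")
    if burn_in < 0 or spacing <= 0:
        raise ValueError("burn_in must be >= 0 and spacing > 0")
    if n_chains is None:
        n_chains = min(n_samples, 2048)
    per_chain = -(-n_samples // n_chains)  # ceil
    rng = np.random.default_rng(seed)
    floor = 1e-6 * max(params.g, 1e-12)
    x = np.full(n_chains, max(params.g, floor), dtype=float)
    x = _heun_steps(x, params, dt, max(1, round(burn_in / dt)), rng, floor)
    spacing_steps = max(1, round(spacing / dt))
    out = np.empty((per_chain, n_chains), dtype=float)
    for i in range(per_chain):
        x = _heun_steps(x, params, dt, spacing_steps, rng, floor)
        out[i] = x
    return out.ravel()[:n_samples]


def simulate_trajectory(params: SDEParams, dt: float, n_steps: int,
                        seed: int, x0: float | None = None):
    """Single trajectory; returns (times, x) with x recorded every step."""
    if dt <= 0:
        raise ValueError(f"dt must be > 0, got {dt}")
    rng = np.random.default_rng(seed)
    floor = 1e-6 * max(params.g, 1e-12)
    x = np.array([params.g if x0 is None else float(x0)])
    xs = np.empty(n_steps + 1)
    xs[0] = x[0]
    for i in range(n_steps):
        x = _heun_steps(x, params, dt, 1, rng, floor)
        xs[i + 1] = x[0]
    return np.arange(n_steps + 1) * dt, xs


# ---------------------------------------------------------------------------
# Synthetic cohorts


@dataclass(frozen=True)
class CohortSpec:
    """Design of a synthetic replicate-expression cohort.

    conditions : list of (age_days, time_h, n_replicates) triples
    class_mix : proportions of (gaussian, intermediate, power) regime genes
    drift_fraction : fraction of genes given a monotone harvest-order trend
    drift_sd_multiple : early-vs-late mean offset of drifted genes, in
        units of the gene's stationary SD (4 makes the trend unambiguous)
    """

    n_genes: int = 1000
    conditions: tuple = (
        (7, 1, 21), (7, 7, 21), (7, 13, 25), (7, 19, 24),
        (22, 1, 22), (22, 7, 24), (22, 13, 24), (22, 19, 27),
    )
    class_mix: tuple = (0.44, 0.26, 0.30)
    drift_fraction: float = 0.0
    drift_sd_multiple: float = 4.0
    priors: dict = field(default_factory=lambda: DEFAULT_REGIME_PRIORS)
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_genes < 1:
            raise ValueError("n_genes must be >= 1")
        if len(self.conditions) == 0:
            raise ValueError("at least one condition is required")
        for cond in self.conditions:
            if len(cond) != 3 or cond[2] < 2:
                raise ValueError(f"bad condition {cond}: need >= 2 replicates")
        if abs(sum(self.class_mix) - 1.0) > 1e-9 or min(self.class_mix) < 0:
            raise ValueError("class_mix must be nonnegative and sum to 1")
        if not 0.0 <= self.drift_fraction <= 1.0:
            raise ValueError("drift_fraction must be in [0, 1]")


@dataclass
class Cohort:
    """Generated cohort: expression matrix plus metadata and ground truth."""

    matrix: pd.DataFrame        # genes x samples
    metadata: pd.DataFrame      # sample_id, age_days, time_h, harvest_order
    annotation: pd.DataFrame    # gene_id, category, essential
    truth: pd.DataFrame         # gene_id, regime, g, f, K, drift

    def write(self, outdir) -> None:
        from pathlib import Path
        outdir = Path(outdir)
        outdir.mkdir(parents=True, exist_ok=True)
        self.matrix.to_csv(outdir / "matrix.tsv", sep="\t",
                           index_label="gene_id")
        self.metadata.to_csv(outdir / "metadata.tsv", sep="\t", index=False)
        self.annotation.to_csv(outdir / "annotation.tsv", sep="\t",
                               index=False)
        self.truth.to_csv(outdir / "truth.tsv", sep="\t", index=False)


_CATEGORIES = ("transcription_factor", "nucleic_acid_binding", "mitochondria",
               "plastid", "ribosome", "cytosol", "other")
# Gaussian-regime genes lean toward housekeeping categories and the
# essential flag; power-regime genes toward regulatory categories.
_CATEGORY_WEIGHTS = {
    "gaussian": (0.04, 0.05, 0.10, 0.18, 0.15, 0.18, 0.30),
    "intermediate": (0.10, 0.12, 0.12, 0.12, 0.10, 0.14, 0.30),
    "power": (0.20, 0.20, 0.12, 0.06, 0.05, 0.07, 0.30),
}
_ESSENTIAL_P = {"gaussian": 0.35, "intermediate": 0.15, "power": 0.08}


def _draw_gene_params(regime: str, priors: dict,
                      rng: np.random.Generator) -> GPParams:
    pr = priors[regime]
    g = math.exp(rng.uniform(math.log(pr["g"][0]), math.log(pr["g"][1])))
    lo, hi = pr["K_over_g"]
    if lo > 0:
        K_over_g = math.exp(rng.uniform(math.log(lo), math.log(hi)))
    else:
        K_over_g = rng.uniform(lo, hi)
    if "f_over_K" in pr:
        f = K_over_g * g * rng.uniform(*pr["f_over_K"])
    else:
        f = g * rng.uniform(*pr["f_over_g"])
    return GPParams(g=g, f=f, K=K_over_g * g)


def generate_cohort(spec: CohortSpec) -> Cohort:
    """Generate a cohort from the stationary Gauss-power law per gene.

    Each gene gets one (g, f, K) triple drawn from its regime's prior and
    shared across conditions; replicate values are i.i.d. stationary draws.
    Drifted genes additionally receive a linear trend across harvest order
    whose early-half/late-half mean difference is ``drift_sd_multiple``
    stationary SDs.  Fully deterministic given ``spec.seed``.
    """
    ss = np.random.SeedSequence(spec.seed)
    rng = np.random.default_rng(ss.spawn(1)[0])
    n = spec.n_genes
    regimes = rng.choice(len(REGIMES), size=n, p=np.asarray(spec.class_mix))
    drift = rng.uniform(size=n) < spec.drift_fraction
    gene_ids = [f"G{i:05d}" for i in range(n)]

    sample_rows = []
    for age, time_h, reps in spec.conditions:
        for r in range(reps):
            sample_rows.append({
                "sample_id": f"A{age:02d}T{time_h:02d}R{r + 1:02d}",
                "age_days": age, "time_h": time_h, "harvest_order": r + 1,
            })
    metadata = pd.DataFrame(sample_rows)
    n_total = len(metadata)
    rep_counts = [c[2] for c in spec.conditions]

    gene_seeds = ss.generate_state(2 * n, dtype=np.uint32)
    values = np.empty((n, n_total))
    truth_rows = []
    ann_rows = []
    for i in range(n):
        regime = REGIMES[regimes[i]]
        prng = np.random.default_rng(int(gene_seeds[2 * i]))
        params = _draw_gene_params(regime, spec.priors, prng)
        draws = gp_sample(params, n_total, seed=int(gene_seeds[2 * i + 1]),
                          grid_size=2048)
        if drift[i]:
            # per-condition linear ramp over harvest order
            pos = 0
            for reps in rep_counts:
                block = draws[pos:pos + reps]
                sd = block.std(ddof=1)
                ramp = np.linspace(-0.5, 0.5, reps) * (
                    2.0 * spec.drift_sd_multiple * sd)
                draws[pos:pos + reps] = np.maximum(block + ramp, 0.0)
                pos += reps
        values[i] = draws
        truth_rows.append({
            "gene_id": gene_ids[i], "regime": regime, "g": params.g,
            "f": params.f, "K": params.K,
            "log10_K_over_g": (math.log10(params.K / params.g)
                               if params.K > 0 else -np.inf),
            "drift": bool(drift[i]),
        })
        ann_rows.append({
            "gene_id": gene_ids[i],
            "category": prng.choice(_CATEGORIES,
                                    p=_CATEGORY_WEIGHTS[regime]),
            "essential": bool(prng.uniform() < _ESSENTIAL_P[regime]),
        })

    matrix = pd.DataFrame(values, index=pd.Index(gene_ids, name="gene_id"),
                          columns=metadata["sample_id"].to_numpy())
    return Cohort(matrix=matrix, metadata=metadata,
                  annotation=pd.DataFrame(ann_rows),
                  truth=pd.DataFrame(truth_rows))
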