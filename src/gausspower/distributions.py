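"""Gauss-power (G-P) mixing distribution and generalized negative binomial.

The G-P density is the stationary law of a gene whose expression level
``x`` relaxes at rate ``C`` toward a mean drive ``G`` while being kicked by
multiplicative feedback noise of magnitude ``F`` saturating at level ``K``
(a Michaelis-Menten-shaped term).  After rescaling time by the degradation
rate (``g = G/C``, ``f = F/C``) the density reads

    P(x) = A * (K + x) / (f x) * x**((2 g K - K^2) / f^2)
           * exp(-(1/f^2) * (g K^2 / x + (2 K - g) x + x^2 / 2)),   x > 0

with ``A`` fixed by normalization.  For ``K = 0`` this collapses to a
normal(g, f) density truncated to the positive half-line; for ``K >> g``
(with ``f`` co-scaled) a power-law-like region ``P ~ x^-2`` opens between
``x = g`` and ``x = K``.

The competing fit is a continuous gamma-function extension of the negative
binomial,

    N(x) = B * Gamma(s x + k + 1) / (Gamma(k) Gamma(s x + 1))
           * Q^k * (1 - Q)^(s x),   x >= 0,

with scale ``s``, shape ``k``, success probability ``Q`` and normalization
``B``.  Note the ``+1`` in the numerator gamma: at ``s = 1`` and integer
``x`` this equals ``(x + k)`` times the textbook NB pmf, so it is *not* a
reparametrized NB pmf.  It is evaluated as written; set
``textbook_numerator=True`` on :class:`NBParams` for the ``Gamma(s x + k)``
variant in sensitivity checks.

All gamma and density evaluations run in log space.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, replace

import numpy as np
from scipy import integrate
from scipy.special import gammaln, log_ndtr, ndtr

__all__ = [
    "GPParams",
    "NBParams",
    "gp_logpdf_unnorm",
    "gp_density_unnormalized",
    "gp_normalize",
    "gp_density",
    "gp_support_grid",
    "gp_cdf_grid",
    "gp_sample",
    "truncnorm_logpdf",
    "nb_logpdf_unnorm",
    "nb_density",
    "nb_normalize",
]


@dataclass(frozen=True)
class GPParams:
    """Parameters of the Gauss-power mixing density.

    g : mean drive level (activation rate over degradation rate), > 0
    f : feedback noise strength over degradation rate, > 0
    K : feedback half-saturation level, >= 0
    A : normalization coefficient; None until :func:`gp_normalize` sets it
    """

    g: float
    f: float
    K: float
    A: float | None = None

    def __post_init__(self) -> None:
        for name in ("g", "f", "K"):
            v = getattr(self, name)
            if not math.isfinite(v):
                raise ValueError(f"GPParams.{name} must be finite, got {v!r}")
        if self.g <= 0:
            raise ValueError(f"g must be > 0, got {self.g}")
        if self.f <= 0:
            raise ValueError(f"f must be > 0, got {self.f}")
        if self.K < 0:
            raise ValueError(f"K must be >= 0, got {self.K}")
        if self.A is not None and not (self.A > 0 and math.isfinite(self.A)):
            raise ValueError(f"A must be positive and finite, got {self.A}")

    def to_dict(self) -> dict:
        return {"g": self.g, "f": self.f, "K": self.K, "A": self.A}


@dataclass(frozen=True)
class NBParams:
    """Parameters of the generalized negative binomial density.

    s : scale, > 0; k : shape, > 0; Q : success probability in (0, 1);
    B : normalization coefficient (None until computed).
    """

    s: float
    k: float
    Q: float
    B: float | None = None
    textbook_numerator: bool = False

    def __post_init__(self) -> None:
        if not (self.s > 0 and math.isfinite(self.s)):
            raise ValueError(f"s must be > 0, got {self.s}")
        if not (self.k > 0 and math.isfinite(self.k)):
            raise ValueError(f"k must be > 0, got {self.k}")
        if not (0 < self.Q < 1):
            raise ValueError(f"Q must be in (0, 1), got {self.Q}")
        if self.B is not None and not (self.B > 0 and math.isfinite(self.B)):
            raise ValueError(f"B must be positive and finite, got {self.B}")

    def to_dict(self) -> dict:
        return {"s": self.s, "k": self.k, "Q": self.Q, "B": self.B}


# ---------------------------------------------------------------------------
# G-P density


def gp_logpdf_unnorm(x, params: GPParams):
    """Log of the unnormalized G-P density (A = 1) at x > 0."""
    x = np.asarray(x, dtype=float)
    if np.any(x <= 0):
        raise ValueError("gp density requires x > 0")
    g, f, K = params.g, params.f, params.K
    f2 = f * f
    return (
        np.log(K + x)
        - np.log(f * x)
        + ((2.0 * g * K - K * K) / f2) * np.log(x)
        - (g * K * K / x + (2.0 * K - g) * x + 0.5 * x * x) / f2
    )


def gp_density_unnormalized(x, params: GPParams):
    """Unnormalized G-P density (A = 1); scalar in, scalar out."""
    out = np.exp(gp_logpdf_unnorm(x, params))
    if np.isscalar(x) or np.ndim(x) == 0:
        return float(out)
    return out


def _log_mode_height(params: GPParams) -> float:
    """Max of the unnormalized log density on a coarse bracketing grid."""
    g, f, K = params.g, params.f, params.K
    hi = g + 2.0 * K + 10.0 * f
    lo = min(g, f, K if K > 0 else g) * 1e-8 + 1e-300
    grid = np.geomspace(max(lo, 1e-12), hi, 512)
    return float(np.max(gp_logpdf_unnorm(grid, params)))


def gp_support_grid(params: GPParams, n: int = 4096, tail_tol: float = 1e-12):
    """Grid covering essentially all probability mass of the G-P density.

    The upper end is extended until the local density has fallen
    ``tail_tol`` below the modal height (the x^2/2 term guarantees this
    terminates); the lower end goes deep enough into the x -> 0 cutoff.
    """
    g, f, K = params.g, params.f, params.K
    log_peak = _log_mode_height(params)
    log_tol = math.log(tail_tol)
    hi = g + 2.0 * K + 10.0 * f
    while float(gp_logpdf_unnorm(hi, params)) - log_peak > log_tol:
        hi *= 1.5
    if K > 0:
        # exp(-gK^2/(f^2 x)) kills the density as x -> 0; walk down to it
        lo = min(g, K) * 1e-2
        while (float(gp_logpdf_unnorm(lo, params)) - log_peak > log_tol
               and lo > hi * 1e-15):
            lo /= 4.0
    else:
        lo = hi * 1e-12
    # log-spaced through the cutoff + linear through the bulk
    n_geo = n // 2
    grid = np.unique(np.concatenate([
        np.geomspace(lo, hi, n_geo),
        np.linspace(lo, hi, n - n_geo),
    ]))
    return grid


def gp_normalize(params: GPParams, upper_limit: float | None = None,
                 tol: float = 1e-10) -> GPParams:
    """Return params with A set so the density integrates to 1 on (0, inf).

    Adaptive quadrature on a shifted log scale; the integration window is
    widened automatically until the truncated tail is below ``tol``.
    Falls back to dense trapezoid integration if quad fails to converge.
    """
    if tol <= 0:
        raise ValueError("tol must be > 0")
    grid = gp_support_grid(params, tail_tol=min(tol * 1e-3, 1e-12))
    lo, hi = float(grid[0]), float(grid[-1])
    if upper_limit is not None:
        if upper_limit <= 0:
            raise ValueError("upper_limit must be > 0")
        hi = max(hi, float(upper_limit))
    log_peak = _log_mode_height(params)

    def integrand(x):
        return np.exp(gp_logpdf_unnorm(x, params) - log_peak)

    mode_x = float(grid[np.argmax(gp_logpdf_unnorm(grid, params))])
    pts = sorted({min(mode_x, hi * 0.99), min(params.g + params.K, hi * 0.99)})
    try:
        val, err = integrate.quad(integrand, lo, hi, points=pts,
                                  limit=400, epsabs=0.0, epsrel=min(tol, 1e-10))
        ok = np.isfinite(val) and val > 0 and err < 100 * tol * val
    except Exception:  # pragma: no cover - quad failure path
        ok = False
    if not ok:
        y = np.exp(gp_logpdf_unnorm(grid, params) - log_peak)
        val = float(np.trapezoid(y, grid))
        if not (np.isfinite(val) and val > 0):
            raise FloatingPointError(
                f"G-P normalization failed for {params}: integral={val!r}")
    A = math.exp(-log_peak) / val
    return replace(params, A=A)


def gp_density(x, params: GPParams):
    """Normalized G-P density; requires A (see :func:`gp_normalize`)."""
    if params.A is None:
        raise ValueError("params.A unset; call gp_normalize first")
    out = params.A * np.exp(gp_logpdf_unnorm(x, params))
    if np.isscalar(x) or np.ndim(x) == 0:
        return float(out)
    return out


def gp_cdf_grid(params: GPParams, n: int = 8192):
    """(x, F(x)) on a dense grid by cumulative trapezoid quadrature.

    The returned CDF is exact to the grid's discretization error and is the
    oracle used for Kolmogorov-Smirnov checks and inverse-CDF sampling.
    """
    if params.A is None:
        params = gp_normalize(params)
    x = gp_support_grid(params, n=n)
    pdf = gp_density(x, params)
    cdf = integrate.cumulative_trapezoid(pdf, x, initial=0.0)
    cdf /= cdf[-1]
    return x, cdf


def gp_sample(params: GPParams, n: int, seed: int,
              grid_size: int = 8192) -> np.ndarray:
    """Draw n i.i.d. values from the G-P law by inverse-CDF on a fine grid."""
    if n <= 0:
        raise ValueError(f"n must be >= 1, got {n}")
    x, cdf = gp_cdf_grid(params, n=grid_size)
    # strictly increasing knots for interpolation
    keep = np.concatenate([[True], np.diff(cdf) > 0])
    rng = np.random.default_rng(seed)
    u = rng.uniform(0.0, 1.0, size=n)
    return np.interp(u, cdf[keep], x[keep])


def truncnorm_logpdf(x, g: float, f: float):
    """Log density of normal(g, f) truncated to x > 0 (K = 0 closed form)."""
    x = np.asarray(x, dtype=float)
    z = (x - g) / f
    return (-0.5 * z * z - 0.5 * math.log(2.0 * math.pi) - math.log(f)
            - log_ndtr(g / f))


def truncnorm_mean(g: float, f: float) -> float:
    """Mean of normal(g, f) truncated to x > 0."""
    a = g / f
    phi = math.exp(-0.5 * a * a) / math.sqrt(2.0 * math.pi)
    return g + f * phi / ndtr(a)


# ---------------------------------------------------------------------------
# Generalized negative binomial


def nb_logpdf_unnorm(x, params: NBParams):
    """Log of the unnormalized generalized NB density (B = 1) at x >= 0."""
    x = np.asarray(x, dtype=float)
    if np.any(x < 0):
        raise ValueError("nb density requires x >= 0")
    s, k, Q = params.s, params.k, params.Q
    sx = s * x
    top = sx + k if params.textbook_numerator else sx + k + 1.0
    out = (gammaln(top) - gammaln(k) - gammaln(sx + 1.0)
           + k * math.log(Q) + sx * math.log1p(-Q))
    if not np.all(np.isfinite(out)):
        raise FloatingPointError(f"non-finite NB log density for {params}")
    return out


def nb_density(x, params: NBParams):
    """Generalized NB density; uses B if set, else B = 1."""
    B = 1.0 if params.B is None else params.B
    out = B * np.exp(nb_logpdf_unnorm(x, params))
    if np.isscalar(x) or np.ndim(x) == 0:
        return float(out)
    return out


def nb_normalize(params: NBParams, support: np.ndarray) -> NBParams:
    """Set B by trapezoid normalization over the given support grid.

    Mirrors the numeric normalization of A: both families are normalized
    over the same support used for fitting.
    """
    support = np.asarray(support, dtype=float)
    if support.ndim != 1 or support.size < 2:
        raise ValueError("support must be a 1-D grid with >= 2 points")
    logp = nb_logpdf_unnorm(support, params)
    m = float(np.max(logp))
    val = float(np.trapezoid(np.exp(logp - m), support))
    if not (np.isfinite(val) and val > 0):
        raise FloatingPointError(f"NB normalization failed for {params}")
    return replace(params, B=math.exp(-m) / val)
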