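import numpy as np
import pytest

from gausspower.distributions import (GPParams, gp_cdf_grid, gp_density,
                                      gp_normalize, gp_support_grid)
from gausspower.fit import EPDFCurve


def curve_from_gp_density(params: GPParams, n_grid: int = 100,
                          q=(0.001, 0.999)) -> EPDFCurve:
    """Noiseless ePDF curve tabulated from a normalized G-P density."""
    from scipy.integrate import cumulative_trapezoid
    p = gp_normalize(params)
    sup = gp_support_grid(p)
    pdf = gp_density(sup, p)
    cdf = cumulative_trapezoid(pdf, sup, initial=0.0)
    cdf /= cdf[-1]
    grid = np.linspace(np.interp(q[0], cdf, sup),
                       np.interp(q[1], cdf, sup), n_grid)
    dens = gp_density(grid, p)
    return EPDFCurve(x=grid, density=dens / np.trapezoid(dens, grid))


@pytest.fixture(scope="session")
def gp_ks_oracle():
    """KS distance of a sample against the quadrature CDF of a G-P law."""
    def _ks(sample, params: GPParams) -> float:
        x, cdf = gp_cdf_grid(gp_normalize(params))
        F = np.interp(np.sort(sample), x, cdf)
        n = len(sample)
        up = np.max(np.abs(F - np.arange(1, n + 1) / n))
        lo = np.max(np.abs(F - np.arange(n) / n))
        return float(max(up, lo))
    return _ks


@pytest.fixture(scope="session")
def small_cohort():
    """One-condition cohort shared by preprocess/pipeline tests."""
    from gausspower.simulate import CohortSpec, generate_cohort
    spec = CohortSpec(n_genes=120, conditions=((7, 13, 24),),
                      class_mix=(0.4, 0.3, 0.3), drift_fraction=0.2,
                      seed=123)
    return spec, generate_cohort(spec)
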