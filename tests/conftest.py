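"""Shared fixtures and independent oracles for the test suite."""
from __future__ import annotations

import numpy as np
import pytest
from scipy import integrate, stats

from uratetrial import config as config_mod
from uratetrial.bayes import BetaDistribution, TrialData
from uratetrial.trial import ArmRegimen, TrialDesign


@pytest.fixture(scope="session")
def default_model():
    return config_mod.default_population_model()


@pytest.fixture(scope="session")
def default_config():
    return config_mod.generate_default_config(20_201_231)


@pytest.fixture()
def short_design():
    """A cheap 28-day variant of the first candidate design."""
    return TrialDesign(
        design_id="psi1_short",
        scenario="base_case",
        arms=(ArmRegimen("allopurinol", 300.0), ArmRegimen("febuxostat", 80.0)),
        duration=28,
        inclusion_threshold=6.0,
    )


def grid_posterior_moments(
    prior: BetaDistribution, data: TrialData, n_grid: int = 2001
) -> tuple[float, float, float]:
    """Brute-force posterior mean and 2.5/97.5% quantiles on a theta grid.

    Normalises likelihood x prior density on ``n_grid`` equispaced points and
    integrates numerically; independent of the conjugate closed form it is
    used to check.
    """
    theta = np.linspace(0.0, 1.0, n_grid)
    log_post = stats.beta.logpdf(theta, prior.alpha, prior.beta) + stats.binom.logpmf(
        data.m, data.n, theta
    )
    with np.errstate(invalid="ignore"):
        dens = np.exp(log_post - np.nanmax(log_post[np.isfinite(log_post)]))
    dens[~np.isfinite(dens)] = 0.0
    norm = integrate.simpson(dens, x=theta)
    dens /= norm
    mean = float(integrate.simpson(dens * theta, x=theta))
    cdf = integrate.cumulative_trapezoid(dens, theta, initial=0.0)
    cdf /= cdf[-1]
    q_lo = float(np.interp(0.025, cdf, theta))
    q_hi = float(np.interp(0.975, cdf, theta))
    return mean, q_lo, q_hi
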