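"""Company return on investment and optimal sample-size selection.

For a candidate design and per-arm sample size ``n``, future trial data are
drawn from the prior predictive (theta from the CTS prior, responders from
the binomial likelihood), the posteriors are formed by conjugate updating,
the economic model converts the posterior response rates into a maximum
reimbursement price, and ROI follows the payoff rule: revenue at the
reimbursed price net of production/marketing and trial costs, or zero if the
price falls below the company's minimum and development is terminated.  The
optimal ``n`` maximises the Monte Carlo mean ROI (ties go to the smaller,
cheaper trial).
"""
from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from . import econ
from .bayes import BetaDistribution, SampleSizeGrid
from .econ import MarkovSpec
from .pkpd import InvalidInputError
from .trial import TrialDesign

__all__ = [
    "ROIInputs",
    "MarketModel",
    "ROITable",
    "market_size",
    "trial_cost",
    "roi_single",
    "expected_roi",
]


@dataclass(frozen=True)
class ROIInputs:
    """Payoff-model inputs: trial costs, unit economics, and the minimum price."""

    trial_fixed_cost: float = 5_000_000.0
    trial_variable_cost: float = 20_000.0  # GBP per enrolled subject
    production_marketing: float = 10.0  # GBP per patient-year
    minimum_price: float = 70.0  # GBP per patient-year

    def __post_init__(self) -> None:
        for name in ("trial_fixed_cost", "trial_variable_cost",
                     "production_marketing", "minimum_price"):
            val = getattr(self, name)
            if not (np.isfinite(val) and val >= 0):
                raise InvalidInputError(f"{name} must be non-negative, got {val!r}")


@dataclass(frozen=True)
class MarketModel:
    """Eligible market: annual incidence, uptake, horizon, and the halving rule.

    ``halve_at_threshold_8`` halves the eligible incidence for designs whose
    treatment threshold is 8 mg/dL (a stricter treatment population).
    """

    annual_incidence: float = 15_000.0
    horizon_years: float = 10.0
    uptake: float = 0.5
    halve_at_threshold_8: bool = True

    def __post_init__(self) -> None:
        if self.annual_incidence < 0 or self.horizon_years < 0:
            raise InvalidInputError("incidence and horizon must be non-negative")
        if not 0 <= self.uptake <= 1:
            raise InvalidInputError("uptake must lie in [0, 1]")


@dataclass
class ROITable:
    """Decision surface: expected ROI per (design, per-arm n)."""

    design_id: str
    scenario: str
    sizes: tuple[int, ...]
    expected: np.ndarray
    p_termination: np.ndarray
    optimal_n: int

    def to_dataframe(self) -> pd.DataFrame:
        return pd.DataFrame(
            {
                "design": self.design_id,
                "scenario": self.scenario,
                "n_per_arm": list(self.sizes),
                "expected_roi": self.expected,
                "p_termination": self.p_termination,
                "optimal": [s == self.optimal_n for s in self.sizes],
            }
        )


def market_size(market: MarketModel, inclusion_threshold: float) -> float:
    """Patients receiving the new drug over the horizon: incidence x uptake x H.

    Halved when the treatment threshold is 8 mg/dL and the halving rule is on.
    """
    s = market.annual_incidence * market.uptake * market.horizon_years
    if market.halve_at_threshold_8 and inclusion_threshold >= 8.0:
        s *= 0.5
    return s


def trial_cost(total_n: int, inputs: ROIInputs) -> float:
    """Fixed cost plus per-subject variable cost for ``total_n`` enrolled subjects."""
    if total_n < 0:
        raise InvalidInputError("total_n must be non-negative")
    return inputs.trial_fixed_cost + inputs.trial_variable_cost * total_n


def roi_single(
    p2: float, t2: float, s: float, ctrial: float, inputs: ROIInputs
) -> float:
    """Payoff for one realised price: revenue branch if p2 >= minimum price, else 0."""
    if p2 >= inputs.minimum_price:
        return (p2 - inputs.production_marketing) * t2 * s - ctrial
    return 0.0


def _posterior_means(
    prior: BetaDistribution, theta: np.ndarray, n: int, rng: np.random.Generator
) -> tuple[np.ndarray, np.ndarray]:
    m = rng.binomial(n, theta)
    post_mean = (prior.alpha + m) / (prior.alpha + prior.beta + n)
    return m, post_mean


def expected_roi(
    design: TrialDesign,
    priors: tuple[BetaDistribution, BetaDistribution],
    grid: SampleSizeGrid,
    r_replicates: int,
    seed,
    econ_spec: MarkovSpec,
    market: MarketModel,
    inputs: ROIInputs,
    lam: float = 20_000.0,
    posterior_point: str = "mean",
) -> ROITable:
    """Monte Carlo expected ROI over the preposterior distribution, per grid size.

    Each replicate draws (theta_j, m_j) for both arms from the prior
    predictive, performs the conjugate update, maps the posterior point
    estimates through the economic model to a maximum reimbursement price,
    and applies the payoff rule.  ``posterior_point`` selects whether the
    posterior mean (default: expected-value payer) or a posterior draw (an
    uncertainty-propagating payer) enters the economic model.
    """
    if r_replicates < 1:
        raise InvalidInputError("r_replicates must be positive")
    if posterior_point not in ("mean", "draw"):
        raise InvalidInputError("posterior_point must be 'mean' or 'draw'")
    prior_soc, prior_new = priors

    q_soc_basis, c_soc_basis = econ._state_values(econ_spec, include_soc_drug=True)
    q_new_basis, c_new_basis = econ._state_values(econ_spec, include_soc_drug=False)
    t2 = econ.expected_persistence(
        econ_spec.dropout_shape,
        econ_spec.dropout_scale_days,
        econ_spec.horizon_years,
        econ_spec.discount_rate,
    )
    s_market = market_size(market, design.inclusion_threshold)

    master = (
        seed
        if isinstance(seed, np.random.SeedSequence)
        else np.random.SeedSequence(seed)
    )
    children = master.spawn(len(grid))

    sizes = tuple(grid)
    expected = np.empty(len(sizes))
    p_term = np.empty(len(sizes))
    for i, n in enumerate(sizes):
        rng = np.random.default_rng(children[i])
        theta1 = rng.beta(prior_soc.alpha, prior_soc.beta, size=r_replicates)
        m1, pm1 = _posterior_means(prior_soc, theta1, n, rng)
        theta2 = rng.beta(prior_new.alpha, prior_new.beta, size=r_replicates)
        m2, pm2 = _posterior_means(prior_new, theta2, n, rng)
        if posterior_point == "draw":
            pm1 = rng.beta(prior_soc.alpha + m1, prior_soc.beta + n - m1)
            pm2 = rng.beta(prior_new.alpha + m2, prior_new.beta + n - m2)
        split = econ_spec.nonresponder_split
        start1 = _start_matrix(pm1, split)
        start2 = _start_matrix(pm2, split)
        q1 = start1 @ q_soc_basis
        c1 = start1 @ c_soc_basis
        q2 = start2 @ q_new_basis
        c2_nd = start2 @ c_new_basis
        p2 = (c1 - c2_nd + lam * (q2 - q1)) / t2
        ctrial = trial_cost(2 * n, inputs)
        go = p2 >= inputs.minimum_price
        payoff = np.where(
            go, (p2 - inputs.production_marketing) * t2 * s_market - ctrial, 0.0
        )
        expected[i] = payoff.mean()
        p_term[i] = 1.0 - go.mean()

    optimal_idx = int(np.argmax(expected))  # first max: smallest n wins ties
    return ROITable(
        design_id=design.design_id,
        scenario=design.scenario,
        sizes=sizes,
        expected=expected,
        p_termination=p_term,
        optimal_n=sizes[optimal_idx],
    )


def _start_matrix(theta: np.ndarray, split: float) -> np.ndarray:
    rest = 1.0 - theta
    return np.column_stack(
        [theta, rest * split, rest * (1.0 - split), np.zeros_like(theta)]
    )
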