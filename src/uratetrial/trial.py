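"""Trial execution: cohorts, adherence, discontinuation, and the response endpoint.

A trial arm is simulated by (1) sampling subject attributes from the gout
population model, (2) applying the baseline-sUA inclusion threshold,
(3) drawing a daily dosing history under imperfect implementation and a
Weibull discontinuation hazard, and (4) running the PK/PD engine to the final
trough.  Subjects who discontinue revert to their baseline sUA.  The primary
endpoint is the proportion of subjects with final trough sUA strictly below
6 mg/dL.
"""
from __future__ import annotations

import warnings
from dataclasses import dataclass, field, replace
from functools import lru_cache
from typing import Mapping

import numpy as np
import pandas as pd_frame  # pandas; avoid clashing with PD params naming
from scipy.special import expit
from scipy.optimize import brentq

from . import pkpd
from .pkpd import (
    CovariateModel,
    DosingHistory,
    InvalidInputError,
    PDParams,
    PKParams,
    SubjectCovariates,
)

__all__ = [
    "RESPONSE_THRESHOLD",
    "ArmRegimen",
    "TrialDesign",
    "AdherenceParams",
    "PopulationSpec",
    "DrugModel",
    "PopulationModel",
    "Cohort",
    "ArmResult",
    "sample_population",
    "apply_inclusion",
    "sample_dosing_history",
    "simulate_arm",
    "response_rate",
]

#: Responder definition: final trough sUA strictly below this value (mg/dL).
RESPONSE_THRESHOLD = 6.0

BASE_CASE = "base_case"
REDUCED = "reduced"


@dataclass(frozen=True)
class ArmRegimen:
    drug: str
    dose: float  # mg once daily

    def __post_init__(self) -> None:
        if not self.drug:
            raise InvalidInputError("drug name must be non-empty")
        if not (np.isfinite(self.dose) and self.dose > 0):
            raise InvalidInputError(f"dose must be positive, got {self.dose!r}")


@dataclass(frozen=True)
class TrialDesign:
    """A two-arm design: regimens, duration, inclusion threshold, and scenario."""

    design_id: str
    scenario: str  # base_case | reduced (uncertainty scenario label)
    arms: tuple[ArmRegimen, ArmRegimen]
    duration: int = 182
    inclusion_threshold: float = 6.0

    def __post_init__(self) -> None:
        if self.scenario not in (BASE_CASE, REDUCED):
            raise InvalidInputError(f"unknown scenario {self.scenario!r}")
        if len(self.arms) != 2:
            raise InvalidInputError("a trial design must have exactly two arms")
        if not (isinstance(self.duration, int) and self.duration > 0):
            raise InvalidInputError("duration must be a positive integer (days)")
        if not (np.isfinite(self.inclusion_threshold) and self.inclusion_threshold > 0):
            raise InvalidInputError("inclusion_threshold must be positive")
        object.__setattr__(self, "arms", tuple(self.arms))


@dataclass(frozen=True)
class AdherenceParams:
    """Initiation, dose implementation, and Weibull discontinuation.

    Implementation probabilities are subject-specific, logit-normal with the
    location solved so the population mean equals ``implementation_mean``.
    The discontinuation hazard is Weibull with shape < 1 (falling risk); day
    ``d`` is the first day whose cumulative hazard ``(d / scale) ** shape``
    exceeds the subject's unit-exponential draw.
    """

    initiation_prob: float = 1.0
    implementation_mean: float = 0.9
    implementation_dispersion: float = 1.0  # logit-scale SD
    weibull_shape: float = 0.5
    weibull_scale: float = 2000.0  # days

    def __post_init__(self) -> None:
        for name in ("initiation_prob", "implementation_mean"):
            val = getattr(self, name)
            if not (np.isfinite(val) and 0 <= val <= 1):
                raise InvalidInputError(f"{name} must lie in [0, 1], got {val!r}")
        if self.implementation_dispersion < 0:
            raise InvalidInputError("implementation_dispersion must be non-negative")
        for name in ("weibull_shape", "weibull_scale"):
            val = getattr(self, name)
            if not (np.isfinite(val) and val > 0):
                raise InvalidInputError(f"{name} must be positive, got {val!r}")


@lru_cache(maxsize=None)
def _logit_location(mean: float, sigma: float) -> float:
    """Location mu such that E[expit(mu + sigma Z)] = mean for Z ~ N(0, 1)."""
    nodes, weights = np.polynomial.hermite_e.hermegauss(101)
    weights = weights / weights.sum()

    def expected(mu: float) -> float:
        return float(np.sum(weights * expit(mu + sigma * nodes))) - mean

    return brentq(expected, -60.0, 60.0, xtol=1e-12)


def _implementation_probabilities(adh: AdherenceParams, z: np.ndarray) -> np.ndarray:
    mean, sigma = adh.implementation_mean, adh.implementation_dispersion
    if mean >= 1.0 - 1e-12:
        return np.ones_like(z)
    if mean <= 1e-12:
        return np.zeros_like(z)
    if sigma == 0.0:
        return np.full_like(z, mean)
    return expit(_logit_location(mean, sigma) + sigma * z)


@dataclass(frozen=True)
class PopulationSpec:
    """Attribute distributions of the trial-eligible gout population.

    Baseline sUA and weight are lognormal (median, log-scale sigma); age is
    normal, clipped to a plausible adult range.  ``iiv`` maps PK/PD parameter
    names to lognormal interindividual variability (omega, SD of log).
    """

    baseline_sua_median: float = 8.6
    baseline_sua_sigma: float = 0.16
    weight_median: float = 85.0
    weight_sigma: float = 0.18
    age_mean: float = 52.0
    age_sd: float = 11.0
    age_min: float = 18.0
    age_max: float = 90.0
    iiv: Mapping[str, float] = field(
        default_factory=lambda: {
            "ka": 0.3, "cl": 0.25, "v1": 0.2, "ic50": 0.3, "clr_ua": 0.2,
        }
    )

    def __post_init__(self) -> None:
        for name in ("baseline_sua_median", "weight_median", "age_mean", "age_sd"):
            val = getattr(self, name)
            if not (np.isfinite(val) and val > 0):
                raise InvalidInputError(f"{name} must be positive, got {val!r}")
        for name in ("baseline_sua_sigma", "weight_sigma"):
            if getattr(self, name) < 0:
                raise InvalidInputError(f"{name} must be non-negative")
        for key, omega in self.iiv.items():
            if not (np.isfinite(omega) and omega >= 0):
                raise InvalidInputError(f"iiv[{key!r}] must be non-negative, got {omega!r}")
        object.__setattr__(self, "iiv", dict(self.iiv))


@dataclass(frozen=True)
class DrugModel:
    """One drug: linear PK plus its effect parameters on the urate chain."""

    pk: PKParams
    imax: float
    ic50: float
    emax_x: float = 0.0
    ec50_x: float = 1.0


@dataclass(frozen=True)
class PopulationModel:
    """Everything needed to simulate an arm: drugs, system PD, population, adherence.

    ``system`` holds the drug-free urate chain (its ``imax`` is zero); the
    active arm's drug effect fields are merged in at simulation time.
    """

    drugs: Mapping[str, DrugModel]
    system: PDParams
    population: PopulationSpec = PopulationSpec()
    adherence: AdherenceParams = AdherenceParams()
    covariates: CovariateModel = CovariateModel()

    def __post_init__(self) -> None:
        object.__setattr__(self, "drugs", dict(self.drugs))
        if not self.drugs:
            raise InvalidInputError("at least one drug model is required")

    def arm_pd(self, drug: str) -> PDParams:
        d = self.drugs[drug]
        return replace(
            self.system, imax=d.imax, ic50=d.ic50, emax_x=d.emax_x, ec50_x=d.ec50_x
        )


@dataclass
class Cohort:
    """A sampled trial cohort held as column arrays (one row per subject)."""

    baseline_sua: np.ndarray
    weight: np.ndarray
    age: np.ndarray
    p_implementation: np.ndarray
    eta: dict[str, np.ndarray]

    def __len__(self) -> int:
        return int(self.baseline_sua.size)

    def subject(self, i: int) -> SubjectCovariates:
        return SubjectCovariates(
            baseline_sua=float(self.baseline_sua[i]),
            weight=float(self.weight[i]),
            age=float(self.age[i]),
        )

    def select(self, mask: np.ndarray) -> "Cohort":
        return Cohort(
            baseline_sua=self.baseline_sua[mask],
            weight=self.weight[mask],
            age=self.age[mask],
            p_implementation=self.p_implementation[mask],
            eta={k: v[mask] for k, v in self.eta.items()},
        )

    def to_dataframe(self) -> "pd_frame.DataFrame":
        data = {
            "baseline_sua": self.baseline_sua,
            "weight": self.weight,
            "age": self.age,
            "p_implementation": self.p_implementation,
        }
        for key in sorted(self.eta):
            data[f"eta_{key}"] = self.eta[key]
        return pd_frame.DataFrame(data)


def _as_rng(seed) -> np.random.Generator:
    if isinstance(seed, np.random.Generator):
        return seed
    return np.random.default_rng(seed)


def sample_population(
    spec: PopulationSpec,
    adherence: AdherenceParams,
    n: int,
    seed,
) -> Cohort:
    """Sample ``n`` subjects: covariates, implementation probability, random effects.

    Draw order is fixed (baseline, weight, age, implementation, then etas in
    sorted parameter order), so results are reproducible for a given seed.
    """
    if n <= 0:
        raise InvalidInputError("n must be positive")
    rng = _as_rng(seed)
    baseline = spec.baseline_sua_median * np.exp(
        spec.baseline_sua_sigma * rng.standard_normal(n)
    )
    weight = spec.weight_median * np.exp(spec.weight_sigma * rng.standard_normal(n))
    age = np.clip(
        spec.age_mean + spec.age_sd * rng.standard_normal(n), spec.age_min, spec.age_max
    )
    p_impl = _implementation_probabilities(adherence, rng.standard_normal(n))
    eta = {
        key: spec.iiv[key] * rng.standard_normal(n) if spec.iiv[key] > 0 else np.zeros(n)
        for key in sorted(spec.iiv)
    }
    return Cohort(baseline, weight, age, p_impl, eta)


def apply_inclusion(cohort: Cohort, threshold: float) -> Cohort:
    """Retain subjects with baseline sUA strictly above ``threshold`` (mg/dL)."""
    if not (np.isfinite(threshold) and threshold >= 0):
        raise InvalidInputError("threshold must be non-negative")
    mask = cohort.baseline_sua > threshold
    if not mask.any():
        warnings.warn(
            f"inclusion threshold {threshold} mg/dL excluded every subject",
            stacklevel=2,
        )
    return cohort.select(mask)


def _sample_dropout_days(adh: AdherenceParams, n: int, rng: np.random.Generator) -> np.ndarray:
    """First discontinuation day (1-based); survival to day t is exp(-(t/scale)^shape)."""
    e = rng.exponential(size=n)
    days = np.ceil(adh.weibull_scale * e ** (1.0 / adh.weibull_shape))
    return np.minimum(days, 2**31 - 1).astype(np.int64)


def _sample_dosing_matrix(
    adh: AdherenceParams,
    p_implementation: np.ndarray,
    duration: int,
    rng: np.random.Generator,
) -> tuple[np.ndarray, np.ndarray]:
    """Per-day dose indicators (n, duration) and dropout days (n,)."""
    n = p_implementation.size
    dropout = _sample_dropout_days(adh, n, rng)
    u = rng.random((n, duration))
    taken = u < p_implementation[:, None]
    if adh.initiation_prob < 1.0:
        taken &= (rng.random(n) < adh.initiation_prob)[:, None]
    days = np.arange(duration)
    taken &= days[None, :] < dropout[:, None]
    return taken, dropout


def sample_dosing_history(
    adh: AdherenceParams,
    p_implementation: float,
    dose: float,
    duration: int,
    seed,
) -> DosingHistory:
    """Dosing history of a single subject (Bernoulli implementation up to dropout)."""
    if duration <= 0:
        raise InvalidInputError("duration must be positive")
    rng = _as_rng(seed)
    taken, dropout = _sample_dosing_matrix(adh, np.array([p_implementation]), duration, rng)
    d = int(dropout[0])
    return DosingHistory(
        dose_amount=dose,
        taken=taken[0].astype(np.int8),
        dropout_day=d if d < duration else None,
    )


@dataclass
class ArmResult:
    """Per-subject outcomes of one simulated arm."""

    baseline_sua: np.ndarray
    final_sua: np.ndarray
    responder: np.ndarray
    dropout_day: np.ndarray  # >= duration means the subject completed
    duration: int

    def __post_init__(self) -> None:
        n = self.final_sua.size
        if not (self.baseline_sua.size == self.responder.size == self.dropout_day.size == n):
            raise InvalidInputError("ArmResult arrays must have equal length")
        if not np.array_equal(self.responder, self.final_sua < RESPONSE_THRESHOLD):
            raise InvalidInputError("responder flags inconsistent with final sUA cutoff")

    @property
    def n(self) -> int:
        return int(self.final_sua.size)

    @property
    def dropped(self) -> np.ndarray:
        return self.dropout_day < self.duration

    def to_dataframe(self) -> "pd_frame.DataFrame":
        return pd_frame.DataFrame(
            {
                "baseline_sua": self.baseline_sua,
                "final_sua": self.final_sua,
                "responder": self.responder.astype(int),
                "dropout_day": np.where(self.dropped, self.dropout_day, -1),
            }
        )


def response_rate(result: ArmResult) -> float:
    """Proportion of subjects with final trough sUA < 6 mg/dL (strict)."""
    if result.n == 0:
        raise InvalidInputError("cannot compute a response rate for an empty arm")
    return float(result.responder.mean())


@dataclass
class _ArmTask:
    """Integration-ready inputs for one arm (dropouts already resolved)."""

    params: dict[str, np.ndarray]
    rates: np.ndarray
    coefs: np.ndarray
    taken: np.ndarray
    sim_index: np.ndarray
    baseline_sua: np.ndarray
    dropout_day: np.ndarray
    duration: int

    @property
    def n_sim(self) -> int:
        return int(self.sim_index.size)


_PD_FIELDS = ("kin", "k_hx_x", "k_x_ua", "clr_hx", "clr_x", "clr_ua",
              "v_hx", "v_x", "v_ua", "imax", "ic50", "emax_x", "ec50_x")


def _individualize_arrays(
    pk: PKParams,
    pd: PDParams,
    cohort: Cohort,
    model: CovariateModel,
) -> tuple[dict[str, np.ndarray], dict[str, np.ndarray]]:
    """Array counterpart of :func:`uratetrial.pkpd.individualize_params`."""
    n = len(cohort)
    wf_cl = model.weight_factor_clearance(cohort.weight)
    wf_v = model.weight_factor_volume(cohort.weight)
    af = model.age_factor_renal(cohort.age)

    def eta(name: str) -> np.ndarray:
        arr = cohort.eta.get(name)
        return np.exp(arr) if arr is not None else np.ones(n)

    pk_arrays: dict[str, np.ndarray] = {}
    for name in ("ka", "cl", "v1", "q", "v2"):
        value = getattr(pk, name)
        if value is None:
            continue
        mult = np.ones(n)
        if name in pkpd._PK_CLEARANCE_FIELDS:
            mult = wf_cl
        elif name in pkpd._PK_VOLUME_FIELDS:
            mult = wf_v
        pk_arrays[name] = value * mult * eta(name)
    pk_arrays["f"] = np.full(n, pk.f)

    pd_arrays: dict[str, np.ndarray] = {}
    for name in _PD_FIELDS:
        value = getattr(pd, name)
        if name in pkpd._PD_RENAL_FIELDS:
            pd_arrays[name] = value * wf_cl * af * eta(name)
        elif name in pkpd._PD_VOLUME_FIELDS:
            pd_arrays[name] = value * wf_v * eta(name)
        elif name == "imax":
            pd_arrays[name] = np.full(n, value)
        else:
            pd_arrays[name] = value * eta(name)
    return pk_arrays, pd_arrays


def _disposition_arrays(
    pk: PKParams, pk_arrays: Mapping[str, np.ndarray], dose: float
) -> tuple[np.ndarray, np.ndarray]:
    """Per-subject exponential terms, dose folded into the coefficients."""
    n = pk_arrays["ka"].size
    rates = np.zeros((n, 3))
    coefs = np.zeros((n, 3))
    ka = pk_arrays["ka"].copy()
    f = pk_arrays["f"]
    if pk.model_order == pkpd.ONE_COMPARTMENT:
        ke = pk_arrays["cl"] / pk_arrays["v1"]
        close = np.abs(ka - ke) <= pkpd._RATE_COINCIDENCE_TOL * np.maximum(ka, ke)
        ka[close] *= 1.0 + pkpd._RATE_NUDGE
        pref = f * dose * ka / (pk_arrays["v1"] * (ka - ke))
        rates[:, 0], rates[:, 1] = ke, ka
        coefs[:, 0], coefs[:, 1] = pref, -pref
        return rates, coefs
    k10 = pk_arrays["cl"] / pk_arrays["v1"]
    k12 = pk_arrays["q"] / pk_arrays["v1"]
    k21 = pk_arrays["q"] / pk_arrays["v2"]
    s = k10 + k12 + k21
    disc = np.sqrt(np.maximum(s * s - 4.0 * k10 * k21, 0.0))
    lam_a = 0.5 * (s + disc)
    lam_b = 0.5 * (s - disc)
    for lam in (lam_a, lam_b):
        close = np.abs(ka - lam) <= pkpd._RATE_COINCIDENCE_TOL * np.maximum(ka, lam)
        ka[close] *= 1.0 + pkpd._RATE_NUDGE
    pref = f * dose * ka / pk_arrays["v1"]
    rates[:, 0], rates[:, 1], rates[:, 2] = lam_a, lam_b, ka
    coefs[:, 0] = pref * (k21 - lam_a) / ((ka - lam_a) * (lam_b - lam_a))
    coefs[:, 1] = pref * (k21 - lam_b) / ((ka - lam_b) * (lam_a - lam_b))
    coefs[:, 2] = pref * (k21 - ka) / ((lam_a - ka) * (lam_b - ka))
    return rates, coefs


def _prepare_arm(
    design: TrialDesign,
    arm_index: int,
    cohort: Cohort,
    model: PopulationModel,
    rng: np.random.Generator,
) -> _ArmTask:
    regimen = design.arms[arm_index]
    if regimen.drug not in model.drugs:
        raise InvalidInputError(f"no drug model for {regimen.drug!r}")
    drug = model.drugs[regimen.drug]
    pd_pop = model.arm_pd(regimen.drug)
    pk_arrays, pd_arrays = _individualize_arrays(drug.pk, pd_pop, cohort, model.covariates)
    pd_arrays["kin"] = pkpd._calibrated_kin_arrays(pd_arrays, cohort.baseline_sua)

    taken, dropout = _sample_dosing_matrix(
        model.adherence, cohort.p_implementation, design.duration, rng
    )
    completed = dropout >= design.duration
    sim_index = np.flatnonzero(completed)
    rates, coefs = _disposition_arrays(drug.pk, pk_arrays, regimen.dose)
    return _ArmTask(
        params={k: v[sim_index] for k, v in pd_arrays.items()},
        rates=rates[sim_index],
        coefs=coefs[sim_index],
        taken=taken[sim_index],
        sim_index=sim_index,
        baseline_sua=cohort.baseline_sua,
        dropout_day=dropout,
        duration=design.duration,
    )


def _finalize_arm(task: _ArmTask, troughs: np.ndarray | None, dt: float) -> ArmResult:
    final = task.baseline_sua.copy()  # dropouts revert to baseline exactly
    if task.n_sim:
        assert troughs is not None
        final[task.sim_index] = troughs[:, -1]
    return ArmResult(
        baseline_sua=task.baseline_sua,
        final_sua=final,
        responder=final < RESPONSE_THRESHOLD,
        dropout_day=task.dropout_day,
        duration=task.duration,
    )


def _integrate_task(task: _ArmTask, dt: float) -> np.ndarray | None:
    if task.n_sim == 0:
        return None
    conc = pkpd._conc_grid_from_doses(
        task.rates, task.coefs, task.taken, task.duration, dt
    )
    return pkpd._integrate_chain(task.params, conc, task.duration, dt)


def simulate_arm(
    design: TrialDesign,
    arm_index: int,
    cohort: Cohort,
    model: PopulationModel,
    seed,
    dt: float = 0.1,
) -> ArmResult:
    """Simulate one arm of ``design`` on an included cohort.

    Completers get their final trough from the PK/PD simulation at day
    ``duration``; subjects who discontinue revert to baseline sUA exactly.
    """
    if arm_index not in (0, 1):
        raise InvalidInputError("arm_index must be 0 or 1")
    if len(cohort) == 0:
        raise InvalidInputError("cohort is empty; apply_inclusion left no subjects?")
    rng = _as_rng(seed)
    task = _prepare_arm(design, arm_index, cohort, model, rng)
    troughs = _integrate_task(task, dt)
    return _finalize_arm(task, troughs, dt)
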