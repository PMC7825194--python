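"""Replicated clinical trial simulation and Beta prior fitting.

Parameter uncertainty is propagated by replicating the trial simulation with
population parameters resampled from a constant-coefficient-of-variation
(lognormal) model.  Each replicate perturbs the population model, samples a
fresh cohort, applies the inclusion threshold, and simulates both arms; the
replicate-level response rates form a Monte Carlo sample of the trial outcome
``theta`` per arm.  Method-of-moments fitting of a Beta distribution to that
sample yields the prior used for Bayesian design evaluation.
"""
from __future__ import annotations

import dataclasses
import math
from dataclasses import dataclass
from typing import Mapping, Sequence

import numpy as np

from . import trial
from .bayes import BetaDistribution
from .pkpd import InvalidInputError
from .trial import PopulationModel, TrialDesign

__all__ = [
    "UncertaintySpec",
    "CTSResult",
    "PriorSummary",
    "InfeasibleMomentsError",
    "perturb_parameters",
    "run_cts",
    "summarize",
    "summarize_samples",
    "fit_beta_moments",
]


class InfeasibleMomentsError(ValueError):
    """Raised when (mean, sd) admit no Beta distribution (sd^2 >= mean(1-mean))."""


@dataclass(frozen=True)
class UncertaintySpec:
    """Per-parameter coefficients of variation for population parameters.

    Keys are dot-paths into the population model, e.g.
    ``drugs.febuxostat.pk.cl`` or ``system.clr_ua``.  A parameter perturbed
    with CV ``c`` is multiplied by ``exp(eta)`` with
    ``eta ~ N(0, log(1 + c^2))``, so the lognormal factor has coefficient of
    variation exactly ``c``.
    """

    scenario: str
    cvs: Mapping[str, float]

    def __post_init__(self) -> None:
        for path, cv in self.cvs.items():
            if not (np.isfinite(cv) and cv >= 0):
                raise InvalidInputError(f"CV for {path!r} must be non-negative, got {cv!r}")
        object.__setattr__(self, "cvs", dict(self.cvs))


def _set_path(model: PopulationModel, path: str, factor: float) -> PopulationModel:
    parts = path.split(".")
    if parts[0] == "system" and len(parts) == 2:
        new_system = dataclasses.replace(
            model.system, **{parts[1]: getattr(model.system, parts[1]) * factor}
        )
        return dataclasses.replace(model, system=new_system)
    if parts[0] == "drugs" and len(parts) == 4:
        _, drug_name, block, fieldname = parts
        drug = model.drugs[drug_name]
        if block == "pk":
            new_drug = dataclasses.replace(
                drug, pk=dataclasses.replace(drug.pk, **{fieldname: getattr(drug.pk, fieldname) * factor})
            )
        elif block == "effect":
            new_drug = dataclasses.replace(drug, **{fieldname: getattr(drug, fieldname) * factor})
        else:
            raise InvalidInputError(f"unknown uncertainty path {path!r}")
        drugs = dict(model.drugs)
        drugs[drug_name] = new_drug
        return dataclasses.replace(model, drugs=drugs)
    raise InvalidInputError(f"unknown uncertainty path {path!r}")


def perturb_parameters(
    model: PopulationModel, spec: UncertaintySpec, seed
) -> PopulationModel:
    """Multiply each targeted population parameter by a lognormal factor.

    Parameters with CV 0 are left untouched (and consume no random draws).
    Draws follow the sorted path order, so perturbation is reproducible for a
    given seed.
    """
    rng = seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)
    for path in sorted(spec.cvs):
        cv = spec.cvs[path]
        if cv == 0.0:
            continue
        sigma = math.sqrt(math.log1p(cv * cv))
        factor = math.exp(rng.normal(0.0, sigma))
        model = _set_path(model, path, factor)
    return model


@dataclass
class CTSResult:
    """Response-rate samples ``theta`` (replicates x 2 arms) for one design."""

    design_id: str
    scenario: str
    theta: np.ndarray
    n_included: np.ndarray
    replicate_index: np.ndarray
    master_seed: int | None = None
    n_failed: int = 0

    def __post_init__(self) -> None:
        theta = np.asarray(self.theta, dtype=float)
        if theta.ndim != 2 or theta.shape[1] != 2 or theta.shape[0] < 2:
            raise InvalidInputError("theta must be (R, 2) with R > 1")
        if ((theta < 0) | (theta > 1)).any():
            raise InvalidInputError("response rates must lie in [0, 1]")
        self.theta = theta

    @property
    def n_replicates(self) -> int:
        return int(self.theta.shape[0])


@dataclass(frozen=True)
class PriorSummary:
    """Summary of simulated response rates and the moment-fitted Beta prior.

    Location statistics are stored as percentages for reporting; the Beta
    parameters are fitted on the proportion scale.  ``degenerate`` marks a
    zero-variance sample for which no proper Beta exists.
    """

    arm: str
    mean_pct: float
    sd_pct: float
    p2_5_pct: float
    p97_5_pct: float
    alpha: float | None
    beta: float | None
    degenerate: bool = False

    def __post_init__(self) -> None:
        if not self.degenerate:
            if self.alpha is None or self.beta is None or self.alpha <= 0 or self.beta <= 0:
                raise InvalidInputError("non-degenerate summary requires alpha, beta > 0")
        if not (self.p2_5_pct <= self.mean_pct <= self.p97_5_pct):
            raise InvalidInputError("percentiles must bracket the mean")

    def prior(self) -> BetaDistribution:
        if self.degenerate:
            raise InfeasibleMomentsError(
                "degenerate response-rate sample has no proper Beta prior"
            )
        return BetaDistribution(self.alpha, self.beta)


def fit_beta_moments(mean: float, sd: float) -> BetaDistribution:
    """Method-of-moments Beta fit: nu = m(1-m)/sd^2 - 1, alpha = m nu, beta = (1-m) nu.

    The fitted Beta reproduces the input mean and sd exactly.  Raises
    :class:`InfeasibleMomentsError` when ``sd^2 >= mean(1-mean)`` (no Beta has
    that much spread) or the mean is outside (0, 1).
    """
    if not (0.0 < mean < 1.0):
        raise InfeasibleMomentsError(f"mean must lie strictly in (0, 1), got {mean!r}")
    var = sd * sd
    bound = mean * (1.0 - mean)
    if not (0.0 < var < bound):
        raise InfeasibleMomentsError(
            f"need 0 < sd^2 < mean(1-mean) = {bound:.6g}, got sd^2 = {var:.6g}"
        )
    nu = bound / var - 1.0
    return BetaDistribution(mean * nu, (1.0 - mean) * nu)


def _replicate_seed_tree(master_seed) -> np.random.SeedSequence:
    if isinstance(master_seed, np.random.SeedSequence):
        return master_seed
    return np.random.SeedSequence(master_seed)


def _prepare_replicate(
    design: TrialDesign,
    model: PopulationModel,
    uncertainty: UncertaintySpec,
    n_subjects: int,
    rep_ss: np.random.SeedSequence,
    fixed_cohort: trial.Cohort | None,
):
    """All stochastic per-replicate work except the (deterministic) integration."""
    ss_draw, ss_arm0, ss_arm1 = rep_ss.spawn(3)
    rng = np.random.default_rng(ss_draw)
    perturbed = perturb_parameters(model, uncertainty, rng)
    if fixed_cohort is None:
        cohort = trial.sample_population(
            perturbed.population, perturbed.adherence, n_subjects, rng
        )
    else:
        cohort = fixed_cohort
    cohort = trial.apply_inclusion(cohort, design.inclusion_threshold)
    if len(cohort) == 0:
        raise RuntimeError("no subjects passed inclusion in this replicate")
    tasks = [
        trial._prepare_arm(design, 0, cohort, perturbed, np.random.default_rng(ss_arm0)),
        trial._prepare_arm(design, 1, cohort, perturbed, np.random.default_rng(ss_arm1)),
    ]
    return tasks, len(cohort)


def _run_batch(batch, dt: float):
    """Integrate a batch of prepared replicates, arm by arm, in one stacked call.

    Stacking is purely a throughput device: the integrator is elementwise
    across subjects, so results are bit-identical to replicate-by-replicate
    execution (and hence independent of batch size or worker count).
    """
    results = []
    for arm in (0, 1):
        tasks = [tasks_pair[arm] for tasks_pair, _ in batch]
        sizes = [t.n_sim for t in tasks]
        troughs_split: list[np.ndarray | None] = [None] * len(tasks)
        active = [i for i, s in enumerate(sizes) if s > 0]
        if active:
            duration = tasks[active[0]].duration
            stacked = trial._ArmTask(
                params={
                    k: np.concatenate([tasks[i].params[k] for i in active])
                    for k in tasks[active[0]].params
                },
                rates=np.concatenate([tasks[i].rates for i in active]),
                coefs=np.concatenate([tasks[i].coefs for i in active]),
                taken=np.concatenate([tasks[i].taken for i in active]),
                sim_index=np.arange(sum(sizes[i] for i in active)),
                baseline_sua=np.concatenate([tasks[i].baseline_sua for i in active]),
                dropout_day=np.concatenate([tasks[i].dropout_day for i in active]),
                duration=duration,
            )
            all_troughs = trial._integrate_task(stacked, dt)
            offset = 0
            for i in active:
                troughs_split[i] = all_troughs[offset: offset + sizes[i]]
                offset += sizes[i]
        results.append(
            [trial._finalize_arm(t, tr, dt) for t, tr in zip(tasks, troughs_split)]
        )
    out = []
    for j in range(len(batch)):
        out.append((results[0][j], results[1][j]))
    return out


def run_cts(
    design: TrialDesign,
    model: PopulationModel,
    uncertainty: UncertaintySpec,
    r_replicates: int,
    n_subjects: int,
    seed,
    dt: float = 0.1,
    batch_size: int = 20,
    n_jobs: int = 1,
    resample_cohort: bool = True,
) -> CTSResult:
    """Monte Carlo distribution of the two-arm response rates for one design.

    Replicate ``r``: perturb population parameters, sample a cohort of
    ``n_subjects`` (or reuse one fixed cohort when ``resample_cohort`` is
    False), apply inclusion, simulate both arms, and record the per-arm
    response rates.  Replicates draw from independent seed-sequence children
    of ``seed``, so the result is reproducible and independent of
    ``batch_size`` and ``n_jobs``.  Failed replicates are dropped; more than
    1% failures raises.
    """
    if r_replicates < 2:
        raise InvalidInputError("r_replicates must be at least 2")
    if n_subjects < 1:
        raise InvalidInputError("n_subjects must be at least 1")
    master = _replicate_seed_tree(seed)
    children = master.spawn(r_replicates + 1)
    fixed_cohort = None
    if not resample_cohort:
        rng0 = np.random.default_rng(children[r_replicates])
        fixed_cohort = trial.sample_population(
            model.population, model.adherence, n_subjects, rng0
        )

    prepared: list[tuple] = []
    failures: list[tuple[int, str]] = []
    for r in range(r_replicates):
        try:
            prepared.append(
                (r, _prepare_replicate(design, model, uncertainty, n_subjects,
                                       children[r], fixed_cohort))
            )
        except Exception as exc:  # noqa: BLE001 - failure policy requires capture
            failures.append((r, repr(exc)))

    batches = [prepared[i:i + batch_size] for i in range(0, len(prepared), batch_size)]

    def process(batch):
        payload = [(tasks, n_inc) for _, (tasks, n_inc) in batch]
        return _run_batch(payload, dt)

    if n_jobs != 1 and len(batches) > 1:
        from joblib import Parallel, delayed

        batch_results = Parallel(n_jobs=n_jobs, prefer="threads")(
            delayed(process)(b) for b in batches
        )
    else:
        batch_results = [process(b) for b in batches]

    theta_rows: list[tuple[int, float, float, int]] = []
    for batch, arm_pairs in zip(batches, batch_results):
        for (r, (_tasks, n_inc)), (res0, res1) in zip(batch, arm_pairs):
            t0, t1 = trial.response_rate(res0), trial.response_rate(res1)
            if not (np.isfinite(t0) and np.isfinite(t1)):
                failures.append((r, "non-finite response rate"))
                continue
            theta_rows.append((r, t0, t1, n_inc))

    if failures and len(failures) > 0.01 * r_replicates:
        raise RuntimeError(
            f"{len(failures)} of {r_replicates} CTS replicates failed: {failures[:5]}"
        )
    theta_rows.sort(key=lambda row: row[0])
    theta = np.array([[t0, t1] for _, t0, t1, _ in theta_rows])
    return CTSResult(
        design_id=design.design_id,
        scenario=design.scenario,
        theta=theta,
        n_included=np.array([n for _, _, _, n in theta_rows]),
        replicate_index=np.array([r for r, _, _, _ in theta_rows]),
        master_seed=None if isinstance(seed, np.random.SeedSequence) else int(seed),
        n_failed=len(failures),
    )


def summarize_samples(samples: Sequence[float] | np.ndarray, arm: str) -> PriorSummary:
    """Mean, SD (ddof=1), empirical 2.5/97.5 percentiles, and the Beta moment fit."""
    x = np.asarray(samples, dtype=float)
    if x.size < 2:
        raise InvalidInputError("need at least two samples to summarise")
    mean = float(x.mean())
    sd = float(x.std(ddof=1))
    p_lo, p_hi = np.percentile(x, [2.5, 97.5])
    try:
        fit = fit_beta_moments(mean, sd)
        alpha, beta_, degenerate = fit.alpha, fit.beta, False
    except InfeasibleMomentsError:
        alpha, beta_, degenerate = None, None, True
    return PriorSummary(
        arm=arm,
        mean_pct=100.0 * mean,
        sd_pct=100.0 * sd,
        p2_5_pct=100.0 * float(p_lo),
        p97_5_pct=100.0 * float(p_hi),
        alpha=alpha,
        beta=beta_,
        degenerate=degenerate,
    )


def summarize(cts: CTSResult, arm_names: Sequence[str] = ("arm_1", "arm_2")) -> tuple[PriorSummary, PriorSummary]:
    """Per-arm prior summaries of a CTS result."""
    return (
        summarize_samples(cts.theta[:, 0], arm_names[0]),
        summarize_samples(cts.theta[:, 1], arm_names[1]),
    )
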