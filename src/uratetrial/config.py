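"""Configuration, default parameter fixtures, and YAML (de)serialisation.

All model inputs are config-driven so that estimated parameter sets can be
dropped in without code changes.  :func:`generate_default_config` emits a
complete, validated configuration: the six two-arm designs (allopurinol
300/600 mg vs febuxostat 80/120 mg, 182 days, inclusion thresholds 6 or
8 mg/dL, base-case or reduced parameter uncertainty), a plausible default
parameter set for both drugs and the urate chain, and the payoff-model
inputs (fixed trial cost 5,000,000; 20,000 per subject; production and
marketing 10/patient-year; minimum price 70/patient-year).
"""
from __future__ import annotations

import dataclasses
import hashlib
import json
from dataclasses import dataclass, field
from pathlib import Path
from typing import Any, Mapping

import yaml

from .bayes import DEFAULT_GRID, SampleSizeGrid
from .cts import UncertaintySpec
from .econ import MarkovSpec
from .pkpd import CovariateModel, InvalidInputError, PDParams, PKParams
from .roi import MarketModel, ROIInputs
from .trial import (
    AdherenceParams,
    ArmRegimen,
    DrugModel,
    PopulationModel,
    PopulationSpec,
    TrialDesign,
)

__all__ = [
    "ConfigError",
    "FixtureSet",
    "RunConfig",
    "generate_default_config",
    "default_designs",
    "save_config",
    "load_config",
    "config_to_dict",
    "config_hash",
]


class ConfigError(ValueError):
    """Raised when a configuration file fails validation."""


ALLOPURINOL = "allopurinol"
FEBUXOSTAT = "febuxostat"

#: Population-parameter paths carrying uncertainty, and the default CVs of the
#: two scenarios (the reduced scenario shrinks every CV).
_UNCERTAIN_PATHS = (
    f"drugs.{ALLOPURINOL}.pk.ka",
    f"drugs.{ALLOPURINOL}.pk.cl",
    f"drugs.{ALLOPURINOL}.pk.v1",
    f"drugs.{ALLOPURINOL}.effect.ic50",
    f"drugs.{FEBUXOSTAT}.pk.ka",
    f"drugs.{FEBUXOSTAT}.pk.cl",
    f"drugs.{FEBUXOSTAT}.pk.v1",
    f"drugs.{FEBUXOSTAT}.pk.q",
    f"drugs.{FEBUXOSTAT}.pk.v2",
    f"drugs.{FEBUXOSTAT}.effect.ic50",
    f"drugs.{FEBUXOSTAT}.effect.emax_x",
    "system.k_hx_x",
    "system.k_x_ua",
    "system.clr_hx",
    "system.clr_x",
    "system.clr_ua",
)
BASE_CASE_CV = 0.25
REDUCED_CV = 0.10


def default_uncertainty() -> dict[str, UncertaintySpec]:
    return {
        "base_case": UncertaintySpec(
            scenario="base_case", cvs={p: BASE_CASE_CV for p in _UNCERTAIN_PATHS}
        ),
        "reduced": UncertaintySpec(
            scenario="reduced", cvs={p: REDUCED_CV for p in _UNCERTAIN_PATHS}
        ),
    }


def default_population_model() -> PopulationModel:
    """Plausible default PK/PD parameter set for the two urate-lowering drugs.

    Allopurinol exposure is represented by a persistent one-compartment
    profile (standing in for its active metabolite's slow elimination) with a
    weak inhibitory potency; febuxostat is a two-compartment, highly potent
    inhibitor that also stimulates renal excretion of xanthine.
    """
    allopurinol = DrugModel(
        pk=PKParams(model_order="one_compartment", ka=20.0, cl=25.0, v1=40.0, f=0.8),
        imax=0.85,
        ic50=9.0,
    )
    febuxostat = DrugModel(
        pk=PKParams(
            model_order="two_compartment",
            ka=25.0, cl=250.0, v1=35.0, f=0.85, q=100.0, v2=40.0,
        ),
        imax=0.95,
        ic50=0.05,
        emax_x=1.0,
        ec50_x=0.05,
    )
    system = PDParams(
        kin=2000.0,  # nominal; recalibrated per subject to their baseline sUA
        k_hx_x=3.0,
        k_x_ua=3.0,
        clr_hx=50.0,
        clr_x=50.0,
        clr_ua=13.0,
        v_hx=50.0,
        v_x=50.0,
        v_ua=40.0,
        imax=0.0,
        ic50=1.0,
    )
    return PopulationModel(
        drugs={ALLOPURINOL: allopurinol, FEBUXOSTAT: febuxostat},
        system=system,
        population=PopulationSpec(),
        adherence=AdherenceParams(),
        covariates=CovariateModel(),
    )


def default_designs(duration: int = 182) -> list[TrialDesign]:
    """The six candidate designs: dose pairs x inclusion threshold x uncertainty."""
    spec = [
        ("psi1", "base_case", 300.0, 80.0, 6.0),
        ("psi2", "base_case", 300.0, 80.0, 8.0),
        ("psi3", "base_case", 600.0, 120.0, 6.0),
        ("psi4", "reduced", 300.0, 80.0, 6.0),
        ("psi5", "reduced", 300.0, 80.0, 8.0),
        ("psi6", "reduced", 600.0, 120.0, 6.0),
    ]
    return [
        TrialDesign(
            design_id=design_id,
            scenario=scenario,
            arms=(
                ArmRegimen(drug=ALLOPURINOL, dose=allo_dose),
                ArmRegimen(drug=FEBUXOSTAT, dose=feb_dose),
            ),
            duration=duration,
            inclusion_threshold=threshold,
        )
        for design_id, scenario, allo_dose, feb_dose, threshold in spec
    ]


@dataclass(frozen=True)
class FixtureSet:
    """Self-contained default inputs for every pipeline stage."""

    model: PopulationModel = field(default_factory=default_population_model)
    uncertainty: Mapping[str, UncertaintySpec] = field(default_factory=default_uncertainty)
    econ: MarkovSpec = field(default_factory=MarkovSpec)
    market: MarketModel = field(default_factory=MarketModel)
    roi: ROIInputs = field(default_factory=ROIInputs)
    lam: float = 20_000.0

    def __post_init__(self) -> None:
        object.__setattr__(self, "uncertainty", dict(self.uncertainty))
        if not (self.lam > 0):
            raise InvalidInputError("lambda must be positive")


@dataclass
class RunConfig:
    """A complete, reproducible pipeline run description."""

    seed: int
    designs: list[TrialDesign] = field(default_factory=default_designs)
    fixtures: FixtureSet = field(default_factory=FixtureSet)
    cts_replicates: int = 200
    cts_subjects: int = 200
    preposterior_replicates: int = 500
    full_cts_replicates: int = 10_000
    full_cts_subjects: int = 1_000
    full_preposterior_replicates: int = 10_000
    full_fidelity: bool = False
    sample_size_grid: tuple[int, ...] = DEFAULT_GRID
    posterior_point: str = "mean"
    resample_cohort: bool = True
    pd_dt: float = 0.1
    batch_size: int = 20
    n_jobs: int = 1
    output_dir: str = "runs"

    def __post_init__(self) -> None:
        if self.seed is None:
            raise ConfigError("a master seed is required")
        self.seed = int(self.seed)
        if not self.designs:
            raise ConfigError("at least one design is required")
        for d in self.designs:
            for arm in d.arms:
                if arm.drug not in self.fixtures.model.drugs:
                    raise ConfigError(f"design {d.design_id}: unknown drug {arm.drug!r}")
            if d.scenario not in self.fixtures.uncertainty:
                raise ConfigError(
                    f"design {d.design_id}: no uncertainty spec for {d.scenario!r}"
                )
        for name in ("cts_replicates", "cts_subjects", "preposterior_replicates"):
            if getattr(self, name) < 2:
                raise ConfigError(f"{name} must be at least 2")
        if (
            self.cts_replicates > self.full_cts_replicates
            or self.cts_subjects > self.full_cts_subjects
            or self.preposterior_replicates > self.full_preposterior_replicates
        ):
            raise ConfigError("scaled-down settings must not exceed full-fidelity ones")
        SampleSizeGrid(self.sample_size_grid)  # validates
        self.sample_size_grid = tuple(int(s) for s in self.sample_size_grid)
        if self.posterior_point not in ("mean", "draw"):
            raise ConfigError("posterior_point must be 'mean' or 'draw'")

    @property
    def effective_cts_replicates(self) -> int:
        return self.full_cts_replicates if self.full_fidelity else self.cts_replicates

    @property
    def effective_cts_subjects(self) -> int:
        return self.full_cts_subjects if self.full_fidelity else self.cts_subjects

    @property
    def effective_preposterior_replicates(self) -> int:
        return (
            self.full_preposterior_replicates
            if self.full_fidelity
            else self.preposterior_replicates
        )


def generate_default_config(seed: int = 20_201_231) -> RunConfig:
    """A complete default configuration (validated on construction)."""
    return RunConfig(seed=seed)


# ---------------------------------------------------------------------------
# serialisation


def _to_plain(obj: Any) -> Any:
    if dataclasses.is_dataclass(obj) and not isinstance(obj, type):
        return {f.name: _to_plain(getattr(obj, f.name)) for f in dataclasses.fields(obj)}
    if isinstance(obj, Mapping):
        return {k: _to_plain(v) for k, v in obj.items()}
    if isinstance(obj, (list, tuple)):
        return [_to_plain(v) for v in obj]
    if isinstance(obj, (int, float, str, bool)) or obj is None:
        return obj
    raise ConfigError(f"cannot serialise {type(obj)!r}")


def config_to_dict(config: RunConfig) -> dict:
    return _to_plain(config)


#: Keys that affect where/how a run executes but not what it computes.
_EXECUTION_KEYS = ("output_dir", "n_jobs", "batch_size")


def config_hash(config: RunConfig) -> str:
    """Stable short hash of the scientific configuration (used to tag outputs).

    Execution-only settings (output directory, worker count, batch size) are
    excluded: they never change results, so outputs produced anywhere with
    any parallelism carry the same hash.
    """
    payload = config_to_dict(config)
    for key in _EXECUTION_KEYS:
        payload.pop(key, None)
    return hashlib.sha256(json.dumps(payload, sort_keys=True).encode()).hexdigest()[:12]


def save_config(config: RunConfig, path: str | Path) -> Path:
    path = Path(path)
    path.parent.mkdir(parents=True, exist_ok=True)
    with open(path, "w") as fh:
        yaml.safe_dump(config_to_dict(config), fh, sort_keys=False)
    return path


def _build(cls, data: Mapping[str, Any], context: str):
    if not isinstance(data, Mapping):
        raise ConfigError(f"{context}: expected a mapping, got {type(data)!r}")
    names = {f.name for f in dataclasses.fields(cls)}
    unknown = set(data) - names
    if unknown:
        raise ConfigError(f"{context}: unknown keys {sorted(unknown)}")
    try:
        return cls(**data)
    except (TypeError, ValueError) as exc:
        raise ConfigError(f"{context}: {exc}") from exc


def _design_from_dict(data: Mapping[str, Any]) -> TrialDesign:
    data = dict(data)
    arms = tuple(_build(ArmRegimen, a, "design.arms") for a in data.pop("arms", ()))
    return _build(TrialDesign, {**data, "arms": arms}, "design")


def _fixtures_from_dict(data: Mapping[str, Any]) -> FixtureSet:
    data = dict(data)
    model_d = dict(data.pop("model"))
    drugs = {
        name: DrugModel(
            pk=_build(PKParams, dict(d["pk"]), f"model.drugs.{name}.pk"),
            **{k: v for k, v in d.items() if k != "pk"},
        )
        for name, d in model_d.pop("drugs").items()
    }
    model = PopulationModel(
        drugs=drugs,
        system=_build(PDParams, model_d.pop("system"), "model.system"),
        population=_build(PopulationSpec, model_d.pop("population"), "model.population"),
        adherence=_build(AdherenceParams, model_d.pop("adherence"), "model.adherence"),
        covariates=_build(CovariateModel, model_d.pop("covariates"), "model.covariates"),
    )
    if model_d:
        raise ConfigError(f"model: unknown keys {sorted(model_d)}")
    uncertainty = {
        name: _build(UncertaintySpec, u, f"uncertainty.{name}")
        for name, u in data.pop("uncertainty").items()
    }
    return FixtureSet(
        model=model,
        uncertainty=uncertainty,
        econ=_build_markov(data.pop("econ")),
        market=_build(MarketModel, data.pop("market"), "market"),
        roi=_build(ROIInputs, data.pop("roi"), "roi"),
        lam=float(data.pop("lam")),
    )


def _build_markov(data: Mapping[str, Any]) -> MarkovSpec:
    data = dict(data)
    for key in ("flare_rate", "utility", "management_cost_annual"):
        if key in data:
            data[key] = tuple(data[key])
    return _build(MarkovSpec, data, "econ")


def config_from_dict(data: Mapping[str, Any]) -> RunConfig:
    data = dict(data)
    designs = [_design_from_dict(d) for d in data.pop("designs")]
    fixtures = _fixtures_from_dict(data.pop("fixtures"))
    if "sample_size_grid" in data:
        data["sample_size_grid"] = tuple(data["sample_size_grid"])
    return _build(RunConfig, {**data, "designs": designs, "fixtures": fixtures}, "run config")


def load_config(path: str | Path) -> RunConfig:
    """Load and validate a YAML configuration produced by :func:`save_config`."""
    with open(path) as fh:
        data = yaml.safe_load(fh)
    if not isinstance(data, Mapping):
        raise ConfigError(f"{path}: not a configuration mapping")
    return config_from_dict(data)
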