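"""End-to-end four-stage pipeline with caching and CSV/JSON result bundles.

Stages: ``cts`` (trial simulation -> response-rate samples), ``priors``
(Beta prior table), ``pricing`` (preposterior draws -> maximum reimbursement
prices), and ``roi`` (expected-ROI table and optimal sample sizes).  Each
stage is cached on disk keyed by a hash of the configuration and the
upstream stage key, so re-running a late stage does not re-execute earlier
ones.  All randomness derives from the master seed through explicit
seed-sequence spawn keys, making runs byte-reproducible and independent of
batching or worker count.
"""
from __future__ import annotations

import json
import logging
import time
from dataclasses import dataclass, field
from hashlib import sha256
from pathlib import Path

import numpy as np
import pandas as pd

from . import cts as cts_mod
from . import econ, roi as roi_mod
from .bayes import SampleSizeGrid
from .config import RunConfig, config_hash, config_to_dict
from .trial import TrialDesign

__all__ = ["STAGES", "PipelineResult", "run_pipeline", "read_result_csv"]

logger = logging.getLogger("uratetrial")

STAGES = ("cts", "priors", "pricing", "roi")

_STAGE_FILES = {
    "cts": "theta_samples.csv",
    "priors": "priors.csv",
    "pricing": "price_draws.csv",
    "roi": "roi.csv",
}

ARM_NAMES = ("allopurinol", "febuxostat")


@dataclass
class PipelineResult:
    """Outputs of a pipeline run: stage tables, file paths, provenance."""

    config_hash: str
    seed: int
    tables: dict[str, pd.DataFrame]
    paths: dict[str, Path]
    executed: list[str] = field(default_factory=list)

    def table(self, stage: str) -> pd.DataFrame:
        return self.tables[stage]


def _stage_seed(config: RunConfig, stage_index: int, *key: int) -> np.random.SeedSequence:
    return np.random.SeedSequence(entropy=config.seed, spawn_key=(stage_index, *key))


def _relevant_config(config: RunConfig, stage: str) -> dict:
    """Configuration subset that determines a stage's output."""
    full = config_to_dict(config)
    drop_always = {"output_dir", "n_jobs", "batch_size"}
    keep: dict = {k: v for k, v in full.items() if k not in drop_always}
    if stage in ("cts", "priors"):
        for k in ("preposterior_replicates", "full_preposterior_replicates",
                  "sample_size_grid", "posterior_point"):
            keep.pop(k, None)
        fixtures = dict(keep["fixtures"])
        for k in ("econ", "market", "roi", "lam"):
            fixtures.pop(k, None)
        keep["fixtures"] = fixtures
    return keep


def _stage_key(config: RunConfig, stage: str, upstream_key: str | None) -> str:
    payload = json.dumps(
        {"stage": stage, "config": _relevant_config(config, stage), "upstream": upstream_key},
        sort_keys=True,
    ).encode()
    return sha256(payload).hexdigest()[:16]


def _write_csv(df: pd.DataFrame, path: Path, config: RunConfig) -> None:
    path.parent.mkdir(parents=True, exist_ok=True)
    with open(path, "w", newline="") as fh:
        fh.write(f"# uratetrial result table: {path.name}\n")
        fh.write(f"# config_hash={config_hash(config)} seed={config.seed}\n")
        df.to_csv(fh, index=False)


def read_result_csv(path: str | Path) -> pd.DataFrame:
    """Read a pipeline CSV, skipping the provenance header lines."""
    return pd.read_csv(path, comment="#")


def _load_cache(out_dir: Path, stage: str, key: str) -> pd.DataFrame | None:
    meta_path = out_dir / ".cache.json"
    csv_path = out_dir / _STAGE_FILES[stage]
    if not (meta_path.exists() and csv_path.exists()):
        return None
    try:
        meta = json.loads(meta_path.read_text())
    except json.JSONDecodeError:
        return None
    if meta.get(stage) != key:
        return None
    return read_result_csv(csv_path)


def _store_cache(out_dir: Path, stage: str, key: str) -> None:
    meta_path = out_dir / ".cache.json"
    meta = {}
    if meta_path.exists():
        try:
            meta = json.loads(meta_path.read_text())
        except json.JSONDecodeError:
            meta = {}
    meta[stage] = key
    meta_path.write_text(json.dumps(meta, sort_keys=True, indent=1))


# ---------------------------------------------------------------------------
# stage computations


def _compute_cts(config: RunConfig) -> pd.DataFrame:
    frames = []
    for d_idx, design in enumerate(config.designs):
        uncertainty = config.fixtures.uncertainty[design.scenario]
        result = cts_mod.run_cts(
            design,
            config.fixtures.model,
            uncertainty,
            r_replicates=config.effective_cts_replicates,
            n_subjects=config.effective_cts_subjects,
            seed=_stage_seed(config, 1, d_idx),
            dt=config.pd_dt,
            batch_size=config.batch_size,
            n_jobs=config.n_jobs,
            resample_cohort=config.resample_cohort,
        )
        for arm_idx, arm_name in enumerate(ARM_NAMES):
            frames.append(
                pd.DataFrame(
                    {
                        "design": design.design_id,
                        "scenario": design.scenario,
                        "arm": arm_name,
                        "replicate": result.replicate_index,
                        "theta": result.theta[:, arm_idx],
                        "n_included": result.n_included,
                    }
                )
            )
    return pd.concat(frames, ignore_index=True)


def _compute_priors(config: RunConfig, theta_df: pd.DataFrame) -> pd.DataFrame:
    rows = []
    for design in config.designs:
        sub = theta_df[theta_df["design"] == design.design_id]
        for arm_name in ARM_NAMES:
            samples = sub.loc[sub["arm"] == arm_name, "theta"].to_numpy()
            summ = cts_mod.summarize_samples(samples, arm_name)
            rows.append(
                {
                    "scenario": design.scenario,
                    "design": design.design_id,
                    "arm": arm_name,
                    "mean_pct": summ.mean_pct,
                    "sd_pct": summ.sd_pct,
                    "p2_5_pct": summ.p2_5_pct,
                    "p97_5_pct": summ.p97_5_pct,
                    "alpha": summ.alpha if summ.alpha is not None else np.nan,
                    "beta": summ.beta if summ.beta is not None else np.nan,
                }
            )
    return pd.DataFrame(rows)


def _priors_for_design(priors_df: pd.DataFrame, design: TrialDesign):
    from .bayes import BetaDistribution

    sub = priors_df[priors_df["design"] == design.design_id]
    out = []
    for arm_name in ARM_NAMES:
        row = sub[sub["arm"] == arm_name].iloc[0]
        if not (np.isfinite(row["alpha"]) and np.isfinite(row["beta"])):
            raise cts_mod.InfeasibleMomentsError(
                f"design {design.design_id}, arm {arm_name}: degenerate prior"
            )
        out.append(BetaDistribution(float(row["alpha"]), float(row["beta"])))
    return tuple(out)


def _compute_pricing(config: RunConfig, priors_df: pd.DataFrame) -> pd.DataFrame:
    fx = config.fixtures
    q_soc, c_soc = econ._state_values(fx.econ, include_soc_drug=True)
    q_new, c_new = econ._state_values(fx.econ, include_soc_drug=False)
    t2 = econ.expected_persistence(
        fx.econ.dropout_shape,
        fx.econ.dropout_scale_days,
        fx.econ.horizon_years,
        fx.econ.discount_rate,
    )
    grid = SampleSizeGrid(config.sample_size_grid)
    r = config.effective_preposterior_replicates
    frames = []
    for d_idx, design in enumerate(config.designs):
        prior_soc, prior_new = _priors_for_design(priors_df, design)
        for n_idx, n in enumerate(grid):
            rng = np.random.default_rng(_stage_seed(config, 3, d_idx, n_idx))
            theta1 = rng.beta(prior_soc.alpha, prior_soc.beta, size=r)
            m1 = rng.binomial(n, theta1)
            pm1 = (prior_soc.alpha + m1) / (prior_soc.alpha + prior_soc.beta + n)
            theta2 = rng.beta(prior_new.alpha, prior_new.beta, size=r)
            m2 = rng.binomial(n, theta2)
            pm2 = (prior_new.alpha + m2) / (prior_new.alpha + prior_new.beta + n)
            if config.posterior_point == "draw":
                pm1 = rng.beta(prior_soc.alpha + m1, prior_soc.beta + n - m1)
                pm2 = rng.beta(prior_new.alpha + m2, prior_new.beta + n - m2)
            split = fx.econ.nonresponder_split
            start1 = roi_mod._start_matrix(pm1, split)
            start2 = roi_mod._start_matrix(pm2, split)
            q1 = start1 @ q_soc
            c1 = start1 @ c_soc
            q2 = start2 @ q_new
            c2_nd = start2 @ c_new
            p2 = (c1 - c2_nd + fx.lam * (q2 - q1)) / t2
            frames.append(
                pd.DataFrame(
                    {
                        "design": design.design_id,
                        "scenario": design.scenario,
                        "n_per_arm": n,
                        "replicate": np.arange(r),
                        "theta_allopurinol": theta1,
                        "m_allopurinol": m1,
                        "post_point_allopurinol": pm1,
                        "theta_febuxostat": theta2,
                        "m_febuxostat": m2,
                        "post_point_febuxostat": pm2,
                        "q_soc": q1,
                        "c_soc": c1,
                        "q_new": q2,
                        "c_new_nondrug": c2_nd,
                        "t_persist": t2,
                        "price_max": p2,
                    }
                )
            )
    return pd.concat(frames, ignore_index=True)


def _compute_roi(config: RunConfig, price_df: pd.DataFrame) -> pd.DataFrame:
    fx = config.fixtures
    rows = []
    for design in config.designs:
        sub = price_df[price_df["design"] == design.design_id]
        s_market = roi_mod.market_size(fx.market, design.inclusion_threshold)
        means = {}
        for n, grp in sub.groupby("n_per_arm", sort=True):
            p2 = grp["price_max"].to_numpy()
            t2 = grp["t_persist"].to_numpy()
            ctrial = roi_mod.trial_cost(2 * int(n), fx.roi)
            go = p2 >= fx.roi.minimum_price
            payoff = np.where(
                go, (p2 - fx.roi.production_marketing) * t2 * s_market - ctrial, 0.0
            )
            means[int(n)] = (payoff.mean(), 1.0 - go.mean())
        sizes = sorted(means)
        expected = np.array([means[n][0] for n in sizes])
        optimal_n = sizes[int(np.argmax(expected))]
        for n in sizes:
            rows.append(
                {
                    "scenario": design.scenario,
                    "design": design.design_id,
                    "n_per_arm": n,
                    "expected_roi": means[n][0],
                    "p_termination": means[n][1],
                    "optimal": n == optimal_n,
                }
            )
    return pd.DataFrame(rows)


def _mrp_summary(price_df: pd.DataFrame) -> pd.DataFrame:
    def agg(grp: pd.DataFrame) -> pd.Series:
        p2 = grp["price_max"].to_numpy()
        return pd.Series(
            {
                "mean": p2.mean(),
                "sd": p2.std(ddof=1),
                "p2_5": np.percentile(p2, 2.5),
                "p97_5": np.percentile(p2, 97.5),
            }
        )

    out = (
        price_df.groupby(["scenario", "design", "n_per_arm"], sort=True)
        .apply(agg, include_groups=False)
        .reset_index()
    )
    return out


def _roi_wide(roi_df: pd.DataFrame) -> pd.DataFrame:
    wide = roi_df.pivot_table(
        index=["scenario", "design"], columns="n_per_arm", values="expected_roi"
    )
    wide.columns = [f"n{int(c)}" for c in wide.columns]
    optimal = roi_df[roi_df["optimal"]].set_index(["scenario", "design"])["n_per_arm"]
    wide["optimal_n"] = optimal
    return wide.reset_index()


_STAGE_COMPUTE = {
    "cts": lambda cfg, upstream: _compute_cts(cfg),
    "priors": lambda cfg, upstream: _compute_priors(cfg, upstream),
    "pricing": lambda cfg, upstream: _compute_pricing(cfg, upstream),
    "roi": lambda cfg, upstream: _compute_roi(cfg, upstream),
}


def run_pipeline(
    config: RunConfig,
    stages: str | tuple[str, ...] | list[str] | None = None,
    force: bool = False,
) -> PipelineResult:
    """Execute the pipeline up to the last requested stage, reusing cached stages.

    ``stages`` may be a single stage name or a collection; upstream stages are
    always ensured (from cache when valid).  Outputs are written to
    ``config.output_dir`` with the configuration hash in every file header.
    """
    if stages is None:
        wanted = list(STAGES)
    elif isinstance(stages, str):
        wanted = [stages]
    else:
        wanted = list(stages)
    for s in wanted:
        if s not in STAGES:
            raise ValueError(f"unknown stage {s!r}; valid stages: {STAGES}")
    last = max(STAGES.index(s) for s in wanted)
    pipeline = STAGES[: last + 1]

    out_dir = Path(config.output_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    chash = config_hash(config)
    logger.info("pipeline start: config_hash=%s seed=%d stages=%s", chash, config.seed, pipeline)

    tables: dict[str, pd.DataFrame] = {}
    paths: dict[str, Path] = {}
    executed: list[str] = []
    upstream_key: str | None = None
    upstream_table: pd.DataFrame | None = None
    for stage in pipeline:
        key = _stage_key(config, stage, upstream_key)
        cached = None if force else _load_cache(out_dir, stage, key)
        if cached is not None:
            logger.info("stage %-8s cached (key=%s)", stage, key)
            table = cached
        else:
            t0 = time.perf_counter()
            table = _STAGE_COMPUTE[stage](config, upstream_table)
            elapsed = time.perf_counter() - t0
            logger.info("stage %-8s computed in %.2f s (key=%s)", stage, elapsed, key)
            _write_csv(table, out_dir / _STAGE_FILES[stage], config)
            _store_cache(out_dir, stage, key)
            executed.append(stage)
        tables[stage] = table
        paths[stage] = out_dir / _STAGE_FILES[stage]
        upstream_key = key
        upstream_table = table

    if "pricing" in tables:
        mrp = _mrp_summary(tables["pricing"])
        _write_csv(mrp, out_dir / "mrp.csv", config)
        tables["mrp"] = mrp
        paths["mrp"] = out_dir / "mrp.csv"
    if "roi" in tables:
        wide = _roi_wide(tables["roi"])
        _write_csv(wide, out_dir / "roi_by_design.csv", config)
        tables["roi_wide"] = wide
        paths["roi_wide"] = out_dir / "roi_by_design.csv"

    bundle = {
        "config_hash": chash,
        "seed": config.seed,
        "stages": {s: str(paths[s]) for s in tables if s in paths},
    }
    if "roi" in tables:
        roi_df = tables["roi"]
        bundle["optimal_n"] = {
            str(design): int(n)
            for design, n in roi_df[roi_df["optimal"]]
            .set_index("design")["n_per_arm"]
            .items()
        }
        bundle["expected_roi"] = {
            f"{r.design}:n{int(r.n_per_arm)}": float(r.expected_roi)
            for r in roi_df.itertuples()
        }
    if "priors" in tables:
        bundle["priors"] = tables["priors"].to_dict(orient="records")
    bundle_path = out_dir / "bundle.json"
    bundle_path.write_text(json.dumps(bundle, sort_keys=True, indent=1))
    paths["bundle"] = bundle_path

    return PipelineResult(
        config_hash=chash, seed=config.seed, tables=tables, paths=paths, executed=executed
    )
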