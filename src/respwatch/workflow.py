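"""End-to-end orchestration: simulate → epochs → features → models → evaluation.

A single :class:`RunConfig` (YAML-loadable, unknown keys rejected) drives
the whole run.  One global seed is fanned out to per-stage child seeds by a
deterministic derivation (``numpy.random.SeedSequence([seed, stage_index])``)
so stages are individually re-runnable and a full run is byte-identical
under a fixed seed.  Admissions are split into a development half (model
fitting, imputation medians, relative-risk denominators) and a validation
half (all evaluation), emulating external validation with independent
admissions.
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
import logging
from dataclasses import dataclass, field
from pathlib import Path
from typing import Any, Mapping, Sequence

import numpy as np
import pandas as pd
import yaml

from . import io as rio
from .cohort import AdmissionRecord, CohortConfig, generate_cohort
from .features import (
    FEATURE_NAMES,
    FeatureParams,
    compute_admission_features,
    feature_medians,
    impute_missing,
    iter_windows,
)
from .risk_models import (
    MODEL_PRESETS,
    FittedRiskModel,
    fit_model,
    make_basis,
    predict_relative_risk,
)
from .vent_epochs import EpochRules, VentilationEpoch, build_epochs, censor_mask, split_at_intubation
from . import evaluation as ev

logger = logging.getLogger(__name__)

__all__ = [
    "EvalParams",
    "RunConfig",
    "load_config",
    "config_to_dict",
    "config_hash",
    "stage_seed",
    "reconstruct_epochs",
    "censor_grid",
    "extract_features",
    "split_dev_val",
    "fit_models",
    "evaluate_model",
    "run_pipeline",
    "write_report",
]


@dataclass(frozen=True)
class EvalParams:
    """Evaluation-stage parameters."""

    windows_hours: tuple[float, ...] = tuple(range(4, 25, 2))
    n_bootstrap: int = 200
    lag_hours: float = 12.0
    trajectory_axis_hours: float = 48.0
    calibration_horizon_hours: float = 12.0

    def __post_init__(self) -> None:
        if self.n_bootstrap < 1:
            raise ValueError("n_bootstrap must be >= 1")
        if not self.windows_hours:
            raise ValueError("windows_hours must be non-empty")


@dataclass(frozen=True)
class RunConfig:
    """Full pipeline configuration."""

    cohort: CohortConfig = field(default_factory=CohortConfig)
    epoch_rules: EpochRules = field(default_factory=EpochRules)
    features: FeatureParams = field(default_factory=FeatureParams)
    evaluation: EvalParams = field(default_factory=EvalParams)
    models: tuple[str, ...] = ("politano", "moss_micu", "moss_sicu")
    politano_stepwise: bool = False
    dev_fraction: float = 0.5
    relative_risk_cap: float | None = None
    seed: int = 0
    plots: bool = False

    def __post_init__(self) -> None:
        if not 0 < self.dev_fraction < 1:
            raise ValueError("dev_fraction must lie in (0, 1)")
        known = set(MODEL_PRESETS(FEATURE_NAMES))
        unknown = set(self.models) - known
        if unknown:
            raise ValueError(f"unknown model name(s): {sorted(unknown)}")


_SECTION_TYPES = {
    "cohort": CohortConfig,
    "epoch_rules": EpochRules,
    "features": FeatureParams,
    "evaluation": EvalParams,
}

_TUPLE_FIELDS = {
    "doc_interval_hours",
    "dfa_scales",
    "windows_hours",
    "models",
    "knot_quantiles",
}


def _build_dataclass(cls, data: Mapping[str, Any], path: str):
    names = {f.name for f in dataclasses.fields(cls)}
    unknown = set(data) - names
    if unknown:
        raise ValueError(f"unknown config key(s) under '{path}': {sorted(unknown)}")
    kwargs = {
        k: tuple(v) if k in _TUPLE_FIELDS and isinstance(v, (list, tuple)) else v
        for k, v in data.items()
    }
    try:
        return cls(**kwargs)
    except (TypeError, ValueError) as exc:
        raise ValueError(f"invalid config under '{path}': {exc}") from exc


def config_from_dict(data: Mapping[str, Any] | None) -> RunConfig:
    data = dict(data or {})
    kwargs: dict[str, Any] = {}
    for section, cls in _SECTION_TYPES.items():
        if section in data:
            kwargs[section] = _build_dataclass(cls, data.pop(section) or {}, section)
    top_names = {f.name for f in dataclasses.fields(RunConfig)}
    unknown = set(data) - top_names
    if unknown:
        raise ValueError(f"unknown config key(s): {sorted(unknown)}")
    for k, v in data.items():
        kwargs[k] = tuple(v) if k in _TUPLE_FIELDS and isinstance(v, (list, tuple)) else v
    return RunConfig(**kwargs)


def load_config(path: Path | str) -> RunConfig:
    """Load and validate a YAML run configuration; defaults fill absent keys."""
    with open(path, "r", encoding="utf-8") as fh:
        data = yaml.safe_load(fh)
    return config_from_dict(data)


def config_to_dict(config: RunConfig) -> dict:
    return dataclasses.asdict(config)


def config_hash(config: RunConfig) -> str:
    """Stable short hash of the full configuration."""
    canon = json.dumps(config_to_dict(config), sort_keys=True, default=list)
    return hashlib.sha256(canon.encode()).hexdigest()[:12]


def stage_seed(seed: int, stage: int) -> int:
    """Deterministic child seed (< 2^31) for a numbered stage."""
    ss = np.random.SeedSequence([int(seed), int(stage)])
    return int(ss.generate_state(1)[0] % 2**31)


# ---------------------------------------------------------------------------
# stages


def reconstruct_epochs(
    records: Sequence[AdmissionRecord], rules: EpochRules
) -> dict[str, list[VentilationEpoch]]:
    """Build ventilation epochs per admission from its flowsheet entries and
    reconcile them with the known emergent-intubation time."""
    out: dict[str, list[VentilationEpoch]] = {}
    for r in records:
        eps = build_epochs(r.flowsheet, rules)
        events = [r.event_time] if r.event_time is not None else []
        out[r.admission_id] = split_at_intubation(
            eps, r.flowsheet, events, rules, admission_end=r.duration
        )
    return out


def censor_grid(
    record: AdmissionRecord,
    epochs: Sequence[VentilationEpoch],
    params: FeatureParams,
) -> np.ndarray:
    """Censor mask on the admission's window-end grid."""
    ends = np.array([e for _, e in iter_windows(0.0, record.duration, params)])
    return censor_mask(ends, epochs, dni=record.dni)


def extract_features(
    records: Sequence[AdmissionRecord],
    epochs: Mapping[str, Sequence[VentilationEpoch]],
    params: FeatureParams,
) -> pd.DataFrame:
    """Concatenated per-admission feature tables, censored windows dropped."""
    frames = []
    for r in records:
        mask = censor_grid(r, epochs.get(r.admission_id, []), params)
        df = compute_admission_features(r, params, censor=mask)
        if len(df):  # fully-censored (e.g. DNI) admissions contribute no rows
            frames.append(df)
    if not frames:
        return pd.DataFrame(columns=["admission_id", "window_end_min", *FEATURE_NAMES])
    return pd.concat(frames, ignore_index=True)


def split_dev_val(
    records: Sequence[AdmissionRecord], dev_fraction: float, seed: int
) -> tuple[set[str], set[str]]:
    """Deterministic development/validation split, stratified by event status."""
    rng = np.random.default_rng(np.random.SeedSequence([seed, 91]))
    dev: set[str] = set()
    val: set[str] = set()
    for has_event in (True, False):
        ids = sorted(
            r.admission_id for r in records if (r.event_time is not None) == has_event
        )
        ids = list(np.array(ids)[rng.permutation(len(ids))])
        n_dev = int(round(len(ids) * dev_fraction))
        dev.update(ids[:n_dev])
        val.update(ids[n_dev:])
    return dev, val


def _labels_for(features: pd.DataFrame, event_times: Mapping[str, float | None],
                horizon_hours: float) -> np.ndarray:
    ev = np.array(
        [
            np.nan if event_times.get(a) is None else float(event_times[a])
            for a in features["admission_id"]
        ],
        dtype=float,
    )
    delta = ev - features["window_end_min"].to_numpy(dtype=float)
    return ((delta > 0) & (delta <= horizon_hours * 60.0)).astype(int)


def fit_models(
    dev_features: pd.DataFrame,
    event_times: Mapping[str, float | None],
    model_names: Sequence[str],
    politano_stepwise: bool = False,
) -> dict[str, FittedRiskModel]:
    """Fit the requested preset models on the (imputed) development features."""
    presets = MODEL_PRESETS(FEATURE_NAMES)
    fitted: dict[str, FittedRiskModel] = {}
    for name in model_names:
        spec = presets[name]
        if name == "politano" and politano_stepwise:
            spec = dataclasses.replace(spec, selection="forward-stepwise")
        design, knots = make_basis(dev_features, spec)
        y = _labels_for(dev_features, event_times, spec.horizon_hours)
        fitted[name] = fit_model(design, y, spec, knots=knots)
        logger.info(
            "fitted %s: %d dev epochs, prevalence %.4f, train_mean_p %.4f",
            name, len(y), y.mean(), fitted[name].train_mean_p,
        )
    return fitted


def evaluate_model(
    risk: pd.DataFrame,
    event_times: Mapping[str, float | None],
    train_mean_p: float,
    params: EvalParams,
    seed: int,
) -> dict[str, pd.DataFrame]:
    """Full evaluation of one model's validation risk series."""
    aligned = ev.align_to_event(risk, event_times, params.trajectory_axis_hours)
    trajectory = ev.mean_trajectory_ci(aligned)
    pvals = ev.signed_rank_lag_test(aligned, params.lag_hours)
    trajectory = trajectory.merge(pvals, on="offset_min", how="left")
    auc_curve = ev.auc_vs_window(
        risk,
        event_times,
        windows_hours=params.windows_hours,
        n_boot=params.n_bootstrap,
        seed=seed,
    )
    calibration = ev.calibration_deciles(
        risk, event_times, train_mean_p, params.calibration_horizon_hours
    )
    return {
        "aligned": aligned,
        "trajectory": trajectory,
        "auc_curve": auc_curve,
        "calibration": calibration,
    }


# ---------------------------------------------------------------------------
# full pipeline


def run_pipeline(config: RunConfig, outdir: Path | str | None = None) -> dict:
    """Execute the whole analysis; optionally write artifacts to ``outdir``.

    Returns a dict with the cohort records, reconstructed epochs, feature
    tables, fitted models, per-model risk series and evaluation outputs.
    """
    meta = f"config_hash={config_hash(config)} seed={config.seed}"
    logger.info("run_pipeline: %s", meta)

    cohort_cfg = dataclasses.replace(config.cohort, seed=stage_seed(config.seed, 0))
    records = generate_cohort(cohort_cfg)
    event_times = {r.admission_id: r.event_time for r in records}

    epochs = reconstruct_epochs(records, config.epoch_rules)
    features = extract_features(records, epochs, config.features)

    dev_ids, val_ids = split_dev_val(records, config.dev_fraction, stage_seed(config.seed, 1))
    dev_raw = features[features["admission_id"].isin(dev_ids)].reset_index(drop=True)
    val_raw = features[features["admission_id"].isin(val_ids)].reset_index(drop=True)
    medians = feature_medians(dev_raw)
    dev_feat = impute_missing(dev_raw, medians)
    val_feat = impute_missing(val_raw, medians)

    models = fit_models(dev_feat, event_times, config.models, config.politano_stepwise)

    risk: dict[str, pd.DataFrame] = {}
    results: dict[str, dict[str, pd.DataFrame]] = {}
    for k, (name, model) in enumerate(models.items()):
        risk[name] = predict_relative_risk(model, val_feat, cap=config.relative_risk_cap)
        results[name] = evaluate_model(
            risk[name],
            event_times,
            model.train_mean_p,
            config.evaluation,
            seed=stage_seed(config.seed, 100 + k),
        )

    artifacts = {
        "meta": meta,
        "config": config,
        "records": records,
        "event_times": event_times,
        "epochs": epochs,
        "features": features,
        "medians": medians,
        "dev_ids": dev_ids,
        "val_ids": val_ids,
        "dev_features": dev_feat,
        "val_features": val_feat,
        "models": models,
        "risk": risk,
        "results": results,
    }
    if outdir is not None:
        write_artifacts(artifacts, outdir)
    return artifacts


def write_artifacts(artifacts: dict, outdir: Path | str) -> None:
    """Persist stage tables, model JSONs and the run report."""
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    meta = artifacts["meta"]
    config: RunConfig = artifacts["config"]

    rio.write_csv(rio.epochs_to_frame(artifacts["epochs"]), outdir / "epochs.csv", meta)
    rio.write_csv(artifacts["features"], outdir / "features.csv", meta)
    med = artifacts["medians"].rename_axis("feature").reset_index(name="median")
    rio.write_csv(med, outdir / "medians.csv", meta)
    for name, model in artifacts["models"].items():
        (outdir / f"model_{name}.json").write_text(model.to_json(), encoding="utf-8")
    for name, df in artifacts["risk"].items():
        rio.write_csv(df, outdir / f"risk_{name}.csv", meta)
    for name, res in artifacts["results"].items():
        rio.write_csv(res["trajectory"], outdir / f"trajectory_{name}.csv", meta)
        rio.write_csv(res["auc_curve"], outdir / f"auc_curve_{name}.csv", meta)
        rio.write_csv(res["calibration"], outdir / f"calibration_{name}.csv", meta)
    (outdir / "run_meta.json").write_text(
        json.dumps(
            {
                "config_hash": config_hash(config),
                "seed": config.seed,
                "n_admissions": len(artifacts["records"]),
                "n_events": sum(
                    1 for t in artifacts["event_times"].values() if t is not None
                ),
                "models": list(artifacts["models"]),
            },
            indent=2,
        ),
        encoding="utf-8",
    )
    write_report(artifacts, outdir)


def _leadtime_table(artifacts: dict) -> pd.DataFrame:
    """Events with uncensored monitoring data as a function of lead time."""
    rows = []
    hours = np.arange(0, 49, 4)
    any_model = next(iter(artifacts["results"].values()), None)
    if any_model is None:
        return pd.DataFrame(columns=["leadtime_hours", "n_events_with_data"])
    aligned: pd.DataFrame = any_model["aligned"]
    offs = np.asarray(aligned.columns, dtype=float)
    for h in hours:
        col = offs[np.argmin(np.abs(offs + h * 60.0))]
        n = int(aligned[col].notna().sum())
        rows.append({"leadtime_hours": int(h), "n_events_with_data": n})
    return pd.DataFrame(rows)


def write_report(artifacts: dict, outdir: Path | str) -> None:
    """Plain-text run report plus the lead-time table (and optional plots)."""
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    config: RunConfig = artifacts["config"]
    lines = [
        "respwatch run report",
        f"{artifacts['meta']}",
        "",
        f"admissions: {len(artifacts['records'])} "
        f"(events: {sum(1 for t in artifacts['event_times'].values() if t is not None)}, "
        f"dni: {sum(1 for r in artifacts['records'] if r.dni)})",
        f"development/validation admissions: {len(artifacts['dev_ids'])}/{len(artifacts['val_ids'])}",
        f"feature epochs (uncensored): {len(artifacts['features'])}",
        "",
    ]
    lead = _leadtime_table(artifacts)
    rio.write_csv(lead, outdir / "leadtime.csv", artifacts["meta"])
    if lead.empty or not artifacts["results"]:
        lines.append("no events: trajectory/AUC/calibration sections empty")
    for name, res in artifacts["results"].items():
        traj = res["trajectory"]
        auc = res["auc_curve"]
        cal = res["calibration"]
        lines.append(f"model {name}:")
        if len(traj):
            near = traj.iloc[-1]
            far = traj.iloc[0]
            lines.append(
                f"  mean relative risk {far['mean']:.2f} at {far['offset_min']/60:.0f} h "
                f"-> {near['mean']:.2f} at {near['offset_min']/60:.0f} h"
            )
            sig = traj[(traj["p"] < 0.05)]
            if len(sig):
                lines.append(
                    f"  signed-rank p<0.05 from {sig['offset_min'].min()/60:.2f} h "
                    f"({len(sig)} of {traj['p'].notna().sum()} tested offsets)"
                )
        for row in auc.itertuples(index=False):
            lines.append(
                f"  AUC({row.window_hours:.0f} h window) = {row.auc:.3f} "
                f"[{row.ci_low:.3f}, {row.ci_high:.3f}]"
            )
        lines.append(
            "  calibration deciles (predicted -> observed): "
            + ", ".join(
                f"{r.predicted_rr:.2f}->{r.observed_rr:.2f}" for r in cal.itertuples(index=False)
            )
        )
        lines.append("")
    (outdir / "report.txt").write_text("\n".join(lines) + "\n", encoding="utf-8")
    if config.plots:
        _write_plots(artifacts, outdir)


def _write_plots(artifacts: dict, outdir: Path) -> None:  # pragma: no cover
    try:
        import matplotlib

        matplotlib.use("Agg")
        import matplotlib.pyplot as plt
    except ImportError:
        logger.warning("matplotlib unavailable; skipping plots")
        return
    for name, res in artifacts["results"].items():
        traj = res["trajectory"]
        fig, axes = plt.subplots(1, 3, figsize=(14, 4))
        ax = axes[0]
        ax.plot(traj["offset_min"] / 60.0, traj["mean"], color="k")
        ax.fill_between(
            traj["offset_min"] / 60.0, traj["ci_low"], traj["ci_high"],
            color="0.8", label="95% CI",
        )
        sig = traj[traj["p"] < 0.05]
        ax.plot(sig["offset_min"] / 60.0, sig["mean"], "wo", mec="k", ms=4)
        ax.set_xlabel("hours before emergent intubation")
        ax.set_ylabel("mean relative risk")
        auc = res["auc_curve"]
        ax = axes[1]
        ax.errorbar(
            auc["window_hours"], auc["auc"],
            yerr=[auc["auc"] - auc["ci_low"], auc["ci_high"] - auc["auc"]],
            fmt="o-", capsize=3,
        )
        ax.set_xlabel("event window (h)")
        ax.set_ylabel("AUC")
        cal = res["calibration"]
        ax = axes[2]
        ax.plot(cal["predicted_rr"], cal["observed_rr"], "o-")
        lim = max(cal["predicted_rr"].max(), cal["observed_rr"].max()) * 1.05
        ax.plot([0, lim], [0, lim], "k--", lw=1)
        ax.set_xlabel("predicted relative risk")
        ax.set_ylabel("observed relative risk")
        fig.suptitle(name)
        fig.tight_layout()
        fig.savefig(outdir / f"figures_{name}.png", dpi=120)
        plt.close(fig)
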