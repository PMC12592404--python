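"""End-to-end orchestration: simulate -> preprocess -> psychometrics ->
models -> comparison, with a reproducibility manifest.

All stage outputs are plain CSV/JSON; the manifest records the config
snapshot, seeds, file digests and warnings so a rerun with the same manifest
inputs is byte-identical.
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
import logging
import time
from dataclasses import dataclass, field
from pathlib import Path
from typing import Mapping, Sequence

import numpy as np
import pandas as pd

from magest.comparison import (
    ModelComparisonRow,
    fit_comparison_model,
    rank_models,
)
from magest.datamodel import (
    Modality,
    PipelineConfig,
    Session,
    Task,
    TrialRecord,
    default_config,
    load_config,
    read_trials,
    trials_to_frame,
    write_trials,
)
from magest.errors import MagestError, ValidationError
from magest.models import ModelName, build_model_prior, predict_session
from magest.preprocess import (
    baseline_fit_table,
    detect_outliers,
    fit_line,
    normalize_responses,
)
from magest.psychometrics import (
    PrecisionProfile,
    modality_weights,
    regression_index,
    sensory_precision,
)
from magest.simulate import (
    CohortSpec,
    ObserverParams,
    Regime,
    cohort_manifest,
    simulate_cohort,
)

logger = logging.getLogger(__name__)

#: Task-dominant modality (most reliable sense for the judgment).
DOMINANT = {Task.TEMPORAL: Modality.A, Task.SPATIAL: Modality.V}


def calibrate_noise_floors(
    config: PipelineConfig,
    task: Task,
    ri_dominant: float = 0.2,
    ri_nondominant: float = 0.6,
) -> dict[Modality, float]:
    """Constant likelihood SDs that target given baseline regression indices.

    In a baseline session the expected RI equals w_P = sigma_L^2 /
    (sigma_L^2 + sigma_P^2) against the modality's own set prior, so
    sigma_L = sigma_P * sqrt(RI / (1 - RI)).
    """
    from magest.priors import TargetProvenance, set_moment_target, solve_prior

    floors = {}
    for modality in Modality:
        sset = config.stimulus_set(task, modality)
        prior = solve_prior(
            set_moment_target(sset, TargetProvenance(config.prior_provenance)),
            tol=config.solver_tol,
            on_infeasible="best_fit",
        )
        ri = ri_dominant if modality is DOMINANT[task] else ri_nondominant
        floors[modality] = prior.implied_sd * np.sqrt(ri / (1.0 - ri))
    return floors


def default_observer_params(
    config: PipelineConfig, task: Task, regime: Regime | str, seed: int = 0
) -> ObserverParams:
    """Observer parameters with noise calibrated to the task's RI ordering."""
    floors = calibrate_noise_floors(config, task)
    return ObserverParams(
        sigma_A_floor=floors[Modality.A],
        sigma_V_floor=floors[Modality.V],
        motor_sd=0.0,
        regime=Regime(regime),
        seed=seed,
    )


# ---------------------------------------------------------------------------
# Analysis stages on record collections
# ---------------------------------------------------------------------------


def split_by_participant(
    records: Sequence[TrialRecord],
) -> dict[str, list[TrialRecord]]:
    out: dict[str, list[TrialRecord]] = {}
    for r in records:
        out.setdefault(r.participant_id, []).append(r)
    return out


def preprocess_stage(
    records: Sequence[TrialRecord], config: PipelineConfig
) -> tuple[list[TrialRecord], "pd.DataFrame", dict]:
    """Outlier screening on baseline RMSE, then per-participant normalization.

    Returns (retained normalized records, outlier table, exclusions dict).
    """
    fits = baseline_fit_table(records)
    report = detect_outliers(fits, threshold=config.outlier_threshold)
    retained: list[TrialRecord] = []
    for task in {r.task for r in records}:
        dropped = report.excluded_for(task)
        task_records = [r for r in records if r.task is task]
        for pid, trials in sorted(split_by_participant(task_records).items()):
            if pid in dropped:
                logger.info("excluding %s from %s task", pid, task.value)
                continue
            if config.normalize:
                trials = normalize_responses(trials, config)
            retained.extend(trials)
    exclusions = {
        task.value: sorted(report.excluded_for(task)) for task in {r.task for r in records}
    }
    return retained, report.table, exclusions


def psychometrics_stage(
    records: Sequence[TrialRecord], config: PipelineConfig
) -> tuple[pd.DataFrame, pd.DataFrame, dict]:
    """Per-cell fits/RIs, per-stimulus precision, per-participant weights.

    Returns (metrics frame, precision frame, context dict). The context maps
    (participant, task) to its precision profiles and modality weights for
    downstream model prediction.
    """
    metric_rows = []
    precision_rows = []
    context: dict[tuple[str, str], dict] = {}
    by_pt: dict[tuple[str, Task], list[TrialRecord]] = {}
    for r in records:
        by_pt.setdefault((r.participant_id, r.task), []).append(r)

    for (pid, task), trials in sorted(by_pt.items(), key=lambda kv: (kv[0][0], kv[0][1].value)):
        profiles: dict[Modality, PrecisionProfile] = {}
        for session in (Session.AUDIO, Session.VISION, Session.INTERLEAVED):
            for modality in Modality:
                cell = [
                    t for t in trials if t.session is session and t.modality is modality
                ]
                if not cell:
                    continue
                fit = fit_line([t.stimulus for t in cell], [t.response for t in cell])
                ri = regression_index(fit, task, modality, session)
                metric_rows.append(
                    {
                        "participant_id": pid,
                        "task": task.value,
                        "session": session.value,
                        "modality": modality.value,
                        "slope": fit.slope,
                        "intercept": fit.intercept,
                        "ri": ri.ri,
                        "rmse": fit.rmse,
                        "n": fit.n,
                    }
                )
                if session is not Session.INTERLEAVED:
                    profile = sensory_precision(cell, fit)
                    profiles[modality] = profile
                    for s, v in profile.variances.items():
                        precision_rows.append(
                            {
                                "participant_id": pid,
                                "task": task.value,
                                "modality": modality.value,
                                "stimulus": s,
                                "variance": v,
                                "sd": float(np.sqrt(v)),
                                "n": profile.counts[s],
                            }
                        )
        entry: dict = {"profiles": profiles}
        if Modality.A in profiles and Modality.V in profiles:
            entry["weights"] = modality_weights(
                profiles[Modality.A], profiles[Modality.V], config.precision_pooling
            )
        context[(pid, task.value)] = entry

    metrics = pd.DataFrame(
        metric_rows,
        columns=[
            "participant_id", "task", "session", "modality",
            "slope", "intercept", "ri", "rmse", "n",
        ],
    )
    precision = pd.DataFrame(
        precision_rows,
        columns=["participant_id", "task", "modality", "stimulus", "variance", "sd", "n"],
    )
    return metrics, precision, context


def prediction_stage(
    records: Sequence[TrialRecord],
    config: PipelineConfig,
    context: Mapping[tuple[str, str], dict],
    models: Sequence[ModelName | str] = tuple(ModelName),
) -> pd.DataFrame:
    """Per-trial model predictions for the interleaved sessions.

    Segregation/CTE priors are shared across participants; the WCTE prior is
    rebuilt per participant from that participant's modality weights.
    """
    frames = []
    by_pt: dict[tuple[str, Task], list[TrialRecord]] = {}
    for r in records:
        if r.session is Session.INTERLEAVED:
            by_pt.setdefault((r.participant_id, r.task), []).append(r)

    model_names = [ModelName(m) for m in models]
    shared: dict[tuple[Task, ModelName], object] = {}
    for (pid, task), trials in sorted(by_pt.items(), key=lambda kv: (kv[0][0], kv[0][1].value)):
        entry = context.get((pid, task.value))
        if entry is None or "weights" not in entry:
            raise ValidationError(
                f"no baseline psychometrics for participant {pid}, task {task.value}"
            )
        for name in model_names:
            if name is ModelName.WCTE:
                spec = build_model_prior(
                    name, config, task, weights=entry["weights"]
                )
            else:
                key = (task, name)
                if key not in shared:
                    shared[key] = build_model_prior(name, config, task)
                spec = shared[key]
            frame = predict_session(trials, entry["profiles"], spec)
            frame.insert(1, "task", task.value)
            frames.append(frame)
    if not frames:
        raise ValidationError("no interleaved trials to predict")
    return pd.concat(frames, ignore_index=True)


def comparison_stage(
    records: Sequence[TrialRecord],
    predictions: pd.DataFrame,
    config: PipelineConfig,
    with_predicted_r2: bool = True,
) -> dict[str, object]:
    """Score every model per task and rank them."""
    observed = trials_to_frame(
        [r for r in records if r.session is Session.INTERLEAVED]
    )
    reports: dict[str, object] = {}
    for task_key, preds_task in predictions.groupby("task", sort=True):
        rows: list[ModelComparisonRow] = []
        for model_name, preds in preds_task.groupby("model", sort=True):
            merged = observed[observed["task"] == task_key].merge(
                preds,
                on=["participant_id", "trial_index"],
                suffixes=("", "_pred"),
                validate="one_to_one",
            )
            if len(merged) != (observed["task"] == task_key).sum():
                raise ValidationError(
                    f"prediction/observation mismatch for model {model_name}"
                )
            rows.append(
                fit_comparison_model(
                    merged["response"].to_numpy(),
                    merged["predicted"].to_numpy(),
                    merged["stimulus"].to_numpy(),
                    merged["participant_id"].to_numpy(),
                    model_name=str(model_name),
                    cv_folds=config.cv_folds if with_predicted_r2 else None,
                    cv_seed=config.cv_seed,
                )
            )
        reports[str(task_key)] = rank_models(rows)
    return reports


# ---------------------------------------------------------------------------
# Full run
# ---------------------------------------------------------------------------


@dataclass(frozen=True)
class RunOptions:
    """Options for one full pipeline run."""

    task: Task = Task.TEMPORAL
    regime: Regime = Regime.SEG_AUDIO
    n_participants: int = 19
    master_seed: int = 1
    motor_sd: float = 0.0
    jitter: Mapping[str, float] = field(default_factory=dict)
    input_csv: str | None = None  # analyze a user table instead of simulating
    with_predicted_r2: bool = True


def _sha256(path: Path) -> str:
    return hashlib.sha256(path.read_bytes()).hexdigest()


def run_full(
    config: PipelineConfig | str | Path | None,
    out_dir: str | Path,
    options: RunOptions | None = None,
) -> dict:
    """Execute the full chain and write all artifacts plus a manifest.

    Artifacts: ``trials.csv`` (simulated input, with ``trials.params.json``
    sidecar), ``normalized.csv``, ``outliers.csv``, ``metrics.csv``,
    ``precision.csv``, ``predictions.csv``, ``table1_<task>.csv``,
    ``report.json``, ``manifest.json``.
    """
    if config is None or isinstance(config, (str, Path)):
        config = load_config(config)
    options = options or RunOptions()
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    written: list[Path] = []
    warnings_log: list[str] = []

    if options.input_csv:
        records = read_trials(options.input_csv, config)
        sidecar = None
    else:
        base = default_observer_params(
            config, options.task, options.regime, seed=options.master_seed
        )
        base = dataclasses.replace(base, motor_sd=options.motor_sd)
        spec = CohortSpec(
            n_participants=options.n_participants,
            base_params=base,
            master_seed=options.master_seed,
            jitter=options.jitter,
        )
        records = simulate_cohort(spec, config, options.task)
        sidecar = cohort_manifest(spec, options.task)

    trials_path = write_trials(records, out / "trials.csv")
    written.append(trials_path)
    if sidecar is not None:
        p = out / "trials.params.json"
        p.write_text(json.dumps(sidecar, indent=2, sort_keys=True))
        written.append(p)

    retained, outlier_table, exclusions = preprocess_stage(records, config)
    outliers_path = out / "outliers.csv"
    outlier_table.to_csv(outliers_path, index=False)
    written.append(outliers_path)
    normalized_path = write_trials(retained, out / "normalized.csv")
    written.append(normalized_path)
    for task_name, dropped in exclusions.items():
        if dropped:
            warnings_log.append(f"excluded from {task_name}: {', '.join(dropped)}")

    metrics, precision, context = psychometrics_stage(retained, config)
    metrics_path = out / "metrics.csv"
    metrics.to_csv(metrics_path, index=False)
    precision_path = out / "precision.csv"
    precision.to_csv(precision_path, index=False)
    written.extend([metrics_path, precision_path])

    predictions = prediction_stage(retained, config, context)
    predictions_path = out / "predictions.csv"
    predictions.to_csv(predictions_path, index=False)
    written.append(predictions_path)

    reports = comparison_stage(
        retained, predictions, config, with_predicted_r2=options.with_predicted_r2
    )
    report_payload = {}
    for task_key, report in reports.items():
        table_path = out / f"table1_{task_key}.csv"
        frame = report.to_frame()
        frame[["model", "AIC", "logLik", "deviance", "R2", "predicted_R2"]].to_csv(
            table_path, index=False
        )
        written.append(table_path)
        if report.degenerate:
            warnings_log.append(
                f"{task_key}: comparable AIC support for {', '.join(report.degenerate)}"
            )
        report_payload[task_key] = {
            "best_by_bic": report.best_by_bic,
            "best_by_aic": report.best_by_aic,
            "delta_aic": report.delta_aic,
            "delta_bic": report.delta_bic,
            "degenerate": list(report.degenerate),
            "rows": [dataclasses.asdict(r) for r in report.rows],
        }
    report_path = out / "report.json"
    report_path.write_text(json.dumps(report_payload, indent=2, sort_keys=True))
    written.append(report_path)

    manifest = {
        "config": config_snapshot(config),
        "options": {
            "task": options.task.value,
            "regime": options.regime.value,
            "n_participants": options.n_participants,
            "master_seed": options.master_seed,
            "motor_sd": options.motor_sd,
            "jitter": dict(options.jitter),
            "input_csv": options.input_csv,
        },
        "outputs": {p.name: _sha256(p) for p in written},
        "warnings": warnings_log,
        "timestamp": time.strftime("%Y-%m-%dT%H:%M:%S", time.gmtime()),
    }
    manifest_path = out / "manifest.json"
    manifest_path.write_text(json.dumps(manifest, indent=2, sort_keys=True))
    return manifest


def config_snapshot(config: PipelineConfig) -> dict:
    """JSON-serializable snapshot of a config (hash-stable)."""
    return {
        "stimulus_sets": {
            f"{task.value}/{modality.value}": {
                "values": list(sset.values),
                "lower_bound": sset.lower_bound,
                "upper_bound": sset.upper_bound,
            }
            for (task, modality), sset in sorted(
                config.stimulus_sets.items(), key=lambda kv: (kv[0][0].value, kv[0][1].value)
            )
        },
        "session_designs": {
            task.value: {
                "baseline": d.trials_per_modality_baseline,
                "interleaved": d.trials_per_modality_interleaved,
            }
            for task, d in sorted(config.session_designs.items(), key=lambda kv: kv[0].value)
        },
        "outlier_threshold": config.outlier_threshold,
        "solver_tol": config.solver_tol,
        "cv_folds": config.cv_folds,
        "cv_seed": config.cv_seed,
        "normalize": config.normalize,
        "prior_provenance": config.prior_provenance,
        "precision_pooling": config.precision_pooling,
    }


def validate_config(path: str | Path) -> list[str]:
    """Collect all schema violations in a config file; empty list means valid."""
    diagnostics: list[str] = []
    try:
        config = load_config(path)
    except MagestError as exc:
        return [str(exc)]
    except Exception as exc:  # malformed YAML/JSON
        return [f"unreadable config: {exc}"]

    for (task, modality), sset in config.stimulus_sets.items():
        expected = 9 if task is Task.TEMPORAL else 6
        if len(sset.values) != expected:
            diagnostics.append(
                f"stimulus set {task.value}/{modality.value} has "
                f"{len(sset.values)} values; the default design uses {expected}"
            )
    for task, design in config.session_designs.items():
        n_values = len(config.stimulus_set(task, Modality.A).values)
        for label, count in (
            ("baseline", design.trials_per_modality_baseline),
            ("interleaved", design.trials_per_modality_interleaved),
        ):
            if count % n_values:
                diagnostics.append(
                    f"{task.value} {label} count {count} not divisible by "
                    f"{n_values} stimulus values; remainder trials will be "
                    "assigned by the schedule seed"
                )
    diagnostics.extend(_simulation_diagnostics(path))
    return diagnostics


def _simulation_diagnostics(path: str | Path) -> list[str]:
    """Check the optional ``simulation:`` section of a raw config file."""
    import yaml

    try:
        data = yaml.safe_load(Path(path).read_text()) or {}
    except Exception:
        return []
    sim = data.get("simulation")
    if not isinstance(sim, Mapping):
        return []
    out = []
    for name in ("sigma_A_coef", "sigma_A_floor", "sigma_V_coef",
                 "sigma_V_floor", "motor_sd"):
        if name in sim and float(sim[name]) < 0:
            out.append(f"simulation.{name} must be >= 0")
    if "regime" in sim:
        try:
            Regime(sim["regime"])
        except ValueError:
            out.append(f"simulation.regime {sim['regime']!r} is not a known regime")
    if "n_participants" in sim and int(sim["n_participants"]) < 1:
        out.append("simulation.n_participants must be >= 1")
    return out
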