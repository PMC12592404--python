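"""Canonical data types, trial-table I/O and pipeline configuration.

The canonical trial table is a long-format CSV with columns
``participant_id,task,session,modality,stimulus,response,trial_index``.
Stimulus magnitudes are milliseconds for the temporal task and degrees of
visual angle for the spatial task; no unit conversion happens anywhere
downstream.
"""

from __future__ import annotations

import enum
import json
import math
from dataclasses import dataclass, field, replace
from pathlib import Path
from typing import Iterable, Mapping, Sequence

import pandas as pd
import yaml

from magest.errors import SchemaError, ValidationError

#: Canonical CSV column order.
TRIAL_COLUMNS = (
    "participant_id",
    "task",
    "session",
    "modality",
    "stimulus",
    "response",
    "trial_index",
)

#: Absolute tolerance (task units) for stimulus set membership tests.
MEMBERSHIP_ATOL = 1e-9


class Task(str, enum.Enum):
    TEMPORAL = "temporal"
    SPATIAL = "spatial"


class Session(str, enum.Enum):
    AUDIO = "audio"
    VISION = "vision"
    INTERLEAVED = "interleaved"


class Modality(str, enum.Enum):
    A = "A"
    V = "V"


#: Single-modality (baseline) session implied by each modality.
BASELINE_SESSION = {Modality.A: Session.AUDIO, Modality.V: Session.VISION}


@dataclass(frozen=True)
class StimulusSet:
    """Ordered stimulus magnitudes with their physical bounds for one task x modality."""

    task: Task
    modality: Modality
    values: tuple[float, ...]
    lower_bound: float
    upper_bound: float

    def __post_init__(self):
        vals = tuple(float(v) for v in self.values)
        object.__setattr__(self, "values", vals)
        if len(vals) < 2:
            raise ValidationError("StimulusSet needs at least two values")
        if any(v <= 0 for v in vals):
            raise ValidationError("stimulus magnitudes must be positive")
        if any(b <= a for a, b in zip(vals, vals[1:])):
            raise ValidationError("stimulus values must be strictly increasing")
        if not math.isclose(self.lower_bound, vals[0], abs_tol=MEMBERSHIP_ATOL):
            raise ValidationError("lower_bound must equal min(values)")
        if not math.isclose(self.upper_bound, vals[-1], abs_tol=MEMBERSHIP_ATOL):
            raise ValidationError("upper_bound must equal max(values)")

    @property
    def mean(self) -> float:
        return sum(self.values) / len(self.values)

    @property
    def median(self) -> float:
        n = len(self.values)
        mid = n // 2
        if n % 2:
            return self.values[mid]
        return 0.5 * (self.values[mid - 1] + self.values[mid])

    def contains(self, magnitude: float) -> bool:
        return any(
            math.isclose(magnitude, v, abs_tol=MEMBERSHIP_ATOL) for v in self.values
        )


@dataclass(frozen=True)
class SessionDesign:
    """Trial counts per modality for baseline and interleaved sessions of one task."""

    task: Task
    trials_per_modality_baseline: int
    trials_per_modality_interleaved: int

    def __post_init__(self):
        if self.trials_per_modality_baseline < 1:
            raise ValidationError("baseline trial count must be >= 1")
        if self.trials_per_modality_interleaved < 1:
            raise ValidationError("interleaved trial count must be >= 1")

    @property
    def interleaved_total(self) -> int:
        return 2 * self.trials_per_modality_interleaved

    def repetitions(self, n_values: int, session: Session) -> int:
        count = (
            self.trials_per_modality_interleaved
            if session is Session.INTERLEAVED
            else self.trials_per_modality_baseline
        )
        return count // n_values


@dataclass(frozen=True)
class TrialRecord:
    """One reproduction trial."""

    participant_id: str
    task: Task
    session: Session
    modality: Modality
    stimulus: float
    response: float
    trial_index: int

    def __post_init__(self):
        object.__setattr__(self, "stimulus", float(self.stimulus))
        object.__setattr__(self, "response", float(self.response))
        object.__setattr__(self, "trial_index", int(self.trial_index))
        if self.stimulus <= 0:
            raise ValidationError("stimulus must be > 0")
        if self.response < 0:
            raise ValidationError("response must be >= 0")
        if self.trial_index < 0:
            raise ValidationError("trial_index must be >= 0")
        if self.session is Session.AUDIO and self.modality is not Modality.A:
            raise ValidationError("session=audio requires modality=A")
        if self.session is Session.VISION and self.modality is not Modality.V:
            raise ValidationError("session=vision requires modality=V")


UNITS = {Task.TEMPORAL: "ms", Task.SPATIAL: "deg"}


@dataclass(frozen=True)
class PipelineConfig:
    """Everything the pipeline needs to know about the experimental design.

    ``stimulus_sets`` maps (task, modality) to a :class:`StimulusSet`;
    ``session_designs`` maps task to a :class:`SessionDesign`.
    """

    stimulus_sets: Mapping[tuple[Task, Modality], StimulusSet]
    session_designs: Mapping[Task, SessionDesign]
    outlier_threshold: float = 3.0
    solver_tol: float = 1e-10
    solver_max_iter: int = 200
    cv_folds: int = 10
    cv_seed: int = 20240
    normalize: bool = True
    prior_provenance: str = "discrete_set"
    precision_pooling: str = "unweighted"
    units: Mapping[Task, str] = field(default_factory=lambda: dict(UNITS))

    def __post_init__(self):
        if self.outlier_threshold <= 0:
            raise ValidationError("outlier_threshold must be > 0")
        if self.cv_folds < 2:
            raise ValidationError("cv_folds must be >= 2")
        if self.solver_tol <= 0:
            raise ValidationError("solver_tol must be > 0")
        if self.prior_provenance not in ("discrete_set", "continuous_uniform"):
            raise ValidationError(
                "prior_provenance must be 'discrete_set' or 'continuous_uniform'"
            )
        if self.precision_pooling not in ("unweighted", "n_weighted"):
            raise ValidationError(
                "precision_pooling must be 'unweighted' or 'n_weighted'"
            )

    def stimulus_set(self, task: Task, modality: Modality) -> StimulusSet:
        return self.stimulus_sets[(task, modality)]

    def design(self, task: Task) -> SessionDesign:
        return self.session_designs[task]


def _equally_spaced(lo: float, hi: float, n: int) -> tuple[float, ...]:
    step = (hi - lo) / (n - 1)
    return tuple(lo + i * step for i in range(n))


def default_config() -> PipelineConfig:
    """Default experimental design.

    Temporal sets are nine equally spaced durations (auditory 490-850 ms,
    visual 760-1120 ms, both on a 45 ms grid); spatial sets are six equally
    spaced lengths (auditory 22-50 deg, visual 5.5-33 deg). Baseline sessions
    hold 180 (temporal) / 120 (spatial) trials per modality and interleaved
    sessions the same per-modality counts, i.e. 360 / 240 trials in total.
    """
    sets = {
        (Task.TEMPORAL, Modality.A): StimulusSet(
            Task.TEMPORAL, Modality.A, _equally_spaced(490.0, 850.0, 9), 490.0, 850.0
        ),
        (Task.TEMPORAL, Modality.V): StimulusSet(
            Task.TEMPORAL, Modality.V, _equally_spaced(760.0, 1120.0, 9), 760.0, 1120.0
        ),
        (Task.SPATIAL, Modality.A): StimulusSet(
            Task.SPATIAL, Modality.A, _equally_spaced(22.0, 50.0, 6), 22.0, 50.0
        ),
        (Task.SPATIAL, Modality.V): StimulusSet(
            Task.SPATIAL, Modality.V, _equally_spaced(5.5, 33.0, 6), 5.5, 33.0
        ),
    }
    designs = {
        Task.TEMPORAL: SessionDesign(Task.TEMPORAL, 180, 180),
        Task.SPATIAL: SessionDesign(Task.SPATIAL, 120, 120),
    }
    return PipelineConfig(stimulus_sets=sets, session_designs=designs)


# ---------------------------------------------------------------------------
# Trial-table I/O
# ---------------------------------------------------------------------------


def read_trials(path: str | Path, config: PipelineConfig | None = None) -> list[TrialRecord]:
    """Read a canonical trial CSV and validate every row.

    Raises :class:`SchemaError` on a missing column and
    :class:`ValidationError` (with the offending row number) on invalid rows.
    When ``config`` is given, each stimulus must be a member of the declared
    set for its (task, modality).
    """
    path = Path(path)
    if not path.exists():
        raise SchemaError(f"trial file not found: {path}")
    frame = pd.read_csv(path, dtype={"participant_id": str}, float_precision="round_trip")
    missing = [c for c in TRIAL_COLUMNS if c not in frame.columns]
    if missing:
        raise SchemaError(f"missing column(s): {', '.join(missing)}")

    records: list[TrialRecord] = []
    for i, row in enumerate(frame.itertuples(index=False)):
        rownum = i + 2  # 1-based, after header
        try:
            task = Task(row.task)
            session = Session(row.session)
            modality = Modality(row.modality)
        except ValueError as exc:
            raise ValidationError(f"row {rownum}: {exc}") from exc
        try:
            stimulus = float(row.stimulus)
            response = float(row.response)
            trial_index = int(row.trial_index)
        except (TypeError, ValueError) as exc:
            raise ValidationError(f"row {rownum}: non-numeric field ({exc})") from exc
        if math.isnan(stimulus) or math.isnan(response):
            raise ValidationError(f"row {rownum}: non-numeric stimulus/response")
        try:
            rec = TrialRecord(
                participant_id=str(row.participant_id),
                task=task,
                session=session,
                modality=modality,
                stimulus=stimulus,
                response=response,
                trial_index=trial_index,
            )
        except ValidationError as exc:
            raise ValidationError(f"row {rownum}: {exc}") from exc
        if config is not None:
            sset = config.stimulus_set(task, modality)
            if not sset.contains(stimulus):
                raise ValidationError(
                    f"row {rownum}: stimulus {stimulus!r} not in the declared "
                    f"{task.value}/{modality.value} set"
                )
        records.append(rec)
    return records


def write_trials(records: Iterable[TrialRecord], path: str | Path) -> Path:
    """Write records to canonical CSV (deterministic column order, '.' decimals)."""
    path = Path(path)
    rows = [
        {
            "participant_id": r.participant_id,
            "task": r.task.value,
            "session": r.session.value,
            "modality": r.modality.value,
            "stimulus": repr(float(r.stimulus)),
            "response": repr(float(r.response)),
            "trial_index": r.trial_index,
        }
        for r in records
    ]
    frame = pd.DataFrame(rows, columns=list(TRIAL_COLUMNS))
    path.parent.mkdir(parents=True, exist_ok=True)
    frame.to_csv(path, index=False)
    return path


def trials_to_frame(records: Sequence[TrialRecord]) -> pd.DataFrame:
    """Long-format DataFrame view of a record collection (enum values as strings)."""
    return pd.DataFrame(
        {
            "participant_id": [r.participant_id for r in records],
            "task": [r.task.value for r in records],
            "session": [r.session.value for r in records],
            "modality": [r.modality.value for r in records],
            "stimulus": [r.stimulus for r in records],
            "response": [r.response for r in records],
            "trial_index": [r.trial_index for r in records],
        }
    )


def frame_to_trials(frame: pd.DataFrame) -> list[TrialRecord]:
    return [
        TrialRecord(
            participant_id=str(row.participant_id),
            task=Task(row.task),
            session=Session(row.session),
            modality=Modality(row.modality),
            stimulus=float(row.stimulus),
            response=float(row.response),
            trial_index=int(row.trial_index),
        )
        for row in frame.itertuples(index=False)
    ]


# ---------------------------------------------------------------------------
# Config file loading
# ---------------------------------------------------------------------------


def _set_from_dict(task: Task, modality: Modality, spec: Mapping) -> StimulusSet:
    values = tuple(float(v) for v in spec["values"])
    return StimulusSet(
        task=task,
        modality=modality,
        values=values,
        lower_bound=float(spec.get("lower_bound", values[0])),
        upper_bound=float(spec.get("upper_bound", values[-1])),
    )


def load_config(path: str | Path | None = None) -> PipelineConfig:
    """Load a YAML/JSON config file; every field is optional and defaults apply.

    Layout mirrors :class:`PipelineConfig`::

        stimulus_sets:
          temporal:
            A: {values: [490, 535, ...]}
        session_designs:
          temporal: {baseline: 180, interleaved: 180}
        outlier_threshold: 3.0
    """
    cfg = default_config()
    if path is None:
        return cfg
    path = Path(path)
    if not path.exists():
        raise SchemaError(f"config file not found: {path}")
    text = path.read_text()
    if path.suffix.lower() == ".json":
        data = json.loads(text)
    else:
        data = yaml.safe_load(text)
    if data is None:
        return cfg
    if not isinstance(data, Mapping):
        raise SchemaError("config root must be a mapping")

    sets = dict(cfg.stimulus_sets)
    for task_key, per_mod in (data.get("stimulus_sets") or {}).items():
        task = Task(task_key)
        for mod_key, spec in per_mod.items():
            modality = Modality(mod_key)
            sets[(task, modality)] = _set_from_dict(task, modality, spec)

    designs = dict(cfg.session_designs)
    for task_key, spec in (data.get("session_designs") or {}).items():
        task = Task(task_key)
        base = designs[task]
        designs[task] = SessionDesign(
            task=task,
            trials_per_modality_baseline=int(
                spec.get("baseline", base.trials_per_modality_baseline)
            ),
            trials_per_modality_interleaved=int(
                spec.get("interleaved", base.trials_per_modality_interleaved)
            ),
        )

    scalar_fields = (
        "outlier_threshold",
        "solver_tol",
        "solver_max_iter",
        "cv_folds",
        "cv_seed",
        "normalize",
        "prior_provenance",
        "precision_pooling",
    )
    overrides = {k: data[k] for k in scalar_fields if k in data}
    return replace(cfg, stimulus_sets=sets, session_designs=designs, **overrides)
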