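"""Response normalization, perceived-vs-real linear fits and outlier screening.

Normalization convention (documented because the underlying convention in the
source literature is ambiguous): within one participant x task, responses in
each session x modality cell are centered on that cell's mean response and
re-anchored by a task-level constant, the mean of the two modality sets'
median stimulus values. Slopes, and therefore regression indices, are
invariant to this transformation; only intercepts shift by a constant. It can
be switched off via ``PipelineConfig.normalize``.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Mapping, Sequence

import numpy as np
import pandas as pd

from magest.datamodel import (
    Modality,
    PipelineConfig,
    Session,
    Task,
    TrialRecord,
)
from magest.errors import DegenerateDesignError, ValidationError


@dataclass(frozen=True)
class LinearFit:
    """Ordinary least-squares fit of perceived = slope * real + intercept."""

    slope: float
    intercept: float
    rmse: float
    residuals: tuple[float, ...]
    n: int

    def __post_init__(self):
        if self.n < 2:
            raise ValidationError("a linear fit needs n >= 2")
        if self.rmse < 0:
            raise ValidationError("rmse must be >= 0")


def fit_line(real: Sequence[float], perceived: Sequence[float]) -> LinearFit:
    """OLS fit with intercept; rmse = sqrt(SSE / (n - 2)) (dof-adjusted,
    matching the usual curve-fitting-toolbox convention).

    Raises :class:`DegenerateDesignError` when all ``real`` values coincide.
    """
    x = np.asarray(real, dtype=float)
    y = np.asarray(perceived, dtype=float)
    if x.shape != y.shape or x.ndim != 1:
        raise ValidationError("real and perceived must be 1-D and equal length")
    n = x.size
    if n < 2:
        raise ValidationError("need at least 2 points")
    if np.ptp(x) == 0:
        raise DegenerateDesignError("all stimulus values identical; slope undefined")
    design = np.column_stack([x, np.ones(n)])
    coef, *_ = np.linalg.lstsq(design, y, rcond=None)
    slope, intercept = float(coef[0]), float(coef[1])
    resid = y - (slope * x + intercept)
    sse = float(resid @ resid)
    dof = max(n - 2, 1)
    return LinearFit(
        slope=slope,
        intercept=intercept,
        rmse=float(np.sqrt(sse / dof)),
        residuals=tuple(float(r) for r in resid),
        n=n,
    )


def _anchor(config: PipelineConfig, task: Task) -> float:
    med_a = config.stimulus_set(task, Modality.A).median
    med_v = config.stimulus_set(task, Modality.V).median
    return 0.5 * (med_a + med_v)


def normalize_responses(
    trials: Sequence[TrialRecord], config: PipelineConfig
) -> list[TrialRecord]:
    """Center responses per session x modality cell, re-anchor to the task anchor.

    ``trials`` must belong to a single participant x task and include both
    baseline sessions. Stimuli are untouched; the map is affine per cell, so
    slopes and within-cell variances are preserved exactly.
    """
    if not trials:
        return []
    participants = {t.participant_id for t in trials}
    tasks = {t.task for t in trials}
    if len(participants) > 1 or len(tasks) > 1:
        raise ValidationError("normalize_responses expects one participant x task")
    task = next(iter(tasks))
    sessions = {t.session for t in trials}
    if Session.AUDIO not in sessions or Session.VISION not in sessions:
        raise ValidationError("both baseline sessions required for normalization")

    anchor = _anchor(config, task)
    cell_means: dict[tuple[Session, Modality], float] = {}
    for key in {(t.session, t.modality) for t in trials}:
        cell = [t.response for t in trials if (t.session, t.modality) == key]
        if len(cell) < 2:
            raise ValidationError(
                f"cell session={key[0].value}, modality={key[1].value} has "
                f"{len(cell)} trial(s); need >= 2"
            )
        cell_means[key] = float(np.mean(cell))

    out = []
    for t in trials:
        shifted = t.response - cell_means[(t.session, t.modality)] + anchor
        out.append(
            TrialRecord(
                participant_id=t.participant_id,
                task=t.task,
                session=t.session,
                modality=t.modality,
                stimulus=t.stimulus,
                response=max(shifted, 0.0),
                trial_index=t.trial_index,
            )
        )
    return out


@dataclass(frozen=True)
class OutlierReport:
    """Per-cell RMSE screening result.

    ``table`` has one row per participant x task x session with the group
    median/SD of RMSE and the excluded flag; ``excluded`` maps task to the
    set of participants removed from that entire task.
    """

    table: pd.DataFrame
    threshold: float
    excluded: Mapping[Task, frozenset[str]]

    def excluded_for(self, task: Task) -> frozenset[str]:
        return self.excluded.get(task, frozenset())


def detect_outliers(
    fits: pd.DataFrame, threshold: float = 3.0
) -> OutlierReport:
    """Flag participants whose fit RMSE strays from the group.

    ``fits`` needs columns ``participant_id, task, session, rmse``. Within
    each task x session cell the center is the group *median* and the scale
    the group *SD* of RMSE; a participant flagged in any session of a task is
    excluded from that whole task. Requires >= 3 participants per cell.
    """
    required = {"participant_id", "task", "session", "rmse"}
    missing = required - set(fits.columns)
    if missing:
        raise ValidationError(f"fits table missing column(s): {sorted(missing)}")
    if threshold <= 0:
        raise ValidationError("threshold must be > 0")

    rows = []
    excluded: dict[Task, set[str]] = {}
    for (task_key, session_key), cell in fits.groupby(["task", "session"], sort=True):
        task = Task(task_key)
        if cell["participant_id"].nunique() < 3:
            raise ValidationError(
                f"task={task_key}, session={session_key}: fewer than 3 "
                "participants; SD-based screening is unstable"
            )
        med = float(cell["rmse"].median())
        sd = float(cell["rmse"].std(ddof=1))
        for row in cell.itertuples(index=False):
            flag = sd > 0 and abs(row.rmse - med) > threshold * sd
            if flag:
                excluded.setdefault(task, set()).add(str(row.participant_id))
            rows.append(
                {
                    "participant_id": str(row.participant_id),
                    "task": task_key,
                    "session": session_key,
                    "rmse": float(row.rmse),
                    "group_median": med,
                    "group_sd": sd,
                    "excluded": flag,
                }
            )
    table = pd.DataFrame(
        rows,
        columns=[
            "participant_id",
            "task",
            "session",
            "rmse",
            "group_median",
            "group_sd",
            "excluded",
        ],
    )
    return OutlierReport(
        table=table,
        threshold=threshold,
        excluded={k: frozenset(v) for k, v in excluded.items()},
    )


def baseline_fit_table(
    trials: Sequence[TrialRecord],
) -> pd.DataFrame:
    """Per participant x task x baseline-session linear-fit summaries.

    Convenience for the outlier stage: fits perceived vs real within each
    participant's audio and vision baseline sessions.
    """
    frame_rows = []
    by_key: dict[tuple[str, Task, Session], list[TrialRecord]] = {}
    for t in trials:
        if t.session is Session.INTERLEAVED:
            continue
        by_key.setdefault((t.participant_id, t.task, t.session), []).append(t)
    for (pid, task, session), cell in sorted(
        by_key.items(), key=lambda kv: (kv[0][0], kv[0][1].value, kv[0][2].value)
    ):
        fit = fit_line([t.stimulus for t in cell], [t.response for t in cell])
        frame_rows.append(
            {
                "participant_id": pid,
                "task": task.value,
                "session": session.value,
                "slope": fit.slope,
                "intercept": fit.intercept,
                "rmse": fit.rmse,
                "n": fit.n,
            }
        )
    return pd.DataFrame(
        frame_rows,
        columns=["participant_id", "task", "session", "slope", "intercept", "rmse", "n"],
    )
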