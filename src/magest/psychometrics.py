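"""Regression index, sensory precision and modality reliability weights."""

from __future__ import annotations

from dataclasses import dataclass
from typing import Mapping, Sequence

import numpy as np

from magest.datamodel import Modality, Session, Task, TrialRecord
from magest.errors import ValidationError
from magest.preprocess import LinearFit


@dataclass(frozen=True)
class RegressionIndex:
    """Central-tendency strength: 1 - slope of the perceived-vs-real fit.

    0 is veridical, 1 is complete regression to the mean; values outside
    [0, 1] are preserved (no clamping).
    """

    ri: float
    slope: float
    task: Task
    modality: Modality
    session: Session


def regression_index(
    fit: LinearFit, task: Task, modality: Modality, session: Session
) -> RegressionIndex:
    return RegressionIndex(
        ri=1.0 - fit.slope, slope=fit.slope, task=task, modality=modality, session=session
    )


@dataclass(frozen=True)
class PrecisionProfile:
    """Per-stimulus sensory variance, corrected for central-tendency shrinkage.

    ``variances[s]`` is Var(residuals at stimulus s) / slope^2 — the residual
    variance a slope != 1 deflates/inflates, mapped back to sensory units.
    Estimated from baseline sessions only.
    """

    task: Task
    modality: Modality
    variances: Mapping[float, float]
    counts: Mapping[float, int]

    def __post_init__(self):
        if any(v < 0 for v in self.variances.values()):
            raise ValidationError("variances must be >= 0")

    def sd(self, stimulus: float) -> float:
        return float(np.sqrt(self.variances[stimulus]))

    def variance_at(self, stimulus: float, atol: float = 1e-9) -> float:
        """Variance at a stimulus value, tolerant lookup."""
        for s, v in self.variances.items():
            if abs(s - stimulus) <= atol:
                return v
        raise KeyError(
            f"stimulus {stimulus!r} not in the {self.task.value}/"
            f"{self.modality.value} precision profile"
        )

    def pooled_variance(self, weighting: str = "unweighted") -> float:
        """Average sensory variance across stimulus levels."""
        vals = np.array(list(self.variances.values()), dtype=float)
        if weighting == "unweighted":
            return float(vals.mean())
        if weighting == "n_weighted":
            ns = np.array([self.counts[s] for s in self.variances], dtype=float)
            return float((vals * ns).sum() / ns.sum())
        raise ValidationError("weighting must be 'unweighted' or 'n_weighted'")


def sensory_precision(
    trials: Sequence[TrialRecord], fit: LinearFit
) -> PrecisionProfile:
    """Per-stimulus sensory variance from one baseline session.

    ``trials`` must be a single participant's baseline session (one task, one
    modality); ``fit`` is that participant's perceived-vs-real line on the
    same trials (residuals are recomputed from its slope/intercept). Each
    stimulus level needs >= 2 trials; the correction divides by slope^2 and is
    undefined at slope 0.
    """
    if not trials:
        raise ValidationError("no trials")
    sessions = {t.session for t in trials}
    if Session.INTERLEAVED in sessions:
        raise ValidationError("sensory precision is defined on baseline sessions only")
    if len(sessions) != 1 or len({t.modality for t in trials}) != 1:
        raise ValidationError("expected a single baseline session")
    if fit.slope == 0:
        raise ValidationError("slope is 0; the shrinkage correction is undefined")

    task = trials[0].task
    modality = trials[0].modality
    by_stim: dict[float, list[float]] = {}
    for t in trials:
        resid = t.response - (fit.slope * t.stimulus + fit.intercept)
        by_stim.setdefault(t.stimulus, []).append(resid)

    variances: dict[float, float] = {}
    counts: dict[float, int] = {}
    for s in sorted(by_stim):
        resid = by_stim[s]
        if len(resid) < 2:
            raise ValidationError(
                f"stimulus {s!r} has {len(resid)} trial(s); need >= 2 for a variance"
            )
        variances[s] = float(np.var(resid, ddof=1)) / fit.slope**2
        counts[s] = len(resid)
    return PrecisionProfile(task=task, modality=modality, variances=variances, counts=counts)


@dataclass(frozen=True)
class ModalityWeights:
    """Relative reliability of audition vs vision within one task."""

    omega_A: float
    sigma2_A: float
    sigma2_V: float
    task: Task

    def __post_init__(self):
        if not 0.0 <= self.omega_A <= 1.0:
            raise ValidationError("omega_A must lie in [0, 1]")

    @property
    def omega_V(self) -> float:
        return 1.0 - self.omega_A


def modality_weights(
    profile_A: PrecisionProfile,
    profile_V: PrecisionProfile,
    pooling: str = "unweighted",
) -> ModalityWeights:
    """omega_A = sigma_V^2 / (sigma_A^2 + sigma_V^2) from pooled baseline variances."""
    if profile_A.task is not profile_V.task:
        raise ValidationError("profiles must come from the same task")
    if profile_A.modality is not Modality.A or profile_V.modality is not Modality.V:
        raise ValidationError("expected an auditory and a visual profile, in that order")
    s2a = profile_A.pooled_variance(pooling)
    s2v = profile_V.pooled_variance(pooling)
    if s2a + s2v == 0:
        raise ValidationError("both pooled variances are zero; weights undefined")
    return ModalityWeights(
        omega_A=s2v / (s2a + s2v), sigma2_A=s2a, sigma2_V=s2v, task=profile_A.task
    )
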