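"""Bayesian ideal-observer response models for the interleaved session.

Four models share the same machinery — a Gaussian likelihood centered on the
stimulus whose SD is the participant's baseline sensory precision for that
modality and stimulus, combined with a single model prior — and differ only
in how the prior is built:

- ``SegAudio``: prior moment-matched to the auditory stimulus set.
- ``SegVision``: prior moment-matched to the visual stimulus set.
- ``CTE``: prior moment-matched to the pooled two-modality set on the
  combined bounds (supra-modal central tendency).
- ``WCTE``: prior mean is the reliability-weighted combination of the two
  segregation prior means; prior SD the square root of the same
  reliability-weighted combination of their variances.

The prior moments entering the posterior weighting are the *implied*
(truncated) moments of the solved prior, so for feasible targets they equal
the experienced stimulus distribution's moments.
"""

from __future__ import annotations

import enum
import math
from dataclasses import dataclass
from typing import Mapping, Sequence

import numpy as np
import pandas as pd

from magest.datamodel import Modality, PipelineConfig, Session, Task, TrialRecord
from magest.errors import ValidationError
from magest.priors import (
    TargetProvenance,
    TruncatedNormalPrior,
    pooled_moment_target,
    set_moment_target,
    solve_prior,
)
from magest.psychometrics import ModalityWeights, PrecisionProfile


class ModelName(str, enum.Enum):
    SEG_AUDIO = "SegAudio"
    SEG_VISION = "SegVision"
    CTE = "CTE"
    WCTE = "WCTE"


def posterior_mean(
    stimulus: float, sigma_L: float, prior_mean: float, prior_sd: float
) -> float:
    """Reliability-weighted posterior mean.

    mu_R = S * w_L + prior_mean * w_P with w_P = sigma_L^2 / (sigma_L^2 +
    sigma_P^2); sigma_L = 0 collapses to the stimulus.
    """
    if prior_sd <= 0:
        raise ValidationError("prior_sd must be > 0")
    if sigma_L < 0:
        raise ValidationError("sigma_L must be >= 0")
    vl = sigma_L * sigma_L
    vp = prior_sd * prior_sd
    w_p = vl / (vl + vp)
    return stimulus * (1.0 - w_p) + prior_mean * w_p


def prior_weight(sigma_L: float, prior_sd: float) -> float:
    """w_P(S_i) = sigma_L^2 / (sigma_L^2 + sigma_P^2)."""
    if prior_sd <= 0:
        raise ValidationError("prior_sd must be > 0")
    vl = sigma_L * sigma_L
    return vl / (vl + prior_sd * prior_sd)


@dataclass(frozen=True)
class WeightedPrior:
    """WCTE prior: reliability-weighted mix of the two segregation priors."""

    mu: float
    sd: float
    omega_A: float

    def __post_init__(self):
        if self.sd <= 0:
            raise ValidationError("weighted prior SD must be > 0")


@dataclass(frozen=True)
class ModelSpec:
    """One model's prior, ready for prediction."""

    name: ModelName
    task: Task
    prior_mean: float
    prior_sd: float
    solved: TruncatedNormalPrior | None = None
    weighted: WeightedPrior | None = None

    def __post_init__(self):
        if self.prior_sd <= 0:
            raise ValidationError("prior_sd must be > 0")


def build_model_prior(
    name: ModelName | str,
    config: PipelineConfig,
    task: Task,
    weights: ModalityWeights | None = None,
    provenance: TargetProvenance | str | None = None,
) -> ModelSpec:
    """Construct one model's prior from the task's stimulus sets.

    Infeasible moment targets (a discrete uniform set's variance exceeds the
    truncated-normal supremum on its own bounds) fall back to the flagged
    least-squares optimum; see :mod:`magest.priors`.
    """
    name = ModelName(name)
    provenance = TargetProvenance(provenance or config.prior_provenance)
    set_a = config.stimulus_set(task, Modality.A)
    set_v = config.stimulus_set(task, Modality.V)
    tol = config.solver_tol

    def _solve(target):
        return solve_prior(target, tol=tol, max_iter=config.solver_max_iter,
                           on_infeasible="best_fit")

    if name is ModelName.SEG_AUDIO:
        prior = _solve(set_moment_target(set_a, provenance))
        return ModelSpec(name, task, prior.implied_mean, prior.implied_sd, solved=prior)
    if name is ModelName.SEG_VISION:
        prior = _solve(set_moment_target(set_v, provenance))
        return ModelSpec(name, task, prior.implied_mean, prior.implied_sd, solved=prior)
    if name is ModelName.CTE:
        prior = _solve(pooled_moment_target(set_a, set_v, provenance))
        return ModelSpec(name, task, prior.implied_mean, prior.implied_sd, solved=prior)
    # WCTE
    if weights is None:
        raise ValidationError("WCTE requires modality weights")
    prior_a = _solve(set_moment_target(set_a, provenance))
    prior_v = _solve(set_moment_target(set_v, provenance))
    wa = weights.omega_A
    mu_w = prior_a.implied_mean * wa + prior_v.implied_mean * (1.0 - wa)
    sd_w = math.sqrt(prior_a.implied_var * wa + prior_v.implied_var * (1.0 - wa))
    return ModelSpec(
        name,
        task,
        mu_w,
        sd_w,
        weighted=WeightedPrior(mu=mu_w, sd=sd_w, omega_A=wa),
    )


def build_all_model_priors(
    config: PipelineConfig,
    task: Task,
    weights: ModalityWeights,
    provenance: TargetProvenance | str | None = None,
) -> dict[ModelName, ModelSpec]:
    return {
        name: build_model_prior(name, config, task, weights=weights, provenance=provenance)
        for name in ModelName
    }


def predict_session(
    trials: Sequence[TrialRecord],
    profiles: Mapping[Modality, PrecisionProfile],
    spec: ModelSpec,
) -> pd.DataFrame:
    """Predict interleaved-session responses under one model.

    Each trial's likelihood SD is looked up from the baseline precision
    profile of the trial's own modality at the same stimulus value; the
    model's single prior applies to auditory and visual trials alike.

    Returns a tidy frame: participant_id, modality, stimulus, sigma_L,
    predicted, model.
    """
    rows = []
    for t in trials:
        if t.session is not Session.INTERLEAVED:
            raise ValidationError("predict_session expects interleaved trials")
        try:
            profile = profiles[t.modality]
        except KeyError as exc:
            raise ValidationError(
                f"no precision profile for modality {t.modality.value}"
            ) from exc
        try:
            var_l = profile.variance_at(t.stimulus)
        except KeyError as exc:
            raise ValidationError(str(exc)) from exc
        sigma_l = math.sqrt(var_l)
        mu_r = posterior_mean(t.stimulus, sigma_l, spec.prior_mean, spec.prior_sd)
        rows.append(
            {
                "participant_id": t.participant_id,
                "modality": t.modality.value,
                "stimulus": t.stimulus,
                "trial_index": t.trial_index,
                "sigma_L": sigma_l,
                "predicted": mu_r,
                "model": spec.name.value,
            }
        )
    return pd.DataFrame(
        rows,
        columns=[
            "participant_id",
            "modality",
            "stimulus",
            "trial_index",
            "sigma_L",
            "predicted",
            "model",
        ],
    )
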