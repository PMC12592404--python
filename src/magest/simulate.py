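"""Synthetic Bayesian-observer cohorts.

Generative model per trial: the observer draws a noisy measurement
m ~ Normal(S, sigma_L(S)^2) with an affine noise law sigma_L(S) = floor +
coef * S, combines it with the regime's prior via the posterior-mean rule,
and responds with added motor noise and a constant bias, truncated at zero.

Regimes
-------
``veridical``
    control without prior or sensory noise: response = S + motor noise + bias.
``seg_audio`` / ``seg_vision`` / ``cte`` / ``wcte``
    in the interleaved session the prior is the corresponding model prior
    (see :mod:`magest.models`); in each baseline session the prior is that
    modality's own set prior — with a single modality on screen the
    supra-modal and modality-specific priors coincide.

Stimulus schedules depend only on the design (each value repeated equally
often, order shuffled with a seed derived from task/session/participant
label), so two cohorts with different master seeds share schedules and
differ only in noise.
"""

from __future__ import annotations

import dataclasses
import enum
import logging
import zlib
from dataclasses import dataclass, field
from typing import Mapping, Sequence

import numpy as np

from magest.datamodel import (
    BASELINE_SESSION,
    Modality,
    PipelineConfig,
    Session,
    StimulusSet,
    Task,
    TrialRecord,
)
from magest.errors import ValidationError
from magest.models import ModelName, build_model_prior, posterior_mean
from magest.priors import TargetProvenance, set_moment_target, solve_prior
from magest.psychometrics import ModalityWeights

logger = logging.getLogger(__name__)


class Regime(str, enum.Enum):
    VERIDICAL = "veridical"
    SEG_AUDIO = "seg_audio"
    SEG_VISION = "seg_vision"
    CTE = "cte"
    WCTE = "wcte"


_REGIME_TO_MODEL = {
    Regime.SEG_AUDIO: ModelName.SEG_AUDIO,
    Regime.SEG_VISION: ModelName.SEG_VISION,
    Regime.CTE: ModelName.CTE,
    Regime.WCTE: ModelName.WCTE,
}


def likelihood_sd(stimulus: float, coef: float, floor: float) -> float:
    """Affine sensory noise law: floor + coef * stimulus."""
    if stimulus <= 0:
        raise ValidationError("stimulus must be > 0")
    if coef < 0 or floor < 0:
        raise ValidationError("noise coefficients must be >= 0")
    return floor + coef * stimulus


@dataclass(frozen=True)
class ObserverParams:
    """Generative parameters for one simulated participant."""

    sigma_A_coef: float = 0.0
    sigma_A_floor: float = 0.0
    sigma_V_coef: float = 0.0
    sigma_V_floor: float = 0.0
    motor_sd: float = 0.0
    bias: float = 0.0
    regime: Regime = Regime.VERIDICAL
    seed: int = 0
    sensory_noise: bool = True
    raw_moments: bool = False  # use the set's raw mean/SD instead of a solved prior

    def __post_init__(self):
        object.__setattr__(self, "regime", Regime(self.regime))
        for name in ("sigma_A_coef", "sigma_A_floor", "sigma_V_coef",
                     "sigma_V_floor", "motor_sd"):
            if getattr(self, name) < 0:
                raise ValidationError(f"{name} must be >= 0")

    def noise_coefs(self, modality: Modality) -> tuple[float, float]:
        if modality is Modality.A:
            return self.sigma_A_coef, self.sigma_A_floor
        return self.sigma_V_coef, self.sigma_V_floor

    def sigma_l(self, stimulus: float, modality: Modality) -> float:
        coef, floor = self.noise_coefs(modality)
        return likelihood_sd(stimulus, coef, floor)


def true_modality_weights(
    params: ObserverParams, config: PipelineConfig, task: Task
) -> ModalityWeights:
    """Reliability weights implied by the generative noise law.

    Pooled per-modality variance is the unweighted mean of sigma_L(S)^2 over
    the modality's stimulus set — the same pooling the analysis applies.
    """
    pooled = {}
    for modality in Modality:
        values = config.stimulus_set(task, modality).values
        pooled[modality] = float(
            np.mean([params.sigma_l(s, modality) ** 2 for s in values])
        )
    total = pooled[Modality.A] + pooled[Modality.V]
    if total == 0:
        raise ValidationError("noiseless observer has undefined modality weights")
    return ModalityWeights(
        omega_A=pooled[Modality.V] / total,
        sigma2_A=pooled[Modality.A],
        sigma2_V=pooled[Modality.V],
        task=task,
    )


def _set_prior_moments(
    sset: StimulusSet, provenance: TargetProvenance, tol: float, raw: bool
) -> tuple[float, float]:
    target = set_moment_target(sset, provenance)
    if raw:
        return target.target_mean, float(np.sqrt(target.target_var))
    prior = solve_prior(target, tol=tol, on_infeasible="best_fit")
    return prior.implied_mean, prior.implied_sd


def regime_prior(
    params: ObserverParams,
    config: PipelineConfig,
    task: Task,
    session: Session,
    modality: Modality,
) -> tuple[float, float] | None:
    """(prior_mean, prior_sd) governing one session x modality, or None."""
    if params.regime is Regime.VERIDICAL:
        return None
    provenance = TargetProvenance(config.prior_provenance)
    if session is not Session.INTERLEAVED:
        sset = config.stimulus_set(task, modality)
        return _set_prior_moments(sset, provenance, config.solver_tol, params.raw_moments)
    if params.raw_moments and params.regime is not Regime.WCTE:
        regime_sets = {
            Regime.SEG_AUDIO: config.stimulus_set(task, Modality.A),
            Regime.SEG_VISION: config.stimulus_set(task, Modality.V),
        }
        if params.regime in regime_sets:
            return _set_prior_moments(
                regime_sets[params.regime], provenance, config.solver_tol, True
            )
    weights = None
    if params.regime is Regime.WCTE:
        weights = true_modality_weights(params, config, task)
    spec = build_model_prior(
        _REGIME_TO_MODEL[params.regime], config, task, weights=weights,
        provenance=provenance,
    )
    return spec.prior_mean, spec.prior_sd


def _schedule_seed(task: Task, session: Session, participant_id: str) -> int:
    key = f"{task.value}:{session.value}:{participant_id}:schedule"
    return zlib.crc32(key.encode())


def session_schedule(
    config: PipelineConfig, task: Task, session: Session, participant_id: str
) -> list[tuple[Modality, float]]:
    """Deterministic stimulus schedule for one session.

    Each stimulus value of each modality in the session is repeated equally
    often (count // n_values times; any remainder is assigned to values drawn
    without replacement by the schedule RNG and logged). The concatenated
    list is shuffled with an RNG seeded from (task, session, participant)
    only — never from the observer's noise seed.
    """
    design = config.design(task)
    rng = np.random.default_rng(_schedule_seed(task, session, participant_id))
    modalities = (
        [Modality.A, Modality.V]
        if session is Session.INTERLEAVED
        else [Modality.A if session is Session.AUDIO else Modality.V]
    )
    items: list[tuple[Modality, float]] = []
    for modality in modalities:
        values = config.stimulus_set(task, modality).values
        count = (
            design.trials_per_modality_interleaved
            if session is Session.INTERLEAVED
            else design.trials_per_modality_baseline
        )
        reps, remainder = divmod(count, len(values))
        items.extend((modality, v) for v in values for _ in range(reps))
        if remainder:
            extra = rng.choice(len(values), size=remainder, replace=False)
            items.extend((modality, values[i]) for i in extra)
            logger.info(
                "%s/%s/%s: %d trials not divisible by %d values; "
                "%d extra trial(s) assigned by schedule seed",
                task.value, session.value, modality.value, count, len(values), remainder,
            )
    order = rng.permutation(len(items))
    return [items[i] for i in order]


def simulate_participant(
    params: ObserverParams,
    config: PipelineConfig,
    task: Task,
    participant_id: str = "P01",
) -> list[TrialRecord]:
    """Simulate one participant's three sessions (audio, vision, interleaved)."""
    rng = np.random.default_rng(params.seed)
    records: list[TrialRecord] = []
    truncated = 0
    for session in (Session.AUDIO, Session.VISION, Session.INTERLEAVED):
        schedule = session_schedule(config, task, session, participant_id)
        priors = {
            modality: regime_prior(params, config, task, session, modality)
            for modality in Modality
        }
        for idx, (modality, stimulus) in enumerate(schedule):
            prior = priors[modality]
            if prior is None:
                center = stimulus
            else:
                sigma_l = params.sigma_l(stimulus, modality)
                mu_l = stimulus
                if params.sensory_noise and sigma_l > 0:
                    mu_l = stimulus + rng.normal(0.0, sigma_l)
                center = posterior_mean(mu_l, sigma_l, prior[0], prior[1])
            response = center + params.bias
            if params.motor_sd > 0:
                response += rng.normal(0.0, params.motor_sd)
            if response < 0:
                truncated += 1
                response = 0.0
            records.append(
                TrialRecord(
                    participant_id=participant_id,
                    task=task,
                    session=session,
                    modality=modality,
                    stimulus=stimulus,
                    response=response,
                    trial_index=idx,
                )
            )
    if truncated:
        logger.info(
            "%s/%s: %d response(s) truncated at 0", participant_id, task.value, truncated
        )
    return records


@dataclass(frozen=True)
class CohortSpec:
    """A cohort: shared base parameters plus per-participant jitter.

    ``jitter`` maps an ObserverParams field name to a fractional half-width
    f; each participant's value is base * (1 + U(-f, f)), floored at 0 for SD
    parameters. Per-participant noise seeds are spawned deterministically
    from ``master_seed``.
    """

    n_participants: int
    base_params: ObserverParams
    master_seed: int = 0
    jitter: Mapping[str, float] = field(default_factory=dict)

    def __post_init__(self):
        if self.n_participants < 1:
            raise ValidationError("n_participants must be >= 1")
        valid = {f.name for f in dataclasses.fields(ObserverParams)}
        for name, frac in self.jitter.items():
            if name not in valid:
                raise ValidationError(f"unknown ObserverParams field: {name}")
            if not 0 <= frac < 1:
                raise ValidationError("jitter fractions must lie in [0, 1)")

    def participant_params(self) -> list[tuple[str, ObserverParams]]:
        ss = np.random.SeedSequence(self.master_seed)
        children = ss.spawn(self.n_participants + 1)
        jitter_rng = np.random.default_rng(children[0])
        out = []
        for i in range(self.n_participants):
            label = f"P{i + 1:02d}"
            overrides = {"seed": int(children[i + 1].generate_state(1)[0])}
            for name, frac in self.jitter.items():
                base_val = getattr(self.base_params, name)
                jittered = base_val * (1.0 + jitter_rng.uniform(-frac, frac))
                overrides[name] = max(jittered, 0.0)
            out.append((label, dataclasses.replace(self.base_params, **overrides)))
        return out


def simulate_cohort(
    spec: CohortSpec, config: PipelineConfig, task: Task
) -> list[TrialRecord]:
    """Simulate every participant in the cohort; bit-reproducible per spec."""
    records: list[TrialRecord] = []
    for label, params in spec.participant_params():
        records.extend(simulate_participant(params, config, task, participant_id=label))
    return records


def cohort_manifest(spec: CohortSpec, task: Task) -> dict:
    """JSON-serializable record of the true generating parameters."""
    return {
        "task": task.value,
        "master_seed": spec.master_seed,
        "n_participants": spec.n_participants,
        "jitter": dict(spec.jitter),
        "participants": {
            label: {
                k: (v.value if isinstance(v, enum.Enum) else v)
                for k, v in dataclasses.asdict(params).items()
            }
            for label, params in spec.participant_params()
        },
    }
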