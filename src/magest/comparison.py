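"""Mixed-model scoring of observer-model predictions and criterion ranking.

Each candidate model is scored by a linear mixed model
``observed ~ 1 + stimulus + prediction`` with a participant random intercept,
fitted by maximum likelihood (not REML) so information criteria are
comparable across candidates that differ only in the prediction regressor.
R^2 is the squared Pearson correlation between observations and fitted
values; predicted R^2 replaces fitted values with cross-validated ones from
participant-grouped folds.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
import statsmodels.api as sm

from magest.errors import ValidationError

#: Two candidate fits within this AIC distance carry comparable support.
DEGENERACY_DELTA_AIC = 2.0


@dataclass(frozen=True)
class ModelComparisonRow:
    """One model's scores (Table-style row)."""

    model: str
    aic: float
    bic: float
    loglik: float
    deviance: float
    r2: float
    predicted_r2: float | None
    n_obs: int
    converged: bool = True


@dataclass(frozen=True)
class ComparisonReport:
    rows: tuple[ModelComparisonRow, ...]
    best_by_bic: str
    best_by_aic: str
    delta_aic: dict[str, float] = field(default_factory=dict)
    delta_bic: dict[str, float] = field(default_factory=dict)
    degenerate: tuple[str, ...] = ()

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            [
                {
                    "model": r.model,
                    "AIC": r.aic,
                    "logLik": r.loglik,
                    "deviance": r.deviance,
                    "R2": r.r2,
                    "predicted_R2": r.predicted_r2,
                    "BIC": r.bic,
                    "delta_AIC": self.delta_aic[r.model],
                    "delta_BIC": self.delta_bic[r.model],
                    "converged": r.converged,
                }
                for r in self.rows
            ]
        )


def _validate_inputs(observed, predicted, stimulus, participants):
    observed = np.asarray(observed, dtype=float)
    predicted = np.asarray(predicted, dtype=float)
    stimulus = np.asarray(stimulus, dtype=float)
    participants = np.asarray(participants)
    n = observed.size
    if not (predicted.size == stimulus.size == participants.size == n):
        raise ValidationError("observed/predicted/stimulus/participants lengths differ")
    if np.unique(participants).size < 2:
        raise ValidationError("need >= 2 participants for a mixed model")
    return observed, predicted, stimulus, participants


def _fit_mixedlm(endog, exog, groups):
    """ML mixed-model fit; falls back to OLS when the mixed fit is singular
    (e.g. a perfect predictor drives the residual variance to zero).

    Returns (result, converged); the fallback is flagged non-converged.
    """
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        try:
            result = sm.MixedLM(endog, exog, groups=groups).fit(reml=False)
            if np.isfinite(result.llf):
                return result, bool(result.converged)
            # The default optimizer can stop exactly on the zero-variance
            # boundary and report an infinite likelihood; Powell handles the
            # boundary gracefully.
            result = sm.MixedLM(endog, exog, groups=groups).fit(
                reml=False, method="powell"
            )
            if np.isfinite(result.llf):
                return result, bool(result.converged)
        except (np.linalg.LinAlgError, ValueError):
            pass
        return sm.OLS(endog, exog).fit(), False


def _fixed_params(result) -> np.ndarray:
    return np.asarray(getattr(result, "fe_params", result.params), dtype=float)


def fit_comparison_model(
    observed,
    predicted,
    stimulus,
    participants,
    model_name: str = "model",
    cv_folds: int | None = None,
    cv_seed: int = 0,
) -> ModelComparisonRow:
    """Score one model's predictions against observations.

    Fits ``observed ~ stimulus + prediction + (1 | participant)`` by ML and
    extracts AIC/BIC/log-likelihood/deviance plus Pearson R^2 of the fitted
    values. When ``cv_folds`` is given, predicted R^2 is computed with
    :func:`predicted_r2`; otherwise it is left as None.

    A fit that fails to converge (singular random-effect variance) is still
    reported, flagged ``converged=False``.
    """
    observed, predicted, stimulus, participants = _validate_inputs(
        observed, predicted, stimulus, participants
    )
    exog = np.column_stack([np.ones_like(observed), stimulus, predicted])
    result, converged = _fit_mixedlm(observed, exog, participants)
    try:
        fitted = np.asarray(result.fittedvalues, dtype=float)
    except (ValueError, np.linalg.LinAlgError):
        # random-effect variance collapsed to zero: BLUPs undefined,
        # fixed-effects fit is the whole story
        fitted = exog @ _fixed_params(result)
    r2 = float(np.corrcoef(observed, fitted)[0, 1] ** 2)
    pr2 = None
    if cv_folds is not None:
        pr2 = predicted_r2(
            observed, predicted, stimulus, participants, folds=cv_folds, seed=cv_seed
        )
    llf = float(result.llf)
    return ModelComparisonRow(
        model=model_name,
        aic=float(result.aic),
        bic=float(result.bic),
        loglik=llf,
        deviance=-2.0 * llf,
        r2=r2,
        predicted_r2=pr2,
        n_obs=int(observed.size),
        converged=converged,
    )


def predicted_r2(
    observed, predicted, stimulus, participants, folds: int = 10, seed: int = 0
) -> float:
    """Cross-validated R^2 with participant-grouped folds.

    Participants are shuffled with ``seed`` and split into ``folds`` groups;
    each fold's observations are predicted from a ML refit on the remaining
    participants using fixed effects only (a held-out participant has no
    random-intercept estimate, so the population intercept applies). The
    value is the squared Pearson correlation between pooled held-out
    predictions and observations.
    """
    if folds < 2:
        raise ValidationError("folds must be >= 2")
    observed, predicted, stimulus, participants = _validate_inputs(
        observed, predicted, stimulus, participants
    )
    labels = np.unique(participants)
    folds = min(folds, labels.size)
    rng = np.random.default_rng(seed)
    order = rng.permutation(labels.size)
    assignments = np.empty(labels.size, dtype=int)
    assignments[order] = np.arange(labels.size) % folds
    fold_of = dict(zip(labels.tolist(), assignments.tolist()))

    exog = np.column_stack([np.ones_like(observed), stimulus, predicted])
    held_out = np.full(observed.size, np.nan)
    trial_folds = np.array([fold_of[p] for p in participants.tolist()])
    for k in range(folds):
        test = trial_folds == k
        result, _ = _fit_mixedlm(observed[~test], exog[~test], participants[~test])
        held_out[test] = exog[test] @ _fixed_params(result)
    if np.isnan(held_out).any():
        raise ValidationError("cross-validation left unpredicted observations")
    return float(np.corrcoef(observed, held_out)[0, 1] ** 2)


def rank_models(rows: list[ModelComparisonRow]) -> ComparisonReport:
    """Sort by BIC, compute deltas vs the best, flag near-degenerate pairs.

    Models whose AIC lies within ``DEGENERACY_DELTA_AIC`` of the best AIC are
    flagged as carrying comparable support.
    """
    if len(rows) < 2:
        raise ValidationError("need >= 2 rows to rank")
    ordered = tuple(sorted(rows, key=lambda r: r.bic))
    best_bic = ordered[0]
    best_aic = min(rows, key=lambda r: r.aic)
    delta_aic = {r.model: r.aic - best_aic.aic for r in ordered}
    delta_bic = {r.model: r.bic - best_bic.bic for r in ordered}
    degenerate = tuple(
        r.model for r in ordered if delta_aic[r.model] < DEGENERACY_DELTA_AIC
    )
    if len(degenerate) < 2:
        degenerate = ()
    return ComparisonReport(
        rows=ordered,
        best_by_bic=best_bic.model,
        best_by_aic=best_aic.model,
        delta_aic=delta_aic,
        delta_bic=delta_bic,
        degenerate=degenerate,
    )
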