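"""Truncated-normal prior machinery.

Forward direction: closed-form mean/variance of a normal(mu, sigma)
restricted to [a, b]. Inverse direction: given target moments (those of the
experienced stimulus distribution) find (mu, sigma) whose truncated moments
match, by bounded least squares with a fixed deterministic initialization.

A hard fact shapes the inverse problem: the density of a truncated normal is
log-concave, so its variance is bounded above by the variance of the uniform
distribution on the same interval, (b-a)^2/12. Discrete equally spaced
stimulus sets have variance step^2 (n^2-1)/12 * ... > (b-a)^2/12, which makes
their moment target unattainable on their own bounds. ``solve_prior`` exposes
this explicitly: by default such targets raise
:class:`~magest.errors.InfeasibleTargetError`; with
``on_infeasible="best_fit"`` the least-squares optimum (a near-uniform prior
pinned at the variance supremum) is returned and flagged, mirroring what a
bounded constrained solver run to convergence produces.
"""

from __future__ import annotations

import enum
import math
from dataclasses import dataclass

import numpy as np
from scipy.optimize import brentq, least_squares
from scipy.special import ndtr

from magest.datamodel import StimulusSet
from magest.errors import InfeasibleTargetError, SolverError, ValidationError

_SQRT2PI = math.sqrt(2.0 * math.pi)

#: Relative slack on the uniform-variance supremum used for feasibility checks.
FEASIBILITY_SLACK = 1e-6

#: Default cap on sigma, in units of (b - a). Large enough that a best-fit
#: solution is numerically indistinguishable from the uniform limit, small
#: enough that Phi(beta) - Phi(alpha) keeps several significant digits.
SIGMA_CAP_FACTOR = 20.0


def _phi(x: np.ndarray) -> np.ndarray:
    return np.exp(-0.5 * x * x) / _SQRT2PI


def _mass(alpha: float, beta: float) -> float:
    # Phi(beta) - Phi(alpha), using the complementary form in the right tail
    # so the difference stays accurate for alpha, beta >> 0.
    if alpha + beta > 0:
        return float(ndtr(-alpha) - ndtr(-beta))
    return float(ndtr(beta) - ndtr(alpha))


def truncnorm_moments(mu: float, sigma: float, a: float, b: float) -> tuple[float, float]:
    """Mean and variance of normal(mu, sigma) truncated to [a, b].

    Stable for standardized bounds up to |alpha|, |beta| ~ 8.
    Raises :class:`ValidationError` for sigma <= 0 or a >= b.
    """
    if sigma <= 0:
        raise ValidationError("sigma must be > 0")
    if a >= b:
        raise ValidationError("need a < b")
    alpha = (a - mu) / sigma
    beta = (b - mu) / sigma
    z = _mass(alpha, beta)
    if z <= 0.0:
        raise SolverError(
            f"truncation mass underflow for mu={mu}, sigma={sigma}, [{a}, {b}]"
        )
    pa = float(_phi(np.asarray(alpha)))
    pb = float(_phi(np.asarray(beta)))
    h = (pa - pb) / z
    mean = mu + sigma * h
    var = sigma * sigma * (1.0 + (alpha * pa - beta * pb) / z - h * h)
    return mean, var


class TargetProvenance(str, enum.Enum):
    DISCRETE_SET = "discrete_set"
    CONTINUOUS_UNIFORM = "continuous_uniform"


@dataclass(frozen=True)
class MomentTarget:
    """Target mean/variance for a prior, with the truncation bounds."""

    target_mean: float
    target_var: float
    a: float
    b: float
    provenance: TargetProvenance

    def __post_init__(self):
        if not self.a <= self.target_mean <= self.b:
            raise ValidationError("target_mean must lie within [a, b]")
        if self.target_var <= 0:
            raise ValidationError("target_var must be > 0")
        if self.a >= self.b:
            raise ValidationError("need a < b")

    @property
    def uniform_var(self) -> float:
        return (self.b - self.a) ** 2 / 12.0

    @property
    def feasible(self) -> bool:
        """Whether any truncated normal on [a, b] can attain target_var."""
        return self.target_var < self.uniform_var * (1.0 - FEASIBILITY_SLACK)


@dataclass(frozen=True)
class TruncatedNormalPrior:
    """A solved prior: parent parameters plus the implied truncated moments.

    ``implied_mean``/``implied_var`` are what the observer's prior actually
    looks like over [a, b]; they are the quantities fed into the posterior
    weighting downstream.
    """

    mu: float
    sigma: float
    a: float
    b: float
    implied_mean: float
    implied_var: float
    converged: bool = True
    residuals: tuple[float, float] = (0.0, 0.0)

    def __post_init__(self):
        if self.sigma <= 0:
            raise ValidationError("sigma must be > 0")
        if self.a >= self.b:
            raise ValidationError("need a < b")
        if not self.a <= self.implied_mean <= self.b:
            raise ValidationError("implied_mean must lie within [a, b]")

    @property
    def implied_sd(self) -> float:
        return math.sqrt(self.implied_var)


def set_moment_target(
    stimulus_set: StimulusSet,
    provenance: TargetProvenance | str = TargetProvenance.DISCRETE_SET,
) -> MomentTarget:
    """Moment target implied by a stimulus set.

    ``discrete_set`` uses the arithmetic mean and population variance of the
    presented values; ``continuous_uniform`` uses the moments of a boxcar over
    [lower_bound, upper_bound].
    """
    provenance = TargetProvenance(provenance)
    a, b = stimulus_set.lower_bound, stimulus_set.upper_bound
    if provenance is TargetProvenance.DISCRETE_SET:
        vals = np.asarray(stimulus_set.values, dtype=float)
        mean = float(vals.mean())
        var = float(((vals - mean) ** 2).mean())
    else:
        mean = 0.5 * (a + b)
        var = (b - a) ** 2 / 12.0
    return MomentTarget(target_mean=mean, target_var=var, a=a, b=b, provenance=provenance)


def pooled_moment_target(
    set_a: StimulusSet,
    set_b: StimulusSet,
    provenance: TargetProvenance | str = TargetProvenance.DISCRETE_SET,
) -> MomentTarget:
    """Moment target of the pooled two-modality stimulus distribution.

    Values from both sets are concatenated with equal weight (the interleaved
    session presents them equally often); bounds are the combined min/max.
    """
    provenance = TargetProvenance(provenance)
    a = min(set_a.lower_bound, set_b.lower_bound)
    b = max(set_a.upper_bound, set_b.upper_bound)
    if provenance is TargetProvenance.DISCRETE_SET:
        vals = np.asarray(set_a.values + set_b.values, dtype=float)
        mean = float(vals.mean())
        var = float(((vals - mean) ** 2).mean())
    else:
        mean = 0.5 * (a + b)
        var = (b - a) ** 2 / 12.0
    return MomentTarget(target_mean=mean, target_var=var, a=a, b=b, provenance=provenance)


def solve_prior(
    target: MomentTarget,
    tol: float = 1e-10,
    max_iter: int = 200,
    on_infeasible: str = "raise",
) -> TruncatedNormalPrior:
    """Find (mu, sigma) whose truncated moments match ``target``.

    Bounded least squares on the two scaled moment residuals, initialized at
    mu0 = target_mean, sigma0 = sqrt(target_var); sigma is constrained to
    (0, SIGMA_CAP_FACTOR * (b - a)]. Deterministic: no random restarts.

    The returned prior satisfies |implied_mean - target_mean| <= tol*(b-a)
    and |implied_var - target_var| <= tol*(b-a)^2 when the target is
    feasible. An infeasible target (target_var at or above the uniform
    supremum) raises :class:`InfeasibleTargetError` by default; pass
    ``on_infeasible="best_fit"`` to get the flagged least-squares optimum
    instead (``converged=False``, residuals recorded).
    """
    if on_infeasible not in ("raise", "best_fit"):
        raise ValueError("on_infeasible must be 'raise' or 'best_fit'")
    a, b = target.a, target.b
    width = b - a
    feasible = target.feasible
    if not feasible and on_infeasible == "raise":
        raise InfeasibleTargetError(
            f"target variance {target.target_var:.6g} is not attainable: the "
            f"truncated-normal supremum on [{a:.6g}, {b:.6g}] is the uniform "
            f"variance {target.uniform_var:.6g}",
            residuals=(0.0, (target.target_var - target.uniform_var) / width**2),
        )

    def residual(x: np.ndarray) -> np.ndarray:
        mean, var = truncnorm_moments(float(x[0]), float(x[1]), a, b)
        return np.array(
            [
                (mean - target.target_mean) / width,
                (var - target.target_var) / width**2,
            ]
        )

    sigma0 = min(math.sqrt(target.target_var), 0.9 * SIGMA_CAP_FACTOR * width)
    x0 = np.array([target.target_mean, sigma0])
    sol = least_squares(
        residual,
        x0,
        bounds=([a - 10.0 * width, 1e-12 * width], [b + 10.0 * width, SIGMA_CAP_FACTOR * width]),
        xtol=1e-15,
        ftol=1e-15,
        gtol=1e-15,
        max_nfev=max_iter * 10,
        method="trf",
    )
    mu, sigma = float(sol.x[0]), float(sol.x[1])
    if not feasible:
        # The least-squares valley is flat in mu at large sigma; pin the
        # implied mean exactly with a 1-D solve (it is increasing in mu).
        lo, hi = a - 10.0 * width, b + 10.0 * width
        f = lambda m: truncnorm_moments(m, sigma, a, b)[0] - target.target_mean
        if f(lo) < 0.0 < f(hi):
            mu = float(brentq(f, lo, hi, xtol=1e-12 * width))
    mean, var = truncnorm_moments(mu, sigma, a, b)
    res = (mean - target.target_mean, var - target.target_var)
    ok = abs(res[0]) <= tol * width and abs(res[1]) <= tol * width**2
    if not ok and feasible:
        raise SolverError(
            f"prior solve did not reach tolerance {tol:g}: residuals {res}",
            residuals=res,
        )
    return TruncatedNormalPrior(
        mu=mu,
        sigma=sigma,
        a=a,
        b=b,
        implied_mean=mean,
        implied_var=var,
        converged=ok,
        residuals=res,
    )
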