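"""False reaction calls and system noise on top of the Poisson model.

A false positive (rate ε+) is an empty partition called positive, e.g.
through contamination; a false negative (rate ε−) is an occupied partition
called negative, e.g. through amplification failure.  Flipping each class
independently turns the true negative fraction q = e^{−λ} into

    q_ε = q (1 − ε+) + (1 − q) ε−

so the chip reports λ_ε = −ln q_ε instead of λ.  Sampling variation is then
evaluated at λ_ε and pooled with an optional extra log-scale system noise
σ_s, and precision is judged against the *true* λ so the bias λ_ε/λ is
included:

    P = max|1 − (λ_ε/λ) e^{±Z σ_t}|,   σ_t = sqrt(σ_ε² + σ_s²).

With all rates zero everything reduces exactly to the ideal model.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

from scipy.optimize import brentq, minimize_scalar

from .core import (
    DEFAULT_SPEC,
    ConfidenceSpec,
    precision,
    sampling_sigma,
)
from .exceptions import InvalidInputError, SaturatedChipError, UnachievablePrecisionError

__all__ = [
    "NoiseModel",
    "ErrorAdjustedEstimate",
    "observed_lambda",
    "sigma_with_errors",
    "pooled_sigma",
    "precision_with_errors",
    "error_adjusted_estimate",
    "optimal_load_with_errors",
    "lod_with_errors",
]


@dataclass(frozen=True)
class NoiseModel:
    """Per-class false call rates plus extra log-scale system noise.

    ``fp_rate`` (ε+): probability a true negative is called positive.
    ``fn_rate`` (ε−): probability a true positive is called negative.
    ``system_sigma`` (σ_s): additional standard deviation on ln λ̂.
    """

    fp_rate: float = 0.0
    fn_rate: float = 0.0
    system_sigma: float = 0.0

    def __post_init__(self) -> None:
        if not 0.0 <= self.fp_rate <= 1.0:
            raise InvalidInputError("fp_rate must be in [0, 1]")
        if not 0.0 <= self.fn_rate <= 1.0:
            raise InvalidInputError("fn_rate must be in [0, 1]")
        if self.system_sigma < 0.0:
            raise InvalidInputError("system_sigma must be nonnegative")

    @property
    def is_ideal(self) -> bool:
        return self.fp_rate == 0.0 and self.fn_rate == 0.0 and self.system_sigma == 0.0


#: No false calls, no system noise.
IDEAL = NoiseModel()


@dataclass(frozen=True)
class ErrorAdjustedEstimate:
    """Error-model summary at a true load λ: observed λ_ε, spreads, bounds, P."""

    lam_true: float
    lam_observed: float
    q_observed: float
    sigma_eps: float
    sigma_total: float
    bounds: tuple[float, float]
    precision: float


def observed_lambda(lam: float, noise: NoiseModel, model: str = "per-class") -> float:
    """Mean copies per partition the chip *reports* under false calls.

    ``model="per-class"`` flips each class independently (the default);
    ``model="additive"`` shifts the negative fraction by −ε+ + ε−, a cruder
    variant kept for sensitivity analysis.
    """
    if lam < 0:
        raise InvalidInputError(f"λ must be nonnegative, got {lam}")
    q = math.exp(-lam)
    if model == "per-class":
        q_eps = q * (1.0 - noise.fp_rate) + (1.0 - q) * noise.fn_rate
    elif model == "additive":
        q_eps = q - noise.fp_rate + noise.fn_rate
    else:
        raise InvalidInputError(f"unknown error model {model!r}")
    if q_eps <= 0.0:
        raise SaturatedChipError(
            "false calls drive the expected negative fraction to zero"
        )
    if q_eps > 1.0:
        q_eps = 1.0
    return -math.log(q_eps)


def sigma_with_errors(lam_eps: float, n: int) -> float:
    """Sampling spread of ln λ̂ evaluated at the observed λ_ε."""
    return sampling_sigma(lam_eps, n)


def pooled_sigma(sigma_eps: float, system_sigma: float) -> float:
    """Total spread: sampling and system noise pooled in quadrature."""
    if sigma_eps < 0 or system_sigma < 0:
        raise InvalidInputError("standard deviations must be nonnegative")
    return math.hypot(sigma_eps, system_sigma)


def error_adjusted_estimate(
    lam: float,
    n: int,
    noise: NoiseModel,
    spec: ConfidenceSpec = DEFAULT_SPEC,
    model: str = "per-class",
) -> ErrorAdjustedEstimate:
    """Observed load, pooled spread, confidence bounds and precision at true λ."""
    if not lam > 0:
        raise InvalidInputError(f"λ must be positive, got {lam}")
    lam_eps = observed_lambda(lam, noise, model=model)
    if lam_eps <= 0.0:
        # every partition reads negative in expectation: no information
        raise InvalidInputError(
            "observed λ is zero; load and false-negative rate leave no positives"
        )
    s_eps = sigma_with_errors(lam_eps, n)
    s_t = pooled_sigma(s_eps, noise.system_sigma)
    zs = spec.z_score * s_t
    if zs > 700.0:
        lo, hi, p = 0.0, math.inf, math.inf
    else:
        lo = lam_eps * math.exp(-zs)
        hi = lam_eps * math.exp(zs)
        ratio = lam_eps / lam
        p = max(abs(1.0 - ratio * math.exp(zs)), abs(1.0 - ratio * math.exp(-zs)))
    return ErrorAdjustedEstimate(
        lam_true=lam,
        lam_observed=lam_eps,
        q_observed=math.exp(-lam_eps),
        sigma_eps=s_eps,
        sigma_total=s_t,
        bounds=(lo, hi),
        precision=p,
    )


def precision_with_errors(
    lam: float,
    n: int,
    noise: NoiseModel,
    spec: ConfidenceSpec = DEFAULT_SPEC,
    model: str = "per-class",
) -> float:
    """Precision against the true λ, bias from false calls included."""
    if noise.is_ideal:
        return precision(lam, n, spec)
    return error_adjusted_estimate(lam, n, noise, spec, model=model).precision


def optimal_load_with_errors(
    n: int,
    noise: NoiseModel,
    spec: ConfidenceSpec = DEFAULT_SPEC,
    model: str = "per-class",
) -> tuple[float, float]:
    """Load minimising error-adjusted precision, with its percent negatives.

    Under ideal conditions the optimum sits at ~20.3% negatives; rising
    false-negative rates push it toward *more* negatives (lower load).
    Returns ``(λ_opt, 100·exp(−λ_opt))``.
    """

    def objective(lam: float) -> float:
        try:
            return precision_with_errors(lam, n, noise, spec, model=model)
        except (SaturatedChipError, InvalidInputError):
            return math.inf

    res = minimize_scalar(
        objective, bounds=(1e-6, 30.0), method="bounded", options={"xatol": 1e-9}
    )
    lam_opt = float(res.x)
    return lam_opt, 100.0 * math.exp(-lam_opt)


def lod_with_errors(
    n: int,
    precision_bound: float,
    noise: NoiseModel,
    spec: ConfidenceSpec = DEFAULT_SPEC,
    model: str = "per-class",
) -> float:
    """Lower limit of detection: smallest λ meeting the precision bound.

    Found by Brent root-finding on the lower (decreasing) flank of the
    error-adjusted precision curve.  False positives raise this limit
    sharply because at low load the few genuine positives are swamped by
    spurious ones.
    """
    if not precision_bound > 0:
        raise InvalidInputError("precision_bound must be positive")
    lam_opt, _ = optimal_load_with_errors(n, noise, spec, model=model)
    p_min = precision_with_errors(lam_opt, n, noise, spec, model=model)
    if precision_bound < p_min:
        raise UnachievablePrecisionError(precision_bound, p_min)

    def f(lam: float) -> float:
        return precision_with_errors(lam, n, noise, spec, model=model) - precision_bound

    lo = 1e-12
    while f(lo) < 0:  # bound already met arbitrarily low (won't occur in practice)
        lo /= 10.0
        if lo < 1e-300:
            return 0.0
    return float(brentq(f, lo, lam_opt, rtol=1e-12))
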