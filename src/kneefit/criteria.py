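"""Threshold criteria applied to fitted level-response curves.

Three criteria are provided:

* ``two_sigma`` — the intensity where the *composed* curve first exceeds
  twice the noise floor, f(t) = 2*sigma.  Under quadrature composition this
  means f0(t) = sqrt(3)*sigma; under additive composition f0(t) = sigma.
  Because the effective noise floor shrinks as 1/sqrt(N) with the number of
  averaged repetitions N, this criterion diverges to -inf with measurement
  depth — the pathology the knee criterion removes.
* ``p_fraction`` — the intensity where the *noise-free* curve exceeds a
  fraction p of its dynamic range, f0(t) = p * a (default p = 0.05).
  Noise-independent, but p is an arbitrary extra parameter.
* ``knee`` — the lower knee t of a fitted hard sigmoid, read off directly.
  No criterion parameter at all; only defined for hard-sigmoid fits.

Closed-form solvers are exposed separately from the ``FitResult`` wrappers
so they can be cross-checked against numeric root-finding.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from typing import Optional

from .exceptions import CriterionError
from .models import (
    ADDITIVE,
    HardSigmoidParams,
    LogisticParams,
    ModelParams,
    NoiseModel,
)

TWO_SIGMA = "two_sigma"
P_FRACTION = "p_fraction"
KNEE = "knee"
CRITERIA = (TWO_SIGMA, P_FRACTION, KNEE)


@dataclass
class ThresholdEstimate:
    """A threshold value under one criterion.

    ``defined`` is False when the criterion has no solution for the fitted
    parameters (e.g. the composed curve never reaches 2*sigma); then
    ``threshold`` is None.
    """

    criterion: str
    threshold: Optional[float]
    defined: bool
    p: Optional[float] = None
    source: object = None
    extrapolated: bool = False


def solve_two_sigma(params: ModelParams, noise: NoiseModel) -> Optional[float]:
    """Closed-form solution of compose(f0(t), noise) = 2*sigma, or None.

    Logistic + quadrature: t = b - c*ln(a/(sqrt(3)*sigma) - 1)
    Logistic + additive:   t = b - c*ln(a/sigma - 1)
    Hard sigmoid:          t_knee + target/s on the linear segment, where
                           target = sqrt(3)*sigma (quadrature) or sigma
                           (additive); unsolvable when target > h.
    """
    if noise.sigma <= 0:
        raise CriterionError("2-sigma criterion is undefined for sigma = 0")
    target = noise.sigma if noise.mode == ADDITIVE else math.sqrt(3.0) * noise.sigma
    if isinstance(params, LogisticParams):
        if params.a <= target:  # f0 < a everywhere: never reaches the target
            return None
        return params.b - params.c * math.log(params.a / target - 1.0)
    if isinstance(params, HardSigmoidParams):
        if target > params.h:
            return None
        return params.t + target / params.s
    raise CriterionError(f"unknown parameter type {type(params).__name__}")


def solve_p_fraction(params: ModelParams, p: float) -> float:
    """Closed-form solution of f0(t) = p * (dynamic range).

    Logistic:     t = b - c*ln(1/p - 1)
    Hard sigmoid: t = t_knee + p*h/s
    """
    if not 0.0 < p < 1.0:
        raise CriterionError(f"p must lie in (0, 1), got {p}")
    if isinstance(params, LogisticParams):
        return params.b - params.c * math.log(1.0 / p - 1.0)
    if isinstance(params, HardSigmoidParams):
        return params.t + p * params.h / params.s
    raise CriterionError(f"unknown parameter type {type(params).__name__}")


def two_sigma_vs_sample_size(
    params: LogisticParams, sigma_single_trial: float, n: float,
    mode: str = "quadrature",
) -> Optional[float]:
    """Closed-form 2-sigma threshold at averaging depth ``n``.

    Averaging n repetitions of noise with single-trial RMS sigma_1 leaves an
    effective floor sigma_1/sqrt(n); the returned threshold therefore
    decreases without bound as n grows (by -c*ln(2) per quadrupling of n in
    the large-n limit).  Returns None where the criterion is unsolvable
    (a <= sqrt(3)*sigma_eff).
    """
    sigma_eff = sigma_single_trial / math.sqrt(n)
    return solve_two_sigma(params, NoiseModel(mode, sigma_eff))


def _require_converged(fit) -> None:
    if not fit.converged:
        raise CriterionError("cannot apply a threshold criterion to a non-converged fit")


def _wrap(fit, criterion: str, threshold: Optional[float], p=None) -> ThresholdEstimate:
    defined = threshold is not None
    extrapolated = bool(fit.extrapolated) if defined else False
    return ThresholdEstimate(
        criterion=criterion, threshold=threshold, defined=defined, p=p,
        source=fit, extrapolated=extrapolated,
    )


def threshold_two_sigma(fit) -> ThresholdEstimate:
    """Threshold where the composed fitted curve exceeds 2*sigma."""
    _require_converged(fit)
    return _wrap(fit, TWO_SIGMA, solve_two_sigma(fit.params, fit.noise))


def threshold_p_fraction(fit, p: float = 0.05) -> ThresholdEstimate:
    """Threshold where the noise-free fitted curve exceeds p * dynamic range."""
    _require_converged(fit)
    return _wrap(fit, P_FRACTION, solve_p_fraction(fit.params, p), p=p)


def threshold_knee(fit) -> ThresholdEstimate:
    """Threshold = the lower knee t of a hard-sigmoid fit (no free parameter)."""
    _require_converged(fit)
    if not isinstance(fit.params, HardSigmoidParams):
        raise CriterionError("knee criterion requires a hard-sigmoid fit")
    return _wrap(fit, KNEE, fit.params.t)


def apply_criterion(fit, criterion: str, p: float = 0.05) -> ThresholdEstimate:
    """Dispatch on criterion name ('two_sigma' | 'p_fraction' | 'knee')."""
    if criterion == TWO_SIGMA:
        return threshold_two_sigma(fit)
    if criterion == P_FRACTION:
        return threshold_p_fraction(fit, p=p)
    if criterion == KNEE:
        return threshold_knee(fit)
    raise CriterionError(f"unknown criterion {criterion!r}; expected one of {CRITERIA}")
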