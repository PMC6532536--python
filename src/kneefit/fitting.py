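"""Least-squares fitting of composed level-response models with fixed sigma.

The free parameters are only those of the noise-free model f0 — (a, b, c)
for the logistic, (t, s, h) for the hard sigmoid.  The noise floor sigma is
an input measured from no-stimulus data and is held fixed: the objective is

    sum_i ( y_i - compose(f0(x_i; theta), noise) )^2.

Because the quadrature-composed hard sigmoid has gradient kinks at its two
knees, a single local optimization can stall; fits therefore use bounded
trust-region least squares from a multi-start grid and keep the lowest-RSS
converged start, which makes the result deterministic for fixed data.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Optional, Tuple

import numpy as np
from scipy.optimize import least_squares

from .exceptions import CriterionError, TooFewPointsError
from .models import (
    ADDITIVE,
    HardSigmoidParams,
    LevelResponseCurve,
    LogisticParams,
    ModelParams,
    NoiseModel,
    compose_response,
    evaluate_f0,
)

LOGISTIC = "logistic"
HARD_SIGMOID = "hard_sigmoid"
MODELS = (LOGISTIC, HARD_SIGMOID)

_POS = 1e-9          # open lower bound standing in for "strictly positive"
_RSS_TIE = 1e-10     # starts within this RSS are tied; smallest threshold wins


@dataclass
class FitResult:
    """A fitted composed level-response model.

    ``noise`` echoes the fixed input sigma unchanged — fitting never touches
    it.  ``extrapolated`` flags a threshold parameter (hard-sigmoid knee t,
    logistic inflection b) outside the sampled intensity range.
    """

    model: str
    params: ModelParams
    noise: NoiseModel
    rss: float
    converged: bool
    extrapolated: bool
    n_points: int

    def predict(self, x):
        """Composed model value at intensity x."""
        return compose_response(evaluate_f0(x, self.params), self.noise)


def _hard_sigmoid_starts(x, y, sigma, mode, n_starts):
    span = x[-1] - x[0]
    ymax = y.max()
    if mode == ADDITIVE:
        h0 = max(ymax - sigma, _POS * 10)
    else:
        h0 = np.sqrt(max(ymax**2 - sigma**2, (_POS * 10) ** 2))
    slopes = np.diff(y) / np.diff(x)
    s0 = max(slopes.max(initial=0.0), (ymax - y.min()) / span, _POS * 10)
    lower = np.array([x[0] - span, _POS, _POS])
    upper = np.array([x[-1] + span, np.inf, np.inf])
    starts = [np.array([t0, s0, h0]) for t0 in np.linspace(x[0], x[-1], n_starts)]
    return starts, (lower, upper)


def _logistic_starts(x, y, sigma, mode, n_starts):
    span = x[-1] - x[0]
    ymax = y.max()
    if mode == ADDITIVE:
        a0 = max(ymax - sigma, _POS * 10)
    else:
        a0 = np.sqrt(max(ymax**2 - sigma**2, (_POS * 10) ** 2))
    lower = np.array([_POS, x[0] - span, _POS])
    upper = np.array([np.inf, x[-1] + span, np.inf])
    starts = [
        np.array([a0, b0, c0])
        for b0 in np.linspace(x[0], x[-1], n_starts)
        for c0 in (span / 20.0, span / 6.0)
    ]
    return starts, (lower, upper)


def _residual_fn(model, x, y, noise):
    if model == HARD_SIGMOID:
        def fn(theta):
            f0 = np.clip(theta[1] * (x - theta[0]), 0.0, theta[2])
            return compose_response(f0, noise) - y
    else:
        def fn(theta):
            z = (x - theta[1]) / theta[2]
            f0 = theta[0] / (1.0 + np.exp(-np.clip(z, -500, 500)))
            return compose_response(f0, noise) - y
    return fn


def _to_params(model, theta) -> ModelParams:
    if model == HARD_SIGMOID:
        return HardSigmoidParams(t=float(theta[0]), s=float(theta[1]), h=float(theta[2]))
    return LogisticParams(a=float(theta[0]), b=float(theta[1]), c=float(theta[2]))


def _threshold_param(model, theta) -> float:
    return float(theta[0]) if model == HARD_SIGMOID else float(theta[1])


def fit_level_response(
    curve: LevelResponseCurve,
    model: str = HARD_SIGMOID,
    n_starts: int = 7,
    max_nfev: int = 500,
    tol: float = 1e-8,
) -> FitResult:
    """Fit a composed model to the curve by bounded least squares.

    Requires at least 4 points (3 free parameters).  Unweighted residuals;
    deterministic for fixed data and settings.  If no start converges the
    best-effort parameters are returned with ``converged=False`` and no
    threshold should be derived from them.
    """
    if model not in MODELS:
        raise CriterionError(f"unknown model {model!r}; expected one of {MODELS}")
    x = curve.intensities
    y = curve.responses
    if x.size < 4:
        raise TooFewPointsError(
            f"fit needs at least 4 level-response points, got {x.size}"
        )
    noise = curve.noise
    make_starts = _hard_sigmoid_starts if model == HARD_SIGMOID else _logistic_starts
    starts, bounds = make_starts(x, y, noise.sigma, noise.mode, n_starts)
    fn = _residual_fn(model, x, y, noise)

    best = None  # (rss, threshold_param, theta, success)
    fallback = None
    for theta0 in starts:
        theta0 = np.clip(theta0, bounds[0], bounds[1])
        res = least_squares(
            fn, theta0, bounds=bounds, method="trf",
            xtol=tol, ftol=tol, gtol=tol, max_nfev=max_nfev,
        )
        rss = float(np.sum(res.fun**2))
        entry = (rss, _threshold_param(model, res.x), res.x)
        if res.success:
            if (
                best is None
                or rss < best[0] - _RSS_TIE
                or (abs(rss - best[0]) <= _RSS_TIE and entry[1] < best[1])
            ):
                best = entry
        elif fallback is None or rss < fallback[0]:
            fallback = entry
    converged = best is not None
    rss, thr, theta = best if converged else fallback
    return FitResult(
        model=model,
        params=_to_params(model, theta),
        noise=noise,
        rss=rss,
        converged=converged,
        extrapolated=not (x[0] <= thr <= x[-1]),
        n_points=int(x.size),
    )
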