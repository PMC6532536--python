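"""Noise-free stimulus-response models and their composition with a noise floor.

A sensory system's mean response to a stimulus of intensity ``x`` (dB) is
modelled by a noise-free level-response function ``f0(x)`` — either a
generalized logistic function

    f0(x) = a / (1 + exp(-(x - b) / c))

or a generalized hard sigmoid

    f0(x) = 0            for x < t
          = s * (x - t)  for t <= x while s * (x - t) < h
          = h            otherwise,

whose lower knee ``t`` is the sensory threshold.  A real recording
superimposes ``f0`` with a background-noise floor ``sigma``.  Power-like
response measures (RMS amplitudes of evoked potentials) combine signal and
noise in quadrature, ``f(x) = sqrt(f0(x)**2 + sigma**2)``; rate-like
measures (spike rates on top of spontaneous activity) combine additively,
``f(x) = f0(x) + sigma``.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from typing import Union

import numpy as np
from scipy.special import expit

from .exceptions import DataFormatError, ParameterDomainError

logger = logging.getLogger("kneefit")

ADDITIVE = "additive"
QUADRATURE = "quadrature"
NOISE_MODES = (ADDITIVE, QUADRATURE)


@dataclass(frozen=True)
class LogisticParams:
    """Generalized logistic level-response parameters.

    a : maximal response (response units, e.g. mV or spikes/s), a > 0
    b : inflection-point intensity (dB) where f0(b) = a/2
    c : inverse-slope scale (dB), c > 0; slope at the inflection is a/(4c)
    """

    a: float
    b: float
    c: float

    def __post_init__(self) -> None:
        if not (np.isfinite(self.a) and self.a > 0):
            raise ParameterDomainError(f"maximal response a must be > 0, got {self.a}")
        if not np.isfinite(self.b):
            raise ParameterDomainError(f"inflection point b must be finite, got {self.b}")
        if not (np.isfinite(self.c) and self.c > 0):
            raise ParameterDomainError(f"slope scale c must be > 0, got {self.c}")


@dataclass(frozen=True)
class HardSigmoidParams:
    """Generalized hard-sigmoid level-response parameters.

    t : lower-knee intensity = sensory threshold (dB)
    s : slope of the linear segment (response units per dB), s > 0
    h : saturation value (response units), h > 0

    The upper knee sits at x = t + h/s.
    """

    t: float
    s: float
    h: float

    def __post_init__(self) -> None:
        if not np.isfinite(self.t):
            raise ParameterDomainError(f"knee t must be finite, got {self.t}")
        if not (np.isfinite(self.s) and self.s > 0):
            raise ParameterDomainError(f"slope s must be > 0, got {self.s}")
        if not (np.isfinite(self.h) and self.h > 0):
            raise ParameterDomainError(f"saturation h must be > 0, got {self.h}")

    @property
    def upper_knee(self) -> float:
        return self.t + self.h / self.s


ModelParams = Union[LogisticParams, HardSigmoidParams]


@dataclass(frozen=True)
class NoiseModel:
    """Fixed background-noise floor and the rule for composing it with f0.

    mode  : "additive" (rates) or "quadrature" (RMS amplitudes)
    sigma : noise level >= 0, in the same units as the response
    """

    mode: str
    sigma: float

    def __post_init__(self) -> None:
        if self.mode not in NOISE_MODES:
            raise ParameterDomainError(
                f"noise mode must be one of {NOISE_MODES}, got {self.mode!r}"
            )
        if not (np.isfinite(self.sigma) and self.sigma >= 0):
            raise ParameterDomainError(f"sigma must be >= 0, got {self.sigma}")


def logistic_f0(x, p: LogisticParams):
    """Noise-free generalized logistic response at intensity ``x`` (dB)."""
    x = np.asarray(x, dtype=float)
    out = p.a * expit((x - p.b) / p.c)
    return out if out.ndim else float(out)


def hard_sigmoid_f0(x, p: HardSigmoidParams):
    """Noise-free hard-sigmoid response at intensity ``x`` (dB).

    At the exact breakpoints the boundary value is returned: 0 at x = t and
    h at the upper knee x = t + h/s (the function is continuous, so this
    only pins down bit-level behaviour).
    """
    x = np.asarray(x, dtype=float)
    out = np.clip(p.s * (x - p.t), 0.0, p.h)
    return out if out.ndim else float(out)


def evaluate_f0(x, p: ModelParams):
    """Evaluate whichever noise-free model family ``p`` belongs to."""
    if isinstance(p, LogisticParams):
        return logistic_f0(x, p)
    if isinstance(p, HardSigmoidParams):
        return hard_sigmoid_f0(x, p)
    raise ParameterDomainError(f"unknown parameter type {type(p).__name__}")


def compose_response(f0_value, noise: NoiseModel):
    """Compose a noise-free response with the background-noise floor.

    additive   -> f0 + sigma
    quadrature -> sqrt(f0**2 + sigma**2)
    """
    f0 = np.asarray(f0_value, dtype=float)
    if np.any(f0 < 0):
        raise ParameterDomainError("noise-free response must be non-negative")
    if noise.mode == ADDITIVE:
        out = f0 + noise.sigma
    else:
        out = np.hypot(f0, noise.sigma)
    return out if out.ndim else float(out)


def composed_model(x, p: ModelParams, noise: NoiseModel):
    """Composed level-response curve f(x) for either model family."""
    return compose_response(evaluate_f0(x, p), noise)


@dataclass
class LevelResponseCurve:
    """Reduced (intensity, response) points with their fixed noise floor.

    Intensities are canonicalized on construction: sorted ascending, and
    duplicate intensities averaged (with a logged notice).  ``noise`` carries
    the independently measured floor sigma and the composition mode that the
    fit will hold fixed.
    """

    intensities: np.ndarray
    responses: np.ndarray
    noise: NoiseModel
    meta: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        x = np.asarray(self.intensities, dtype=float).ravel()
        y = np.asarray(self.responses, dtype=float).ravel()
        if x.size != y.size:
            raise DataFormatError(
                f"intensities ({x.size}) and responses ({y.size}) differ in length"
            )
        if x.size == 0:
            raise DataFormatError("level-response curve must contain at least one point")
        if not (np.all(np.isfinite(x)) and np.all(np.isfinite(y))):
            raise DataFormatError("non-finite intensity or response value")
        ux, inverse = np.unique(x, return_inverse=True)
        if ux.size != x.size:
            logger.info(
                "averaging %d duplicate-intensity points", x.size - ux.size
            )
            y = np.bincount(inverse, weights=y) / np.bincount(inverse)
            x = ux
        else:
            order = np.argsort(x)
            x, y = x[order], y[order]
        self.intensities = x
        self.responses = y

    @property
    def n_points(self) -> int:
        return int(self.intensities.size)

    def replace_noise(self, noise: NoiseModel) -> "LevelResponseCurve":
        return LevelResponseCurve(
            self.intensities.copy(), self.responses.copy(), noise, dict(self.meta)
        )

    def drop_points(self, k: int, side: str) -> "LevelResponseCurve":
        """Remove the k lowest- (``side='subthreshold'``) or highest-
        (``side='saturation'``) intensity points."""
        if k < 0 or k >= self.n_points:
            raise DataFormatError(f"cannot drop {k} of {self.n_points} points")
        if side == "subthreshold":
            sl = slice(k, None)
        elif side == "saturation":
            sl = slice(None, self.n_points - k)
        else:
            raise DataFormatError("side must be 'subthreshold' or 'saturation'")
        return LevelResponseCurve(
            self.intensities[sl].copy(), self.responses[sl].copy(), self.noise, dict(self.meta)
        )
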