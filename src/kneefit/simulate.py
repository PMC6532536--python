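"""Surrogate-data generator for validating threshold estimators.

Emulates a far-field evoked-potential (ABR-like) measurement with known
ground truth: at each stimulus intensity x the "neural" response is a short
sine burst whose amplitude follows a chosen template level-response
function, buried in white Gaussian background noise, repeated over many
trials.  Averaging the trials and taking RMS amplitudes reconstructs a
level-response curve whose true threshold is known exactly — the validation
bed for every criterion in this package.

The standard surrogate conditions (``standard_surrogate_config``) are a
logistic template a = 10 mV, b = 60 dB, c = 11.89 dB sampled at 22 equally
spaced intensities from -30 to 130 dB, a 1 kHz sine of 10 ms duration, and
Gaussian noise of sigma0 = 40 mV RMS per trial (S/N = 1/4) with N = 200
repetitions, so the effective noise floor after averaging is
40/sqrt(200) ~ 2.83 mV.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, replace
from typing import List, Optional, Tuple, Union

import numpy as np

from . import criteria
from .exceptions import CriterionError, DataFormatError, ParameterDomainError
from .models import (
    HardSigmoidParams,
    LogisticParams,
    ModelParams,
    NoiseModel,
    evaluate_f0,
)

PEAK = "peak"
RMS = "rms"
AMPLITUDE_MODES = (PEAK, RMS)


@dataclass(frozen=True)
class TrialBlock:
    """Raw repetition data at one stimulus intensity.

    intensity : stimulus intensity in dB, or None for the no-stimulus block
    traces    : (n_trials, n_samples) response matrix (e.g. mV)
    sampling_rate : Hz
    window    : half-open analysis window [start, end) in ms
    phase     : stimulus phase tag for double-trial artifact correction
                (0 = unpaired, +1/-1 = the two members of a pair)
    """

    intensity: Optional[float]
    traces: np.ndarray
    sampling_rate: float
    window: Tuple[float, float]
    phase: int = 0

    def __post_init__(self) -> None:
        traces = np.asarray(self.traces, dtype=float)
        if traces.ndim != 2 or traces.shape[0] < 1 or traces.shape[1] < 1:
            raise DataFormatError(
                f"traces must be a non-empty (n_trials, n_samples) matrix, got shape {traces.shape}"
            )
        object.__setattr__(self, "traces", traces)
        if self.sampling_rate <= 0:
            raise DataFormatError("sampling_rate must be positive")
        start, end = self.window
        extent_ms = traces.shape[1] / self.sampling_rate * 1000.0
        if not (0.0 <= start < end <= extent_ms + 1e-9):
            raise DataFormatError(
                f"window {self.window} ms outside trace extent [0, {extent_ms:g}) ms"
            )

    @property
    def n_trials(self) -> int:
        return int(self.traces.shape[0])

    @property
    def n_samples(self) -> int:
        return int(self.traces.shape[1])

    @property
    def is_no_stimulus(self) -> bool:
        return self.intensity is None


@dataclass(frozen=True)
class SimulationConfig:
    """Ground-truth template plus acquisition parameters for the simulator.

    amplitude_mode controls what the template value f0(x) sets on the sine
    burst: its RMS ("rms", the default: peak = sqrt(2)*f0, so the recovered
    RMS curve saturates exactly at the template maximum and the single-trial
    S/N at saturation is a/sigma0 = 1/4 under the standard conditions) or
    its peak amplitude ("peak", recovered curve saturates at a/sqrt(2)).
    Thresholds other than the amplitude-dependent 2-sigma value are
    unaffected by the choice.
    """

    template: ModelParams
    sigma0: float = 40.0
    n_trials: int = 200
    intensity_grid: Tuple[float, ...] = tuple(np.linspace(-30.0, 130.0, 22))
    carrier_freq: float = 1000.0
    duration_ms: float = 10.0
    sampling_rate: float = 20000.0
    seed: int = 0
    amplitude_mode: str = RMS

    def __post_init__(self) -> None:
        if not isinstance(self.template, (LogisticParams, HardSigmoidParams)):
            raise ParameterDomainError("template must be LogisticParams or HardSigmoidParams")
        if self.sigma0 < 0:
            raise ParameterDomainError("sigma0 must be >= 0")
        if self.n_trials < 1:
            raise ParameterDomainError("n_trials must be >= 1")
        grid = tuple(float(x) for x in self.intensity_grid)
        if len(grid) == 0 or np.any(np.diff(grid) <= 0):
            raise ParameterDomainError("intensity_grid must be non-empty and strictly increasing")
        object.__setattr__(self, "intensity_grid", grid)
        if self.sampling_rate <= 2.0 * self.carrier_freq:
            raise ParameterDomainError("sampling_rate must exceed twice the carrier frequency")
        if self.duration_ms <= 0:
            raise ParameterDomainError("duration_ms must be positive")
        if self.amplitude_mode not in AMPLITUDE_MODES:
            raise ParameterDomainError(f"amplitude_mode must be one of {AMPLITUDE_MODES}")

    @property
    def n_samples(self) -> int:
        return int(round(self.duration_ms / 1000.0 * self.sampling_rate))

    @property
    def window(self) -> Tuple[float, float]:
        return (0.0, self.duration_ms)

    @property
    def effective_sigma(self) -> float:
        """Expected noise floor after averaging n_trials: sigma0/sqrt(N)."""
        return self.sigma0 / math.sqrt(self.n_trials)


def standard_surrogate_config(**overrides) -> SimulationConfig:
    """The standard logistic-template surrogate measurement conditions."""
    cfg = SimulationConfig(template=LogisticParams(a=10.0, b=60.0, c=11.89))
    return replace(cfg, **overrides) if overrides else cfg


def hard_sigmoid_surrogate_config(**overrides) -> SimulationConfig:
    """Hard-sigmoid-template variant at the same S/N and dynamic range.

    t = 40 dB, slope s = 0.25 mV/dB, saturation h = 10 mV (upper knee at
    80 dB), with the same noise, grid and trial count as the standard
    surrogate.
    """
    cfg = SimulationConfig(template=HardSigmoidParams(t=40.0, s=0.25, h=10.0))
    return replace(cfg, **overrides) if overrides else cfg


def trial_rng(seed: int, block_index: int, trial_index: int) -> np.random.Generator:
    """Per-trial noise stream, stable under generation order.

    Streams are derived from (seed, block index, trial index) via numpy's
    SeedSequence spawn keys, so any trial can be regenerated independently.
    """
    return np.random.default_rng(
        np.random.SeedSequence(seed, spawn_key=(block_index, trial_index))
    )


def _sine_amplitude(cfg: SimulationConfig, x: Optional[float]) -> float:
    if x is None:
        return 0.0
    f0 = float(evaluate_f0(x, cfg.template))
    return f0 if cfg.amplitude_mode == PEAK else math.sqrt(2.0) * f0


def simulate_trial(
    x: Optional[float], cfg: SimulationConfig, rng: np.random.Generator
) -> np.ndarray:
    """One raw trial at intensity ``x`` (None = no stimulus).

    A sine burst of the configured carrier frequency and duration, with
    amplitude set by the template response at x, plus i.i.d. Gaussian noise
    of standard deviation sigma0 on every sample.
    """
    n = cfg.n_samples
    amp = _sine_amplitude(cfg, x)
    if amp != 0.0:
        times = np.arange(n) / cfg.sampling_rate
        trace = amp * np.sin(2.0 * math.pi * cfg.carrier_freq * times)
    else:
        trace = np.zeros(n)
    if cfg.sigma0 > 0:
        trace = trace + rng.normal(0.0, cfg.sigma0, size=n)
    return trace


def simulate_block(
    x: Optional[float], cfg: SimulationConfig, block_index: int,
    n_trials: Optional[int] = None,
) -> TrialBlock:
    n_trials = cfg.n_trials if n_trials is None else n_trials
    traces = np.stack(
        [simulate_trial(x, cfg, trial_rng(cfg.seed, block_index, k)) for k in range(n_trials)]
    )
    return TrialBlock(
        intensity=None if x is None else float(x),
        traces=traces,
        sampling_rate=cfg.sampling_rate,
        window=cfg.window,
    )


def simulate_noise_block(cfg: SimulationConfig, n_trials: Optional[int] = None) -> TrialBlock:
    """The no-stimulus block alone (noise-floor estimation)."""
    return simulate_block(None, cfg, block_index=len(cfg.intensity_grid), n_trials=n_trials)


def simulate_dataset(cfg: SimulationConfig) -> List[TrialBlock]:
    """One TrialBlock per grid intensity plus a final no-stimulus block.

    Fully reproducible from cfg.seed; identical configs give bit-identical
    datasets.
    """
    blocks = [simulate_block(x, cfg, i) for i, x in enumerate(cfg.intensity_grid)]
    blocks.append(simulate_noise_block(cfg))
    return blocks


def ground_truth_threshold(
    cfg: SimulationConfig, criterion: str, p: float = 0.05,
    noise: Optional[NoiseModel] = None,
) -> float:
    """Closed-form threshold of the noise-free template under a criterion.

    The 2-sigma criterion is noise-dependent by construction, so ``noise``
    (the effective floor after averaging) must be given for it.
    """
    template = cfg.template
    if criterion == criteria.KNEE:
        if not isinstance(template, HardSigmoidParams):
            raise CriterionError("knee ground truth requires a hard-sigmoid template")
        return template.t
    if criterion == criteria.P_FRACTION:
        return criteria.solve_p_fraction(template, p)
    if criterion == criteria.TWO_SIGMA:
        if noise is None:
            raise CriterionError(
                "2-sigma ground truth needs the effective noise floor (criterion is noise-dependent)"
            )
        t = criteria.solve_two_sigma(template, noise)
        if t is None:
            raise CriterionError("2-sigma criterion unsolvable for this template/noise")
        return t
    raise CriterionError(f"unknown criterion {criterion!r}")
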