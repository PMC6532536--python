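"""Reduction of raw repetition data to level-response curves.

Trace data (evoked potentials): trials are averaged per intensity, the RMS
over the analysis window is the response, and the noise floor sigma is the
RMS of the averaged no-stimulus block — quadrature composition downstream.

Spike data: responses are mean evoked rates in the analysis window and
sigma is the spontaneous rate — additive composition downstream.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from typing import Dict, List, Optional, Sequence, Tuple, Union

import numpy as np

from .exceptions import DataFormatError, MissingNoiseDataError
from .models import ADDITIVE, QUADRATURE, LevelResponseCurve, NoiseModel
from .simulate import TrialBlock

logger = logging.getLogger("kneefit")


@dataclass
class SpikeRaster:
    """Spike events over (intensity, trial, time).

    events are three parallel arrays; rows with NaN intensity are treated
    as no-stimulus trials.  ``analysis_window`` delimits the evoked-rate
    count, ``spontaneous_window`` (if any) the spontaneous-rate count used
    as the noise floor sigma.
    Windows are half-open [start, end) in ms.
    """

    intensity: np.ndarray
    trial: np.ndarray
    time_ms: np.ndarray
    n_trials: int
    analysis_window: Tuple[float, float] = (0.0, 200.0)
    spontaneous_window: Optional[Tuple[float, float]] = None

    def __post_init__(self) -> None:
        self.intensity = np.asarray(self.intensity, dtype=float).ravel()
        self.trial = np.asarray(self.trial, dtype=int).ravel()
        self.time_ms = np.asarray(self.time_ms, dtype=float).ravel()
        if not (self.intensity.size == self.trial.size == self.time_ms.size):
            raise DataFormatError("raster event arrays must have equal length")
        if self.n_trials < 1:
            raise DataFormatError("n_trials must be >= 1")
        if self.trial.size and (self.trial.min() < 0 or self.trial.max() >= self.n_trials):
            raise DataFormatError("trial indices must lie in [0, n_trials)")

    @property
    def stimulus_intensities(self) -> np.ndarray:
        vals = self.intensity[np.isfinite(self.intensity)]
        return np.unique(vals)

    def _window_mask(self, window: Tuple[float, float]) -> np.ndarray:
        start, end = window
        return (self.time_ms >= start) & (self.time_ms < end)

    def evoked_rates(
        self, trial_subset: Optional[Sequence[int]] = None
    ) -> Tuple[np.ndarray, np.ndarray]:
        """Mean evoked rate (spikes/s) per stimulus intensity."""
        subset = np.arange(self.n_trials) if trial_subset is None else np.asarray(trial_subset)
        if subset.size == 0:
            raise DataFormatError("empty trial subset")
        start, end = self.analysis_window
        dur_s = (end - start) / 1000.0
        in_win = self._window_mask(self.analysis_window)
        in_subset = np.isin(self.trial, subset)
        xs = self.stimulus_intensities
        rates = np.empty(xs.size)
        for i, x in enumerate(xs):
            n_spikes = np.count_nonzero(in_win & in_subset & (self.intensity == x))
            rates[i] = n_spikes / (subset.size * dur_s)
        return xs, rates

    def spontaneous_rate(self, trial_subset: Optional[Sequence[int]] = None) -> float:
        """Mean spontaneous rate (spikes/s): the noise floor for spike data.

        Uses no-stimulus events (NaN intensity) if present, otherwise the
        spontaneous window across all stimulus conditions.
        """
        subset = np.arange(self.n_trials) if trial_subset is None else np.asarray(trial_subset)
        in_subset = np.isin(self.trial, subset)
        no_stim = ~np.isfinite(self.intensity)
        if np.any(no_stim):
            start, end = self.analysis_window
            n = np.count_nonzero(no_stim & in_subset & self._window_mask(self.analysis_window))
            return n / (subset.size * (end - start) / 1000.0)
        if self.spontaneous_window is None:
            raise MissingNoiseDataError(
                "no spontaneous window and no no-stimulus trials: sigma cannot be "
                "estimated, and it is never fitted — record spontaneous activity"
            )
        start, end = self.spontaneous_window
        n_conditions = self.stimulus_intensities.size
        if n_conditions == 0:
            raise DataFormatError("raster contains no stimulus conditions")
        n = np.count_nonzero(in_subset & self._window_mask(self.spontaneous_window))
        return n / (n_conditions * subset.size * (end - start) / 1000.0)


def window_slice(window: Tuple[float, float], sampling_rate: float, n_samples: int) -> slice:
    """Half-open [start, end) ms window -> sample slice.

    Converted by floor(start*rate) .. floor(end*rate), matching the
    convention that a [0, 10) ms window at 20 kHz covers samples 0..199.
    """
    start, end = window
    i0 = int(np.floor(start / 1000.0 * sampling_rate))
    i1 = int(np.floor(end / 1000.0 * sampling_rate))
    if not (0 <= i0 < i1 <= n_samples):
        raise DataFormatError(
            f"window {window} ms maps to empty or out-of-range samples [{i0}, {i1}) "
            f"of {n_samples}"
        )
    return slice(i0, i1)


def average_trials(
    block: TrialBlock, trial_subset: Optional[Sequence[int]] = None
) -> np.ndarray:
    """Pointwise mean trace across the selected trials."""
    if trial_subset is None:
        return block.traces.mean(axis=0)
    idx = np.asarray(trial_subset, dtype=int)
    if idx.size == 0:
        raise DataFormatError("empty trial subset")
    if idx.min() < 0 or idx.max() >= block.n_trials:
        raise DataFormatError("trial subset indices out of range")
    return block.traces[idx].mean(axis=0)


def rms_window(
    trace: np.ndarray, sampling_rate: float, window: Tuple[float, float]
) -> float:
    """RMS amplitude of the trace inside the half-open window (ms)."""
    trace = np.asarray(trace, dtype=float)
    sl = window_slice(window, sampling_rate, trace.size)
    seg = trace[sl]
    return float(np.sqrt(np.mean(seg * seg)))


def correct_double_trial(trace_a: np.ndarray, trace_b: np.ndarray) -> np.ndarray:
    """Average responses to the two phase-inverted stimuli of a double trial.

    Any component that inverts with the stimulus phase (speaker artifact)
    cancels exactly; the phase-insensitive neural response survives.
    """
    a = np.asarray(trace_a, dtype=float)
    b = np.asarray(trace_b, dtype=float)
    if a.shape != b.shape:
        raise DataFormatError(f"trace shapes differ: {a.shape} vs {b.shape}")
    return 0.5 * (a + b)


SIGMA_SINGLE_TRIAL = "single_trial"
SIGMA_AVERAGED = "averaged"


def estimate_sigma(
    no_stim: Union[TrialBlock, SpikeRaster, None],
    n_average: Optional[int] = None,
    trial_subset: Optional[Sequence[int]] = None,
    method: str = SIGMA_SINGLE_TRIAL,
) -> float:
    """Effective noise floor sigma from no-stimulus data; never fitted.

    Trace data, ``method="single_trial"`` (default): the standard deviation
    of the single-trial no-stimulus samples inside the analysis window,
    divided by sqrt(n_average) — averaging N independent trials shrinks
    white noise by exactly that factor, and pooling every single-trial
    sample makes this the far more precise estimator.
    ``method="averaged"``: RMS (over the window) of the across-trial
    average of the selected trials — the direct empirical route; same
    expectation, noisier.
    Spike data: mean spontaneous rate (no sqrt(N) reduction: rates are
    trial-averaged means, not RMS of averaged noise).

    ``n_average`` is the number of trials that will be averaged downstream;
    it defaults to the number of selected trials.
    """
    if no_stim is None:
        raise MissingNoiseDataError(
            "no no-stimulus data supplied: the noise floor sigma must be measured "
            "from a recording without stimulation and held fixed (it is never fitted)"
        )
    if isinstance(no_stim, SpikeRaster):
        return no_stim.spontaneous_rate(trial_subset)
    if trial_subset is None and n_average is not None:
        if not 1 <= n_average <= no_stim.n_trials:
            raise DataFormatError(
                f"n_average={n_average} outside [1, {no_stim.n_trials}]"
            )
        trial_subset = np.arange(n_average)
    if trial_subset is not None:
        idx = np.asarray(trial_subset, dtype=int)
        if idx.size == 0:
            raise DataFormatError("empty trial subset")
        traces = no_stim.traces[idx]
    else:
        traces = no_stim.traces
    n_avg = n_average if n_average is not None else traces.shape[0]
    if method == SIGMA_AVERAGED:
        avg = traces.mean(axis=0)
        return rms_window(avg, no_stim.sampling_rate, no_stim.window)
    if method != SIGMA_SINGLE_TRIAL:
        raise DataFormatError(
            f"unknown sigma method {method!r}; expected "
            f"{SIGMA_SINGLE_TRIAL!r} or {SIGMA_AVERAGED!r}"
        )
    sl = window_slice(no_stim.window, no_stim.sampling_rate, traces.shape[1])
    return float(np.std(traces[:, sl]) / np.sqrt(n_avg))


def _combine_phase_pairs(blocks: List[TrialBlock]) -> List[Tuple[float, np.ndarray]]:
    """Average trials per block, applying double-trial correction to phase pairs.

    Returns (intensity, averaged trace) per stimulus intensity.
    """
    by_intensity: Dict[float, List[TrialBlock]] = {}
    for blk in blocks:
        by_intensity.setdefault(blk.intensity, []).append(blk)
    out = []
    for x, group in by_intensity.items():
        if len(group) == 1:
            out.append((x, average_trials(group[0])))
        elif len(group) == 2 and {g.phase for g in group} == {1, -1}:
            out.append((x, correct_double_trial(average_trials(group[0]),
                                                average_trials(group[1]))))
        else:
            raise DataFormatError(
                f"intensity {x} appears in {len(group)} blocks without a valid "
                "+1/-1 phase pairing"
            )
    return out


def reduce_to_curve(
    data: Union[List[TrialBlock], SpikeRaster],
    noise_mode: Optional[str] = None,
    trial_subsets: Optional[Dict[int, Sequence[int]]] = None,
    sigma: Optional[float] = None,
    sigma_method: str = SIGMA_SINGLE_TRIAL,
    meta: Optional[dict] = None,
) -> LevelResponseCurve:
    """Reduce raw repetition data to one (intensity, response) point each.

    ``trial_subsets`` maps positional block index (for trace data) or the
    key -1 / any index (for rasters, one subset for all conditions) to the
    trial indices to use — the hook the delete-d jackknife drives.  ``sigma``
    overrides the noise floor instead of estimating it from the no-stimulus
    data (used when subsample-wise re-estimation is switched off).
    """
    meta = dict(meta or {})
    if isinstance(data, SpikeRaster):
        subset = None
        if trial_subsets:
            subset = next(iter(trial_subsets.values()))
        xs, rates = data.evoked_rates(subset)
        if sigma is None:
            sigma = data.spontaneous_rate(subset)
        mode = noise_mode or ADDITIVE
        meta.setdefault("source", "spikes")
        meta.setdefault("units", "spikes/s")
        return LevelResponseCurve(xs, rates, NoiseModel(mode, sigma), meta)

    blocks = list(data)
    if not blocks:
        raise DataFormatError("no trial blocks supplied")
    rates = {b.sampling_rate for b in blocks}
    windows = {b.window for b in blocks}
    if len(rates) > 1 or len(windows) > 1:
        raise DataFormatError(
            f"inconsistent sampling rates {rates} or windows {windows} across blocks"
        )
    if trial_subsets:
        blocks = [
            TrialBlock(
                b.intensity,
                b.traces[np.asarray(trial_subsets[i], dtype=int)],
                b.sampling_rate, b.window, b.phase,
            ) if i in trial_subsets else b
            for i, b in enumerate(blocks)
        ]
    stim = [b for b in blocks if not b.is_no_stimulus]
    no_stim = [b for b in blocks if b.is_no_stimulus]
    if not stim:
        raise DataFormatError("no stimulus blocks supplied")
    if sigma is None:
        if not no_stim:
            raise MissingNoiseDataError(
                "dataset has no no-stimulus block: sigma must be measured, never fitted"
            )
        sigma = estimate_sigma(no_stim[0], method=sigma_method)
    pairs = _combine_phase_pairs(stim)
    sr = stim[0].sampling_rate
    win = stim[0].window
    xs = np.array([x for x, _ in pairs])
    ys = np.array([rms_window(trace, sr, win) for _, trace in pairs])
    mode = noise_mode or QUADRATURE
    meta.setdefault("source", "traces")
    return LevelResponseCurve(xs, ys, NoiseModel(mode, float(sigma)), meta)
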