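"""Delete-d jackknife subsampling of measurement repetitions.

From N recorded trials per intensity, N-d are repeatedly drawn without
replacement (independently per intensity and per subsample), the curve is
re-reduced — by default including re-estimation of the noise floor from the
equally subsampled no-stimulus trials, so the effective sigma matches the
averaging depth — re-fitted, and the criterion re-applied.  The resulting
empirical threshold distribution provides quantile-based uncertainty
summaries; the delete-d criterion sqrt(N) < d < N makes those quantiles
honest confidence surrogates.
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass, field
from typing import Callable, Dict, List, Optional, Sequence, Union

import numpy as np

from . import criteria as _criteria
from .exceptions import DataFormatError, KneefitError
from .fitting import HARD_SIGMOID, fit_level_response
from .models import LevelResponseCurve
from .signal import SpikeRaster, estimate_sigma, reduce_to_curve
from .simulate import TrialBlock

Dataset = Union[List[TrialBlock], SpikeRaster]


@dataclass(frozen=True)
class SubsampleSpec:
    """How many delete-d subsamples to draw and how large each is.

    subsample_size is N-d, the trials drawn per intensity without
    replacement.
    """

    subsample_size: int
    n_subsamples: int = 100
    seed: int = 0

    def __post_init__(self) -> None:
        if self.subsample_size < 1:
            raise DataFormatError("subsample_size must be >= 1")
        if self.n_subsamples < 1:
            raise DataFormatError("n_subsamples must be >= 1")


@dataclass
class ThresholdDistribution:
    """Per-subsample thresholds with quantile summaries.

    Undefined thresholds (non-converged fits, unsolvable criteria) are NaN
    in ``values`` and excluded from the summary; ``n_defined`` reports how
    many subsamples produced a threshold.
    """

    values: np.ndarray
    n_defined: int
    summary: Dict[str, float] = field(default_factory=dict)

    @classmethod
    def from_values(cls, values: Sequence[float]) -> "ThresholdDistribution":
        vals = np.asarray(values, dtype=float)
        defined = vals[np.isfinite(vals)]
        if defined.size:
            p5, q1, med, q3, p95 = np.percentile(defined, [5, 25, 50, 75, 95])
        else:
            p5 = q1 = med = q3 = p95 = float("nan")
        return cls(
            values=vals,
            n_defined=int(defined.size),
            summary={"p5": p5, "q1": q1, "median": med, "q3": q3, "p95": p95},
        )

    @property
    def median(self) -> float:
        return self.summary["median"]

    @property
    def iqr(self) -> float:
        return self.summary["q3"] - self.summary["q1"]

    def mad(self) -> float:
        """Median absolute deviation of the defined thresholds."""
        defined = self.values[np.isfinite(self.values)]
        if not defined.size:
            return float("nan")
        return float(np.median(np.abs(defined - np.median(defined))))


def _available_trials(data: Dataset) -> int:
    if isinstance(data, SpikeRaster):
        return data.n_trials
    return min(b.n_trials for b in data)


def _subset_rng(seed: int, subsample_index: int, block_index: int) -> np.random.Generator:
    return np.random.default_rng(
        np.random.SeedSequence(seed, spawn_key=(subsample_index, block_index))
    )


def draw_subsets(data: Dataset, spec: SubsampleSpec, subsample_index: int) -> Dict[int, np.ndarray]:
    """Trial-index subsets for one subsample, independent per intensity.

    Draws are seeded from (seed, subsample index, block index), so any
    subsample is reproducible in isolation.
    """
    if isinstance(data, SpikeRaster):
        rng = _subset_rng(spec.seed, subsample_index, 0)
        return {0: np.sort(rng.choice(data.n_trials, size=spec.subsample_size, replace=False))}
    return {
        j: np.sort(
            _subset_rng(spec.seed, subsample_index, j).choice(
                blk.n_trials, size=spec.subsample_size, replace=False
            )
        )
        for j, blk in enumerate(data)
    }


def _check_delete_d(spec: SubsampleSpec, n_available: int) -> None:
    if spec.subsample_size > n_available:
        raise DataFormatError(
            f"subsample_size={spec.subsample_size} exceeds available trials ({n_available})"
        )
    d = n_available - spec.subsample_size
    if d <= math.sqrt(n_available):
        warnings.warn(
            f"delete-d jackknife with d={d} <= sqrt(N)={math.sqrt(n_available):.1f}: "
            "quantile coverage may be optimistic (criterion sqrt(N) < d < N)",
            UserWarning,
            stacklevel=3,
        )


def subsample_thresholds(
    data: Dataset,
    spec: SubsampleSpec,
    model: str = HARD_SIGMOID,
    criterion: str = _criteria.KNEE,
    noise_mode: Optional[str] = None,
    p: float = 0.05,
    reestimate_sigma: bool = True,
    curve_transform: Optional[Callable[[LevelResponseCurve], LevelResponseCurve]] = None,
) -> ThresholdDistribution:
    """Empirical threshold distribution over delete-d subsamples.

    ``reestimate_sigma=False`` reuses the full-data noise floor for every
    subsample instead of re-estimating it from the subsampled no-stimulus
    trials.  ``curve_transform`` (e.g. supporting-point removal) is applied
    to each reduced curve before fitting.
    """
    n_available = _available_trials(data)
    _check_delete_d(spec, n_available)
    sigma_override = None
    if not reestimate_sigma:
        if isinstance(data, SpikeRaster):
            sigma_override = data.spontaneous_rate()
        else:
            no_stim = [b for b in data if b.is_no_stimulus]
            sigma_override = estimate_sigma(no_stim[0] if no_stim else None)
    values = []
    for i in range(spec.n_subsamples):
        subsets = draw_subsets(data, spec, i)
        values.append(
            _threshold_once(
                data, subsets, model, criterion, noise_mode, p,
                sigma_override, curve_transform,
            )
        )
    return ThresholdDistribution.from_values(values)


def _threshold_once(
    data, subsets, model, criterion, noise_mode, p, sigma_override, curve_transform
) -> float:
    curve = reduce_to_curve(
        data, noise_mode=noise_mode, trial_subsets=subsets, sigma=sigma_override
    )
    if curve_transform is not None:
        curve = curve_transform(curve)
    fit = fit_level_response(curve, model)
    if not fit.converged:
        return float("nan")
    try:
        est = _criteria.apply_criterion(fit, criterion, p=p)
    except KneefitError:
        raise
    return est.threshold if est.defined else float("nan")
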