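"""Validation protocols: sample-size sweeps and supporting-point removal.

The sample-size sweep reruns the delete-d subsampling at increasing
subsample sizes.  Under the 2-sigma criterion the median threshold
decreases without bound with averaging depth (the divergence pathology);
under the 5% and knee criteria the median is flat and only the spread
shrinks.

The point-removal sweep deletes reduced-curve supporting points from the
sub-threshold or saturation side before fitting, probing the robustness
claims: the knee of a hard-sigmoid fit barely moves, while the symmetric
logistic drifts when its saturation half is unsampled.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from typing import List, Optional, Sequence

import numpy as np

from . import criteria as _criteria
from .exceptions import DataFormatError
from .fitting import HARD_SIGMOID
from .models import LevelResponseCurve, ModelParams, evaluate_f0
from .resampling import (
    Dataset,
    SubsampleSpec,
    ThresholdDistribution,
    subsample_thresholds,
)

logger = logging.getLogger("kneefit")

MIN_FIT_POINTS = 4


@dataclass
class SweepResult:
    """Per-step threshold distributions along a sweep axis."""

    axis: np.ndarray
    distributions: List[ThresholdDistribution]
    config: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        self.axis = np.asarray(self.axis)
        if self.axis.size != len(self.distributions):
            raise DataFormatError("one distribution required per axis step")
        if self.axis.size > 1 and np.any(np.diff(self.axis.astype(float)) <= 0):
            raise DataFormatError("sweep axis must be strictly increasing")

    @property
    def medians(self) -> np.ndarray:
        return np.array([d.median for d in self.distributions])

    @property
    def iqrs(self) -> np.ndarray:
        return np.array([d.iqr for d in self.distributions])


def default_size_grid(n_trials: int, n_steps: int = 10, min_size: int = 10) -> List[int]:
    """Logarithmically spaced subsample sizes from min_size up to N."""
    if n_trials < min_size:
        raise DataFormatError(f"need at least {min_size} trials, got {n_trials}")
    sizes = np.unique(
        np.round(np.geomspace(min_size, n_trials, n_steps)).astype(int)
    )
    return [int(s) for s in sizes]


def sample_size_sweep(
    data: Dataset,
    sizes: Sequence[int],
    n_subsamples: int = 100,
    seed: int = 0,
    model: str = HARD_SIGMOID,
    criterion: str = _criteria.KNEE,
    noise_mode: Optional[str] = None,
    p: float = 0.05,
    reestimate_sigma: bool = True,
) -> SweepResult:
    """Threshold distributions as a function of subsample size N-d.

    Re-estimating sigma per subsample (default) lets the effective noise
    floor track the averaging depth, sigma0/sqrt(size) — the mechanism the
    2-sigma divergence feeds on.
    """
    sizes = list(sizes)
    dists = [
        subsample_thresholds(
            data,
            SubsampleSpec(subsample_size=size, n_subsamples=n_subsamples, seed=seed),
            model=model, criterion=criterion, noise_mode=noise_mode, p=p,
            reestimate_sigma=reestimate_sigma,
        )
        for size in sizes
    ]
    return SweepResult(
        axis=np.asarray(sizes),
        distributions=dists,
        config={
            "sweep": "sample_size", "model": model, "criterion": criterion,
            "noise_mode": noise_mode, "p": p, "n_subsamples": n_subsamples,
            "seed": seed, "reestimate_sigma": reestimate_sigma,
        },
    )


def point_removal_sweep(
    data: Dataset,
    side: str,
    max_removed: int,
    subsample_size: int,
    n_subsamples: int = 100,
    seed: int = 0,
    model: str = HARD_SIGMOID,
    criterion: str = _criteria.KNEE,
    noise_mode: Optional[str] = None,
    p: float = 0.05,
    reestimate_sigma: bool = True,
) -> SweepResult:
    """Threshold distributions as supporting points are removed.

    Step k removes the k lowest-intensity (side='subthreshold') or
    k highest-intensity (side='saturation') reduced-curve points before
    fitting.  The same seed is used at every step so each subsample's trial
    draw is identical across steps, isolating the removal effect.  The
    sweep truncates (with a logged notice) once fewer than 4 points remain.
    """
    if side not in ("subthreshold", "saturation"):
        raise DataFormatError("side must be 'subthreshold' or 'saturation'")
    if max_removed < 0:
        raise DataFormatError("max_removed must be >= 0")
    spec = SubsampleSpec(subsample_size=subsample_size, n_subsamples=n_subsamples, seed=seed)
    steps, dists = [], []
    for k in range(max_removed + 1):
        probe = _n_points(data) - k
        if probe < MIN_FIT_POINTS:
            logger.warning(
                "point-removal sweep truncated at k=%d: only %d points would remain "
                "(need >= %d)", k, probe, MIN_FIT_POINTS,
            )
            break
        transform = (lambda c, k=k: c.drop_points(k, side)) if k else None
        dists.append(
            subsample_thresholds(
                data, spec, model=model, criterion=criterion, noise_mode=noise_mode,
                p=p, reestimate_sigma=reestimate_sigma, curve_transform=transform,
            )
        )
        steps.append(k)
    return SweepResult(
        axis=np.asarray(steps),
        distributions=dists,
        config={
            "sweep": "point_removal", "side": side, "model": model,
            "criterion": criterion, "noise_mode": noise_mode, "p": p,
            "n_subsamples": n_subsamples, "seed": seed,
            "subsample_size": subsample_size, "reestimate_sigma": reestimate_sigma,
        },
    )


def _n_points(data) -> int:
    try:
        return len({b.intensity for b in data if not b.is_no_stimulus})
    except (TypeError, AttributeError):
        return int(data.stimulus_intensities.size)


def count_dynamic_range_points(
    template: ModelParams, intensities: Sequence[float],
    lo: float = 0.05, hi: float = 0.95,
) -> int:
    """Supporting points whose noise-free template response lies strictly
    between ``lo`` and ``hi`` of the template maximum.

    Operationalizes "the dynamic range" of a sampled curve; used to define
    how many saturation-side points amount to "half the dynamic range".
    """
    x = np.asarray(intensities, dtype=float)
    f0 = np.asarray(evaluate_f0(x, template))
    fmax = f0.max()
    return int(np.count_nonzero((f0 > lo * fmax) & (f0 < hi * fmax)))
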