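"""Optional matplotlib renderings of curves, fits and sweeps.

matplotlib is imported lazily; install the ``plots`` extra to use this
module.
"""

from __future__ import annotations

import numpy as np

from .fitting import FitResult
from .experiments import SweepResult
from .models import LevelResponseCurve


def _plt():
    import matplotlib.pyplot as plt

    return plt


def plot_curve_fit(curve: LevelResponseCurve, fit: FitResult, ax=None):
    """Level-response points, the composed fit, and the noise floor."""
    ax = ax or _plt().subplots()[1]
    ax.plot(curve.intensities, curve.responses, "o", label="data")
    xs = np.linspace(curve.intensities[0], curve.intensities[-1], 400)
    ax.plot(xs, fit.predict(xs), "-", label=f"{fit.model} fit")
    ax.axhline(curve.noise.sigma, ls="--", color="gray",
               label=f"noise floor {curve.noise.sigma:.2g}")
    ax.set_xlabel("stimulus intensity (dB)")
    ax.set_ylabel("response")
    ax.legend()
    return ax


def plot_sweep(sweep: SweepResult, ax=None):
    """Median with quartile band and 5-95% whiskers along the sweep axis."""
    ax = ax or _plt().subplots()[1]
    axis = sweep.axis.astype(float)
    med = sweep.medians
    q1 = np.array([d.summary["q1"] for d in sweep.distributions])
    q3 = np.array([d.summary["q3"] for d in sweep.distributions])
    p5 = np.array([d.summary["p5"] for d in sweep.distributions])
    p95 = np.array([d.summary["p95"] for d in sweep.distributions])
    ax.fill_between(axis, p5, p95, alpha=0.15, label="5-95%")
    ax.fill_between(axis, q1, q3, alpha=0.35, label="quartiles")
    ax.plot(axis, med, "r-", label="median")
    kind = sweep.config.get("sweep", "")
    ax.set_xlabel("subsample size (trials)" if kind == "sample_size"
                  else "points removed")
    ax.set_ylabel("threshold (dB)")
    ax.legend()
    return ax
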