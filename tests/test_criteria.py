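import math

import numpy as np
import pytest
from hypothesis import given
from hypothesis import strategies as st
from scipy.optimize import brentq

import kneefit as kf

LOG = kf.LogisticParams(a=10.0, b=60.0, c=11.89)
HS = kf.HardSigmoidParams(t=40.0, s=1.0, h=10.0)


def numeric_two_sigma(params, noise):
    """Independent oracle: numeric root of compose(f0(x)) = 2*sigma."""
    target = 2.0 * noise.sigma

    def fn(x):
        return kf.composed_model(x, params, noise) - target

    if isinstance(params, kf.LogisticParams):
        lo, hi = params.b - 80 * params.c, params.b + 80 * params.c
    else:
        lo, hi = params.t - 1.0, params.upper_knee
    if fn(lo) >= 0 or fn(hi) <= 0:
        return None
    return brentq(fn, lo, hi, xtol=1e-10)


def _fit_like(params, noise, converged=True, extrapolated=False):
    """Minimal FitResult carrier for criterion application."""
    model = kf.LOGISTIC if isinstance(params, kf.LogisticParams) else kf.HARD_SIGMOID
    return kf.FitResult(
        model=model, params=params, noise=noise, rss=0.0,
        converged=converged, extrapolated=extrapolated, n_points=22,
    )


class TestTwoSigma:
    def test_logistic_quadrature_closed_form(self):
        noise = kf.NoiseModel(kf.QUADRATURE, 2.828)
        est = kf.threshold_two_sigma(_fit_like(LOG, noise))
        assert est.defined
        assert est.threshold == pytest.approx(59.52, abs=0.01)

    def test_hard_sigmoid_quadrature_closed_form(self):
        noise = kf.NoiseModel(kf.QUADRATURE, 1.0)
        est = kf.threshold_two_sigma(_fit_like(HS, noise))
        assert est.threshold == pytest.approx(40.0 + math.sqrt(3.0), abs=1e-9)

    def test_unsolvable_at_boundary(self):
        # a = sqrt(3)*sigma: the composed curve never reaches 2*sigma
        noise = kf.NoiseModel(kf.QUADRATURE, LOG.a / math.sqrt(3.0))
        est = kf.threshold_two_sigma(_fit_like(LOG, noise))
        assert not est.defined and est.threshold is None

    def test_sigma_zero_is_an_error(self):
        with pytest.raises(kf.CriterionError):
            kf.threshold_two_sigma(_fit_like(LOG, kf.NoiseModel(kf.QUADRATURE, 0.0)))

    def test_requires_convergence(self):
        fit = _fit_like(LOG, kf.NoiseModel(kf.QUADRATURE, 1.0), converged=False)
        with pytest.raises(kf.CriterionError):
            kf.threshold_two_sigma(fit)


class TestPFraction:
    @pytest.mark.parametrize(
        "params, p, expected",
        [
            (LOG, 0.05, 24.99),                         # b - c*ln(19)
            (LOG, 0.5, 60.0),                           # the inflection point
            (kf.HardSigmoidParams(40.0, 0.25, 10.0), 0.05, 42.0),  # t + p*h/s
        ],
    )
    def test_closed_forms(self, params, p, expected):
        est = kf.threshold_p_fraction(_fit_like(params, kf.NoiseModel(kf.ADDITIVE, 0.0)), p=p)
        assert est.threshold == pytest.approx(expected, abs=0.01)

    @pytest.mark.parametrize("p", [0.0, 1.0, -0.2, 1.5])
    def test_p_outside_unit_interval_rejected(self, p):
        with pytest.raises(kf.CriterionError):
            kf.threshold_p_fraction(_fit_like(LOG, kf.NoiseModel(kf.ADDITIVE, 0.0)), p=p)

    def test_noise_independent(self):
        """p-fraction is defined on the noise-free f0: sigma plays no role."""
        for sigma in (0.0, 2.0, 40.0):
            est = kf.threshold_p_fraction(
                _fit_like(LOG, kf.NoiseModel(kf.QUADRATURE, sigma)), p=0.05
            )
            assert est.threshold == pytest.approx(24.9906, abs=1e-3)


class TestKnee:
    def test_reads_fitted_knee(self):
        fit = _fit_like(kf.HardSigmoidParams(40.0, 0.25, 10.0), kf.NoiseModel(kf.QUADRATURE, 3.0))
        est = kf.threshold_knee(fit)
        assert est.defined and est.threshold == 40.0

    def test_logistic_fit_rejected(self):
        with pytest.raises(kf.CriterionError):
            kf.threshold_knee(_fit_like(LOG, kf.NoiseModel(kf.QUADRATURE, 1.0)))

    def test_extrapolated_flag_propagates(self):
        fit = _fit_like(
            kf.HardSigmoidParams(-45.0, 0.25, 10.0),
            kf.NoiseModel(kf.QUADRATURE, 3.0),
            extrapolated=True,
        )
        est = kf.threshold_knee(fit)
        assert est.threshold == -45.0 and est.extrapolated


@given(
    a=st.floats(0.5, 100.0), b=st.floats(-50.0, 120.0), c=st.floats(0.5, 40.0),
    sigma=st.floats(0.01, 30.0), mode=st.sampled_from(kf.NOISE_MODES),
)
def test_two_sigma_closed_form_matches_numeric_root_logistic(a, b, c, sigma, mode):
    params = kf.LogisticParams(a, b, c)
    noise = kf.NoiseModel(mode, sigma)
    closed = kf.solve_two_sigma(params, noise)
    numeric = numeric_two_sigma(params, noise)
    if closed is None:
        assert numeric is None
    else:
        assert numeric is not None and closed == pytest.approx(numeric, abs=1e-6)


@given(
    t=st.floats(-50.0, 120.0), s=st.floats(0.01, 10.0), h=st.floats(0.5, 100.0),
    sigma=st.floats(0.01, 30.0), mode=st.sampled_from(kf.NOISE_MODES),
)
def test_two_sigma_closed_form_matches_numeric_root_hard_sigmoid(t, s, h, sigma, mode):
    params = kf.HardSigmoidParams(t, s, h)
    noise = kf.NoiseModel(mode, sigma)
    closed = kf.solve_two_sigma(params, noise)
    numeric = numeric_two_sigma(params, noise)
    if closed is None or numeric is None:
        # boundary solutions (root exactly at the upper knee) may be lost by
        # the open numeric bracket; closed-form None must imply numeric None
        assert closed is not None or numeric is None
    else:
        assert closed == pytest.approx(numeric, abs=1e-6)


def test_two_sigma_divergence_in_sample_size():
    """The 2-sigma threshold decreases without bound with averaging depth,
    by -c*ln(2) per quadrupling of N in the large-N limit."""
    ns = np.array([1e4, 4e4, 1.6e5, 6.4e5, 2.56e6, 1.024e7, 4.096e7])
    ts = np.array([kf.two_sigma_vs_sample_size(LOG, 40.0, n) for n in ns])
    assert np.all(np.diff(ts) < 0)
    shifts = np.diff(ts)  # consecutive entries are one quadrupling apart
    limit = -LOG.c * math.log(2.0)
    assert shifts[-1] == pytest.approx(limit, abs=0.05)
    # convergence towards the limit is monotone from above in magnitude
    assert abs(shifts[-1] - limit) < abs(shifts[0] - limit)
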