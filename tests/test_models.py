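import math

import numpy as np
import pytest
from hypothesis import given
from hypothesis import strategies as st

import kneefit as kf

LOG = kf.LogisticParams(a=10.0, b=60.0, c=11.89)
HS = kf.HardSigmoidParams(t=40.0, s=0.25, h=10.0)

pos = st.floats(1e-3, 1e4)
db = st.floats(-200.0, 200.0)
scale = st.floats(1e-3, 1e3)


@pytest.mark.parametrize(
    "x, expected, tol",
    [
        (60.0, 5.0, 1e-12),          # inflection point gives a/2
        (24.99, 0.500, 1e-3),        # 5% of the maximum at b - c*ln(19)
        (1e6, 10.0, 1e-9),           # upper asymptote
    ],
)
def test_logistic_known_values(x, expected, tol):
    assert kf.logistic_f0(x, LOG) == pytest.approx(expected, abs=tol)


@pytest.mark.parametrize(
    "x, expected",
    [(30.0, 0.0), (40.0, 0.0), (60.0, 5.0), (80.0, 10.0), (90.0, 10.0)],
)
def test_hard_sigmoid_piecewise_values(x, expected):
    assert kf.hard_sigmoid_f0(x, HS) == expected


@pytest.mark.parametrize(
    "f0, mode, sigma, expected",
    [
        (0.0, kf.QUADRATURE, 40.0, 40.0),   # sub-threshold asymptote = noise floor
        (3.0, kf.QUADRATURE, 4.0, 5.0),     # 3-4-5 identity
        (7.0, kf.ADDITIVE, 2.0, 9.0),
    ],
)
def test_compose_response(f0, mode, sigma, expected):
    assert kf.compose_response(f0, kf.NoiseModel(mode, sigma)) == pytest.approx(expected)


@pytest.mark.parametrize(
    "factory",
    [
        lambda: kf.LogisticParams(a=-1.0, b=60.0, c=10.0),
        lambda: kf.LogisticParams(a=10.0, b=float("inf"), c=10.0),
        lambda: kf.LogisticParams(a=10.0, b=60.0, c=0.0),
        lambda: kf.HardSigmoidParams(t=40.0, s=0.0, h=10.0),
        lambda: kf.HardSigmoidParams(t=40.0, s=1.0, h=-2.0),
        lambda: kf.NoiseModel("quadrature", -1.0),
        lambda: kf.NoiseModel("multiplicative", 1.0),
    ],
)
def test_invalid_parameters_rejected(factory):
    with pytest.raises(kf.ParameterDomainError):
        factory()


def test_negative_f0_rejected_not_clamped():
    with pytest.raises(kf.ParameterDomainError):
        kf.compose_response(-0.1, kf.NoiseModel(kf.QUADRATURE, 1.0))


@given(a=pos, b=db, c=pos, sigma=st.floats(0.0, 1e3),
       mode=st.sampled_from(kf.NOISE_MODES))
def test_composed_logistic_is_nondecreasing(a, b, c, sigma, mode):
    p = kf.LogisticParams(a, b, c)
    x = np.linspace(b - 6 * c, b + 6 * c, 101)
    y = kf.composed_model(x, p, kf.NoiseModel(mode, sigma))
    assert np.all(np.diff(y) >= -1e-12 * max(a, sigma, 1.0))


@given(t=db, s=pos, h=pos, sigma=st.floats(0.0, 1e3),
       mode=st.sampled_from(kf.NOISE_MODES))
def test_composed_hard_sigmoid_is_nondecreasing(t, s, h, sigma, mode):
    p = kf.HardSigmoidParams(t, s, h)
    x = np.linspace(t - 10.0, t + h / s + 10.0, 101)
    y = kf.composed_model(x, p, kf.NoiseModel(mode, sigma))
    assert np.all(np.diff(y) >= -1e-9 * max(h, sigma, 1.0))


@given(a=pos, b=db, c=pos, sigma=st.floats(1e-3, 1e3))
def test_quadrature_floor(a, b, c, sigma):
    """With sigma > 0 the quadrature curve exceeds f0 everywhere and tends
    to sigma as f0 vanishes."""
    p = kf.LogisticParams(a, b, c)
    noise = kf.NoiseModel(kf.QUADRATURE, sigma)
    x = np.linspace(b - 8 * c, b + 8 * c, 51)
    f0 = kf.logistic_f0(x, p)
    y = kf.composed_model(x, p, noise)
    assert np.all(y > f0)
    assert kf.composed_model(b - 60 * c, p, noise) == pytest.approx(sigma, rel=1e-6)


@given(k=scale, a=pos, b=db, c=pos, sigma=st.floats(0.0, 1e3), x=db,
       mode=st.sampled_from(kf.NOISE_MODES))
def test_scale_equivariance_logistic(k, a, b, c, sigma, x, mode):
    """Scaling (a, sigma) by k scales the composed curve by k; b, c untouched."""
    base = kf.composed_model(x, kf.LogisticParams(a, b, c), kf.NoiseModel(mode, sigma))
    scaled = kf.composed_model(
        x, kf.LogisticParams(k * a, b, c), kf.NoiseModel(mode, k * sigma)
    )
    assert scaled == pytest.approx(k * base, rel=1e-9, abs=1e-12)


@given(k=scale, t=db, s=pos, h=pos, sigma=st.floats(0.0, 1e3), x=db,
       mode=st.sampled_from(kf.NOISE_MODES))
def test_scale_equivariance_hard_sigmoid(k, t, s, h, sigma, x, mode):
    """Scaling (s, h, sigma) by k scales the composed curve by k; t untouched."""
    base = kf.composed_model(x, kf.HardSigmoidParams(t, s, h), kf.NoiseModel(mode, sigma))
    scaled = kf.composed_model(
        x, kf.HardSigmoidParams(t, k * s, k * h), kf.NoiseModel(mode, k * sigma)
    )
    assert scaled == pytest.approx(k * base, rel=1e-9, abs=1e-12)


class TestLevelResponseCurve:
    def test_sorts_and_averages_duplicates(self):
        curve = kf.LevelResponseCurve(
            [70.0, 60.0, 60.0], [1.0, 4.0, 6.0], kf.NoiseModel(kf.QUADRATURE, 1.0)
        )
        assert curve.intensities.tolist() == [60.0, 70.0]
        assert curve.responses.tolist() == [5.0, 1.0]

    def test_length_mismatch_rejected(self):
        with pytest.raises(kf.DataFormatError):
            kf.LevelResponseCurve([1.0, 2.0], [1.0], kf.NoiseModel(kf.ADDITIVE, 0.0))

    def test_drop_points_sides(self):
        curve = kf.LevelResponseCurve(
            np.arange(5.0), np.arange(5.0), kf.NoiseModel(kf.ADDITIVE, 0.0)
        )
        assert curve.drop_points(2, "subthreshold").intensities.tolist() == [2.0, 3.0, 4.0]
        assert curve.drop_points(2, "saturation").intensities.tolist() == [0.0, 1.0, 2.0]
        with pytest.raises(kf.DataFormatError):
            curve.drop_points(5, "saturation")
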