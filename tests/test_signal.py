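import math

import numpy as np
import pytest

import kneefit as kf
from kneefit.signal import SIGMA_AVERAGED, window_slice


def _block(traces, rate=1000.0, window=(0.0, None), intensity=50.0, phase=0):
    traces = np.asarray(traces, dtype=float)
    if window[1] is None:
        window = (window[0], traces.shape[1] / rate * 1000.0)
    return kf.TrialBlock(intensity=intensity, traces=traces, sampling_rate=rate,
                         window=window, phase=phase)


class TestAverageTrials:
    def test_mean_and_identity(self):
        block = _block([[1.0, 2.0, 3.0], [3.0, 2.0, 1.0]])
        np.testing.assert_array_equal(kf.average_trials(block), [2.0, 2.0, 2.0])
        np.testing.assert_array_equal(
            kf.average_trials(block, [1]), [3.0, 2.0, 1.0]
        )

    def test_empty_subset_rejected(self):
        with pytest.raises(kf.DataFormatError):
            kf.average_trials(_block([[1.0, 2.0]]), [])


class TestRmsWindow:
    def test_constant_and_zero(self):
        assert kf.rms_window(np.full(100, -3.0), 1000.0, (0.0, 100.0)) == 3.0
        assert kf.rms_window(np.zeros(100), 1000.0, (0.0, 100.0)) == 0.0

    def test_sine_rms_identity(self):
        """A sine of peak A over integer cycles has RMS A/sqrt(2)."""
        rate, freq, amp = 20000.0, 1000.0, 7.0
        t = np.arange(200) / rate  # exactly 10 cycles
        trace = amp * np.sin(2 * np.pi * freq * t)
        rms = kf.rms_window(trace, rate, (0.0, 10.0))
        assert rms == pytest.approx(amp / math.sqrt(2.0), rel=1e-12)

    def test_window_is_half_open(self):
        # [0, 2) ms at 1 kHz covers exactly samples 0 and 1
        trace = np.array([3.0, 3.0, 100.0])
        assert kf.rms_window(trace, 1000.0, (0.0, 2.0)) == 3.0

    def test_empty_window_rejected(self):
        with pytest.raises(kf.DataFormatError):
            window_slice((1.0, 1.0), 1000.0, 10)


class TestDoubleTrialCorrection:
    def test_artifact_cancels_exactly(self):
        rng = np.random.default_rng(0)
        response = rng.normal(size=50)
        artifact = rng.normal(size=50)
        out = kf.correct_double_trial(response + artifact, response - artifact)
        np.testing.assert_allclose(out, response, atol=1e-12)

    def test_idempotent_on_identical_pair(self):
        trace = np.arange(10.0)
        np.testing.assert_array_equal(kf.correct_double_trial(trace, trace), trace)

    def test_pure_inverted_artifacts_vanish(self):
        art = np.sin(np.arange(30.0))
        np.testing.assert_allclose(kf.correct_double_trial(art, -art), 0.0, atol=1e-15)

    def test_length_mismatch_rejected(self):
        with pytest.raises(kf.DataFormatError):
            kf.correct_double_trial(np.zeros(3), np.zeros(4))


class TestEstimateSigma:
    def test_all_zero_block(self):
        block = _block(np.zeros((4, 100)), intensity=None)
        assert kf.estimate_sigma(block) == 0.0

    def test_missing_data_error_mentions_fixed_sigma(self):
        with pytest.raises(kf.MissingNoiseDataError, match="never fitted"):
            kf.estimate_sigma(None)

    def test_gaussian_block_matches_sqrt_n_scaling(self):
        rng = np.random.default_rng(3)
        block = _block(rng.normal(0.0, 40.0, size=(200, 200)),
                       rate=20000.0, intensity=None)
        expected = 40.0 / math.sqrt(200.0)
        assert kf.estimate_sigma(block) == pytest.approx(expected, rel=0.05)
        assert kf.estimate_sigma(block, method=SIGMA_AVERAGED) == pytest.approx(
            expected, rel=0.15
        )

    def test_estimator_routes_agree_in_expectation(self):
        """Pooled single-trial std / sqrt(N) and RMS-of-average estimate the
        same floor; over many realizations their means coincide."""
        rng = np.random.default_rng(5)
        single, averaged = [], []
        for _ in range(40):
            block = _block(rng.normal(0.0, 10.0, size=(50, 100)), intensity=None)
            single.append(kf.estimate_sigma(block))
            averaged.append(kf.estimate_sigma(block, method=SIGMA_AVERAGED))
        expected = 10.0 / math.sqrt(50.0)
        assert np.mean(single) == pytest.approx(expected, rel=0.02)
        assert np.mean(averaged) == pytest.approx(expected, rel=0.05)

    def test_spike_raster_spontaneous_rate(self):
        # 50 spikes in a 0.5 s spontaneous window over 10 trials x 1 condition
        raster = kf.SpikeRaster(
            intensity=np.full(50, 60.0),
            trial=np.arange(50) % 10,
            time_ms=np.linspace(-499.0, -1.0, 50),
            n_trials=10,
            analysis_window=(0.0, 200.0),
            spontaneous_window=(-500.0, 0.0),
        )
        assert kf.estimate_sigma(raster) == pytest.approx(10.0)

    def test_raster_without_spontaneous_data_rejected(self):
        raster = kf.SpikeRaster(
            intensity=np.array([60.0]), trial=np.array([0]), time_ms=np.array([5.0]),
            n_trials=4,
        )
        with pytest.raises(kf.MissingNoiseDataError):
            kf.estimate_sigma(raster)


class TestReduceToCurve:
    def test_noise_free_dataset_recovers_template(self):
        cfg = kf.hard_sigmoid_surrogate_config(sigma0=0.0, n_trials=2)
        curve = kf.reduce_to_curve(kf.simulate_dataset(cfg))
        expected = kf.hard_sigmoid_f0(curve.intensities, cfg.template)
        np.testing.assert_allclose(curve.responses, expected, atol=1e-9)
        assert curve.noise.mode == kf.QUADRATURE  # trace default
        assert curve.noise.sigma == 0.0

    def test_missing_no_stimulus_block_rejected(self, small_dataset):
        with pytest.raises(kf.MissingNoiseDataError, match="never fitted"):
            kf.reduce_to_curve(small_dataset[:-1])

    def test_inconsistent_sampling_rates_rejected(self):
        b1 = _block(np.zeros((2, 100)), rate=1000.0)
        b2 = _block(np.zeros((2, 100)), rate=2000.0, window=(0.0, 50.0), intensity=60.0)
        with pytest.raises(kf.DataFormatError):
            kf.reduce_to_curve([b1, b2])

    def test_phase_pairs_are_artifact_corrected(self):
        rng = np.random.default_rng(1)
        resp = np.abs(rng.normal(size=100)) + 1.0
        art = rng.normal(size=100) * 5.0
        bp = _block((resp + art)[None, :], phase=1)
        bm = _block((resp - art)[None, :], phase=-1)
        ns = _block(np.zeros((2, 100)), intensity=None)
        curve = kf.reduce_to_curve([bp, bm, ns])
        expected = math.sqrt(np.mean(resp**2))
        assert curve.responses[0] == pytest.approx(expected, rel=1e-12)

    def test_flat_raster_gives_flat_curve_additive(self):
        # one spike per (intensity, trial) inside a 1 s analysis window
        xs = np.repeat([40.0, 60.0, 80.0], 5)
        raster = kf.SpikeRaster(
            intensity=xs, trial=np.tile(np.arange(5), 3),
            time_ms=np.full(15, 100.0), n_trials=5,
            analysis_window=(0.0, 1000.0), spontaneous_window=(-1000.0, 0.0),
        )
        curve = kf.reduce_to_curve(raster)
        np.testing.assert_allclose(curve.responses, 1.0)
        assert curve.noise.mode == kf.ADDITIVE  # spike default
        assert curve.noise.sigma == 0.0

    def test_commutes_with_trial_subsetting(self, small_dataset):
        """Reducing a pre-subsetted dataset equals reducing with subsets —
        the contract the jackknife relies on."""
        subset = np.array([0, 3, 7, 9, 12])
        via_arg = kf.reduce_to_curve(
            small_dataset, trial_subsets={i: subset for i in range(len(small_dataset))}
        )
        pre = [
            kf.TrialBlock(b.intensity, b.traces[subset], b.sampling_rate, b.window, b.phase)
            for b in small_dataset
        ]
        via_pre = kf.reduce_to_curve(pre)
        np.testing.assert_array_equal(via_arg.responses, via_pre.responses)
        assert via_arg.noise.sigma == via_pre.noise.sigma
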