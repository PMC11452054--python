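"""Preprocessing chain: resampling, offset correction, band-pass behavior,
epoch segmentation/zeroing, outlier rule, normalization, pipeline order."""

import dataclasses
import warnings

import numpy as np
import pytest

from gaitvae.core import EPOCH_SAMPLES, Epoch, GaitEvents, ImuRecording
from gaitvae.preprocessing import (bandpass, correct_gyro_offset, denormalize,
                                   estimate_gyro_offset, filter_epoch,
                                   flag_outliers, normalize,
                                   preprocess_recording, resample_to_100hz,
                                   segment_epochs, zero_start)
from gaitvae.synthetic import simulate_walk
from tests.conftest import REFERENCE_PARAMS


def make_recording(acc, gyr, fs=104.0, **kw):
    n = len(acc)
    return ImuRecording(time=np.arange(n) / fs, acc=np.asarray(acc, float),
                        gyr=np.asarray(gyr, float), fs=fs, **kw)


def make_epoch(data, **kw):
    defaults = dict(start_index=0, foot="right", measurement_id="m0")
    defaults.update(kw)
    return Epoch(data=np.asarray(data, float), **defaults)


class TestResample:
    def test_sample_count_120s(self):
        n = 12480  # 120 s at 104 Hz
        rec = make_recording(np.zeros((n, 3)), np.zeros((n, 3)))
        out = resample_to_100hz(rec)
        assert len(out) == 12000
        assert out.fs == 100.0

    def test_constant_signal_exact(self):
        rec = make_recording(np.full((1040, 3), 0.7), np.full((1040, 3), -3.0))
        out = resample_to_100hz(rec)
        np.testing.assert_allclose(out.acc, 0.7, atol=1e-12)
        np.testing.assert_allclose(out.gyr, -3.0, atol=1e-12)

    def test_2hz_sinusoid_amplitude_preserved(self):
        t = np.arange(1040) / 104.0
        s = np.sin(2 * np.pi * 2.0 * t)
        rec = make_recording(np.column_stack([s, s, s]), np.zeros((1040, 3)))
        out = resample_to_100hz(rec)
        expected = np.sin(2 * np.pi * 2.0 * out.time)
        assert np.max(np.abs(out.acc[:, 0] - expected)) < 0.01

    def test_low_fs_rejected(self):
        rec = make_recording(np.zeros((200, 3)), np.zeros((200, 3)), fs=50.0)
        with pytest.raises(ValueError):
            resample_to_100hz(rec)


class TestGyroOffset:
    def test_zero_offset_is_identity(self):
        rec = make_recording(np.zeros((300, 3)), np.random.default_rng(0).normal(size=(300, 3)))
        out = correct_gyro_offset(rec, (0.0, 0.0, 0.0))
        np.testing.assert_array_equal(out.gyr, rec.gyr)

    def test_injected_offset_removed_in_stance(self):
        offset = (0.5, -0.8, 1.2)
        p = dataclasses.replace(REFERENCE_PARAMS, gyro_offset=offset)
        _, right, truth = simulate_walk(p, 30.0, 104.0, seed=2)
        corrected = correct_gyro_offset(right, offset)
        s, e = truth.true_stance_intervals["right"][3]
        stance_mean = corrected.gyr[s:e].mean(axis=0)
        assert np.all(np.abs(stance_mean) < 3 * p.noise_gyro_sd / np.sqrt(e - s) + 0.05)

    def test_static_estimation_recovers_offset(self):
        rng = np.random.default_rng(1)
        offset = np.array([1.0, -2.0, 0.5])
        gyr = offset + rng.normal(0, 0.5, (1248, 3))  # 12 s static at 104 Hz
        rec = make_recording(np.zeros((1248, 3)), gyr)
        est = estimate_gyro_offset(rec, static_end_s=10.0)
        # SE = 0.5/sqrt(1040) ~= 0.016 deg/s, so 0.05 is a ~3-sigma margin
        assert np.all(np.abs(est - offset) < 0.05)


class TestBandpass:
    def test_dc_rejected(self):
        # the 0.01-Hz low edge implies a ~16-s transient; check well past it
        x = np.full((20000, 1), 2.0)
        y = bandpass(x, fs=100.0)
        assert np.abs(y[-500:]).max() < 0.01 * np.abs(y).max()

    def test_1hz_passband_gain(self):
        t = np.arange(6000) / 100.0
        y = bandpass(np.sin(2 * np.pi * 1.0 * t)[:, None], fs=100.0)
        gain = np.abs(y[3000:]).max()
        assert 0.9 <= gain <= 1.0

    def test_40hz_attenuated(self):
        t = np.arange(6000) / 100.0
        y = bandpass(np.sin(2 * np.pi * 40.0 * t)[:, None], fs=100.0)
        assert np.abs(y[3000:]).max() < 0.3


class TestSegmentation:
    def test_overlap_arithmetic_with_stance_everywhere(self):
        n = 12000
        rec = make_recording(np.zeros((n, 3)), np.zeros((n, 3)), fs=100.0,
                             measurement_id="m")
        # degenerate events: one wall-to-wall stance, strides spanning the signal
        events = GaitEvents(foot_contacts=np.array([-1, 0, 4000, 8000, n - 1]),
                            stance_intervals=np.array([[0, n]]),
                            swing_intervals=np.empty((0, 2)), n_samples=n)
        epochs = segment_epochs(rec, events)
        starts = [e.start_index for e in epochs]
        assert starts == list(range(0, n - 1 - EPOCH_SAMPLES + 1, 256))
        assert len(epochs) == 45

    def test_reference_walk_epoch_count(self):
        p = dataclasses.replace(REFERENCE_PARAMS, stride_time=1.1)
        _, right, _ = simulate_walk(p, 120.0, 104.0, seed=6)
        epochs, events, _ = preprocess_recording(right)
        assert 40 <= len(epochs) <= 46  # ~43 epochs per two-minute measurement
        stance = events.stance_mask(12000)
        assert all(stance[e.start_index] for e in epochs)

    def test_too_short_recording_yields_nothing(self):
        rec = make_recording(np.zeros((400, 3)), np.zeros((400, 3)), fs=100.0)
        events = GaitEvents(foot_contacts=np.array([10, 110, 210, 310, 390]),
                            stance_intervals=np.array([[10, 60], [110, 160],
                                                       [210, 260], [310, 360]]),
                            swing_intervals=np.array([[60, 110], [160, 210],
                                                      [260, 310]]), n_samples=400)
        assert segment_epochs(rec, events) == []

    def test_fewer_than_four_strides_warns_empty(self):
        rec = make_recording(np.zeros((2000, 3)), np.zeros((2000, 3)), fs=100.0)
        events = GaitEvents(foot_contacts=np.array([0, 600, 1200]),
                            stance_intervals=np.array([[0, 300], [600, 900]]),
                            swing_intervals=np.array([[300, 600]]), n_samples=2000)
        with pytest.warns(UserWarning):
            assert segment_epochs(rec, events) == []


class TestZeroStartAndNormalize:
    def test_zero_start_properties(self):
        rng = np.random.default_rng(0)
        e = make_epoch(rng.normal(size=(512, 6)) + 5.0)
        z = zero_start(e)
        np.testing.assert_array_equal(z.data[0], np.zeros(6))
        np.testing.assert_allclose(zero_start(z).data, z.data)  # idempotent
        const = make_epoch(np.tile(np.arange(6.0), (512, 1)))
        np.testing.assert_array_equal(zero_start(const).data, np.zeros((512, 6)))

    def test_normalize_endpoints_and_roundtrip(self):
        data = np.zeros((512, 6))
        data[0] = [8.0, -4.0, 8.0, 500.0, 0.0, -500.0]
        n = normalize(make_epoch(data))
        np.testing.assert_allclose(n.data[0], [1.0, -0.5, 1.0, 1.0, 0.0, -1.0])
        assert n.normalized
        rng = np.random.default_rng(3)
        raw = rng.uniform(-1, 1, (512, 6)) * [8, 8, 8, 500, 500, 500]
        round_trip = denormalize(normalize(make_epoch(raw)).data)
        np.testing.assert_allclose(round_trip, raw, atol=1e-12)


class TestOutliers:
    def _epochs_from(self, rng, n, shift_one=False):
        epochs = [make_epoch(rng.normal(0, 1, (512, 6))) for _ in range(n)]
        if shift_one:
            data = epochs[-1].data.copy()
            # dataset SD of per-epoch means is ~1/sqrt(512); shift by 10 of those
            data[:, 2] += 10.0 / np.sqrt(512)
            epochs[-1] = make_epoch(data)
        return epochs

    def test_stationary_process_rarely_removed(self):
        epochs = self._epochs_from(np.random.default_rng(4), 200)
        kept, removed, _ = flag_outliers(epochs)
        assert len(removed) <= 1

    def test_constructed_outlier_removed(self):
        epochs = self._epochs_from(np.random.default_rng(5), 200, shift_one=True)
        kept, removed, stats = flag_outliers(epochs)
        assert len(removed) == 1
        assert removed[0] is epochs[-1]
        assert stats[-1].outlier

    def test_identical_epochs_zero_variance_kept(self):
        e = make_epoch(np.ones((512, 6)))
        kept, removed, stats = flag_outliers([e, make_epoch(np.ones((512, 6)))])
        assert removed == []
        assert not stats[0].outlier


def test_pipeline_order_and_outputs(reference_walk):
    """Regression-pins the stage order: the epochs coming out of the
    per-recording chain are 100 Hz cuts that start in stance, are filtered
    and zeroed but not yet normalized."""
    _, right, _ = reference_walk
    epochs, events, rec100 = preprocess_recording(right)
    assert rec100.fs == 100.0
    assert len(epochs) > 30
    for e in epochs[:5]:
        assert e.data.shape == (512, 6)
        np.testing.assert_allclose(e.data[0], 0.0, atol=1e-12)  # zeroed start
        assert not e.normalized
    stance = events.stance_mask(len(rec100))
    assert all(stance[e.start_index] for e in epochs)


def test_outlier_fraction_on_nominal_cohort_below_2pct(trained_vae):
    assert trained_vae["n_removed"] / trained_vae["n_total"] < 0.02
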