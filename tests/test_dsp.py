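"""Preprocessing chain contracts: frequency response, linearity,
zero-phase behaviour, Nyquist clamping and envelope smoothing."""

from __future__ import annotations

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st
from scipy import signal as sps

import myogest as mg
from myogest import dsp


def _response_db(fs: float, spec: mg.FilterSpec, freq: float) -> float:
    """Magnitude (dB) of the designed filter at one frequency — the
    independent frequency-response oracle (doubled for zero-phase)."""
    sos = sps.butter(
        spec.order,
        [spec.low_cut, dsp.effective_highcut(spec, fs)],
        btype="bandpass",
        fs=fs,
        output="sos",
    )
    _, h = sps.sosfreqz(sos, worN=[freq], fs=fs)
    mag_db = 20 * np.log10(np.abs(h[0]))
    return 2 * mag_db if spec.zero_phase else mag_db


def _sine_gain_db(freq: float, fs: float, spec: mg.FilterSpec) -> float:
    t = np.arange(int(4 * fs)) / fs
    x = np.sin(2 * np.pi * freq * t)
    y = mg.bandpass(x, fs, spec)
    mid = slice(int(fs), int(3 * fs))  # discard edge transients
    return 20 * np.log10(np.sqrt((y[mid] ** 2).mean()) / np.sqrt((x[mid] ** 2).mean()))


class TestRemoveDc:
    def test_arithmetic(self):
        np.testing.assert_allclose(mg.remove_dc([1, 2, 3]), [-1, 0, 1])

    def test_constant_goes_to_zero(self):
        np.testing.assert_allclose(mg.remove_dc([5, 5, 5, 5]), np.zeros(4))

    def test_empty_rejected(self):
        with pytest.raises(ValueError):
            mg.remove_dc(np.array([]))

    @settings(derandomize=True, max_examples=50, deadline=None)
    @given(st.lists(st.floats(-1e6, 1e6), min_size=1, max_size=200))
    def test_output_sums_to_zero(self, xs):
        out = mg.remove_dc(np.array(xs))
        assert abs(out.sum()) <= 1e-6 * max(1.0, np.abs(xs).max())


class TestBandpass:
    def test_dc_rejected(self):
        fs = 1000.0
        x = np.full(4000, 7.0)
        y = mg.bandpass(x, fs)
        assert np.sqrt((y**2).mean()) < 1e-6 * 7.0

    def test_passband_50hz_within_1db(self):
        spec = mg.FilterSpec()
        assert abs(_sine_gain_db(50.0, 1000.0, spec)) < 1.0
        # measured gain agrees with the frequency-response oracle
        assert _sine_gain_db(50.0, 1000.0, spec) == pytest.approx(
            _response_db(1000.0, spec, 50.0), abs=0.2
        )

    def test_stopband_5hz_attenuated_20db(self):
        spec = mg.FilterSpec()
        assert _sine_gain_db(5.0, 1000.0, spec) <= -20.0
        assert _response_db(1000.0, spec, 5.0) <= -20.0

    def test_highcut_clamped_to_90hz_at_fs200(self, caplog):
        dsp._warned_clamps.clear()
        with caplog.at_level("WARNING", logger="myogest.dsp"):
            assert dsp.effective_highcut(mg.FilterSpec(), 200.0) == pytest.approx(90.0)
        assert any("clamping" in r.message for r in caplog.records)
        # no clamping (and no warning) when the band already fits
        caplog.clear()
        with caplog.at_level("WARNING", logger="myogest.dsp"):
            assert dsp.effective_highcut(mg.FilterSpec(high_cut=400.0), 1000.0) == 400.0
        assert not caplog.records

    def test_low_sampling_rate_invalid(self):
        with pytest.raises(ValueError, match="low_cut"):
            mg.bandpass(np.zeros(100), 30.0)

    def test_linearity(self):
        rng = np.random.default_rng(2)
        x = rng.standard_normal(1000)
        y = rng.standard_normal(1000)
        lhs = mg.bandpass(2.5 * x - 1.5 * y, 1000.0)
        rhs = 2.5 * mg.bandpass(x, 1000.0) - 1.5 * mg.bandpass(y, 1000.0)
        np.testing.assert_allclose(lhs, rhs, atol=1e-9)

    def test_zero_phase_no_group_delay(self):
        """A band-limited pulse comes out time-aligned (lag 0 +/- 1)."""
        fs = 1000.0
        n = 2000
        t = (np.arange(n) - n / 2) / fs
        x = np.exp(-(t**2) / (2 * 0.02**2)) * np.cos(2 * np.pi * 100 * t)
        y = mg.bandpass(x, fs)
        lags = sps.correlation_lags(n, n)
        lag = lags[np.argmax(sps.correlate(y, x))]
        assert abs(lag) <= 1


class TestRectify:
    def test_definition(self):
        np.testing.assert_allclose(mg.rectify([-3, 2, 0]), [3, 2, 0])

    def test_all_negative_negated(self):
        x = -np.arange(1.0, 5.0)
        np.testing.assert_allclose(mg.rectify(x), -x)

    @settings(derandomize=True, max_examples=50, deadline=None)
    @given(st.lists(st.floats(-1e9, 1e9), min_size=1, max_size=100))
    def test_idempotent_and_nonnegative(self, xs):
        once = mg.rectify(np.array(xs))
        assert np.all(once >= 0)
        np.testing.assert_array_equal(mg.rectify(once), once)


class TestEnvelope:
    def test_constant_passes(self):
        fs = 200.0
        out = mg.envelope(np.full(2000, 3.0), fs)
        np.testing.assert_allclose(out, 3.0, rtol=1e-6)

    def test_zero_in_zero_out(self):
        assert not mg.envelope(np.zeros(1000), 200.0).any()

    def test_cutoff_validated(self):
        with pytest.raises(ValueError):
            mg.envelope(np.zeros(100), 200.0, cutoff=150.0)
        with pytest.raises(ValueError):
            mg.envelope(np.zeros(100), 200.0, cutoff=0.0)

    def test_burst_envelope_tracks_activation(self):
        """0.5 s silence, 1 s unit-RMS noise burst, 0.5 s silence: the
        envelope peaks inside the burst and stays low at rest."""
        fs = 200.0
        rng = np.random.default_rng(8)
        x = np.zeros(int(2 * fs))
        x[int(0.5 * fs) : int(1.5 * fs)] = rng.standard_normal(int(fs))
        rect = mg.rectify(x)
        env = mg.envelope(rect, fs)
        peak_t = np.argmax(env) / fs
        assert 0.5 < peak_t < 1.5
        rest = np.concatenate([env[: int(0.3 * fs)], env[-int(0.3 * fs) :]])
        plateau = env[int(0.7 * fs) : int(1.3 * fs)].mean()
        assert rest.max() < 0.2 * plateau

    def test_envelope_smoother_than_rectified(self):
        rng = np.random.default_rng(10)
        rect = np.abs(rng.standard_normal(2000))
        env = mg.envelope(rect, 200.0)
        tv = lambda v: np.abs(np.diff(v)).sum()
        assert tv(env) <= tv(rect)
        assert np.all(env >= 0)


class TestPreprocess:
    def test_shapes_and_stages(self):
        rec = mg.generate_gesture_trial(mg.GestureLabel.CLOSE, mg.TrialSpec(seed=4))
        proc = mg.preprocess(rec)
        for stage in (proc.centered, proc.filtered, proc.rectified, proc.envelope):
            assert stage.shape == (800, 8)
        assert np.all(proc.rectified >= 0)
        assert np.all(proc.envelope >= 0)
        rms = np.sqrt((proc.centered**2).mean())
        assert np.abs(proc.centered.mean(axis=0)).max() < 1e-9 * rms
        assert proc.label is rec.label

    def test_all_zero_recording_gives_zero_envelope(self):
        rec = mg.EmgRecording(samples=np.zeros((400, 8), dtype=np.int16), fs=200.0)
        assert not mg.preprocess(rec).envelope.any()

    def test_dominant_channel_plateau_over_rest(self):
        """On a generated trial, the dominant channel's envelope plateau
        exceeds its rest level by at least a factor of 2."""
        spec = mg.TrialSpec(seed=21)
        for g, profile in mg.default_channel_profiles().items():
            rec = mg.generate_gesture_trial(g, spec, profile)
            env = mg.preprocess(rec).envelope[:, np.argmax(profile.gains)]
            fs = spec.fs
            rest = env[: int(0.9 * fs)].mean()
            plateau = env[int(1.5 * fs) : int(2.5 * fs)].mean()
            assert plateau >= 2 * rest
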