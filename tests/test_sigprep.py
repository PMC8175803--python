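"""Preprocessing chain: filters, resampling, ICA and alignment."""
import numpy as np
import pytest

from gaitcmi import sigprep, synth
from gaitcmi.types import MarkerTrajectories, MultiChannelRecording


def _rec(data, rate=500.0, labels=None, kinds=None):
    n_ch = data.shape[1]
    labels = labels or [f"ch{i}" for i in range(n_ch)]
    kinds = kinds or ["EEG"] * n_ch
    return MultiChannelRecording(data, rate, labels, kinds)


class TestRereference:
    def test_subtracts_mastoid_mean(self):
        n = 100
        data = np.column_stack([
            np.full(n, 10.0), np.full(n, 2.0), np.full(n, 4.0),
            np.full(n, 5.0),
        ])
        rec = _rec(data, labels=["Cz", "M1", "M2", "Rt. TA"],
                   kinds=["EEG", "REF", "REF", "EMG"])
        out = sigprep.rereference_mastoids(rec)
        assert np.allclose(out.channel("Cz"), 7.0)
        assert np.allclose(out.channel("Rt. TA"), 5.0)  # EMG untouched

    def test_zero_mastoids_leave_eeg_unchanged(self):
        rng = np.random.default_rng(0)
        data = np.column_stack([
            rng.normal(size=50), np.zeros(50), np.zeros(50)])
        rec = _rec(data, labels=["Cz", "M1", "M2"],
                   kinds=["EEG", "REF", "REF"])
        out = sigprep.rereference_mastoids(rec)
        assert np.allclose(out.channel("Cz"), rec.channel("Cz"))

    def test_missing_mastoid_named_in_error(self):
        rec = _rec(np.zeros((50, 2)), labels=["Cz", "M1"])
        with pytest.raises(ValueError, match="M2"):
            sigprep.rereference_mastoids(rec)


class TestFilterEeg:
    def test_subcutoff_sine_attenuated(self):
        rate = 500.0
        t = np.arange(int(rate * 60)) / rate
        x = np.sin(2 * np.pi * 0.05 * t)
        out = sigprep.filter_eeg(_rec(x[:, None], rate))
        assert np.sqrt((out.data ** 2).mean()) < 0.1 * np.sqrt(
            (x ** 2).mean())

    def test_passband_sine_preserved_zero_lag(self):
        rate = 500.0
        t = np.arange(int(rate * 20)) / rate
        x = np.sin(2 * np.pi * 10 * t)
        out = sigprep.filter_eeg(_rec(x[:, None], rate))
        y = out.data[:, 0]
        assert np.sqrt((y ** 2).mean()) == pytest.approx(
            np.sqrt((x ** 2).mean()), rel=0.05)
        xc = np.correlate(x, y, mode="full")
        assert abs(np.argmax(xc) - (len(x) - 1)) == 0

    def test_dc_removed(self):
        out = sigprep.filter_eeg(_rec(np.full((5000, 1), 3.0), 500.0))
        assert abs(out.data.mean()) < 1e-3

    def test_low_rate_rejected(self):
        with pytest.raises(ValueError, match="too low"):
            sigprep.filter_eeg(_rec(np.zeros((500, 1)), rate=90.0))


class TestResample:
    def test_doubles_sample_count(self):
        out = sigprep.resample_1khz(_rec(np.zeros((5000, 2)), 500.0))
        assert abs(out.n_samples - 10000) <= 1
        assert out.rate == 1000.0

    def test_sinusoid_preserved(self):
        rate = 500.0
        t = np.arange(int(rate * 4)) / rate
        x = np.sin(2 * np.pi * 20 * t)
        out = sigprep.resample_1khz(_rec(x[:, None], rate))
        t2 = np.arange(out.n_samples) / 1000.0
        ref = np.sin(2 * np.pi * 20 * t2)
        sl = slice(100, -100)  # edge effects excluded
        r = np.corrcoef(out.data[sl, 0], ref[sl])[0, 1]
        assert r > 0.999

    def test_idempotent_at_target_rate(self):
        rec = _rec(np.random.default_rng(0).normal(size=(1000, 1)), 1000.0)
        out = sigprep.resample_1khz(rec)
        assert np.array_equal(out.data, rec.data)


class TestRemoveEogIcs:
    def test_blink_session_frontal_correlation_halved(self, session):
        markers, rec, _ = session
        pre = sigprep.resample_1khz(
            sigprep.filter_eeg(sigprep.rereference_mastoids(rec)))
        out, report = sigprep.remove_eog_ics(pre, seed=0)
        assert len(report.removed_ics) >= 1
        veog = pre.channel("VEOG")
        for ch in ("Fp1", "Fp2", "FPz"):
            r_pre = abs(np.corrcoef(pre.channel(ch), veog)[0, 1])
            r_post = abs(np.corrcoef(out.channel(ch), veog)[0, 1])
            assert r_post <= 0.5 * r_pre

    def test_blink_free_session_removes_nothing(self):
        cfg = synth.SynthConfig(seed=21, duration_s=20, blink_rate_hz=0.0)
        _, rec, _ = synth.generate_session(cfg)
        pre = sigprep.resample_1khz(
            sigprep.filter_eeg(sigprep.rereference_mastoids(rec)))
        _, report = sigprep.remove_eog_ics(pre, seed=0)
        assert report.removed_ics == []

    def test_threshold_one_is_identity(self, session):
        _, rec, _ = session
        out, report = sigprep.remove_eog_ics(rec, threshold=1.0)
        assert np.array_equal(out.data, rec.data)
        assert report.removed_ics == []

    def test_missing_veog_rejected(self):
        rec = _rec(np.random.default_rng(0).normal(size=(500, 5)))
        with pytest.raises(ValueError, match="VEOG"):
            sigprep.remove_eog_ics(rec)


class TestFilterSemg:
    def _emg_rec(self, x, rate=1000.0):
        data = np.column_stack([x, x])
        return _rec(data, rate, labels=["Rt. TA", "Cz"],
                    kinds=["EMG", "EEG"])

    def test_line_frequency_notched(self):
        rate = 1000.0
        t = np.arange(int(rate * 10)) / rate
        x = np.sin(2 * np.pi * 50 * t)
        out = sigprep.filter_semg(self._emg_rec(x))
        sl = slice(1000, -1000)
        atten = np.sqrt((out.channel("Rt. TA")[sl] ** 2).mean()) \
            / np.sqrt((x[sl] ** 2).mean())
        assert 20 * np.log10(atten) < -20

    def test_passband_tone_preserved(self):
        rate = 1000.0
        t = np.arange(int(rate * 10)) / rate
        x = np.sin(2 * np.pi * 100 * t)
        out = sigprep.filter_semg(self._emg_rec(x))
        sl = slice(1000, -1000)
        ratio = np.sqrt((out.channel("Rt. TA")[sl] ** 2).mean()) \
            / np.sqrt((x[sl] ** 2).mean())
        assert abs(20 * np.log10(ratio)) < 1.0

    def test_eeg_untouched(self):
        x = np.random.default_rng(0).normal(size=10000)
        out = sigprep.filter_semg(self._emg_rec(x))
        assert np.array_equal(out.channel("Cz"), x)

    def test_low_rate_rejected(self):
        with pytest.raises(ValueError, match="too low"):
            sigprep.filter_semg(self._emg_rec(np.zeros(1000), rate=500.0))


class TestWaveletDenoise:
    def test_noise_variance_shrinks(self):
        x = np.random.default_rng(0).normal(size=8000)
        rec = _rec(x[:, None], 1000.0, labels=["Rt. TA"], kinds=["EMG"])
        out = sigprep.wavelet_denoise(rec)
        assert out.data.var() < x.var()
        assert out.n_samples == rec.n_samples

    def test_cubic_trend_reconstructed(self):
        t = np.linspace(-1, 1, 4096)
        x = 0.5 * t ** 3 - t
        rec = _rec(x[:, None], 1000.0, labels=["Rt. TA"], kinds=["EMG"])
        out = sigprep.wavelet_denoise(rec)
        err = np.sqrt(((out.data[:, 0] - x) ** 2).mean())
        assert err < 0.01 * np.sqrt((x ** 2).mean())

    def test_too_short_signal_rejected(self):
        rec = _rec(np.zeros((8, 1)), 1000.0, labels=["Rt. TA"],
                   kinds=["EMG"])
        with pytest.raises(ValueError, match="shorter"):
            sigprep.wavelet_denoise(rec)


class TestAlignMarkers:
    def test_linear_ramp_exact(self):
        t100 = np.arange(300) / 100.0
        markers = MarkerTrajectories(
            (2.0 * t100)[:, None], 100.0, ["Heel_RZ"])
        rec = _rec(np.zeros((3000, 1)), 1000.0)
        out = sigprep.align_markers(markers, rec)
        assert out.n_samples == rec.n_samples
        expect = 2.0 * np.arange(3000) / 1000.0
        expect = np.minimum(expect, 2.0 * t100[-1])  # clamped past end
        assert np.allclose(out.data[:, 0], expect)

    def test_constant_stays_constant(self):
        markers = MarkerTrajectories(
            np.full((300, 2), 1.5), 100.0, ["a", "b"])
        rec = _rec(np.zeros((3000, 1)), 1000.0)
        out = sigprep.align_markers(markers, rec)
        assert np.allclose(out.data, 1.5)


def test_channel_labels_and_order_never_change(prepped, session):
    _, rec, _ = session
    prec, _, _, _ = prepped
    assert prec.labels == rec.labels
    assert prec.kinds == rec.kinds


def test_artifact_channel_rule_flags_outlier():
    rng = np.random.default_rng(0)
    data = rng.normal(size=(2000, 6))
    data[:, 2] *= 400.0
    rec = _rec(data, labels=[f"c{i}" for i in range(6)])
    report = sigprep.PrepReport()
    out = sigprep.drop_artifact_channels(rec, report=report)
    assert report.removed_channels == ["c2"]
    assert np.allclose(out.data[:, 2], 0.0)
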