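"""Wavelet power maps, histogram entropy/MI and the coupling matrices."""
import numpy as np
import pytest

from gaitcmi import synth, tfcmi
from gaitcmi.tfcmi import (
    MeanPowerCurve,
    band_mean_power,
    channel_power_curve,
    cross_mi,
    extract_topography,
    hist_entropy,
    morlet_tf_power,
    normalize_channel,
    phase_tfcmi,
    tfcmi_matrix,
)
from gaitcmi.types import PHASES, TOPO_ELECTRODES


def entropy_oracle(x, n_bins=40):
    """Literal histogram + -sum p log2 p loop."""
    lo, hi = x.min(), x.max()
    if hi == lo:
        return 0.0
    counts = np.zeros(n_bins)
    for v in x:
        b = int((v - lo) / (hi - lo) * n_bins)
        counts[min(b, n_bins - 1)] += 1
    h = 0.0
    for c in counts:
        if c > 0:
            p = c / len(x)
            h -= p * np.log2(p)
    return h


class TestNormalize:
    def test_zero_mean_unit_sd(self):
        x = np.random.default_rng(0).normal(3, 5, size=1000)
        y = normalize_channel(x)
        assert abs(y.mean()) < 1e-12
        assert abs(y.std() - 1) < 1e-12

    def test_affine_invariant(self):
        x = np.random.default_rng(1).normal(size=500)
        assert np.allclose(normalize_channel(x),
                           normalize_channel(4.2 * x - 7.0))

    def test_constant_rejected(self):
        with pytest.raises(ValueError, match="constant"):
            normalize_channel(np.full(100, 2.0))


class TestMorlet:
    def test_beta_band_map_is_10_by_2000(self):
        x = np.random.default_rng(0).normal(size=2000)
        tf = morlet_tf_power(x, np.arange(16, 26), 1000.0)
        assert tf.power.shape == (10, 2000)

    def test_emg_band_map_is_16_by_2000(self):
        x = np.random.default_rng(0).normal(size=2000)
        tf = morlet_tf_power(x, np.arange(30, 46), 1000.0)
        assert tf.power.shape == (16, 2000)

    def test_tone_peaks_at_its_frequency(self):
        t = np.arange(4000) / 1000.0
        x = np.sin(2 * np.pi * 20 * t)
        tf = morlet_tf_power(x, np.arange(16, 26), 1000.0)
        mean_power = tf.power[:, 500:-500].mean(axis=1)
        assert tf.freqs[np.argmax(mean_power)] == 20

    def test_frequency_above_nyquist_rejected(self):
        with pytest.raises(ValueError, match="Nyquist"):
            morlet_tf_power(np.zeros(100), np.array([300.0]), 500.0)


class TestBandMean:
    def test_single_row_is_identity(self):
        power = np.random.default_rng(0).random(size=(1, 500))
        tf = tfcmi.TFPowerMap(power, np.array([20.0]))
        assert np.allclose(band_mean_power(tf).values, power[0])

    def test_curve_length_matches_map(self):
        power = np.random.default_rng(0).random(size=(10, 2000))
        tf = tfcmi.TFPowerMap(power, np.arange(16, 26.0))
        assert band_mean_power(tf).values.shape == (2000,)

    def test_constant_map_constant_curve(self):
        tf = tfcmi.TFPowerMap(np.full((4, 100), 2.5),
                              np.arange(4.0) + 1)
        assert np.allclose(band_mean_power(tf).values, 2.5)


class TestHistEntropy:
    def test_constant_curve_zero_bits(self):
        assert hist_entropy(np.full(500, 3.3)) == 0.0

    def test_uniform_over_40_bins(self):
        # 40 equal-count bins: place samples at bin centers.
        x = np.repeat(np.arange(40.0), 25) + 0.5
        assert hist_entropy(x, 40) == pytest.approx(np.log2(40))

    def test_matches_bruteforce_oracle(self):
        rng = np.random.default_rng(3)
        for _ in range(1000):
            x = rng.normal(size=rng.integers(50, 200))
            assert hist_entropy(x) == pytest.approx(
                entropy_oracle(x), abs=1e-12)


class TestCrossMi:
    def test_self_information_equals_entropy(self):
        x = np.random.default_rng(0).normal(size=2000)
        assert cross_mi(x, x) == pytest.approx(hist_entropy(x), abs=1e-12)

    def test_symmetry_exact(self):
        rng = np.random.default_rng(1)
        x, y = rng.normal(size=2000), rng.normal(size=2000)
        assert cross_mi(x, y) == cross_mi(y, x)

    def test_independent_noise_bias_bounded(self):
        # Plug-in MI of independent N=2000 white-noise pairs carries a
        # finite-sample bias around 0.36 bits with 40x40 bins; it stays
        # well below the dependent regime.
        rng = np.random.default_rng(2)
        vals = [cross_mi(rng.normal(size=2000), rng.normal(size=2000))
                for _ in range(50)]
        assert np.mean(vals) < 0.45
        assert max(vals) < 0.55

    def test_length_mismatch_rejected(self):
        with pytest.raises(ValueError, match="length"):
            cross_mi(np.zeros(10), np.zeros(11))


class TestTfcmiMatrix:
    def _curves(self, n=4, length=2000, seed=0):
        rng = np.random.default_rng(seed)
        return [MeanPowerCurve(rng.random(length) + 0.1, channel=f"c{i}")
                for i in range(n)]

    def test_unit_diagonal_and_symmetry(self):
        mat = tfcmi_matrix(self._curves())
        assert np.allclose(np.diag(mat.values), 1.0)
        assert np.array_equal(mat.values, mat.values.T)
        assert np.all((mat.values >= 0) & (mat.values <= 1))

    def test_all_normalizations_unit_diagonal(self):
        for norm in ("sqrt", "min", "joint"):
            mat = tfcmi_matrix(self._curves(), normalization=norm)
            assert np.allclose(np.diag(mat.values), 1.0)

    def test_identical_curves_give_one(self):
        x = np.random.default_rng(0).random(2000)
        mat = tfcmi_matrix([MeanPowerCurve(x, channel="a"),
                            MeanPowerCurve(x.copy(), channel="b")])
        assert mat.pair("a", "b") == pytest.approx(1.0)

    def test_zero_entropy_channel_named(self):
        curves = self._curves(3)
        curves[1] = MeanPowerCurve(np.full(2000, 1.0), channel="flat")
        with pytest.raises(ValueError, match="flat"):
            tfcmi_matrix(curves)

    def test_added_noise_never_increases_coupling(self):
        # Data-processing flavour: corrupting one channel with
        # independent noise lowers its mean coupling to the others.
        rng = np.random.default_rng(5)
        diffs = []
        for _ in range(20):
            base = rng.normal(size=2000)
            a = base + 0.5 * rng.normal(size=2000)
            b = base + 0.5 * rng.normal(size=2000)
            clean = cross_mi(a, b)
            noisy = cross_mi(a + 2.0 * rng.normal(size=2000), b)
            diffs.append(clean - noisy)
        assert np.mean(diffs) > 0


class TestCouplingRecovery:
    def _pair_value(self, kappa, seed, phase="LR"):
        cfg = synth.SynthConfig(
            duration_s=30, seed=seed,
            coupling=[synth.Coupling("Cz", "Rt. TA", phase, kappa)])
        markers, rec, gt = synth.generate_session(cfg)
        labels = gt.phase_labels(rec.n_samples, rec.rate)
        cz = channel_power_curve(rec.channel("Cz"), rec.rate, "EEG").values
        ta = channel_power_curve(rec.channel("Rt. TA"), rec.rate,
                                 "EMG").values
        out = {}
        for ph in PHASES:
            m = labels == ph
            mi = cross_mi(cz[m], ta[m])
            out[ph] = mi / np.sqrt(hist_entropy(cz[m])
                                   * hist_entropy(ta[m]))
        return out

    def test_kappa_monotone_on_seed_means(self):
        kappas = [0.0, 0.5, 1.0]
        means = []
        for k in kappas:
            vals = [self._pair_value(k, s)["LR"] for s in range(5)]
            means.append(np.mean(vals))
        assert means[0] < means[1] < means[2]

    def test_coupled_phase_elevated_above_uncoupled(self):
        seeds = range(4)
        elev = {p: [] for p in PHASES}
        for s in seeds:
            v1 = self._pair_value(1.0, s)
            v0 = self._pair_value(0.0, s)
            for p in PHASES:
                elev[p].append(v1[p] - v0[p])
        coupled = np.mean(elev["LR"])
        for p in PHASES:
            if p != "LR":
                assert coupled > np.mean(elev[p])
        assert coupled > 0.02


class TestPhaseTfcmi:
    def test_seven_phase_maps_with_structure(self, prepped, segmented):
        prec, pmark, _, _ = prepped
        segs, _ = segmented
        chans = [("Cz", "EEG"), ("C3", "EEG"), ("Rt. TA", "EMG"),
                 ("Lt. GM", "EMG")]
        maps = {
            phase: phase_tfcmi(prec, segs, phase, marker_rate=pmark.rate,
                               channels=chans)
            for phase in PHASES
        }
        assert len(maps) == 7
        for mat in maps.values():
            assert np.allclose(np.diag(mat.values), 1.0)
            assert np.allclose(mat.values, mat.values.T)
            assert np.all((mat.values >= 0) & (mat.values <= 1))

    def test_concat_mode_matches_channels(self, prepped, segmented):
        prec, pmark, _, _ = prepped
        segs, _ = segmented
        chans = [("Cz", "EEG"), ("Rt. TA", "EMG")]
        mat = phase_tfcmi(prec, segs, "LR", marker_rate=pmark.rate,
                          channels=chans, epoch_mode="concat")
        assert mat.labels == ["Cz", "Rt. TA"]
        assert mat.n_cycles == len(segs)

    def test_unknown_phase_rejected(self, prepped, segmented):
        prec, pmark, _, _ = prepped
        segs, _ = segmented
        with pytest.raises(ValueError, match="phase"):
            phase_tfcmi(prec, segs, "XX", marker_rate=pmark.rate)


class TestTopography:
    def test_thirteen_electrodes_in_range(self, prepped, segmented):
        prec, pmark, _, _ = prepped
        segs, _ = segmented
        mat = phase_tfcmi(prec, segs, "LR", marker_rate=pmark.rate,
                          epoch_mode="concat")
        topo = extract_topography(mat, "Rt. TA")
        assert list(topo) == list(TOPO_ELECTRODES)
        assert all(0 <= v <= 1 for v in topo.values())

    def test_extraction_round_trips(self):
        rng = np.random.default_rng(0)
        labels = list(TOPO_ELECTRODES) + ["Rt. TA"]
        n = len(labels)
        vals = (rng.random((n, n)) + rng.random((n, n)).T) / 4
        np.fill_diagonal(vals, 1.0)
        vals = (vals + vals.T) / 2
        mat = tfcmi.TFCMIMatrix(vals, labels)
        topo = extract_topography(mat, "Rt. TA")
        for el, v in topo.items():
            assert mat.pair(el, "Rt. TA") == v

    def test_missing_muscle_rejected(self):
        mat = tfcmi.TFCMIMatrix(np.eye(2), ["Cz", "Pz"])
        with pytest.raises(KeyError):
            extract_topography(mat, "Rt. TA")
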