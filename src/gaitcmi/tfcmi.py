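"""Time-frequency cross mutual information between channel pairs.

Each channel is z-scored, transformed with a complex Morlet wavelet over
its band of interest (16-25 Hz for EEG, 30-45 Hz for sEMG, 1 Hz steps),
and reduced to a band-mean power curve. Dependence between two channels
is the histogram mutual information of their power curves,

    H(F_i)        = -sum_b p(F_i,b) log2 p(F_i,b)            (40 bins)
    TFMI(F_i,F_j) = H(F_i) + H(F_j) - H(F_i,F_j)

normalized to ``TFMI / sqrt(H_i * H_j)`` so the self-coupling diagonal is
exactly one. All 23 cap channels (montage minus VEOG) and 8 sEMG channels
enter a symmetric 31 x 31 map; per-phase maps average the per-cycle maps
of phase segments resampled to a fixed epoch length.
"""
from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
from scipy.signal import fftconvolve, resample

from .types import (
    EMG_CHANNELS,
    PHASES,
    TFCMI_EEG_CHANNELS,
    TOPO_ELECTRODES,
    MultiChannelRecording,
    PhaseSegmentation,
)

EEG_BAND = (16.0, 25.0)
EMG_BAND = (30.0, 45.0)
DEFAULT_BINS = 40
DEFAULT_EPOCH_LEN = 2000
MIN_PHASE_SAMPLES = 50


@dataclass
class TFPowerMap:
    """Wavelet power, frequency bins x time samples."""

    power: np.ndarray
    freqs: np.ndarray
    channel: str = ""

    def __post_init__(self) -> None:
        self.power = np.asarray(self.power, dtype=float)
        self.freqs = np.asarray(self.freqs, dtype=float)
        if self.power.shape[0] != len(self.freqs):
            raise ValueError("one frequency per power row required")
        if np.any(np.diff(self.freqs) <= 0):
            raise ValueError("freqs must be strictly increasing")
        if np.any(self.power < 0):
            raise ValueError("power must be nonnegative")


@dataclass
class MeanPowerCurve:
    """Band-mean power over time for one channel."""

    values: np.ndarray
    channel: str = ""
    band: tuple[float, float] = EEG_BAND

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=float).ravel()
        if not np.all(np.isfinite(self.values)):
            raise ValueError("curve must be finite")


@dataclass
class TFCMIMatrix:
    """Symmetric unit-diagonal channel x channel coupling map in [0, 1]."""

    values: np.ndarray
    labels: list[str]
    n_bins: int = DEFAULT_BINS
    raw_entropies: np.ndarray | None = None
    n_cycles: int = 1

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=float)
        if self.values.shape != (len(self.labels), len(self.labels)):
            raise ValueError("values must be square matching labels")

    def pair(self, a: str, b: str) -> float:
        return float(
            self.values[self.labels.index(a), self.labels.index(b)])


def normalize_channel(signal: np.ndarray) -> np.ndarray:
    """Z-score; raises on a constant channel."""
    x = np.asarray(signal, dtype=float)
    sd = x.std()
    if sd == 0:
        raise ValueError("constant channel cannot be normalized")
    return (x - x.mean()) / sd


def morlet_tf_power(
    signal: np.ndarray,
    freqs: np.ndarray,
    rate: float,
    omega0: float = 6.0,
    channel: str = "",
) -> TFPowerMap:
    """Complex-Morlet wavelet power map at the listed frequencies.

    The wavelet at frequency f has scale ``s = omega0 * rate / (2 pi f)``
    samples; power is the squared magnitude of the L2-normalized
    convolution, one row per frequency, same length as the input.
    """
    x = np.asarray(signal, dtype=float)
    freqs = np.asarray(freqs, dtype=float)
    if np.any(freqs >= rate / 2):
        raise ValueError("all frequencies must be below Nyquist")
    power = np.empty((len(freqs), len(x)))
    for i, f in enumerate(freqs):
        s = omega0 * rate / (2 * np.pi * f)
        half = int(np.ceil(4 * s))
        t = np.arange(-half, half + 1)
        wav = (np.pi ** -0.25) * np.exp(1j * omega0 * t / s) \
            * np.exp(-0.5 * (t / s) ** 2)
        wav = wav / np.sqrt(s)
        conv = fftconvolve(x, np.conj(wav[::-1]), mode="same")
        power[i] = np.abs(conv) ** 2
    return TFPowerMap(power, freqs, channel=channel)


def band_mean_power(tf_map: TFPowerMap) -> MeanPowerCurve:
    """Mean over frequency rows at each time sample."""
    return MeanPowerCurve(
        tf_map.power.mean(axis=0),
        channel=tf_map.channel,
        band=(float(tf_map.freqs[0]), float(tf_map.freqs[-1])),
    )


def _bin_indices(x: np.ndarray, n_bins: int) -> np.ndarray:
    """Equal-width bin index of each sample on the curve's own range."""
    lo, hi = x.min(), x.max()
    if hi == lo:
        return np.zeros(len(x), dtype=np.intp)
    idx = np.floor((x - lo) / (hi - lo) * n_bins).astype(np.intp)
    return np.minimum(idx, n_bins - 1)


def hist_entropy(curve: np.ndarray, n_bins: int = DEFAULT_BINS) -> float:
    """Shannon entropy (bits) of the equal-width histogram PDF.

    Bins span [min, max] of the curve; a constant curve occupies a single
    bin and has zero entropy.
    """
    x = np.asarray(curve, dtype=float).ravel()
    if not np.all(np.isfinite(x)):
        raise ValueError("curve must be finite")
    counts = np.bincount(_bin_indices(x, n_bins), minlength=n_bins)
    p = counts / counts.sum()
    p = p[p > 0]
    return float(-(p * np.log2(p)).sum())


def cross_mi(
    curve_i: np.ndarray, curve_j: np.ndarray, n_bins: int = DEFAULT_BINS
) -> float:
    """Histogram mutual information H_i + H_j - H_ij in bits.

    Each axis of the joint histogram is binned on its own [min, max]
    range, matching the marginal binning. Floored at zero against
    numerical negatives.
    """
    x = np.asarray(curve_i, dtype=float).ravel()
    y = np.asarray(curve_j, dtype=float).ravel()
    if len(x) != len(y):
        raise ValueError("curves must have equal length")
    bi = _bin_indices(x, n_bins)
    bj = _bin_indices(y, n_bins)
    joint = np.bincount(bi * n_bins + bj, minlength=n_bins * n_bins)
    n = len(x)
    pj = joint[joint > 0] / n
    h_ij = -(pj * np.log2(pj)).sum()
    h_i = hist_entropy(x, n_bins)
    h_j = hist_entropy(y, n_bins)
    return max(float(h_i + h_j - h_ij), 0.0)


def tfcmi_matrix(
    curves: list[MeanPowerCurve],
    n_bins: int = DEFAULT_BINS,
    normalization: str = "sqrt",
) -> TFCMIMatrix:
    """Normalized pairwise coupling map from per-channel power curves.

    ``normalization`` is one of ``"sqrt"`` (TFMI / sqrt(H_i H_j)),
    ``"min"`` (TFMI / min(H_i, H_j)) or ``"joint"`` (TFMI / H_ij); all
    give a unit diagonal. Raises naming any zero-entropy channel.
    """
    if len(curves) < 2:
        raise ValueError("need at least 2 channels")
    n = len(curves)
    lengths = {len(c.values) for c in curves}
    if len(lengths) != 1:
        raise ValueError("all curves must have equal length")
    ents = np.array([hist_entropy(c.values, n_bins) for c in curves])
    for c, h in zip(curves, ents):
        if h == 0:
            raise ValueError(f"zero-entropy channel {c.channel!r}")
    vals = np.eye(n)
    for i in range(n):
        for j in range(i + 1, n):
            mi = cross_mi(curves[i].values, curves[j].values, n_bins)
            if normalization == "sqrt":
                norm = np.sqrt(ents[i] * ents[j])
            elif normalization == "min":
                norm = min(ents[i], ents[j])
            elif normalization == "joint":
                norm = ents[i] + ents[j] - mi
            else:
                raise ValueError(f"unknown normalization {normalization!r}")
            vals[i, j] = vals[j, i] = min(mi / norm, 1.0)
    return TFCMIMatrix(
        vals, [c.channel for c in curves], n_bins=n_bins,
        raw_entropies=ents,
    )


def _band_freqs(band: tuple[float, float]) -> np.ndarray:
    return np.arange(band[0], band[1] + 0.5, 1.0)


def channel_power_curve(
    signal: np.ndarray,
    rate: float,
    kind: str,
    channel: str = "",
    omega0: float = 6.0,
) -> MeanPowerCurve:
    """Z-score, Morlet-transform and band-average one channel.

    EEG channels use the 16-25 Hz beta band (10 frequency rows), sEMG
    channels 30-45 Hz (16 rows).
    """
    band = EEG_BAND if kind in ("EEG", "REF", "EOG") else EMG_BAND
    x = normalize_channel(signal)
    tf = morlet_tf_power(x, _band_freqs(band), rate, omega0, channel)
    return band_mean_power(tf)


def session_channels(rec: MultiChannelRecording) -> list[tuple[str, str]]:
    """The (label, kind) list entering the 31x31 map: 23 EEG + 8 sEMG."""
    out = []
    for label in TFCMI_EEG_CHANNELS:
        if label in rec.labels:
            out.append((label, "EEG"))
    for label in EMG_CHANNELS:
        if label in rec.labels:
            out.append((label, "EMG"))
    return out


def _phase_sample_ranges(
    segmentations: list[PhaseSegmentation],
    phase: str,
    ratio: float,
    n_samples: int,
) -> list[tuple[int, int]]:
    out = []
    for seg in segmentations:
        a, b = seg.phase_interval(phase)
        lo, hi = int(round(a * ratio)), int(round(b * ratio))
        out.append((lo, min(hi, n_samples)))
    return out


def phase_tfcmi(
    rec: MultiChannelRecording,
    segmentations: list[PhaseSegmentation],
    phase: str,
    epoch_len: int = DEFAULT_EPOCH_LEN,
    n_bins: int = DEFAULT_BINS,
    marker_rate: float | None = None,
    channels: list[tuple[str, str]] | None = None,
    omega0: float = 6.0,
    epoch_mode: str = "cycle",
) -> TFCMIMatrix:
    """Coupling map for one gait phase.

    ``epoch_mode="cycle"``: for every segmented cycle the phase's
    biosignal samples are extracted, Fourier-resampled to ``epoch_len``
    samples, reduced to band-mean power curves and turned into a
    normalized coupling matrix; matrices are averaged over cycles
    (cycles shorter than 50 samples are skipped with a warning).

    ``epoch_mode="concat"``: band power curves are computed once over the
    whole recording, the phase's samples are pooled across cycles, and a
    single matrix is computed from the pooled curves. The pooled
    estimator has far lower variance for short phases and is the one to
    use when comparing coupling strengths.
    """
    if phase not in PHASES:
        raise ValueError(f"unknown phase {phase!r}")
    if epoch_mode not in ("cycle", "concat"):
        raise ValueError("epoch_mode must be 'cycle' or 'concat'")
    chans = channels if channels is not None else session_channels(rec)
    ratio = rec.rate / marker_rate if marker_rate else 1.0
    ranges = _phase_sample_ranges(
        segmentations, phase, ratio, rec.n_samples)

    if epoch_mode == "concat":
        keep = [(lo, hi) for lo, hi in ranges if hi > lo]
        if not keep:
            raise ValueError(f"no usable cycles for phase {phase}")
        idx = np.concatenate(
            [np.arange(lo, hi) for lo, hi in keep])
        curves = []
        for label, kind in chans:
            full = channel_power_curve(
                rec.channel(label), rec.rate, kind, label, omega0)
            curves.append(MeanPowerCurve(
                full.values[idx], label, full.band))
        mat = tfcmi_matrix(curves, n_bins=n_bins)
        mat.n_cycles = len(keep)
        return mat

    mats = []
    n_skipped = 0
    for lo, hi in ranges:
        if hi - lo < MIN_PHASE_SAMPLES:
            n_skipped += 1
            continue
        curves = []
        for label, kind in chans:
            x = rec.channel(label)[lo:hi]
            curve = channel_power_curve(x, rec.rate, kind, label, omega0)
            curves.append(MeanPowerCurve(
                resample(curve.values, epoch_len), label, curve.band))
        mats.append(tfcmi_matrix(curves, n_bins=n_bins).values)
    if n_skipped:
        warnings.warn(
            f"phase {phase}: skipped {n_skipped} cycle(s) shorter than "
            f"{MIN_PHASE_SAMPLES} samples", stacklevel=2)
    if not mats:
        raise ValueError(f"no usable cycles for phase {phase}")
    mean = np.mean(mats, axis=0)
    np.fill_diagonal(mean, 1.0)
    return TFCMIMatrix(
        mean, [c for c, _ in chans], n_bins=n_bins, n_cycles=len(mats))


def session_phase_maps(
    rec: MultiChannelRecording,
    segmentations: list[PhaseSegmentation],
    marker_rate: float | None = None,
    epoch_len: int = DEFAULT_EPOCH_LEN,
    channels: list[tuple[str, str]] | None = None,
) -> dict[str, TFCMIMatrix]:
    """One averaged coupling map per gait phase (7 matrices)."""
    return {
        phase: phase_tfcmi(
            rec, segmentations, phase, epoch_len=epoch_len,
            marker_rate=marker_rate, channels=channels,
        )
        for phase in PHASES
    }


def extract_topography(matrix: TFCMIMatrix, muscle: str) -> dict[str, float]:
    """The 13 movement-related electrode values of one muscle's column."""
    if muscle not in matrix.labels:
        raise KeyError(f"muscle {muscle!r} not in matrix")
    return {
        el: matrix.pair(el, muscle)
        for el in TOPO_ELECTRODES
        if el in matrix.labels
    }
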