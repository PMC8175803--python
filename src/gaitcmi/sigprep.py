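"""Preprocessing chain for EEG, sEMG and marker alignment.

The chain follows the acquisition pipeline's order: mastoid re-reference,
zero-phase Butterworth band limiting of EEG, resampling to 1 kHz, ICA-based
ocular artifact removal, elliptic 30-450 Hz band-pass plus least-squares
FIR 50 Hz notch on sEMG, and db4 wavelet denoising. All filters are
applied forward-backward (zero phase); channel order and labels are never
changed, only values.
"""
from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pywt
from scipy.signal import butter, ellip, filtfilt, firls, resample_poly, sosfiltfilt
from sklearn.decomposition import FastICA

from .types import MarkerTrajectories, MultiChannelRecording


@dataclass
class PrepReport:
    """Provenance of every preprocessing action taken."""

    filters_applied: list[dict] = field(default_factory=list)
    removed_ics: list[tuple[int, float]] = field(default_factory=list)
    removed_channels: list[str] = field(default_factory=list)

    def log(self, name: str, **params) -> None:
        self.filters_applied.append({"name": name, **params})


def rereference_mastoids(
    rec: MultiChannelRecording, report: PrepReport | None = None
) -> MultiChannelRecording:
    """Subtract the mastoid mean (M1+M2)/2 from every EEG channel."""
    for need in ("M1", "M2"):
        if need not in rec.labels:
            raise ValueError(f"missing mastoid channel {need!r}")
    out = rec.copy()
    ref = 0.5 * (rec.channel("M1") + rec.channel("M2"))
    idx = rec.pick_kind("EEG")
    out.data[:, idx] -= ref[:, None]
    if report is not None:
        report.log("rereference_mastoids", reference="(M1+M2)/2")
    return out


def filter_eeg(
    rec: MultiChannelRecording,
    hp_hz: float = 0.5,
    lp_hz: float = 50.0,
    report: PrepReport | None = None,
) -> MultiChannelRecording:
    """Zero-phase 2nd-order Butterworth high-pass then low-pass on EEG/EOG."""
    if rec.rate <= 2 * lp_hz:
        raise ValueError(
            f"rate {rec.rate} Hz too low for a {lp_hz} Hz low-pass")
    out = rec.copy()
    idx = rec.pick_kind("EEG", "EOG", "REF")
    sos_hp = butter(2, hp_hz, btype="high", fs=rec.rate, output="sos")
    sos_lp = butter(2, lp_hz, btype="low", fs=rec.rate, output="sos")
    x = out.data[:, idx]
    x = sosfiltfilt(sos_hp, x, axis=0)
    x = sosfiltfilt(sos_lp, x, axis=0)
    out.data[:, idx] = x
    if report is not None:
        report.log("filter_eeg", hp_hz=hp_hz, lp_hz=lp_hz, order=2,
                   design="butterworth", zero_phase=True)
    return out


def resample_1khz(
    rec: MultiChannelRecording,
    target_hz: float = 1000.0,
    report: PrepReport | None = None,
) -> MultiChannelRecording:
    """Polyphase resampling to the target rate (default 1 kHz)."""
    if rec.rate == target_hz:
        return rec.copy()
    from fractions import Fraction

    frac = Fraction(target_hz / rec.rate).limit_denominator(1000)
    data = resample_poly(rec.data, frac.numerator, frac.denominator, axis=0)
    out = MultiChannelRecording(
        data, target_hz, list(rec.labels), list(rec.kinds))
    if report is not None:
        report.log("resample", from_hz=rec.rate, to_hz=target_hz,
                   method="polyphase")
    return out


def remove_eog_ics(
    rec: MultiChannelRecording,
    threshold: float = 0.7,
    max_iter: int = 300,
    seed: int = 0,
    report: PrepReport | None = None,
    raise_on_nonconvergence: bool = False,
) -> tuple[MultiChannelRecording, PrepReport]:
    """Zero independent components correlated with VEOG above threshold.

    FastICA decomposes the EEG channels; components whose absolute Pearson
    correlation with the VEOG channel exceeds ``threshold`` are zeroed and
    the EEG block reconstructed. The report lists each removal with its
    correlation value. Full tolerance convergence is not guaranteed for
    near-Gaussian channels; the report records the iteration count, and
    ``raise_on_nonconvergence`` upgrades that to an error.
    """
    import warnings as _warnings

    from sklearn.exceptions import ConvergenceWarning

    if report is None:
        report = PrepReport()
    if "VEOG" not in rec.labels:
        raise ValueError("missing VEOG channel")
    idx = rec.pick_kind("EEG")
    if len(idx) < 4:
        raise ValueError("need at least 4 EEG channels for ICA")
    if threshold >= 1.0:
        report.log("remove_eog_ics", threshold=threshold, removed=0)
        return rec.copy(), report
    veog = rec.channel("VEOG")
    x = rec.data[:, idx]
    mean = x.mean(axis=0)
    ica = FastICA(
        n_components=len(idx), max_iter=max_iter, random_state=seed,
        whiten="unit-variance", tol=1e-3,
    )
    with _warnings.catch_warnings():
        _warnings.simplefilter("ignore", ConvergenceWarning)
        sources = ica.fit_transform(x - mean)
    converged = ica.n_iter_ < max_iter
    if not converged and raise_on_nonconvergence:
        raise RuntimeError(
            f"ICA did not converge within {ica.n_iter_} iterations")
    keep = np.ones(sources.shape[1], dtype=bool)
    for j in range(sources.shape[1]):
        r = np.corrcoef(sources[:, j], veog)[0, 1]
        if abs(r) > threshold:
            keep[j] = False
            report.removed_ics.append((j, float(r)))
    cleaned = sources * keep[None, :]
    out = rec.copy()
    out.data[:, idx] = ica.inverse_transform(cleaned) + mean
    report.log("remove_eog_ics", threshold=threshold,
               removed=int((~keep).sum()), converged=converged,
               n_iter=int(ica.n_iter_))
    return out, report


def filter_semg(
    rec: MultiChannelRecording,
    band: tuple[float, float] = (30.0, 450.0),
    notch_hz: float = 50.0,
    report: PrepReport | None = None,
) -> MultiChannelRecording:
    """Elliptic band-pass then least-squares FIR notch on EMG channels.

    Elliptic design: order 4, 0.5 dB passband ripple, 40 dB stopband.
    Notch: 501-tap least-squares FIR with a 48-52 Hz stop band, applied
    zero-phase. Non-EMG channels are untouched.
    """
    if rec.rate < 900.0:
        raise ValueError(
            f"rate {rec.rate} Hz too low for a {band[1]} Hz band edge")
    out = rec.copy()
    idx = rec.pick_kind("EMG")
    if len(idx) == 0:
        return out
    hi = min(band[1], 0.99 * rec.rate / 2)
    sos = ellip(4, 0.5, 40.0, [band[0], hi], btype="band", fs=rec.rate,
                output="sos")
    x = sosfiltfilt(sos, out.data[:, idx], axis=0)
    ntaps = 501
    f = [0.0, notch_hz - 4, notch_hz - 2, notch_hz + 2, notch_hz + 4,
         rec.rate / 2]
    taps = firls(ntaps, f, [1, 1, 0, 0, 1, 1], fs=rec.rate)
    x = filtfilt(taps, [1.0], x, axis=0)
    out.data[:, idx] = x
    if report is not None:
        report.log("filter_semg", band=[band[0], hi], ellip_order=4,
                   rp_db=0.5, rs_db=40.0, notch_hz=notch_hz, fir_taps=ntaps)
    return out


def wavelet_denoise(
    rec: MultiChannelRecording,
    wavelet: str = "db4",
    level: int | None = None,
    report: PrepReport | None = None,
) -> MultiChannelRecording:
    """Soft-threshold db4 wavelet shrinkage of the EMG channels.

    Decomposition level defaults to ``floor(log2(rate / 90))`` so the
    coarsest detail band stays above the EMG passband floor. The universal
    threshold ``sigma * sqrt(2 ln N)`` uses the median absolute deviation
    of the finest detail coefficients (MAD / 0.6745) as its noise scale.
    """
    out = rec.copy()
    idx = rec.pick_kind("EMG")
    if len(idx) == 0:
        return out
    if level is None:
        level = max(1, int(np.floor(np.log2(rec.rate / 90.0))))
    wav = pywt.Wavelet(wavelet)
    min_len = pywt.Wavelet(wavelet).dec_len * 2
    if rec.n_samples < min_len:
        raise ValueError(
            f"signal shorter than wavelet support ({min_len} samples)")
    n = rec.n_samples
    for ch in idx:
        coeffs = pywt.wavedec(out.data[:, ch], wav, level=level)
        finest = coeffs[-1]
        sigma = np.median(np.abs(finest)) / 0.6745
        thr = sigma * np.sqrt(2 * np.log(n))
        coeffs = [coeffs[0]] + [
            pywt.threshold(c, thr, mode="soft") for c in coeffs[1:]
        ]
        rec_sig = pywt.waverec(coeffs, wav)
        out.data[:, ch] = rec_sig[:n]
    if report is not None:
        report.log("wavelet_denoise", wavelet=wavelet, level=level,
                   threshold="universal", mode="soft")
    return out


def drop_artifact_channels(
    rec: MultiChannelRecording,
    robust_z: float = 5.0,
    manual: list[str] | None = None,
    report: PrepReport | None = None,
) -> MultiChannelRecording:
    """Zero channels whose RMS is a robust-z outlier across channels.

    Automatic surrogate for visual artifact inspection: a channel is
    flagged when the robust z-score of its RMS across channels exceeds
    ``robust_z``. A manual label list is also honored. Flagged channels
    are zeroed (labels kept) so downstream shapes never change.
    """
    out = rec.copy()
    rms = np.sqrt(np.mean(out.data ** 2, axis=0))
    med = np.median(rms)
    mad = np.median(np.abs(rms - med)) / 0.6745
    flagged = set(manual or [])
    if mad > 0:
        for i, label in enumerate(out.labels):
            if (rms[i] - med) / mad > robust_z:
                flagged.add(label)
    for label in flagged:
        if label in out.labels:
            out.data[:, out.channel_index(label)] = 0.0
            if report is not None:
                report.removed_channels.append(label)
    if report is not None:
        report.log("drop_artifact_channels", robust_z=robust_z,
                   flagged=sorted(flagged))
    return out


def align_markers(
    markers: MarkerTrajectories, rec: MultiChannelRecording
) -> MarkerTrajectories:
    """Linear interpolation of marker traces onto the biosignal clock."""
    t_new = rec.times
    t_old = markers.times
    data = np.empty((len(t_new), markers.data.shape[1]))
    for j in range(markers.data.shape[1]):
        data[:, j] = np.interp(t_new, t_old, markers.data[:, j])
    return MarkerTrajectories(data, rec.rate, list(markers.labels))


def preprocess(
    rec: MultiChannelRecording,
    markers: MarkerTrajectories | None = None,
    eog_threshold: float = 0.7,
    seed: int = 0,
    skip_ica: bool = False,
) -> tuple[MultiChannelRecording, MarkerTrajectories | None, PrepReport]:
    """Full chain in the canonical order.

    re-reference -> EEG band limiting -> resample to 1 kHz -> ICA ocular
    removal -> sEMG band-pass + notch -> wavelet denoise -> marker
    alignment.
    """
    report = PrepReport()
    out = rereference_mastoids(rec, report)
    out = filter_eeg(out, report=report)
    out = resample_1khz(out, report=report)
    if not skip_ica:
        out, report = remove_eog_ics(
            out, threshold=eog_threshold, seed=seed, report=report)
    out = filter_semg(out, report=report)
    out = wavelet_denoise(out, report=report)
    aligned = align_markers(markers, out) if markers is not None else None
    return out, aligned, report
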