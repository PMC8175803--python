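"""Gait-cycle and seven-phase segmentation from foot-marker kinematics.

One gait cycle is delimited by successive prominent minima of the right
heel's vertical trajectory. Within a cycle, six events are located
sequentially from crossings and extrema of five traces (Heel_RZ, Toe_RZ,
Heel_LZ, Heel_RY, Heel_LY):

e1  first zero crossing of Heel_RZ - Toe_RZ      (right foot flat; end MSW)
e2  next maximum of Heel_RY - Heel_LY            (feet furthest; end TSW)
e3  next zero crossing of Heel_RZ - Heel_LZ      (end of loading; end LR)
e4  next maximum of Heel_LZ                      (end MST; see ``mst_rule``)
e5  second zero crossing of Heel_RZ - Toe_RZ     (right foot flat; end TST)
e6  next minimum of Heel_RY - Heel_LY            (feet closest; end PSW)

ISW runs from e6 to the cycle end. Zero crossings are located by sign
change plus linear interpolation; extrema by discrete argmax/argmin on the
admissible sub-interval after a 5-sample moving-average smoothing.
"""
from __future__ import annotations

import numpy as np
from scipy.signal import find_peaks

from .types import (
    GaitCycle,
    MarkerTrajectories,
    MultiChannelRecording,
    PHASES,
    PhaseSegmentation,
)

_SMOOTH_WIN = 5


class EventNotFoundError(RuntimeError):
    """An event rule found no admissible crossing or extremum."""


def _smooth(x: np.ndarray, win: int = _SMOOTH_WIN) -> np.ndarray:
    if win <= 1:
        return x
    kernel = np.ones(win) / win
    pad = win // 2
    xp = np.pad(x, pad, mode="edge")
    return np.convolve(xp, kernel, mode="valid")[: len(x)]


def detect_cycles(
    heel_rz: np.ndarray,
    rate: float,
    prominence_frac: float = 0.25,
    min_autocorr: float = 0.3,
) -> list[GaitCycle]:
    """Delimit gait cycles at prominent minima of the right heel height.

    The stride period is first estimated from the autocorrelation peak of
    the demeaned, smoothed trace; minima closer than half that period are
    suppressed. First and last partial cycles are discarded (a cycle is
    the half-open interval between successive retained minima).
    """
    x = np.asarray(heel_rz, dtype=float)
    if len(x) < 2 * rate:
        raise ValueError("need at least 2 s of marker data")
    xs = _smooth(x)
    xc = xs - xs.mean()
    ac = np.correlate(xc, xc, mode="full")[len(xc) - 1:]
    if ac[0] <= 0:
        raise EventNotFoundError("no periodicity detected (flat trace)")
    ac = ac / ac[0]
    # First autocorrelation peak beyond a 0.2 s dead zone.
    lag0 = max(int(0.2 * rate), 1)
    peaks, _ = find_peaks(ac[lag0:])
    if len(peaks) == 0:
        raise EventNotFoundError("no periodicity detected")
    lags = peaks + lag0
    best = lags[np.argmax(ac[lags])]
    if ac[best] < min_autocorr:
        raise EventNotFoundError(
            f"no periodicity detected (autocorrelation peak "
            f"{ac[best]:.2f} < {min_autocorr})"
        )
    rng_amp = xs.max() - xs.min()
    minima, _ = find_peaks(
        -xs, prominence=prominence_frac * rng_amp, distance=int(0.5 * best)
    )
    if len(minima) < 2:
        raise EventNotFoundError("fewer than two cycle boundaries found")
    return [
        GaitCycle(int(a), int(b)) for a, b in zip(minima[:-1], minima[1:])
    ]


def _zero_crossings(x: np.ndarray) -> np.ndarray:
    """Sub-sample zero-crossing positions by linear interpolation."""
    s = np.sign(x)
    idx = np.where((s[:-1] != s[1:]) & (s[:-1] != 0))[0]
    denom = x[idx + 1] - x[idx]
    frac = np.where(denom != 0, -x[idx] / denom, 0.0)
    return idx + frac


def _first_crossing_after(x: np.ndarray, after: float) -> float:
    zc = _zero_crossings(x)
    zc = zc[zc > after]
    if len(zc) == 0:
        raise EventNotFoundError("no zero crossing in sub-interval")
    return float(zc[0])


def _extremum_between(
    x: np.ndarray, a: float, b: float, mode: str
) -> float:
    lo = int(np.ceil(a)) + 1
    hi = int(np.floor(b))
    if hi <= lo:
        raise EventNotFoundError("empty extremum search window")
    seg = x[lo:hi]
    i = int(np.argmax(seg) if mode == "max" else np.argmin(seg))
    return float(lo + i)


def detect_phase_events(
    markers: MarkerTrajectories,
    cycle: GaitCycle,
    mst_rule: str = "left",
) -> PhaseSegmentation:
    """Apply the six event rules inside one cycle.

    ``mst_rule`` selects the trace whose maximum ends mid-stance:
    ``"left"`` (maximum of Heel_LZ) or ``"right"`` (maximum of Heel_RZ).
    Raises :class:`EventNotFoundError` naming the failing rule, or
    ``ValueError`` on a non-monotone event sequence.
    """
    if mst_rule not in ("left", "right"):
        raise ValueError("mst_rule must be 'left' or 'right'")
    sl = slice(cycle.start, cycle.end)
    heel_rz = markers.trace("Heel_RZ")[sl]
    toe_rz = markers.trace("Toe_RZ")[sl]
    heel_lz = markers.trace("Heel_LZ")[sl]
    heel_ry = markers.trace("Heel_RY")[sl]
    heel_ly = markers.trace("Heel_LY")[sl]

    d_raw = heel_rz - toe_rz
    if np.allclose(d_raw, 0.0,
                   atol=1e-12 * max(1.0, np.abs(heel_rz).max())):
        raise EventNotFoundError(
            "rule e1 degenerate: Heel_RZ identical to Toe_RZ")
    # Symmetric smoothing leaves noise-free crossings and extrema in place
    # but tames sample-level jitter on noisy traces.
    d = _smooth(d_raw)
    g = _smooth(heel_ry - heel_ly)
    h_lr = _smooth(heel_rz - heel_lz)
    mst_trace = _smooth(heel_lz if mst_rule == "left" else heel_rz)

    try:
        e1 = _first_crossing_after(d, 0.0)
    except EventNotFoundError:
        raise EventNotFoundError("rule e1 (Heel_RZ-Toe_RZ crossing) failed")
    # e2: first maximum of g after e1. Local maxima via peak finding; fall
    # back to the window argmax if the peak is at the search edge.
    peaks, _ = find_peaks(g)
    cand = peaks[peaks > e1]
    if len(cand) == 0:
        raise EventNotFoundError("rule e2 (Heel_RY-Heel_LY maximum) failed")
    e2 = float(cand[0])
    try:
        e3 = _first_crossing_after(h_lr, e2)
    except EventNotFoundError:
        raise EventNotFoundError("rule e3 (Heel_RZ-Heel_LZ crossing) failed")
    try:
        e5 = _zero_crossings(d)
        e5 = float(e5[e5 > e3][0]) if len(e5[e5 > e3]) else None
    except IndexError:  # pragma: no cover - defensive
        e5 = None
    if e5 is None:
        raise EventNotFoundError(
            "rule e5 (second Heel_RZ-Toe_RZ crossing) failed")
    try:
        e4 = _extremum_between(mst_trace, e3, e5, "max")
    except EventNotFoundError:
        raise EventNotFoundError("rule e4 (Heel_LZ maximum) failed")
    troughs, _ = find_peaks(-g)
    cand = troughs[troughs > e5]
    if len(cand) == 0:
        raise EventNotFoundError("rule e6 (Heel_RY-Heel_LY minimum) failed")
    e6 = float(cand[0])

    floats = [e1, e2, e3, e4, e5, e6]
    if not all(a < b for a, b in zip(floats, floats[1:])):
        raise ValueError(f"non-monotone event sequence: {floats}")
    events = [cycle.start + int(np.floor(e + 0.5)) for e in floats]
    # Guard rounding collisions on very short phases.
    for i in range(1, 6):
        if events[i] <= events[i - 1]:
            events[i] = events[i - 1] + 1
    if events[-1] >= cycle.end:
        raise ValueError("events overflow the cycle after rounding")
    times = [(cycle.start + e) / markers.rate for e in floats]
    return PhaseSegmentation(cycle=cycle, events=events, event_times=times)


def segment_session(
    markers: MarkerTrajectories, mst_rule: str = "left"
) -> list[PhaseSegmentation]:
    """Detect cycles then the seven phases of each cycle."""
    cycles = detect_cycles(markers.trace("Heel_RZ"), markers.rate)
    out = []
    for cyc in cycles:
        out.append(detect_phase_events(markers, cyc, mst_rule=mst_rule))
    return out


def label_biosignal(
    segmentations: list[PhaseSegmentation],
    rec: MultiChannelRecording,
    marker_rate: float,
) -> np.ndarray:
    """Map marker-clock phase intervals onto the biosignal clock.

    Returns one label per biosignal sample; samples outside complete
    cycles are labeled ``"none"``. Clocks are assumed sample-0 aligned.
    """
    labels = np.full(rec.n_samples, "none", dtype=object)
    ratio = rec.rate / marker_rate
    for seg in segmentations:
        for name, (a, b) in seg.phases:
            lo = int(round(a * ratio))
            hi = int(round(b * ratio))
            labels[lo: min(hi, rec.n_samples)] = name
    return labels


def segmentation_to_records(
    segmentations: list[PhaseSegmentation], rate: float
) -> list[dict]:
    """BED-like rows (cycle, phase, start_ms, end_ms) for TSV export."""
    rows = []
    for k, seg in enumerate(segmentations):
        for name, (a, b) in seg.phases:
            rows.append({
                "cycle": k, "phase": name,
                "start_ms": 1e3 * a / rate, "end_ms": 1e3 * b / rate,
            })
    return rows
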