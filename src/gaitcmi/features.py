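"""Slope-sign-change and mean-power-frequency features per phase instance.

One classification instance is one (cycle, phase) pair; its feature vector
holds the SSC count and/or MPF of every requested channel over that
phase's samples. Three feature-set layouts ("cases") are supported:

case 1  8 sEMG channels x {SSC, MPF}            -> 16 columns
case 2  case 1 + 21 scalp-EEG channels x {SSC}  -> 37 columns
case 3  case 1 + 21 scalp-EEG channels x {MPF}  -> 37 columns
"""
from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
from scipy.signal import periodogram

from .types import EMG_CHANNELS, PHASES, SCALP_CHANNELS, MultiChannelRecording

MIN_PHASE_SAMPLES = 8


def ssc(signal: np.ndarray, threshold: float = 0.0) -> int:
    """Slope-sign-change count of a 1-D signal.

    Counts interior samples where the product of the backward and forward
    differences ``(x[i]-x[i-1]) * (x[i]-x[i+1])`` reaches ``threshold``:
    strict local extrema for ``threshold = 0`` (the product must be
    positive when the threshold is zero), amplitude-gated reversals
    otherwise.
    """
    x = np.asarray(signal, dtype=float)
    if x.ndim != 1 or len(x) < 3:
        raise ValueError("signal must be 1-D with at least 3 samples")
    if threshold < 0:
        raise ValueError("threshold must be nonnegative")
    prod = (x[1:-1] - x[:-2]) * (x[1:-1] - x[2:])
    if threshold == 0.0:
        return int(np.count_nonzero(prod > 0))
    return int(np.count_nonzero(prod >= threshold))


def mpf(signal: np.ndarray, rate: float) -> float:
    """Mean power frequency: power-weighted mean of the periodogram.

    Uses a Hann-windowed full-segment periodogram, excluding the DC bin.
    Raises on an all-zero signal (zero total power).
    """
    x = np.asarray(signal, dtype=float)
    if len(x) < MIN_PHASE_SAMPLES:
        raise ValueError(f"signal must have >= {MIN_PHASE_SAMPLES} samples")
    f, p = periodogram(x, fs=rate, window="hann", detrend=False)
    f, p = f[1:], p[1:]
    total = p.sum()
    if total <= 0:
        raise ValueError("zero total power: MPF undefined")
    return float((f * p).sum() / total)


@dataclass
class FeatureMatrix:
    """Instances x feature columns with phase labels and provenance."""

    values: np.ndarray
    labels: np.ndarray                      # phase name per instance
    columns: list[tuple[str, str]]          # (channel, feature kind)
    case_id: int | None = None
    speed_label: float | None = None
    meta: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=float)
        self.labels = np.asarray(self.labels, dtype=object)
        if self.values.shape[0] != len(self.labels):
            raise ValueError("one label per instance required")
        if self.values.shape[1] != len(self.columns):
            raise ValueError("column provenance must cover every column")
        if not np.all(np.isfinite(self.values)):
            raise ValueError("feature matrix contains non-finite values")

    @property
    def n_instances(self) -> int:
        return self.values.shape[0]

    def to_frame(self):
        import pandas as pd

        names = [f"{ch}|{kind}" for ch, kind in self.columns]
        df = pd.DataFrame(self.values, columns=names)
        df.insert(0, "phase", self.labels)
        return df


def extract_instances(
    rec: MultiChannelRecording,
    labels: np.ndarray,
    channels: list[str] | None = None,
    ssc_threshold: float = 0.0,
) -> dict[tuple[str, str, str], list[float]]:
    """Per-(phase, channel) SSC and MPF values, one per complete cycle.

    ``labels`` holds one phase name (or ``"none"``) per biosignal sample;
    contiguous runs of one phase are instances. Returns a mapping
    ``(phase, channel, kind) -> list of values`` with one entry per run;
    runs shorter than 8 samples are skipped with a warning.
    """
    if channels is None:
        channels = list(rec.labels)
    lab = np.asarray(labels, dtype=object)
    if len(lab) != rec.n_samples:
        raise ValueError("labels must match recording length")
    change = np.flatnonzero(lab[:-1] != lab[1:]) + 1
    bounds = np.concatenate([[0], change, [len(lab)]])
    out: dict[tuple[str, str, str], list[float]] = {}
    n_short = 0
    for a, b in zip(bounds[:-1], bounds[1:]):
        phase = lab[a]
        if phase == "none" or phase not in PHASES:
            continue
        if b - a < MIN_PHASE_SAMPLES:
            n_short += 1
            continue
        for ch in channels:
            x = rec.channel(ch)[a:b]
            out.setdefault((phase, ch, "SSC"), []).append(
                float(ssc(x, ssc_threshold)))
            out.setdefault((phase, ch, "MPF"), []).append(mpf(x, rec.rate))
    if n_short:
        warnings.warn(
            f"skipped {n_short} phase instance(s) shorter than "
            f"{MIN_PHASE_SAMPLES} samples", stacklevel=2)
    return out


def _case_columns(case_id: int) -> list[tuple[str, str]]:
    base = [(ch, kind) for ch in EMG_CHANNELS for kind in ("SSC", "MPF")]
    if case_id == 1:
        return base
    if case_id == 2:
        return base + [(ch, "SSC") for ch in SCALP_CHANNELS]
    if case_id == 3:
        return base + [(ch, "MPF") for ch in SCALP_CHANNELS]
    raise ValueError(f"unknown case_id {case_id!r} (must be 1, 2 or 3)")


def assemble_case(
    instances: dict[tuple[str, str, str], list[float]],
    case_id: int,
    speed_label: float | None = None,
    pad_to_87: bool = False,
) -> FeatureMatrix:
    """Assemble one of the three feature-set layouts.

    ``pad_to_87`` zero-pads cases 2 and 3 from their natural 37 columns
    to a fixed 87-column layout (29 channels x 3 feature slots, with the
    unused slots zero); the padding columns carry the provenance kind
    ``"PAD"``.
    """
    columns = _case_columns(case_id)
    phases_present = sorted(
        {k[0] for k in instances}, key=PHASES.index)
    values = []
    labels = []
    for phase in phases_present:
        counts = {
            (ch, kind): len(instances.get((phase, ch, kind), []))
            for ch, kind in columns
        }
        missing = [col for col, c in counts.items() if c == 0]
        if missing:
            raise ValueError(
                f"phase {phase}: no instances for columns {missing[:3]}...")
        n = min(counts.values())
        for i in range(n):
            values.append([
                instances[(phase, ch, kind)][i] for ch, kind in columns
            ])
            labels.append(phase)
    vals = np.asarray(values, dtype=float)
    cols = list(columns)
    if pad_to_87 and case_id in (2, 3):
        target = 87
        extra = target - vals.shape[1]
        vals = np.hstack([vals, np.zeros((vals.shape[0], extra))])
        cols = cols + [(f"pad{i}", "PAD") for i in range(extra)]
    return FeatureMatrix(
        vals, np.asarray(labels, dtype=object), cols,
        case_id=case_id, speed_label=speed_label,
    )


def features_from_session(
    rec: MultiChannelRecording,
    labels: np.ndarray,
    case_id: int,
    speed_label: float | None = None,
    ssc_threshold: float = 0.0,
    pad_to_87: bool = False,
) -> FeatureMatrix:
    """Convenience: extract instances and assemble one case."""
    needed = sorted({ch for ch, _ in _case_columns(case_id)})
    inst = extract_instances(rec, labels, channels=needed,
                             ssc_threshold=ssc_threshold)
    return assemble_case(inst, case_id, speed_label=speed_label,
                         pad_to_87=pad_to_87)
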