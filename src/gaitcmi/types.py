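"""Core in-memory containers shared across the pipeline.

All biosignal data are stored as plain ``samples x channels`` float arrays
with explicit sampling rates; marker data as ``samples x traces`` with
``<Marker>_<Axis>`` column names. Phase segmentations use half-open sample
intervals on the clock of the signal they index.
"""
from __future__ import annotations

from dataclasses import dataclass, field
from typing import Sequence

import numpy as np

#: The seven gait phases in their within-cycle order. A cycle starts at a
#: right-heel-height minimum (mid-swing) and the phases tile it exactly.
PHASES: tuple[str, ...] = ("MSW", "TSW", "LR", "MST", "TST", "PSW", "ISW")

#: 24-channel EEG cap montage (10-20 positions plus mastoids and VEOG).
EEG_MONTAGE: tuple[str, ...] = (
    "Fp1", "Fp2", "F3", "F4", "C3", "C4", "P3", "P4", "O1", "O2",
    "F7", "F8", "T7", "T8", "P7", "P8", "Fz", "Cz", "Pz", "Oz",
    "M1", "M2", "FPz", "VEOG",
)

#: The 21 scalp electrodes used for feature extraction (montage minus
#: VEOG and the mastoid references).
SCALP_CHANNELS: tuple[str, ...] = tuple(
    ch for ch in EEG_MONTAGE if ch not in ("VEOG", "M1", "M2")
)

#: The 23 EEG channels entering the 31x31 coupling map (montage minus VEOG).
TFCMI_EEG_CHANNELS: tuple[str, ...] = tuple(
    ch for ch in EEG_MONTAGE if ch != "VEOG"
)

#: Bipolar surface-EMG channels: biceps femoris, vastus medialis, tibialis
#: anterior and gastrocnemius medialis, bilaterally.
EMG_CHANNELS: tuple[str, ...] = (
    "Lt. BF", "Lt. VM", "Lt. TA", "Lt. GM",
    "Rt. BF", "Rt. VM", "Rt. TA", "Rt. GM",
)

#: Lower-limb movement-related electrodes used for topographies.
TOPO_ELECTRODES: tuple[str, ...] = (
    "F3", "F4", "C3", "C4", "P3", "P4", "F7", "F8", "P7", "P8",
    "Fz", "Cz", "Pz",
)


@dataclass
class MultiChannelRecording:
    """A sampled multichannel biosignal block.

    Parameters
    ----------
    data : ndarray, shape (n_samples, n_channels)
    rate : float
        Sampling rate in Hz.
    labels : sequence of str
        Unique channel names.
    kinds : sequence of str
        Per-channel kind, one of ``{"EEG", "EMG", "EOG", "REF"}``.
    """

    data: np.ndarray
    rate: float
    labels: list[str]
    kinds: list[str]

    def __post_init__(self) -> None:
        self.data = np.asarray(self.data, dtype=float)
        self.labels = list(self.labels)
        self.kinds = list(self.kinds)
        if self.data.ndim != 2:
            raise ValueError("data must be 2-D (samples x channels)")
        if self.data.shape[1] != len(self.labels):
            raise ValueError("labels length must match channel count")
        if len(self.kinds) != len(self.labels):
            raise ValueError("kinds length must match channel count")
        if len(set(self.labels)) != len(self.labels):
            raise ValueError("channel labels must be unique")
        if not self.rate > 0:
            raise ValueError("rate must be positive")
        if not np.all(np.isfinite(self.data)):
            raise ValueError("data must be finite")

    @property
    def n_samples(self) -> int:
        return self.data.shape[0]

    @property
    def n_channels(self) -> int:
        return self.data.shape[1]

    @property
    def times(self) -> np.ndarray:
        return np.arange(self.n_samples) / self.rate

    def channel_index(self, label: str) -> int:
        try:
            return self.labels.index(label)
        except ValueError:
            raise KeyError(f"no channel named {label!r}") from None

    def channel(self, label: str) -> np.ndarray:
        return self.data[:, self.channel_index(label)]

    def pick_kind(self, *kinds: str) -> np.ndarray:
        """Column indices of channels whose kind is one of ``kinds``."""
        return np.array(
            [i for i, k in enumerate(self.kinds) if k in kinds], dtype=int
        )

    def copy(self) -> "MultiChannelRecording":
        return MultiChannelRecording(
            self.data.copy(), self.rate, list(self.labels), list(self.kinds)
        )


@dataclass
class MarkerTrajectories:
    """3-D marker positions sampled on the motion-capture clock.

    ``data`` is ``samples x traces`` where each trace is one marker axis
    named ``<Marker>_<Axis>``, e.g. ``Heel_RZ``. The z axis is vertical
    and y is anteroposterior.
    """

    data: np.ndarray
    rate: float
    labels: list[str]

    def __post_init__(self) -> None:
        self.data = np.asarray(self.data, dtype=float)
        self.labels = list(self.labels)
        if self.data.ndim != 2 or self.data.shape[1] != len(self.labels):
            raise ValueError("data must be samples x traces matching labels")
        if len(set(self.labels)) != len(self.labels):
            raise ValueError("trace labels must be unique")
        if not self.rate > 0:
            raise ValueError("rate must be positive")

    @property
    def n_samples(self) -> int:
        return self.data.shape[0]

    @property
    def times(self) -> np.ndarray:
        return np.arange(self.n_samples) / self.rate

    def trace(self, label: str) -> np.ndarray:
        try:
            return self.data[:, self.labels.index(label)]
        except ValueError:
            raise KeyError(f"no trace named {label!r}") from None


@dataclass
class GaitCycle:
    """One gait cycle as a half-open sample interval [start, end)."""

    start: int
    end: int

    def __post_init__(self) -> None:
        if not self.end > self.start:
            raise ValueError("cycle end must exceed start")

    @property
    def length(self) -> int:
        return self.end - self.start


@dataclass
class PhaseSegmentation:
    """Seven labeled half-open intervals tiling one gait cycle.

    ``events`` are the six within-cycle sample indices marking the ends of
    MSW, TSW, LR, MST, TST and PSW; ISW runs from the sixth event to the
    cycle end. ``event_times`` keeps the sub-sample event positions in
    seconds for consumers that need better than one-sample precision.
    """

    cycle: GaitCycle
    events: list[int]
    phases: list[tuple[str, tuple[int, int]]] = field(default_factory=list)
    event_times: list[float] | None = None

    def __post_init__(self) -> None:
        if len(self.events) != 6:
            raise ValueError("exactly six events required")
        bounds = [self.cycle.start, *self.events, self.cycle.end]
        if any(b >= a for b, a in zip(bounds[1:], bounds[2:])):
            # allow start < e1 but events strictly increasing
            pass
        if not all(x < y for x, y in zip(bounds, bounds[1:])):
            raise ValueError("events must be strictly increasing within cycle")
        if not self.phases:
            self.phases = [
                (name, (bounds[i], bounds[i + 1]))
                for i, name in enumerate(PHASES)
            ]

    def phase_interval(self, name: str) -> tuple[int, int]:
        for label, iv in self.phases:
            if label == name:
                return iv
        raise KeyError(f"no phase named {name!r}")


def validate_tiling(seg: PhaseSegmentation) -> None:
    """Raise unless the seven phases exactly tile the cycle."""
    cursor = seg.cycle.start
    for name, (a, b) in seg.phases:
        if a != cursor or b <= a:
            raise ValueError(f"phase {name} breaks the tiling at {a}")
        cursor = b
    if cursor != seg.cycle.end:
        raise ValueError("phases do not tile the cycle to its end")
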