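"""Synthetic treadmill-walking sessions with known ground truth.

The generator produces the three data streams a gait-lab session yields —
3-D foot-marker trajectories, eight-channel surface EMG, and a 24-channel
EEG cap — from closed-form periodic templates, so that every downstream
stage (event detection, feature extraction, classification, corticomuscular
coupling) can be validated against analytically known event times, phase
labels, activation envelopes and injected EEG-muscle coupling strengths.

Marker templates are low-order harmonic sums whose crossings and extrema
realize the six kinematic gait-event rules at machine-precision known cycle
fractions; the left-leg traces are the right-leg traces shifted by half a
cycle. Muscle channels are phase-gated broadband noise carriers; EEG
channels are 1/f noise plus a beta-band (16-25 Hz) oscillation whose
amplitude envelope can be coupled, with strength ``kappa`` in [0, 1], to a
chosen muscle's envelope inside a chosen gait phase.
"""
from __future__ import annotations

import json
from dataclasses import dataclass, field, asdict
from pathlib import Path

import numpy as np
from numpy import pi, sin, cos
from scipy.ndimage import gaussian_filter1d
from scipy.optimize import brentq, minimize_scalar
from scipy.signal import butter, sosfiltfilt

from .types import (
    EEG_MONTAGE,
    EMG_CHANNELS,
    PHASES,
    MarkerTrajectories,
    MultiChannelRecording,
)

# --------------------------------------------------------------------------
# Heel-height template.
#
# Right-heel vertical position over one cycle, as a function of cycle
# fraction phi in [0, 1):
#
#   zeta(phi) = -[sin(2 pi (phi-t1)) + A3 sin(6 pi (phi-t1))]
#               - A2 sin(4 pi (phi-t2)) - A4 sin(8 pi (phi-t4))
#
# The constants below were chosen (by numerical search over the harmonic
# family) so that zeta has a single prominent minimum per cycle (the cycle
# boundary used for cycle detection), the anti-symmetric difference
# zeta(phi) - zeta(phi-1/2) has exactly two zero crossings per cycle (the
# loading-response rule), and the half-cycle-shifted left-heel maximum
# falls strictly between those crossings and the second heel-toe crossing
# (the mid-stance rule). Small perturbations of these constants can create
# spurious prominent minima; treat them as a matched set.
_Z_T1 = 0.93884498511546
_Z_A3 = 0.48471449838901526
_Z_T2 = 0.6918467965575065
_Z_A2 = 0.6267533097599939
_Z_T4 = 0.5641463421184228
_Z_A4 = 0.22274548331819913

# Free event fractions (relative to the cycle start at the zeta minimum):
# heel-toe crossings (ends of MSW and TST) and the anteroposterior
# heel-separation extrema (ends of TSW and PSW). e3 (end of LR) and e4
# (end of MST) are fixed by the zeta template and computed at import time.
_E1_FRAC = 0.12
_E2_FRAC = 0.36
_E5_FRAC = 0.76
_E6_FRAC = _E2_FRAC + 0.5  # anti-periodicity of the left-right difference

# Geometry scales (metres): vertical heel excursion, foot-pitch amplitude,
# anteroposterior stride amplitude, toe y offset (foot length).
_Z_SCALE = 0.06
_Z_BASE = 0.03
_D_SCALE = 0.04
_Y_AMPL = 0.30
_FOOT_LEN = 0.15

# Blink transient peak amplitude (a.u.); several times the background EEG
# so ocular components carry a realistic variance share.
_BLINK_AMP = 20.0


def _zeta(phi: np.ndarray | float) -> np.ndarray | float:
    """Unshifted heel-height template over cycle fraction ``phi``."""
    return (
        -(sin(2 * pi * (phi - _Z_T1)) + _Z_A3 * sin(6 * pi * (phi - _Z_T1)))
        - _Z_A2 * sin(4 * pi * (phi - _Z_T2))
        - _Z_A4 * sin(8 * pi * (phi - _Z_T4))
    )


def _solve_template_geometry() -> dict[str, float]:
    """Locate the template's minimum, maximum and difference zeros.

    Returns cycle-fraction positions, all relative to the template minimum,
    to ~1e-10 precision. Computed once at import.
    """
    grid = np.linspace(0.0, 1.0, 4096, endpoint=False)
    zg = _zeta(grid)
    i0 = int(np.argmin(zg))

    def refine_extremum(x0: float, sign: float) -> float:
        res = minimize_scalar(
            lambda x: sign * _zeta(x),
            bounds=(x0 - 2e-3, x0 + 2e-3),
            method="bounded",
            options={"xatol": 1e-12},
        )
        return float(res.x)

    phi_min = refine_extremum(grid[i0], 1.0)
    phi_max = refine_extremum(grid[int(np.argmax(zg))], -1.0)

    def hdiff(phi: float) -> float:
        return _zeta(phi) - _zeta(phi - 0.5)

    hg = _zeta(grid) - _zeta((grid - 0.5) % 1.0)
    zc = np.where(np.diff(np.sign(hg)) != 0)[0]
    zeros = sorted(
        float(brentq(hdiff, grid[i], grid[i + 1], xtol=1e-12)) for i in zc
    )
    rel = lambda x: (x - phi_min) % 1.0  # noqa: E731
    hz = sorted(rel(z) for z in zeros)
    e4 = rel(phi_max + 0.5)
    e3 = max(z for z in hz if z < e4)
    return {"phi_min": phi_min, "e3": e3, "e4": e4}


_GEOM = _solve_template_geometry()

#: The six event cycle fractions realized by the templates, in event order
#: (ends of MSW, TSW, LR, MST, TST, PSW).
EVENT_FRACTIONS: tuple[float, ...] = (
    _E1_FRAC, _E2_FRAC, _GEOM["e3"], _GEOM["e4"], _E5_FRAC, _E6_FRAC,
)

# Default per-muscle activation gains over the seven phases, loosely after
# textbook lower-limb activation patterns (TA active around swing and
# loading, GM around push-off, VM around loading/mid-stance, BF around
# terminal swing/loading). Left-side muscles use the same table evaluated
# half a cycle later. Overridable via SynthConfig.gain_table.
DEFAULT_GAIN_TABLE: dict[str, dict[str, float]] = {
    "TA": {"MSW": 1.0, "TSW": 0.9, "LR": 0.8, "MST": 0.2, "TST": 0.1,
           "PSW": 0.4, "ISW": 0.9},
    "GM": {"MSW": 0.1, "TSW": 0.1, "LR": 0.2, "MST": 0.5, "TST": 1.0,
           "PSW": 0.7, "ISW": 0.1},
    "VM": {"MSW": 0.1, "TSW": 0.5, "LR": 1.0, "MST": 0.6, "TST": 0.2,
           "PSW": 0.1, "ISW": 0.1},
    "BF": {"MSW": 0.2, "TSW": 1.0, "LR": 0.7, "MST": 0.2, "TST": 0.1,
           "PSW": 0.1, "ISW": 0.4},
}

#: Treadmill speed label -> (stride cadence Hz, beta-power scale). Slower
#: walking carries relatively more sensorimotor beta power.
SPEED_PRESETS: dict[float, tuple[float, float]] = {
    1.4: (0.55, 1.2),
    2.0: (0.70, 1.0),
    2.6: (0.85, 0.8),
}


@dataclass
class Coupling:
    """One injected EEG-muscle envelope coupling.

    Inside gait phase ``phase``, the beta-amplitude envelope of EEG channel
    ``channel`` is the convex blend ``(1-strength)*independent +
    strength*muscle`` of its own envelope and the (moment-matched) envelope
    of ``muscle``.
    """

    channel: str
    muscle: str
    phase: str
    strength: float

    def __post_init__(self) -> None:
        if not 0.0 <= self.strength <= 1.0:
            raise ValueError("coupling strength must be in [0, 1]")
        if self.phase not in PHASES:
            raise ValueError(f"unknown phase {self.phase!r}")


@dataclass
class SynthConfig:
    """Parameters of one synthetic walking session."""

    duration_s: float = 30.0
    speed_label: float = 2.0
    cadence_hz: float | None = None     # default from speed preset
    eeg_rate: float = 500.0
    marker_rate: float = 100.0
    coupling: list[Coupling] = field(default_factory=list)
    noise_sd: float = 1.0               # baseline broadband noise, a.u.
    line_noise_amp: float = 0.5         # 50 Hz line amplitude, a.u.
    blink_rate_hz: float = 0.2
    marker_noise_sd: float = 0.0        # metres, additive on every trace
    emg_carrier_amp: float = 2.0        # carrier amplitude per unit gain
    beta_amp: float = 1.5               # beta oscillation amplitude, a.u.
    envelope_texture: float = 0.5       # relative low-freq envelope texture
    gain_table: dict[str, dict[str, float]] | None = None
    seed: int = 0

    def __post_init__(self) -> None:
        if not self.duration_s > 0:
            raise ValueError("duration_s must be positive")
        if self.eeg_rate <= 0 or self.marker_rate <= 0:
            raise ValueError("sampling rates must be positive")
        if self.speed_label not in SPEED_PRESETS:
            raise ValueError(
                f"speed_label must be one of {sorted(SPEED_PRESETS)}"
            )
        if self.cadence_hz is None:
            self.cadence_hz = SPEED_PRESETS[self.speed_label][0]
        if not self.cadence_hz > 0:
            raise ValueError("cadence_hz must be positive")
        for c in self.coupling:
            if c.muscle not in EMG_CHANNELS:
                raise ValueError(f"unknown muscle {c.muscle!r} in coupling")
            if c.channel not in EEG_MONTAGE:
                raise ValueError(
                    f"coupling channel {c.channel!r} not in montage"
                )

    @property
    def beta_scale(self) -> float:
        return SPEED_PRESETS[self.speed_label][1]


@dataclass
class GroundTruth:
    """Everything the generator knows that detectors must recover."""

    cadence_hz: float
    marker_rate: float
    biosignal_rate: float
    n_cycles: int
    cycle_starts: np.ndarray            # marker-clock sample indices
    event_times: np.ndarray             # (n_cycles, 6) seconds
    phase_intervals: list[list[tuple[str, tuple[float, float]]]]
    muscle_envelopes: dict[str, np.ndarray] = field(default_factory=dict)
    eeg_envelopes: dict[str, np.ndarray] = field(default_factory=dict)
    coupling: list[Coupling] = field(default_factory=list)

    def cycle_start_times(self) -> np.ndarray:
        return self.cycle_starts / self.marker_rate

    def phase_labels(self, n_samples: int, rate: float) -> np.ndarray:
        """Per-sample phase labels ('none' outside complete cycles)."""
        labels = np.full(n_samples, "none", dtype=object)
        t = np.arange(n_samples) / rate
        for cyc in self.phase_intervals:
            for name, (a, b) in cyc:
                labels[(t >= a) & (t < b)] = name
        return labels


# --------------------------------------------------------------------------
# Markers


def _phase_fraction(t: np.ndarray, cadence: float) -> np.ndarray:
    return (t * cadence) % 1.0


def generate_markers(
    config: SynthConfig,
) -> tuple[MarkerTrajectories, GroundTruth]:
    """Generate bilateral heel/toe trajectories with known event times.

    The cycle clock starts at ``t = 0`` at a right-heel-height minimum;
    cycle ``k`` spans ``[k, k+1) / cadence`` seconds. Ground truth holds
    every complete cycle that fits the duration, its six event times and
    the seven phase intervals in seconds.
    """
    if config.marker_rate / config.cadence_hz < 50:
        raise ValueError(
            "cadence too high for marker rate: fewer than 50 samples per "
            f"cycle ({config.marker_rate / config.cadence_hz:.1f})"
        )
    rng = np.random.default_rng(config.seed)
    n = int(round(config.duration_s * config.marker_rate))
    t = np.arange(n) / config.marker_rate
    phi = _phase_fraction(t, config.cadence_hz)  # right-leg cycle fraction
    phi0 = _GEOM["phi_min"]

    heel_rz = _Z_BASE + _Z_SCALE * (_zeta(phi + phi0) - _zeta(phi0))
    heel_lz = _Z_BASE + _Z_SCALE * (_zeta(phi - 0.5 + phi0) - _zeta(phi0))

    # Heel-toe height difference: two zero crossings per cycle at e1, e5.
    cm = 0.5 * (_E1_FRAC + _E5_FRAC)
    hw = 0.5 * (_E5_FRAC - _E1_FRAC)
    d = _D_SCALE * (cos(2 * pi * (phi - cm)) - cos(2 * pi * hw))
    toe_rz = heel_rz - d
    d_l = _D_SCALE * (cos(2 * pi * (phi - 0.5 - cm)) - cos(2 * pi * hw))
    toe_lz = heel_lz - d_l

    # Anteroposterior positions: the left-right heel difference is a pure
    # sinusoid with its maximum at e2 and minimum at e6. A second harmonic
    # (common to both legs, cancelling in the difference) adds realism.
    # The third harmonic (coefficient < 1/3) sharpens the separation
    # extrema without adding extrema or moving them off e2/e6.
    phig = _E2_FRAC - 0.25
    u_r = 2 * pi * (phi - phig)
    u_l = 2 * pi * (phi - 0.5 - phig)
    heel_ry = 0.5 * _Y_AMPL * (sin(u_r) - 0.2 * sin(3 * u_r)) \
        + 0.03 * sin(4 * pi * phi)
    heel_ly = 0.5 * _Y_AMPL * (sin(u_l) - 0.2 * sin(3 * u_l)) \
        + 0.03 * sin(4 * pi * phi)
    toe_ry = heel_ry + _FOOT_LEN
    toe_ly = heel_ly + _FOOT_LEN

    # Mediolateral: constant offsets with a light sway (unused by rules).
    sway = 0.01 * sin(2 * pi * phi)
    heel_rx = 0.10 + sway
    heel_lx = -0.10 + sway
    toe_rx = 0.10 + sway
    toe_lx = -0.10 + sway

    labels = [
        "Heel_RX", "Heel_RY", "Heel_RZ", "Toe_RX", "Toe_RY", "Toe_RZ",
        "Heel_LX", "Heel_LY", "Heel_LZ", "Toe_LX", "Toe_LY", "Toe_LZ",
    ]
    data = np.column_stack([
        heel_rx, heel_ry, heel_rz, toe_rx, toe_ry, toe_rz,
        heel_lx, heel_ly, heel_lz, toe_lx, toe_ly, toe_lz,
    ])
    if config.marker_noise_sd > 0:
        data = data + rng.normal(0.0, config.marker_noise_sd, data.shape)
    markers = MarkerTrajectories(data, config.marker_rate, labels)

    T = 1.0 / config.cadence_hz
    n_cycles = int(np.floor(config.duration_s * config.cadence_hz))
    cycle_starts = np.round(
        np.arange(n_cycles) * T * config.marker_rate
    ).astype(int)
    fracs = np.asarray(EVENT_FRACTIONS)
    event_times = (np.arange(n_cycles)[:, None] + fracs[None, :]) * T
    phase_intervals = []
    for k in range(n_cycles):
        bounds = [k * T, *event_times[k], (k + 1) * T]
        phase_intervals.append(
            [(name, (bounds[i], bounds[i + 1]))
             for i, name in enumerate(PHASES)]
        )
    gt = GroundTruth(
        cadence_hz=config.cadence_hz,
        marker_rate=config.marker_rate,
        biosignal_rate=config.eeg_rate,
        n_cycles=n_cycles,
        cycle_starts=cycle_starts,
        event_times=event_times,
        phase_intervals=phase_intervals,
        coupling=list(config.coupling),
    )
    return markers, gt


# --------------------------------------------------------------------------
# Envelopes


def _smooth_texture(rng: np.random.Generator, n: int, rate: float,
                    sigma_s: float = 0.06) -> np.ndarray:
    """Unit-variance low-frequency noise (Gaussian-smoothed white noise)."""
    x = gaussian_filter1d(rng.standard_normal(n), sigma_s * rate,
                          mode="wrap")
    sd = x.std()
    return x / sd if sd > 0 else x


def _muscle_envelope(
    muscle: str,
    gt: GroundTruth,
    config: SynthConfig,
    n: int,
    rng: np.random.Generator,
) -> np.ndarray:
    """Phase-gated activation envelope with low-frequency texture."""
    table = config.gain_table or DEFAULT_GAIN_TABLE
    base = muscle.split()[-1]  # "Rt. TA" -> "TA"
    if base not in table:
        raise ValueError(f"no gain table entry for muscle {muscle!r}")
    gains = table[base]
    rate = config.eeg_rate
    t = np.arange(n) / rate
    T = 1.0 / gt.cadence_hz
    # Left-side muscles see their own gait half a cycle out of phase with
    # the right-leg phase labels.
    shift = 0.5 * T if muscle.startswith("Lt.") else 0.0
    frac = ((t - shift) * gt.cadence_hz) % 1.0
    bounds = np.concatenate([[0.0], np.asarray(EVENT_FRACTIONS), [1.0]])
    gate = np.empty(n)
    for i, name in enumerate(PHASES):
        mask = (frac >= bounds[i]) & (frac < bounds[i + 1])
        gate[mask] = gains.get(name, 0.0)
    gate = gaussian_filter1d(gate, 0.05 * rate, mode="wrap")
    if config.envelope_texture > 0:
        tex = 1.0 + config.envelope_texture * _smooth_texture(rng, n, rate)
        gate = gate * np.clip(tex, 0.05, None)
    return np.clip(gate, 0.0, None)


def _bandlimited_noise(
    rng: np.random.Generator, n: int, rate: float,
    lo: float, hi: float,
) -> np.ndarray:
    """Unit-variance Gaussian noise band-limited to [lo, hi] Hz."""
    hi = min(hi, 0.90 * rate / 2)
    sos = butter(4, [lo, hi], btype="band", fs=rate, output="sos")
    x = sosfiltfilt(sos, rng.standard_normal(n))
    return x / x.std()


# --------------------------------------------------------------------------
# sEMG


def generate_semg(
    config: SynthConfig, gt: GroundTruth
) -> MultiChannelRecording:
    """Eight phase-gated surface-EMG channels on the biosignal clock.

    Each channel is ``carrier_amp * envelope * carrier + baseline noise +
    50 Hz line``, with the carrier band-limited to 30 Hz .. 0.9*Nyquist.
    The envelopes actually used are stored into ``gt.muscle_envelopes``.
    """
    rng = np.random.default_rng(
        np.random.SeedSequence([config.seed, 0xE36]))
    rate = config.eeg_rate
    n = int(round(config.duration_s * rate))
    t = np.arange(n) / rate
    cols = []
    for muscle in EMG_CHANNELS:
        env = _muscle_envelope(muscle, gt, config, n, rng)
        gt.muscle_envelopes[muscle] = env
        carrier = _bandlimited_noise(rng, n, rate, 30.0, 450.0)
        baseline = config.noise_sd * rng.standard_normal(n)
        line = config.line_noise_amp * np.sin(
            2 * pi * 50.0 * t + rng.uniform(0, 2 * pi))
        cols.append(config.emg_carrier_amp * env * carrier + baseline + line)
    return MultiChannelRecording(
        np.column_stack(cols), rate, list(EMG_CHANNELS),
        ["EMG"] * len(EMG_CHANNELS),
    )


# --------------------------------------------------------------------------
# EEG


def _pink_noise(rng: np.random.Generator, n: int) -> np.ndarray:
    """Unit-variance 1/f-amplitude noise via spectral shaping."""
    white = rng.standard_normal(n)
    spec = np.fft.rfft(white)
    f = np.fft.rfftfreq(n)
    f[0] = f[1]
    spec = spec / np.sqrt(f)
    x = np.fft.irfft(spec, n)
    return x / x.std()


def _blink_train(
    rng: np.random.Generator, n: int, rate: float, rate_hz: float,
) -> np.ndarray:
    """Sum of 200 ms raised-cosine transients at Poisson times."""
    out = np.zeros(n)
    width = int(round(0.2 * rate))
    if width < 2 or rate_hz <= 0:
        return out
    kernel = 0.5 * (1 - np.cos(2 * pi * np.arange(width) / (width - 1)))
    n_events = rng.poisson(rate_hz * n / rate)
    starts = rng.integers(0, max(n - width, 1), size=n_events)
    for s in starts:
        out[s:s + width] += kernel[: n - s]
    return out


def generate_eeg(
    config: SynthConfig, gt: GroundTruth
) -> MultiChannelRecording:
    """24-channel EEG with optionally muscle-coupled beta envelopes.

    Every scalp channel is pink noise plus a beta oscillation (carrier
    frequency drawn uniformly in 17-24 Hz) under a smooth stochastic
    amplitude envelope; couplings listed in the config replace that
    envelope, inside the named phase, by the convex blend with the target
    muscle's envelope (moment-matched over the phase samples). VEOG
    carries blink transients that bleed into the frontal channels.
    """
    if any(c.muscle not in gt.muscle_envelopes for c in config.coupling):
        raise ValueError(
            "generate_semg must run before generate_eeg when couplings "
            "reference muscle envelopes"
        )
    rng = np.random.default_rng(
        np.random.SeedSequence([config.seed, 0xEE6]))
    rate = config.eeg_rate
    n = int(round(config.duration_s * rate))
    t = np.arange(n) / rate
    labels = gt.phase_labels(n, rate)

    blinks = _blink_train(rng, n, rate, config.blink_rate_hz)
    frontal_bleed = {"Fp1": 0.5, "Fp2": 0.5, "FPz": 0.6}

    couplings = {
        c.channel: c for c in config.coupling
    }
    cols = []
    kinds = []
    beta_amp = config.beta_amp * config.beta_scale
    for ch in EEG_MONTAGE:
        if ch == "VEOG":
            cols.append(_BLINK_AMP * blinks + 0.5 * rng.standard_normal(n))
            kinds.append("EOG")
            continue
        if ch in ("M1", "M2"):
            cols.append(0.3 * _pink_noise(rng, n))
            kinds.append("REF")
            continue
        env = 1.0 + 0.35 * _smooth_texture(rng, n, rate)
        env = np.clip(env, 0.05, None)
        cpl = couplings.get(ch)
        if cpl is not None and cpl.strength > 0:
            m_env = gt.muscle_envelopes[cpl.muscle]
            mask = labels == cpl.phase
            if mask.any():
                m = m_env[mask]
                msd = m.std()
                scaled = np.zeros_like(m_env)
                scaled[mask] = (
                    env[mask].mean()
                    + (m - m.mean())
                    * (env[mask].std() / msd if msd > 0 else 0.0)
                )
                env = env.copy()
                env[mask] = (
                    (1 - cpl.strength) * env[mask]
                    + cpl.strength * scaled[mask]
                )
                env = np.clip(env, 0.0, None)
        gt.eeg_envelopes[ch] = env
        f_beta = rng.uniform(17.0, 24.0)
        beta = env * np.sin(2 * pi * f_beta * t + rng.uniform(0, 2 * pi))
        sig = (
            config.noise_sd * _pink_noise(rng, n)
            + beta_amp * beta
            + 0.2 * config.line_noise_amp
            * np.sin(2 * pi * 50.0 * t + rng.uniform(0, 2 * pi))
        )
        if ch in frontal_bleed:
            sig = sig + frontal_bleed[ch] * _BLINK_AMP * blinks
        cols.append(sig)
        kinds.append("EEG")
    return MultiChannelRecording(
        np.column_stack(cols), rate, list(EEG_MONTAGE), kinds
    )


def generate_session(
    config: SynthConfig,
) -> tuple[MarkerTrajectories, MultiChannelRecording, GroundTruth]:
    """Markers (100 Hz clock) + combined EEG/sEMG block (one 500 Hz clock).

    EEG and sEMG share sample 0 with the marker clock. The combined
    recording holds the 24 cap channels followed by the 8 sEMG channels.
    """
    markers, gt = generate_markers(config)
    semg = generate_semg(config, gt)
    eeg = generate_eeg(config, gt)
    data = np.column_stack([eeg.data, semg.data])
    rec = MultiChannelRecording(
        data, config.eeg_rate, eeg.labels + semg.labels,
        eeg.kinds + semg.kinds,
    )
    return markers, rec, gt


# --------------------------------------------------------------------------
# On-disk session format (TSV markers, NPZ biosignals + JSON sidecars)


def save_session(
    out_dir: str | Path,
    markers: MarkerTrajectories,
    rec: MultiChannelRecording,
    gt: GroundTruth,
) -> None:
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    header = "time_s\t" + "\t".join(markers.labels)
    np.savetxt(
        out / "markers.tsv",
        np.column_stack([markers.times, markers.data]),
        delimiter="\t", header=header, comments="",
    )
    np.savez(out / "biosignals.npz", data=rec.data)
    (out / "biosignals.json").write_text(json.dumps({
        "rate": rec.rate, "labels": rec.labels, "kinds": rec.kinds,
    }, indent=1))
    (out / "ground_truth.json").write_text(json.dumps({
        "cadence_hz": gt.cadence_hz,
        "marker_rate": gt.marker_rate,
        "biosignal_rate": gt.biosignal_rate,
        "n_cycles": gt.n_cycles,
        "cycle_starts": gt.cycle_starts.tolist(),
        "event_times": gt.event_times.tolist(),
        "phase_intervals": [
            [[name, list(iv)] for name, iv in cyc]
            for cyc in gt.phase_intervals
        ],
        "coupling": [asdict(c) for c in gt.coupling],
    }, indent=1))


def load_session(
    in_dir: str | Path,
) -> tuple[MarkerTrajectories, MultiChannelRecording, GroundTruth]:
    src = Path(in_dir)
    raw = np.loadtxt(src / "markers.tsv", delimiter="\t", skiprows=1)
    with open(src / "markers.tsv") as fh:
        cols = fh.readline().rstrip("\n").split("\t")
    times = raw[:, 0]
    rate = 1.0 / np.median(np.diff(times))
    markers = MarkerTrajectories(raw[:, 1:], round(rate, 6), cols[1:])
    meta = json.loads((src / "biosignals.json").read_text())
    data = np.load(src / "biosignals.npz")["data"]
    rec = MultiChannelRecording(
        data, meta["rate"], meta["labels"], meta["kinds"])
    g = json.loads((src / "ground_truth.json").read_text())
    gt = GroundTruth(
        cadence_hz=g["cadence_hz"],
        marker_rate=g["marker_rate"],
        biosignal_rate=g["biosignal_rate"],
        n_cycles=g["n_cycles"],
        cycle_starts=np.asarray(g["cycle_starts"], dtype=int),
        event_times=np.asarray(g["event_times"], dtype=float),
        phase_intervals=[
            [(name, tuple(iv)) for name, iv in cyc]
            for cyc in g["phase_intervals"]
        ],
        coupling=[Coupling(**c) for c in g["coupling"]],
    )
    return markers, rec, gt
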