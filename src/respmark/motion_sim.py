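"""Synthetic respiratory-motion sessions for external-marker studies.

This module generates time-synchronized displacement traces for nine
external thoracic markers (M1..M9, laid out on a 3x3 grid over the chest
and abdomen) plus one internal reference point, emulating the kind of
dataset produced by a 4D anthropomorphic phantom driven by a parametric
breathing model.  Each breathing session is controlled by three physical
quantities — maximum anterior-posterior (AP) chest-wall expansion, maximum
superior-inferior (SI) diaphragm excursion, and the respiratory period —
and each marker by gains, phase lag, noise and drift parameters.

The left-right axis is omitted throughout: its displacement is negligible
for thoracic surface points, so every trace carries AP and SI channels only.
All displacements are in mm relative to the end-exhale baseline (value 0 at
the start of each cycle); AP positive is anterior, SI positive is superior.
"""

from __future__ import annotations

import dataclasses
import math
from dataclasses import dataclass, field
from typing import Mapping, Sequence

import numpy as np
from scipy import signal as _sig

from .errors import InvalidParameterError

MARKER_LABELS: tuple[str, ...] = tuple(f"M{i}" for i in range(1, 10))

#: Fixed 3x3 layout: M1-M3 upper row, M4-M6 middle row, M7-M9 lower row.
REGIONS: dict[str, tuple[str, ...]] = {
    "upper": ("M1", "M2", "M3"),
    "middle": ("M4", "M5", "M6"),
    "lower": ("M7", "M8", "M9"),
}
REGION_OF: dict[str, str] = {
    label: region for region, labels in REGIONS.items() for label in labels
}


@dataclass(frozen=True)
class BreathingCycleSpec:
    """One breathing pattern: chest expansion, diaphragm excursion, period.

    Parameters
    ----------
    ap_expansion_cm : float
        Maximum anterior-posterior expansion of the chest wall, in cm.
    diaphragm_motion_cm : float
        Maximum superior-inferior diaphragm excursion, in cm.
    period_s : float
        Respiratory period in seconds; must lie in [2, 10] s, the range of
        plausible resting human breathing.
    """

    ap_expansion_cm: float
    diaphragm_motion_cm: float
    period_s: float

    def __post_init__(self) -> None:
        if self.ap_expansion_cm <= 0 or self.diaphragm_motion_cm <= 0:
            raise InvalidParameterError("expansion amplitudes must be > 0")
        if not (2.0 <= self.period_s <= 10.0):
            raise InvalidParameterError(
                f"period must be in [2, 10] s, got {self.period_s}"
            )

    @property
    def ap_expansion_mm(self) -> float:
        return 10.0 * self.ap_expansion_cm

    @property
    def diaphragm_motion_mm(self) -> float:
        return 10.0 * self.diaphragm_motion_cm


def table_cycles() -> tuple[BreathingCycleSpec, ...]:
    """The five study breathing cycles (chest cm, diaphragm cm, period s)."""
    return (
        BreathingCycleSpec(1.2, 2.0, 5.0),
        BreathingCycleSpec(0.7, 1.7, 5.0),
        BreathingCycleSpec(0.5, 1.2, 4.0),
        BreathingCycleSpec(1.3, 2.2, 6.0),
        BreathingCycleSpec(1.0, 1.8, 5.5),
    )


@dataclass(frozen=True)
class MarkerSpec:
    """Kinematic model of one surface marker (or the internal reference).

    The marker's AP channel is ``ap_gain`` times the chest-wall waveform,
    its SI channel ``si_gain`` times the diaphragm waveform, both delayed
    by ``phase_lag_s``, with additive white Gaussian noise of standard
    deviation ``noise_sd_mm`` and a linear baseline drift of
    ``drift_rate_mm_s``.  ``phase_jitter_sd_s`` adds a random per-session
    phase offset (variable chest/abdomen lag), the mechanism by which a
    marker can correlate well with the reference in one session and poorly
    in another.
    """

    label: str
    region: str
    ap_gain: float
    si_gain: float
    phase_lag_s: float = 0.0
    noise_sd_mm: float = 0.0
    drift_rate_mm_s: float = 0.0
    phase_jitter_sd_s: float = 0.0

    def __post_init__(self) -> None:
        if self.ap_gain < 0 or self.si_gain < 0:
            raise InvalidParameterError("gains must be >= 0")
        if self.noise_sd_mm < 0 or self.phase_jitter_sd_s < 0:
            raise InvalidParameterError("noise_sd and phase jitter must be >= 0")
        if self.label in REGION_OF and REGION_OF[self.label] != self.region:
            raise InvalidParameterError(
                f"{self.label} belongs to the {REGION_OF[self.label]} region"
            )


def default_marker_presets() -> tuple[MarkerSpec, ...]:
    """Nine marker presets emulating the border/midline correlation structure.

    Border markers (M1, M3, M7, M9) move with high gain and low noise and
    track the reference almost perfectly; the mid-column markers (M2, M5,
    M8, over sternum/xiphoid/navel) have low gain and high noise; the
    lateral middle-row markers (M4, M6) move strongly but with a large
    session-to-session phase jitter, so their correlation is high on
    average yet fluctuates between sessions.  These are presets chosen to
    emulate a realistic statistical structure, not measured ground truth.
    """
    return (
        MarkerSpec("M1", "upper", 0.90, 0.50, 0.02, 0.30),
        MarkerSpec("M2", "upper", 0.30, 0.15, 0.05, 1.60),
        MarkerSpec("M3", "upper", 0.88, 0.52, 0.03, 0.30),
        MarkerSpec("M4", "middle", 1.00, 0.70, 0.15, 0.50, phase_jitter_sd_s=0.55),
        MarkerSpec("M5", "middle", 0.28, 0.15, 0.05, 1.60),
        MarkerSpec("M6", "middle", 1.00, 0.68, 0.15, 0.55, phase_jitter_sd_s=0.55),
        MarkerSpec("M7", "lower", 0.95, 0.70, 0.02, 0.30),
        MarkerSpec("M8", "lower", 0.30, 0.16, 0.05, 1.60),
        MarkerSpec("M9", "lower", 0.93, 0.72, 0.02, 0.30),
    )


def default_reference_spec() -> MarkerSpec:
    """Internal reference point: diaphragm-dominated, nearly noise-free."""
    return MarkerSpec("ref", "internal", 0.80, 1.00, 0.0, 0.10)


@dataclass(frozen=True)
class SimulationConfig:
    """Full specification of one synthetic breathing session."""

    cycle: BreathingCycleSpec
    markers: tuple[MarkerSpec, ...] = field(default_factory=default_marker_presets)
    reference_spec: MarkerSpec = field(default_factory=default_reference_spec)
    duration_s: float = 60.0
    dt_s: float = 0.025
    seed: int = 0
    waveform_exponent: int = 2
    gain_jitter_sd: float = 0.10

    def __post_init__(self) -> None:
        if self.dt_s <= 0:
            raise InvalidParameterError("dt must be > 0")
        if self.duration_s < 2 * self.cycle.period_s:
            raise InvalidParameterError("duration must cover >= 2 periods")
        if self.duration_s / self.dt_s < 100:
            raise InvalidParameterError("duration/dt must yield >= 100 samples")
        if self.waveform_exponent < 1:
            raise InvalidParameterError("waveform_exponent must be >= 1")
        labels = [m.label for m in self.markers]
        if len(labels) != len(set(labels)):
            raise InvalidParameterError(f"duplicate marker labels in {labels}")
        if len(self.markers) != 9 or set(labels) != set(MARKER_LABELS):
            raise InvalidParameterError("exactly the nine markers M1..M9 required")

    def to_dict(self) -> dict:
        d = dataclasses.asdict(self)
        d["cycle"] = dataclasses.asdict(self.cycle)
        d["markers"] = [dataclasses.asdict(m) for m in self.markers]
        d["reference_spec"] = dataclasses.asdict(self.reference_spec)
        return d

    @classmethod
    def from_dict(cls, d: Mapping) -> "SimulationConfig":
        d = dict(d)
        d["cycle"] = BreathingCycleSpec(**d["cycle"])
        d["markers"] = tuple(MarkerSpec(**m) for m in d["markers"])
        d["reference_spec"] = MarkerSpec(**d["reference_spec"])
        return cls(**d)


@dataclass(frozen=True)
class MotionTrace:
    """One body point's displacement series: uniform time grid, AP and SI in mm."""

    timestamps: np.ndarray
    ap: np.ndarray
    si: np.ndarray

    def __post_init__(self) -> None:
        t, ap, si = (np.asarray(a, dtype=float) for a in (self.timestamps, self.ap, self.si))
        object.__setattr__(self, "timestamps", t)
        object.__setattr__(self, "ap", ap)
        object.__setattr__(self, "si", si)
        if not (t.shape == ap.shape == si.shape) or t.ndim != 1:
            raise InvalidParameterError("timestamps, ap, si must be equal-length 1-D")
        if np.any(~np.isfinite(t)) or np.any(~np.isfinite(ap)) or np.any(~np.isfinite(si)):
            raise InvalidParameterError("trace contains non-finite values")
        if t.size >= 2:
            dt = np.diff(t)
            if np.any(dt <= 0) or not np.allclose(dt, dt[0], rtol=0, atol=1e-9):
                raise InvalidParameterError("timestamps must be uniform and increasing")

    @property
    def n(self) -> int:
        return int(self.timestamps.size)

    @property
    def dt(self) -> float:
        return float(self.timestamps[1] - self.timestamps[0])

    def channels(self) -> np.ndarray:
        """Return the (n, 2) array of [AP, SI] columns."""
        return np.column_stack([self.ap, self.si])


@dataclass(frozen=True)
class SyntheticSession:
    """Nine labelled marker traces plus the internal reference trace."""

    marker_traces: Mapping[str, MotionTrace]
    reference_trace: MotionTrace
    config: SimulationConfig

    def __post_init__(self) -> None:
        if set(self.marker_traces) != set(MARKER_LABELS):
            raise InvalidParameterError("session must contain exactly M1..M9")
        t0 = self.reference_trace.timestamps
        for label, tr in self.marker_traces.items():
            if tr.n != self.reference_trace.n or not np.array_equal(tr.timestamps, t0):
                raise InvalidParameterError(f"{label} not on the shared time grid")

    @property
    def timestamps(self) -> np.ndarray:
        return self.reference_trace.timestamps


def breathing_waveform(
    t: np.ndarray | float, cycle: BreathingCycleSpec, exponent: int = 2
) -> np.ndarray:
    """Normalized breathing waveform w(t) = sin^(2k)(pi t / T) in [0, 1].

    Zero at the start of each cycle (end-exhale), peaking at 1 at mid-cycle
    (end-inhale).  ``exponent`` k >= 1 controls how peaked (asymmetric in
    dwell time) the waveform is; k = 1 gives a raised cosine, larger k a
    longer exhale plateau typical of resting breathing.
    """
    if exponent < 1 or int(exponent) != exponent:
        raise InvalidParameterError("exponent must be a positive integer")
    if cycle.period_s <= 0:
        raise InvalidParameterError("period must be > 0")
    t = np.asarray(t, dtype=float)
    return np.sin(np.pi * t / cycle.period_s) ** (2 * int(exponent))


def _build_trace(
    t: np.ndarray,
    spec: MarkerSpec,
    cycle: BreathingCycleSpec,
    exponent: int,
    rng: np.random.Generator,
    gain_jitter_sd: float,
) -> MotionTrace:
    jitter = math.exp(rng.normal(0.0, gain_jitter_sd)) if gain_jitter_sd > 0 else 1.0
    lag = spec.phase_lag_s
    if spec.phase_jitter_sd_s > 0:
        lag = lag + rng.normal(0.0, spec.phase_jitter_sd_s)
    w = breathing_waveform(t - lag, cycle, exponent)
    drift = spec.drift_rate_mm_s * t
    ap = jitter * spec.ap_gain * cycle.ap_expansion_mm * w + drift
    si = jitter * spec.si_gain * cycle.diaphragm_motion_mm * w + drift
    if spec.noise_sd_mm > 0:
        ap = ap + rng.normal(0.0, spec.noise_sd_mm, t.size)
        si = si + rng.normal(0.0, spec.noise_sd_mm, t.size)
    return MotionTrace(t, ap, si)


def simulate_session(config: SimulationConfig) -> SyntheticSession:
    """Generate one session deterministically from ``config`` (incl. its seed).

    Each marker trace is gain x amplitude x waveform(t - phase lag) plus
    drift and Gaussian noise; the reference trace is built the same way
    from ``config.reference_spec``.  Markers are processed in label order
    so the random stream is reproducible.
    """
    rng = np.random.default_rng(config.seed)
    n = int(round(config.duration_s / config.dt_s))
    t = np.arange(n) * config.dt_s
    specs = {m.label: m for m in config.markers}
    traces = {
        label: _build_trace(
            t, specs[label], config.cycle, config.waveform_exponent, rng,
            config.gain_jitter_sd,
        )
        for label in MARKER_LABELS
    }
    ref = _build_trace(
        t, config.reference_spec, config.cycle, config.waveform_exponent, rng,
        config.gain_jitter_sd,
    )
    return SyntheticSession(traces, ref, config)


def simulate_study(
    n_sessions: int = 5,
    seed: int = 0,
    cycles: Sequence[BreathingCycleSpec] | None = None,
    markers: tuple[MarkerSpec, ...] | None = None,
    reference: MarkerSpec | None = None,
    duration_s: float = 60.0,
    dt_s: float = 0.025,
    **kwargs,
) -> list[SyntheticSession]:
    """Simulate ``n_sessions`` sessions cycling through the study breathing
    patterns (defaults: the five tabulated cycles, default marker presets).

    Session i uses seed ``seed + i`` so sessions are mutually independent
    yet the whole study is reproducible from one seed.
    """
    if n_sessions < 1:
        raise InvalidParameterError("n_sessions must be >= 1")
    cycles = tuple(cycles) if cycles is not None else table_cycles()
    sessions = []
    for i in range(n_sessions):
        cfg = SimulationConfig(
            cycle=cycles[i % len(cycles)],
            markers=markers if markers is not None else default_marker_presets(),
            reference_spec=reference if reference is not None else default_reference_spec(),
            duration_s=duration_s,
            dt_s=dt_s,
            seed=seed + i,
            **kwargs,
        )
        sessions.append(simulate_session(cfg))
    return sessions


@dataclass(frozen=True)
class AxisStats:
    peak_to_peak_mm: float
    dominant_freq_hz: float  # NaN when the trace is constant
    is_constant: bool


@dataclass(frozen=True)
class TraceStats:
    ap: AxisStats
    si: AxisStats


def _axis_stats(x: np.ndarray, dt: float) -> AxisStats:
    ptp = float(np.max(x) - np.min(x))
    if ptp == 0.0:
        return AxisStats(0.0, float("nan"), True)
    freqs, power = _sig.periodogram(x - np.mean(x), fs=1.0 / dt)
    # skip the DC bin so slow drift does not mask the breathing peak
    k = 1 + int(np.argmax(power[1:]))
    return AxisStats(ptp, float(freqs[k]), False)


def trace_stats(trace: MotionTrace) -> TraceStats:
    """Peak-to-peak amplitude (mm) and dominant frequency (Hz) per axis.

    The dominant frequency is the periodogram peak location; a constant
    axis is flagged (``is_constant``) with amplitude 0 and frequency NaN
    rather than raising.
    """
    if trace.n < 2:
        raise InvalidParameterError("trace too short for statistics")
    dt = trace.dt
    return TraceStats(_axis_stats(trace.ap, dt), _axis_stats(trace.si, dt))
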