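"""Synthetic chest-IMU cohorts emulating a hospital activity circuit.

Real recordings from oxygen-therapy patients are not publicly available, so
this module generates labelled 6-channel inertial traces (3-axis
accelerometer in g, 3-axis gyroscope in deg/s, 25 Hz) with the statistical
structure needed to exercise every downstream stage: gravity-oriented
postures, harmonic gait oscillations at a per-subject cadence, amplified
stair patterns, and white sensor noise.

Axis convention (chest-worn unit): Y points toward the head and Z along the
walking direction, so gravity appears on -Y when upright and on -X when
lying down.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from enum import Enum, IntEnum
from typing import Optional, Sequence

import numpy as np

__all__ = [
    "Intensity",
    "Activity",
    "ACTIVITY_INTENSITY",
    "ACTIVITY_MET",
    "SubjectParams",
    "CircuitProtocol",
    "ImuTrace",
    "CohortRanges",
    "default_protocol",
    "generate_activity_segment",
    "generate_circuit_session",
    "make_cohort",
]


class Intensity(IntEnum):
    """Three-level physical-activity intensity scheme."""

    SEDENTARY = 0
    LIGHT = 1
    MODERATE = 2


class Activity(str, Enum):
    """Daily activities considered for oxygen-therapy patients."""

    SITTING = "sitting"
    STANDING = "standing"
    LYING = "lying"
    WALKING = "walking"
    UPSTAIRS = "upstairs"
    DOWNSTAIRS = "downstairs"


#: Activity -> intensity class (sedentary postures, level walking, stairs).
ACTIVITY_INTENSITY: dict[Activity, Intensity] = {
    Activity.SITTING: Intensity.SEDENTARY,
    Activity.STANDING: Intensity.SEDENTARY,
    Activity.LYING: Intensity.SEDENTARY,
    Activity.WALKING: Intensity.LIGHT,
    Activity.UPSTAIRS: Intensity.MODERATE,
    Activity.DOWNSTAIRS: Intensity.MODERATE,
}

#: Metabolic cost in MET units; stairs span 3.5-5 MET, we use the midpoint.
ACTIVITY_MET: dict[Activity, float] = {
    Activity.SITTING: 1.3,
    Activity.STANDING: 1.3,
    Activity.LYING: 1.3,
    Activity.WALKING: 2.0,
    Activity.UPSTAIRS: 4.25,
    Activity.DOWNSTAIRS: 4.25,
}


@dataclass(frozen=True)
class SubjectParams:
    """Per-subject gait and sensor parameters.

    Parameters
    ----------
    cadence_hz : walking step frequency in Hz (must lie in (0.5, 3)).
    step_amp_g : vertical acceleration oscillation amplitude while walking, g.
    stair_amp_scale : multiplicative amplitude factor applied on stairs.
    stair_cadence_factor : cadence multiplier on stairs (stair climbing is
        slower than level walking; set to 1.0 for equal-cadence comparisons).
    gyro_amp_dps : angular-rate oscillation amplitude, deg/s.
    pitch_mod_dps : amplitude of the slow torso-pitch modulation added to the
        pitch gyro channel on stairs (positive upstairs, negative downstairs).
    noise_sd_g, noise_sd_dps : white-noise standard deviations.
    posture_tilts : small per-posture gravity-orientation offsets in degrees.
    """

    subject_id: str = "s00"
    cadence_hz: float = 1.8
    step_amp_g: float = 0.35
    stair_amp_scale: float = 1.7
    stair_cadence_factor: float = 0.8
    gyro_amp_dps: float = 40.0
    pitch_mod_dps: float = 10.0
    noise_sd_g: float = 0.03
    noise_sd_dps: float = 1.5
    posture_tilts: dict = field(default_factory=dict)
    seed: int = 0

    def __post_init__(self) -> None:
        if not (0.5 < self.cadence_hz < 3.0):
            raise ValueError(f"cadence_hz must lie in (0.5, 3), got {self.cadence_hz}")
        for name in ("step_amp_g", "stair_amp_scale", "gyro_amp_dps",
                     "pitch_mod_dps", "noise_sd_g", "noise_sd_dps"):
            if getattr(self, name) < 0:
                raise ValueError(f"{name} must be >= 0")


@dataclass(frozen=True)
class CircuitProtocol:
    """Hospital circuit protocol: seated rest, activity circuit, seated rest.

    ``segment_plan`` lists the circuit's (activity, duration-seconds) segments
    in order; their durations must sum to ``circuit_s``.  ``segments_per_lap``
    partitions the plan into laps; after each lap a seated stop of 20-40 s is
    inserted with probability ``stop_probability``.
    """

    rest_before_s: float = 180.0
    circuit_s: float = 720.0
    rest_after_s: float = 180.0
    segment_plan: tuple = ()
    stop_probability: float = 0.0
    segments_per_lap: Optional[int] = None

    def __post_init__(self) -> None:
        if not self.segment_plan:
            raise ValueError("segment_plan must not be empty")
        total = sum(d for _, d in self.segment_plan)
        if abs(total - self.circuit_s) > 1e-9:
            raise ValueError(
                f"segment durations sum to {total}, expected circuit_s={self.circuit_s}"
            )
        if not (0.0 <= self.stop_probability <= 1.0):
            raise ValueError("stop_probability must lie in [0, 1]")


def default_protocol(stop_probability: float = 0.3) -> CircuitProtocol:
    """The default 3 + 12 + 3 minute circuit.

    Six identical 120-s laps, each with level walking interleaved with one
    flight of stairs up and one down, bracketed by 3-min seated rests.
    """
    lap = (
        (Activity.WALKING, 45.0),
        (Activity.UPSTAIRS, 9.0),
        (Activity.WALKING, 39.0),
        (Activity.DOWNSTAIRS, 9.0),
        (Activity.WALKING, 18.0),
    )
    return CircuitProtocol(
        segment_plan=lap * 6,
        stop_probability=stop_probability,
        segments_per_lap=len(lap),
    )


@dataclass
class ImuTrace:
    """Uniformly sampled 6-channel inertial trace with optional labels.

    Channels: ax, ay, az in g; gx, gy, gz in deg/s.  ``labels`` holds one
    :class:`Activity` name per sample when present.
    """

    t: np.ndarray
    ax: np.ndarray
    ay: np.ndarray
    az: np.ndarray
    gx: np.ndarray
    gy: np.ndarray
    gz: np.ndarray
    fs: float = 25.0
    labels: Optional[np.ndarray] = None

    CHANNELS = ("ax", "ay", "az", "gx", "gy", "gz")

    def __post_init__(self) -> None:
        if self.fs <= 0:
            raise ValueError("fs must be positive")
        n = len(self.t)
        for name in self.CHANNELS:
            arr = np.asarray(getattr(self, name), dtype=float)
            if len(arr) != n:
                raise ValueError(f"channel {name} length {len(arr)} != {n}")
            setattr(self, name, arr)
        self.t = np.asarray(self.t, dtype=float)
        if n > 1:
            dt = np.diff(self.t)
            if np.any(dt <= 0):
                raise ValueError("non-monotone time vector")
            if not np.allclose(dt, 1.0 / self.fs, rtol=1e-6, atol=1e-9):
                raise ValueError("time vector step must equal 1/fs")
        if self.labels is not None:
            self.labels = np.asarray(self.labels)
            if len(self.labels) != n:
                raise ValueError("labels length mismatch")

    def __len__(self) -> int:
        return len(self.t)

    def channel_matrix(self) -> np.ndarray:
        """Samples as an (n, 6) array in canonical channel order."""
        return np.column_stack([getattr(self, c) for c in self.CHANNELS])

    @staticmethod
    def concatenate(traces: Sequence["ImuTrace"]) -> "ImuTrace":
        """Join traces end to end on a fresh uniform time grid."""
        if not traces:
            raise ValueError("no traces to concatenate")
        fs = traces[0].fs
        if any(tr.fs != fs for tr in traces):
            raise ValueError("sampling rates differ")
        chans = {
            c: np.concatenate([getattr(tr, c) for tr in traces])
            for c in ImuTrace.CHANNELS
        }
        n = len(chans["ax"])
        labels = None
        if all(tr.labels is not None for tr in traces):
            labels = np.concatenate([tr.labels for tr in traces])
        return ImuTrace(t=np.arange(n) / fs, fs=fs, labels=labels, **chans)


def _gravity(activity: Activity, tilt_deg: float) -> tuple[float, float, float]:
    """Gravity components (ax, ay, az) in g for a posture with a small tilt."""
    th = np.deg2rad(tilt_deg)
    if activity is Activity.LYING:
        return (-np.cos(th), -np.sin(th), 0.0)
    return (0.0, -np.cos(th), -np.sin(th))


def generate_activity_segment(
    activity: Activity,
    duration_s: float,
    subject: SubjectParams,
    seed: Optional[int] = None,
    fs: float = 25.0,
) -> ImuTrace:
    """Generate one labelled constant-activity segment.

    Sedentary postures are a gravity-oriented constant plus noise; walking
    adds harmonics at the cadence and twice the cadence on the Y/Z
    accelerometer axes with per-step gyroscope oscillation; stairs reuse the
    walking pattern with ``stair_amp_scale`` applied, a slower cadence, and a
    slow torso-pitch modulation on the pitch gyro channel.  Deterministic
    given ``seed`` (defaults to ``subject.seed``).
    """
    if duration_s <= 0:
        raise ValueError("duration_s must be positive")
    activity = Activity(activity)
    if seed is None:
        seed = subject.seed
    rng = np.random.default_rng(seed)
    n = int(round(duration_s * fs))
    t = np.arange(n) / fs
    # Phases are drawn before noise with a fixed count so that walking and
    # stair segments from the same seed share step phase exactly.
    phases = rng.uniform(0.0, 2.0 * np.pi, size=6)

    tilt = float(subject.posture_tilts.get(activity.value, 0.0))
    gvec = _gravity(activity, tilt)
    acc = np.zeros((n, 3))
    gyr = np.zeros((n, 3))
    acc[:, 0] += gvec[0]
    acc[:, 1] += gvec[1]
    acc[:, 2] += gvec[2]

    intensity = ACTIVITY_INTENSITY[activity]
    if intensity != Intensity.SEDENTARY:
        if intensity == Intensity.MODERATE:
            amp = subject.step_amp_g * subject.stair_amp_scale
            gamp = subject.gyro_amp_dps * subject.stair_amp_scale
            f = subject.cadence_hz * subject.stair_cadence_factor
        else:
            amp = subject.step_amp_g
            gamp = subject.gyro_amp_dps
            f = subject.cadence_hz
        w = 2.0 * np.pi * f * t
        # Dominant harmonic at the cadence, weaker second harmonic.
        acc[:, 2] += amp * np.sin(w + phases[0]) + 0.4 * amp * np.sin(2 * w + phases[1])
        acc[:, 1] += 0.6 * amp * np.sin(w + phases[2]) + 0.3 * amp * np.sin(
            2 * w + phases[3]
        )
        acc[:, 0] += 0.25 * amp * np.sin(0.5 * w + phases[4])  # lateral sway
        gyr[:, 0] += gamp * np.sin(w + phases[5])
        gyr[:, 1] += 0.5 * gamp * np.sin(w + phases[0] + 1.0)
        gyr[:, 2] += 0.35 * gamp * np.sin(w + phases[1] + 2.0)
        if intensity == Intensity.MODERATE:
            sign = 1.0 if activity is Activity.UPSTAIRS else -1.0
            gyr[:, 0] += sign * subject.pitch_mod_dps * np.sin(2.0 * np.pi * 0.2 * t)

    acc += rng.normal(0.0, subject.noise_sd_g, size=(n, 3))
    gyr += rng.normal(0.0, subject.noise_sd_dps, size=(n, 3))

    labels = np.full(n, activity.value, dtype="U10")
    return ImuTrace(
        t=t,
        ax=acc[:, 0], ay=acc[:, 1], az=acc[:, 2],
        gx=gyr[:, 0], gy=gyr[:, 1], gz=gyr[:, 2],
        fs=fs, labels=labels,
    )


def generate_circuit_session(
    subject: SubjectParams,
    protocol: Optional[CircuitProtocol] = None,
    seed: Optional[int] = None,
) -> ImuTrace:
    """One full labelled session: rest, circuit (with optional stops), rest.

    Seated stops of 20-40 s are inserted after each lap with the protocol's
    ``stop_probability``, so the total duration is at least
    ``rest_before_s + circuit_s + rest_after_s``.
    """
    if protocol is None:
        protocol = default_protocol()
    if not protocol.segment_plan:
        raise ValueError("segment_plan must not be empty")
    if seed is None:
        seed = subject.seed
    rng = np.random.default_rng(seed)

    def seg_seed() -> int:
        return int(rng.integers(0, 2**31))

    pieces = [
        generate_activity_segment(
            Activity.SITTING, protocol.rest_before_s, subject, seg_seed()
        )
    ]
    per_lap = protocol.segments_per_lap or len(protocol.segment_plan)
    for i, (activity, dur) in enumerate(protocol.segment_plan):
        pieces.append(generate_activity_segment(activity, dur, subject, seg_seed()))
        lap_end = (i + 1) % per_lap == 0
        if lap_end and protocol.stop_probability > 0:
            if rng.random() < protocol.stop_probability:
                stop_dur = float(rng.integers(20, 41))
                pieces.append(
                    generate_activity_segment(
                        Activity.SITTING, stop_dur, subject, seg_seed()
                    )
                )
    pieces.append(
        generate_activity_segment(
            Activity.SITTING, protocol.rest_after_s, subject, seg_seed()
        )
    )
    return ImuTrace.concatenate(pieces)


@dataclass(frozen=True)
class CohortRanges:
    """Uniform sampling ranges for per-subject parameters.

    Defaults give walking amplitudes of 0.28-0.42 g and stair amplification
    of 1.5-1.9, i.e. stair vertical oscillations roughly 1.5-2x level
    walking, with mild sensor noise.
    """

    cadence_hz: tuple = (1.4, 2.2)
    step_amp_g: tuple = (0.28, 0.42)
    stair_amp_scale: tuple = (1.5, 1.9)
    gyro_amp_dps: tuple = (25.0, 60.0)
    pitch_mod_dps: tuple = (6.0, 14.0)
    noise_sd_g: tuple = (0.02, 0.05)
    noise_sd_dps: tuple = (0.8, 2.0)
    tilt_deg: tuple = (0.0, 8.0)


def make_cohort(
    n_subjects: int = 18,
    base: Optional[CohortRanges] = None,
    seed: int = 0,
    protocol: Optional[CircuitProtocol] = None,
) -> list[tuple[SubjectParams, ImuTrace]]:
    """Generate a cohort of labelled circuit sessions.

    Each subject's gait parameters are drawn uniformly from ``base`` with a
    per-subject seed derived from ``(seed, index)``, so cohorts are
    reproducible subject by subject.  Requires at least two subjects
    (leave-one-subject-out evaluation needs >= 2).
    """
    if n_subjects < 2:
        raise ValueError("n_subjects must be >= 2")
    if base is None:
        base = CohortRanges()
    if protocol is None:
        protocol = default_protocol()

    cohort = []
    for i in range(n_subjects):
        ss = np.random.SeedSequence([int(seed), i])
        subject_seed = int(ss.generate_state(1)[0] & 0x7FFFFFFF)
        rng = np.random.default_rng(ss)

        def u(lo_hi: tuple) -> float:
            return float(rng.uniform(*lo_hi))

        tilts = {
            a.value: u(base.tilt_deg)
            for a in (Activity.SITTING, Activity.STANDING, Activity.LYING)
        }
        params = SubjectParams(
            subject_id=f"s{i:02d}",
            cadence_hz=u(base.cadence_hz),
            step_amp_g=u(base.step_amp_g),
            stair_amp_scale=u(base.stair_amp_scale),
            gyro_amp_dps=u(base.gyro_amp_dps),
            pitch_mod_dps=u(base.pitch_mod_dps),
            noise_sd_g=u(base.noise_sd_g),
            noise_sd_dps=u(base.noise_sd_dps),
            posture_tilts=tilts,
            seed=subject_seed,
        )
        trace = generate_circuit_session(params, protocol, seed=subject_seed)
        cohort.append((params, trace))
    return cohort
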