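"""Flow control: Mealy FSM safety layer, therapy profiles, pulse dosing.

The controller maps each classified activity-intensity window to a pulse
setting through a physician-chosen therapy profile (a lookup table), with a
Mealy finite-state machine in between that moves the delivered intensity at
most one level per window.  This prevents abrupt flow jumps (e.g. sedentary
to moderate in a single step) while still converging to any sustained
intensity within two windows.

Pulse-dose delivery at reference conditions (20 degC, sea level): the
concentrator delivers 180 mL/min per pulse-setting level, split evenly over
breaths, so one bolus is 180 * setting / bpm millilitres.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Optional, Sequence

import numpy as np

from oxiflow.evaluation import round_half_up
from oxiflow.synthetic_data import Intensity

__all__ = [
    "PROFILE_TABLE",
    "TherapyProfile",
    "FsmState",
    "FlowTimeline",
    "Spo2Report",
    "fsm_step",
    "profile_lookup",
    "bolus_volume",
    "run_closed_loop",
    "adherence_rate",
    "spo2_summary",
]

#: Seven selectable therapy profiles: intensity -> pulse setting
#: (sedentary, light, moderate).  Settings are non-decreasing in intensity.
PROFILE_TABLE: dict[int, tuple[int, int, int]] = {
    1: (1, 2, 4),
    2: (1, 3, 5),
    3: (1, 4, 5),
    4: (2, 4, 5),
    5: (3, 4, 5),
    6: (0, 2, 5),
    7: (0, 1, 4),
}

#: Per-setting minute volume in mL/min (level 0 delivers no pulse).
ML_PER_MIN_PER_SETTING = 180.0


@dataclass(frozen=True)
class TherapyProfile:
    """One row of the personalisation table: intensity -> pulse setting."""

    profile_id: int
    settings: tuple[int, int, int]

    def __post_init__(self) -> None:
        if not (1 <= self.profile_id <= 7):
            raise ValueError("profile_id must lie in 1..7")
        if len(self.settings) != 3:
            raise ValueError("settings must map the three intensity classes")
        if any(not (0 <= s <= 5) for s in self.settings):
            raise ValueError("pulse settings must lie in 0..5")
        if list(self.settings) != sorted(self.settings):
            raise ValueError("settings must be non-decreasing in intensity")

    @classmethod
    def from_id(cls, profile_id: int) -> "TherapyProfile":
        if profile_id not in PROFILE_TABLE:
            raise ValueError(f"unknown therapy profile {profile_id}; valid ids are 1..7")
        return cls(profile_id=profile_id, settings=PROFILE_TABLE[profile_id])

    def setting_for(self, intensity: Intensity) -> int:
        return self.settings[int(Intensity(intensity))]


@dataclass
class FsmState:
    """Current delivered intensity level of the safety FSM."""

    current: Intensity = Intensity.SEDENTARY

    def __post_init__(self) -> None:
        self.current = Intensity(self.current)


def profile_lookup(profile_id: int, intensity: Intensity) -> int:
    """Pulse setting for one (profile, intensity) cell of the lookup table."""
    return TherapyProfile.from_id(profile_id).setting_for(intensity)


def fsm_step(
    state: FsmState, observed: Intensity, profile: TherapyProfile
) -> tuple[FsmState, int]:
    """One Mealy FSM transition: move at most one level toward ``observed``.

    Returns the new state and the emitted pulse setting (the profile entry
    of the new state).  Equal observed and current intensity leaves the
    state unchanged.
    """
    cur = int(state.current)
    obs = int(Intensity(observed))
    step = int(np.sign(obs - cur))
    new = Intensity(cur + step)
    return FsmState(current=new), profile.setting_for(new)


def bolus_volume(setting, bpm: float) -> float:
    """Bolus volume in mL at a pulse setting and breathing rate.

    Reference-condition model: 180 mL/min per setting level spread evenly
    over breaths, i.e. ``180 * level / bpm`` (12 mL per level at 15 bpm).
    """
    level = int(setting)
    if not (0 <= level <= 5):
        raise ValueError("pulse setting must lie in 0..5")
    if bpm <= 0:
        raise ValueError("breathing rate must be positive")
    return ML_PER_MIN_PER_SETTING * level / bpm


@dataclass
class FlowTimeline:
    """Per-window controller trajectory over a classified stream.

    ``latencies`` records, for each observed intensity transition, the number
    of windows from the first changed observation until the FSM settles on
    the target level.
    """

    times_s: np.ndarray
    observed: np.ndarray
    states: np.ndarray
    settings: np.ndarray
    adjustments: int
    latencies: list = field(default_factory=list)


def run_closed_loop(
    classified_stream: Sequence,
    profile: TherapyProfile,
    initial: Optional[FsmState] = None,
    window_s: float = 3.0,
    debounce: int = 1,
) -> FlowTimeline:
    """Fold the FSM over a stream of classified windows.

    ``debounce`` requires that many consecutive identical observations
    before the FSM moves (default 1 = react immediately); the one-level-
    per-window limit applies regardless.
    """
    stream = [Intensity(c) for c in classified_stream]
    if not stream:
        raise ValueError("empty classified stream")
    if debounce < 1:
        raise ValueError("debounce must be >= 1")
    state = initial if initial is not None else FsmState(stream[0])
    states, settings = [], []
    run_len = 0
    last_obs = None
    pending = None  # (target, start_index) of an in-flight transition
    latencies = []
    for i, obs in enumerate(stream):
        run_len = run_len + 1 if obs == last_obs else 1
        last_obs = obs
        if obs != state.current and (pending is None or pending[0] != obs):
            pending = (obs, i)
        if obs != state.current and run_len >= debounce:
            state, setting = fsm_step(state, obs, profile)
        else:
            setting = profile.setting_for(state.current)
        if pending is not None and state.current == pending[0]:
            latencies.append(
                {"target": pending[0], "start": pending[1], "windows": i - pending[1] + 1}
            )
            pending = None
        states.append(int(state.current))
        settings.append(setting)
    settings_arr = np.array(settings)
    adjustments = int(np.sum(np.diff(settings_arr) != 0))
    return FlowTimeline(
        times_s=np.arange(len(stream)) * window_s,
        observed=np.array([int(c) for c in stream]),
        states=np.array(states),
        settings=settings_arr,
        adjustments=adjustments,
        latencies=latencies,
    )


def adherence_rate(performed: int, needed: int) -> float:
    """Percentage of needed flow adjustments actually performed (1 decimal)."""
    if needed <= 0:
        raise ValueError("needed must be positive")
    if not (0 <= performed <= needed):
        raise ValueError("performed must lie in [0, needed]")
    return round_half_up(100.0 * performed / needed, 1)


@dataclass(frozen=True)
class Spo2Report:
    """Oximetry summary: CT90/CT85 (% of time below 90/85%), mean, min,
    and the count of desaturation events."""

    ct90: float
    ct85: float
    mean: float
    min: float
    events: int

    def __post_init__(self) -> None:
        if not (0.0 <= self.ct85 <= self.ct90 <= 100.0):
            raise ValueError("need 0 <= ct85 <= ct90 <= 100")


def spo2_summary(
    spo2: Sequence[float],
    t: Optional[Sequence[float]] = None,
    event_threshold: float = 90.0,
    min_event_s: float = 10.0,
    min_recovery_s: float = 10.0,
) -> Spo2Report:
    """Summarise an SpO2 time series (uniformly sampled, percent units).

    CTxx is the percentage of samples below xx%.  A desaturation event is a
    maximal run below ``event_threshold`` lasting at least ``min_event_s``;
    runs separated by less than ``min_recovery_s`` of recovery merge into
    one event.
    """
    spo2 = np.asarray(spo2, dtype=float)
    if spo2.size == 0:
        raise ValueError("empty SpO2 series")
    if np.any((spo2 < 0) | (spo2 > 100)):
        raise ValueError("SpO2 values must lie in [0, 100]")
    if t is None:
        dt = 1.0
    else:
        t = np.asarray(t, dtype=float)
        if t.shape != spo2.shape:
            raise ValueError("t and spo2 length mismatch")
        dt = float(np.median(np.diff(t))) if t.size > 1 else 1.0

    ct90 = 100.0 * float(np.mean(spo2 < 90.0))
    ct85 = 100.0 * float(np.mean(spo2 < 85.0))

    below = spo2 < event_threshold
    runs: list[tuple[int, int]] = []
    start = None
    for i, b in enumerate(below):
        if b and start is None:
            start = i
        elif not b and start is not None:
            runs.append((start, i))
            start = None
    if start is not None:
        runs.append((start, below.size))
    # merge episodes separated by less than min_recovery_s of recovery
    merged: list[list[int]] = []
    for s, e in runs:
        if merged and (s - merged[-1][1]) * dt < min_recovery_s:
            merged[-1][1] = e
        else:
            merged.append([s, e])
    events = sum(1 for s, e in merged if (e - s) * dt >= min_event_s)

    return Spo2Report(
        ct90=ct90,
        ct85=ct85,
        mean=float(np.mean(spo2)),
        min=float(np.min(spo2)),
        events=events,
    )
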