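"""Deterministic meal-cycle state machine with PLR and EMG triggers.

One meal cycle: the user gazes at the continuously lit LED 4 until a
sustained pupil constriction is detected (PLR start trigger); after a 2 s
pause the four LEDs flicker for 4.5 s and the decoder selects the food; the
grab arm fetches the morsel, the spoon arm lifts it, and chewing (temporal
EMG burst) — or, for safety, a fixed 10 s timeout — lowers the spoon and
returns the system to standby.  The PLR trigger is armed only in STANDBY and
the EMG trigger only while LIFTED.  Robot commands are emitted as symbolic
strings; illegal events are logged and ignored, never fatal.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from enum import Enum

import numpy as np
from scipy import signal as sps

__all__ = [
    "State",
    "TriggerEvent",
    "MealCycleState",
    "plr_start_trigger",
    "emg_chew_trigger",
    "step_fsm",
    "run_event_tape",
    "LIFT_TIMEOUT",
]

LIFT_TIMEOUT = 10.0     # s; safety: spoon lowers even without EMG
FLICKER_DELAY = 2.0     # s between PLR confirmation and flicker start
FLICKER_DURATION = 4.5  # s


class State(Enum):
    STANDBY = "STANDBY"
    PLR_CONFIRMED = "PLR_CONFIRMED"
    FLICKER = "FLICKER"
    SELECTING = "SELECTING"
    GRAB = "GRAB"
    LIFTED = "LIFTED"
    LOWERING = "LOWERING"


@dataclass(frozen=True)
class TriggerEvent:
    kind: str  # "plr_start" | "emg_chew" | "timeout" | "tick" | ...
    time: float


@dataclass
class MealCycleState:
    state: State = State.STANDBY
    state_entered: float = 0.0
    log: list[str] = field(default_factory=list)

    def armed(self, kind: str) -> bool:
        if kind == "plr_start":
            return self.state is State.STANDBY
        if kind == "emg_chew":
            return self.state is State.LIFTED
        return True


def plr_start_trigger(diameter: np.ndarray, rate: float,
                      gaze_hold: float = 4.5,
                      constriction_level: float = 0.95) -> TriggerEvent | None:
    """Fire when sustained constriction persists for ``gaze_hold`` seconds.

    ``diameter`` is the baseline-normalised pupil series while LED 4 is lit;
    constriction is any sample below ``constriction_level``.  Returns the
    event at the end of the first qualifying hold, or ``None``.
    """
    below = np.asarray(diameter) < constriction_level
    need = int(round(gaze_hold * rate))
    run = 0
    for i, b in enumerate(below):
        run = run + 1 if b else 0
        if run >= need:
            return TriggerEvent("plr_start", (i + 1) / rate)
    return None


def emg_chew_trigger(emg: np.ndarray, rate: float,
                     band: tuple[float, float] = (20.0, 124.0),
                     envelope_threshold_k: float = 5.0,
                     baseline: float = 1.0,
                     sustain: float = 0.1) -> TriggerEvent | None:
    """Band-pass, rectify, smooth; fire at the first sustained crossing.

    The threshold is ``k`` times the SD of the envelope over the first
    ``baseline`` seconds; the crossing must persist for ``sustain`` seconds.
    """
    x = np.asarray(emg, dtype=float)
    if x.ndim == 2:
        x = x.mean(axis=0)
    hi = min(band[1], rate / 2 - 1)
    sos = sps.butter(4, (band[0], hi), btype="bandpass", fs=rate, output="sos")
    filt = sps.sosfiltfilt(sos, x)
    env = np.abs(filt)
    smooth_n = max(1, int(round(0.05 * rate)))
    kernel = np.ones(smooth_n) / smooth_n
    env = np.convolve(env, kernel, mode="same")
    nb = int(round(baseline * rate))
    thr = envelope_threshold_k * env[:nb].std() + env[:nb].mean()
    if not np.isfinite(thr):
        return None
    above = env > thr
    need = int(round(sustain * rate))
    run = 0
    for i in range(nb, above.size):
        run = run + 1 if above[i] else 0
        if run >= need:
            return TriggerEvent("emg_chew", (i - need + 1) / rate)
    return None


#: commands emitted on entry to each state
_COMMANDS = {
    State.PLR_CONFIRMED: "led4_off",
    State.FLICKER: "leds_flicker",
    State.SELECTING: "decode_selection",
    State.GRAB: "grab_arm_fetch",
    State.LIFTED: "spoon_arm_lift",
    State.LOWERING: "spoon_arm_lower",
    State.STANDBY: "led4_on",
}


def step_fsm(mcs: MealCycleState, event: TriggerEvent
             ) -> tuple[MealCycleState, str | None]:
    """Advance the machine by one event (trigger or clock tick).

    Returns the updated state and the robot command emitted, if any.
    Timed transitions (flicker start, flicker end, lift timeout) fire on
    ``tick`` events carrying the current wall-clock time.
    """
    s, t = mcs.state, event.time
    new: State | None = None
    if event.kind == "plr_start":
        if mcs.armed("plr_start"):
            new = State.PLR_CONFIRMED
        else:
            mcs.log.append(f"t={t:.2f} ignored plr_start in {s.value}")
    elif event.kind == "emg_chew":
        if mcs.armed("emg_chew"):
            new = State.LOWERING
        else:
            mcs.log.append(f"t={t:.2f} ignored emg_chew in {s.value}")
    elif event.kind == "selection_done":
        if s is State.SELECTING:
            new = State.GRAB
        else:
            mcs.log.append(f"t={t:.2f} ignored selection_done in {s.value}")
    elif event.kind == "grab_done":
        if s is State.GRAB:
            new = State.LIFTED
        else:
            mcs.log.append(f"t={t:.2f} ignored grab_done in {s.value}")
    elif event.kind == "lower_done":
        if s is State.LOWERING:
            new = State.STANDBY
        else:
            mcs.log.append(f"t={t:.2f} ignored lower_done in {s.value}")
    elif event.kind in ("tick", "timeout"):
        elapsed = t - mcs.state_entered
        if s is State.PLR_CONFIRMED and elapsed >= FLICKER_DELAY:
            new = State.FLICKER
        elif s is State.FLICKER and elapsed >= FLICKER_DURATION:
            new = State.SELECTING
        elif s is State.LIFTED and elapsed >= LIFT_TIMEOUT:
            new = State.LOWERING
            mcs.log.append(f"t={t:.2f} lift timeout; lowering for safety")
    else:
        mcs.log.append(f"t={t:.2f} unknown event {event.kind!r} ignored")
    if new is None:
        return mcs, None
    mcs.state = new
    mcs.state_entered = t
    cmd = _COMMANDS.get(new)
    mcs.log.append(f"t={t:.2f} -> {new.value} ({cmd})")
    return mcs, cmd


def run_event_tape(events: list[TriggerEvent],
                   tick_dt: float = 0.1) -> tuple[list[State], list[str]]:
    """Replay an event tape, interleaving clock ticks; deterministic."""
    mcs = MealCycleState()
    visited = [mcs.state]
    commands: list[str] = []
    t = 0.0
    queue = sorted(events, key=lambda e: e.time)
    end = (queue[-1].time if queue else 0.0) + LIFT_TIMEOUT + 1.0
    qi = 0
    while t <= end:
        while qi < len(queue) and queue[qi].time <= t:
            mcs, cmd = step_fsm(mcs, queue[qi])
            if cmd:
                commands.append(cmd)
            if visited[-1] is not mcs.state:
                visited.append(mcs.state)
            qi += 1
        mcs, cmd = step_fsm(mcs, TriggerEvent("tick", t))
        if cmd:
            commands.append(cmd)
        if visited[-1] is not mcs.state:
            visited.append(mcs.state)
        t = round(t + tick_dt, 10)
    return visited, commands
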