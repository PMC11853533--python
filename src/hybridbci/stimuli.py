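"""Four-LED stimulus schedules and the trial protocol.

Two stimulation modes are supported:

* ``frequency`` — each LED flickers as a 50 % duty-cycle square wave at a
  fixed frequency (6.6, 7.5, 8.57, 10 Hz), the classic SSVEP bank.
* ``pattern`` — each LED follows a distinct slow on/off luminance pattern
  (different start delays, phase lengths, and for two LEDs a full turn-off at
  2.5 s) chosen so that the pupillary responses to the four LEDs are
  distinguishable while every luminance transition still evokes a flash VEP.

Transition times are enumerated exactly on a millisecond grid using
:class:`fractions.Fraction`, so schedules regenerate bit-identically and no
float drift can move an epoch boundary.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from fractions import Fraction
from pathlib import Path

import yaml

__all__ = [
    "LEDPattern",
    "StimulusSchedule",
    "TrialProtocol",
    "build_default_schedule",
    "transitions_in_window",
    "SSVEP_BANK",
]

#: Default SSVEP frequency bank, LED 1..4 (Hz).
SSVEP_BANK = (6.6, 7.5, 8.57, 10.0)

_MS = Fraction(1, 1000)


@dataclass(frozen=True)
class LEDPattern:
    """Luminance rule for one LED over one trial."""

    led_id: int
    mode: str                      # "frequency" | "pattern"
    trial_length_ms: int = 5000
    frequency: float | None = None # Hz, frequency mode
    start_delay_ms: int = 0
    on_ms: int | None = None       # pattern mode
    off_ms: int | None = None
    full_off_at_ms: int | None = None  # trial-relative time the LED goes dark

    def __post_init__(self) -> None:
        if not 1 <= self.led_id <= 4:
            raise ValueError(f"led_id must be 1-4, got {self.led_id}")
        if self.mode not in ("frequency", "pattern"):
            raise ValueError(f"unknown mode {self.mode!r}")
        if self.start_delay_ms < 0:
            raise ValueError("start_delay must be >= 0")
        if self.mode == "pattern":
            if not (self.on_ms and self.on_ms > 0 and self.off_ms and self.off_ms > 0):
                raise ValueError("pattern mode needs on_ms > 0 and off_ms > 0")
        else:
            if not self.frequency or self.frequency <= 0:
                raise ValueError("frequency mode needs a positive frequency")
        if self.full_off_at_ms is not None and self.full_off_at_ms > self.trial_length_ms:
            raise ValueError("full_off_at must be within the trial")

    def transitions(self) -> tuple[list[Fraction], list[Fraction]]:
        """Exact (onsets, offsets) in seconds as Fractions.

        The full-off cutoff is trial-relative.  An on-phase truncated by the
        cutoff keeps its onset and the forced darkening is recorded as an
        offset, so FVEP offset epochs see every dark transition.
        """
        end = Fraction(self.trial_length_ms) * _MS
        cut = (Fraction(self.full_off_at_ms) * _MS
               if self.full_off_at_ms is not None else end)
        if self.mode == "pattern":
            on = Fraction(self.on_ms) * _MS
            off = Fraction(self.off_ms) * _MS
            t = Fraction(self.start_delay_ms) * _MS
        else:
            period = 1 / Fraction(str(self.frequency))
            on = off = period / 2
            t = Fraction(self.start_delay_ms) * _MS
        onsets: list[Fraction] = []
        offsets: list[Fraction] = []
        while t < cut and t < end:
            onsets.append(t)
            t_off = t + on
            if t_off >= cut:
                offsets.append(cut)
                break
            if t_off >= end:
                break
            offsets.append(t_off)
            t = t_off + off
        return onsets, offsets

    def luminance(self, t: float) -> int:
        """Binary luminance at time ``t`` seconds from trial start."""
        onsets, offsets = self.transitions()
        n_on = sum(1 for x in onsets if float(x) <= t)
        n_off = sum(1 for x in offsets if float(x) <= t)
        return int(n_on > n_off)


@dataclass(frozen=True)
class StimulusSchedule:
    """The four per-LED luminance rules of one trial."""

    patterns: tuple[LEDPattern, LEDPattern, LEDPattern, LEDPattern]

    def __post_init__(self) -> None:
        ids = [p.led_id for p in self.patterns]
        if sorted(ids) != [1, 2, 3, 4]:
            raise ValueError(f"patterns must cover LEDs 1-4 exactly, got {ids}")

    def pattern(self, led: int) -> LEDPattern:
        for p in self.patterns:
            if p.led_id == led:
                return p
        raise KeyError(f"led {led} not in 1-4")

    def onsets(self, led: int) -> list[float]:
        return [float(t) for t in self.pattern(led).transitions()[0]]

    def offsets(self, led: int) -> list[float]:
        return [float(t) for t in self.pattern(led).transitions()[1]]

    def luminance(self, led: int, t: float) -> int:
        return self.pattern(led).luminance(t)

    @property
    def trial_length(self) -> float:
        return self.patterns[0].trial_length_ms / 1000.0

    # -- serialization ------------------------------------------------------

    def to_dict(self) -> dict:
        leds = {}
        for p in self.patterns:
            leds[f"led{p.led_id}"] = {
                "mode": p.mode,
                "frequency_hz": p.frequency,
                "delay_ms": p.start_delay_ms,
                "on_ms": p.on_ms,
                "off_ms": p.off_ms,
                "full_off_ms": p.full_off_at_ms,
                "trial_ms": p.trial_length_ms,
            }
        return leds

    @classmethod
    def from_dict(cls, d: dict) -> "StimulusSchedule":
        pats = []
        for led in range(1, 5):
            cfg = d[f"led{led}"]
            pats.append(LEDPattern(
                led_id=led, mode=cfg["mode"],
                frequency=cfg.get("frequency_hz"),
                start_delay_ms=cfg.get("delay_ms", 0),
                on_ms=cfg.get("on_ms"), off_ms=cfg.get("off_ms"),
                full_off_at_ms=cfg.get("full_off_ms"),
                trial_length_ms=cfg.get("trial_ms", 5000)))
        return cls(tuple(pats))

    def save(self, path: str | Path) -> None:
        path = Path(path)
        text = (yaml.safe_dump(self.to_dict()) if path.suffix in (".yml", ".yaml")
                else json.dumps(self.to_dict(), indent=2))
        path.write_text(text)

    @classmethod
    def load(cls, path: str | Path) -> "StimulusSchedule":
        path = Path(path)
        text = path.read_text()
        d = yaml.safe_load(text) if path.suffix in (".yml", ".yaml") else json.loads(text)
        return cls.from_dict(d)

    def event_table(self) -> list[tuple[float, int, str]]:
        """All transitions as (time_s, led_id, 'on'|'off'), time-sorted."""
        rows = []
        for p in self.patterns:
            ons, offs = p.transitions()
            rows += [(float(t), p.led_id, "on") for t in ons]
            rows += [(float(t), p.led_id, "off") for t in offs]
        rows.sort(key=lambda r: (r[0], r[1], r[2]))
        return rows

    def save_events_tsv(self, path: str | Path) -> None:
        lines = ["time_s\tled_id\ttransition"]
        lines += [f"{t:.6f}\t{led}\t{kind}" for t, led, kind in self.event_table()]
        Path(path).write_text("\n".join(lines) + "\n")


@dataclass(frozen=True)
class TrialProtocol:
    """Timing of one experimental block."""

    cue_duration: float = 2.0
    stimulus_duration: float = 5.0
    rest_duration: float = 3.0
    analysis_window: tuple[float, float] = (0.0, 4.5)
    n_trials: int = 60
    target_sequence: tuple[int, ...] = ()

    def __post_init__(self) -> None:
        if self.analysis_window[1] > self.stimulus_duration:
            raise ValueError("analysis window must end within the stimulus")
        if self.target_sequence and len(self.target_sequence) != self.n_trials:
            raise ValueError("target_sequence length must equal n_trials")


def build_default_schedule(mode: str) -> StimulusSchedule:
    """The default four-LED schedule for either stimulation mode.

    Pattern mode: LED 1 starts immediately, 500/500 ms; LED 2 starts after
    500 ms, 350/350 ms, dark from 2.5 s; LED 3 starts after 500 ms,
    450/450 ms; LED 4 starts immediately, 400/400 ms, dark from 2.5 s.
    Frequency mode: 6.6 / 7.5 / 8.57 / 10 Hz square waves for the full 5 s.
    """
    if mode == "pattern":
        pats = (
            LEDPattern(1, "pattern", on_ms=500, off_ms=500),
            LEDPattern(2, "pattern", start_delay_ms=500, on_ms=350, off_ms=350,
                       full_off_at_ms=2500),
            LEDPattern(3, "pattern", start_delay_ms=500, on_ms=450, off_ms=450),
            LEDPattern(4, "pattern", on_ms=400, off_ms=400, full_off_at_ms=2500),
        )
    elif mode == "frequency":
        pats = tuple(LEDPattern(i + 1, "frequency", frequency=f)
                     for i, f in enumerate(SSVEP_BANK))
    else:
        raise ValueError(f"unknown stimulation mode {mode!r}; "
                         "expected 'frequency' or 'pattern'")
    return StimulusSchedule(pats)  # type: ignore[arg-type]


def transitions_in_window(schedule: StimulusSchedule, led: int,
                          t0: float, t1: float) -> tuple[list[float], list[float]]:
    """Transition times of one LED inside ``[t0, t1)``, in order."""
    if not 1 <= led <= 4:
        raise ValueError(f"led must be 1-4, got {led}")
    ons = [t for t in schedule.onsets(led) if t0 <= t < t1]
    offs = [t for t in schedule.offsets(led) if t0 <= t < t1]
    return ons, offs
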