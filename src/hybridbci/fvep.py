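"""Dry-EEG flash-VEP pipeline.

Because the four LEDs follow different slow luminance patterns, a fixed
epoch grid cannot separate them.  Instead, for every LED the trial is epoched
at *that LED's* luminance transitions (-100 to +350 ms), onset and offset
epochs are averaged separately, and the peak-to-valley amplitude of each
average is the feature: a trial that was actually gazed at LED k shows a
locked transient in LED k's average and washed-out noise in the other three.
Four binary SVMs (one per LED, grid-searched RBF) each judge whether their
LED's feature pair looks like a target; the final four-class decision is the
argmax of the signed SVM margins.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from sklearn.model_selection import GridSearchCV
from sklearn.pipeline import Pipeline
from sklearn.preprocessing import StandardScaler
from sklearn.svm import SVC

from .sigproc import MultichannelSegment, epoch
from .stimuli import StimulusSchedule

__all__ = [
    "FVEP_CHANNELS",
    "FVEPFeatureVector",
    "BinaryLEDModel",
    "averaged_fvep",
    "peak_to_valley",
    "extract_trial_features",
    "train_led_models",
    "combine_decisions",
]

FVEP_CHANNELS = ("Pz", "O1", "O2")
EPOCH_WINDOW = (-100.0, 350.0)  # ms around each transition
DEFAULT_GRID = {
    "svc__C": [0.1, 1.0, 10.0, 100.0],
    "svc__gamma": ["scale", 0.1, 1.0],
}


@dataclass
class FVEPFeatureVector:
    """Per-LED (onset, offset) averaged peak-to-valley amplitudes (uV)."""

    per_led: dict[int, tuple[float, float]]
    n_epochs_used: dict[int, tuple[int, int]]

    def pair(self, led: int) -> np.ndarray:
        return np.asarray(self.per_led[led], dtype=float)


@dataclass
class BinaryLEDModel:
    led_id: int
    estimator: Pipeline
    grid: dict
    selected: dict
    cv_score: float

    def margin(self, pair: np.ndarray) -> float:
        return float(self.estimator.decision_function(pair.reshape(1, -1))[0])


def averaged_fvep(eeg: MultichannelSegment, schedule: StimulusSchedule,
                  led: int, transition: str,
                  onset_shift: float = 0.0) -> MultichannelSegment:
    """Average of the -100..+350 ms epochs at one LED's on or off transitions.

    ``onset_shift`` moves the schedule's clock (used when re-epoching from a
    detected task onset).  The input should already be band-passed and
    restricted to the FVEP channels.
    """
    if transition not in ("onset", "offset"):
        raise ValueError(f"transition must be 'onset' or 'offset', got {transition!r}")
    events = schedule.onsets(led) if transition == "onset" else schedule.offsets(led)
    events = [onset_shift + e for e in events]
    epochs, _dropped = epoch(eeg, events, EPOCH_WINDOW)
    if not epochs:
        raise ValueError(
            f"no usable {transition} epochs for LED {led}: all "
            f"{len(events)} events fall outside the recorded segment")
    stack = np.stack([e.samples for e in epochs])
    return MultichannelSegment(stack.mean(axis=0), eeg.rate,
                               list(eeg.channel_labels),
                               EPOCH_WINDOW[0] / 1000.0)


def peak_to_valley(avg: MultichannelSegment,
                   search_window: tuple[float, float] = (0.0, 350.0)) -> float:
    """max - min of the channel-averaged waveform in the post-transition window.

    ``search_window`` is in ms relative to the transition; the epoch's ``t0``
    encodes the pre-stimulus offset.  Invariant to a constant baseline shift.
    """
    lo, hi = (search_window[0] / 1000.0, search_window[1] / 1000.0)
    times = avg.times
    mask = (times >= lo) & (times < hi)
    if not mask.any():
        raise ValueError("empty peak-to-valley search window")
    wave = avg.samples.mean(axis=0)[mask]
    return float(wave.max() - wave.min())


def extract_trial_features(eeg: MultichannelSegment, schedule: StimulusSchedule,
                           onset_shift: float = 0.0) -> FVEPFeatureVector:
    """One (onset_p2v, offset_p2v) pair per LED, label-blind."""
    per_led: dict[int, tuple[float, float]] = {}
    n_used: dict[int, tuple[int, int]] = {}
    for led in range(1, 5):
        pair = []
        counts = []
        for transition in ("onset", "offset"):
            avg = averaged_fvep(eeg, schedule, led, transition, onset_shift)
            pair.append(peak_to_valley(avg))
            events = (schedule.onsets(led) if transition == "onset"
                      else schedule.offsets(led))
            counts.append(len(events))
        per_led[led] = (pair[0], pair[1])
        n_used[led] = (counts[0], counts[1])
    return FVEPFeatureVector(per_led=per_led, n_epochs_used=n_used)


def train_led_models(features: list[FVEPFeatureVector], labels: list[int],
                     grid: dict | None = None, seed: int = 0,
                     cv: int = 5) -> dict[int, BinaryLEDModel]:
    """Four binary target-vs-rest SVMs, one per LED, RBF kernel, grid search.

    Model k sees only LED k's feature pair from each trial and the binary
    label ``target == k``.
    """
    if grid is None:
        grid = DEFAULT_GRID
    models: dict[int, BinaryLEDModel] = {}
    y_all = np.asarray(labels)
    for led in range(1, 5):
        x = np.stack([f.pair(led) for f in features])
        y = (y_all == led).astype(int)
        if len(np.unique(y)) < 2:
            raise ValueError(
                f"LED {led} needs both target and non-target trials")
        pipe = Pipeline([("scale", StandardScaler()),
                         ("svc", SVC(kernel="rbf", random_state=seed))])
        search = GridSearchCV(pipe, grid, cv=min(cv, int(y.sum())), n_jobs=1)
        search.fit(x, y)
        models[led] = BinaryLEDModel(
            led_id=led, estimator=search.best_estimator_, grid=grid,
            selected=search.best_params_, cv_score=float(search.best_score_))
    return models


def combine_decisions(models: dict[int, BinaryLEDModel],
                      features: FVEPFeatureVector) -> int:
    """argmax over LEDs of each binary model's signed margin on its own pair.

    Always yields a unique four-class decision even when zero or several
    binary models fire; exact ties break toward the lowest LED id.
    """
    missing = [led for led in range(1, 5) if led not in models]
    if missing:
        raise ValueError(f"missing binary models for LEDs {missing}")
    margins = np.array([models[led].margin(features.pair(led))
                        for led in range(1, 5)])
    return int(np.argmax(margins)) + 1
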