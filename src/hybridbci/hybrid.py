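"""Fusion of Riemannian onset detection, PLR classification and FVEP evidence.

The hybrid decoder works per trial:

1. detect the task onset from the dry EEG (sliding-covariance AIR-distance
   change point, reference/target epochs around the nominal stimulus time);
2. if the detected shift fails the flanking-trough consistency check
   (looks unrelated to a stimulus response), pupil-constriction detection
   acts as the secondary index adjustment: no constriction invalidates the
   trial, a constriction near the index confirms it, and a grossly
   different constriction time overrides it;
3. the pupil series is re-epoched to 0-4.5 s from the final onset and
   classified with the trained TCN;
4. optionally, FVEP margins computed on the re-epoched EEG are fused with
   the PLR probabilities (softmax-normalised margins blended by ``weight``);
5. trials in which no covariance shift was detected are excluded and never
   enter accuracy denominators.

The default fusion weight is 1.0 — pure PLR classification after EEG-derived
onset correction — since the EEG's role in the hybrid design is chiefly to
supply onset and validity, while the pupil supplies the class.  Weighted
blending is retained as an extension point.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from . import fvep as fvep_mod
from . import riemann
from .plr import PupilTrial, cwt_features, normalize_pupil
from .sigproc import MultichannelSegment, bandpass, gfp
from .stimuli import StimulusSchedule
from .synthgen import SynthTrial
from .tcn import TCNClassifier, classify_plr

__all__ = ["DecodingResult", "HybridConfig", "decode_trial", "fuse"]


@dataclass(frozen=True)
class HybridConfig:
    epoch_pair: riemann.EpochPair = riemann.DEFAULT_EPOCH_PAIRS[1]
    window_troughs: int = 35
    k1: float = 3.0
    k2: float = 4.0
    jump_floor: float = 0.1
    fusion_weight: float = 1.0
    analysis_length: float = 4.5
    band: tuple[float, float] = (0.7, 54.0)
    tensor_times: int = 139
    #: max |pupil onset - EEG onset| (s) for the pupil to confirm the index;
    #: larger disagreements hand the timing to the pupil estimate
    plr_agreement: float = 0.6


@dataclass
class DecodingResult:
    trial_id: int
    predicted_led: int | None
    source: str  # "plr" | "fvep" | "fused"
    onset: riemann.OnsetDecision | None
    probabilities: np.ndarray | None
    excluded: bool
    detected_onset: float | None = None


def fuse(plr_probs: np.ndarray, fvep_margins: np.ndarray,
         weight: float = 1.0) -> np.ndarray:
    """Blend PLR probabilities with softmax-normalised FVEP margins."""
    if not 0.0 <= weight <= 1.0:
        raise ValueError("weight must be in [0, 1]")
    m = np.asarray(fvep_margins, dtype=float)
    z = m - m.max()
    soft = np.exp(z) / np.exp(z).sum()
    out = weight * np.asarray(plr_probs, dtype=float) + (1 - weight) * soft
    return out / out.sum()


def _epoch_pupil(trial: SynthTrial, onset: float, length: float) -> PupilTrial:
    rate = trial.pupil_rate
    i0 = int(round((onset - trial.pupil_t0) * rate))
    n = int(round(length * rate))
    i0 = max(0, min(i0, trial.pupil_left.size - n))
    sl = slice(i0, i0 + n)
    return PupilTrial(trial.pupil_left[sl], trial.pupil_right[sl],
                      trial.confidence_left[sl], trial.confidence_right[sl],
                      rate, trial.target_led)


def pupil_tensor(trial: SynthTrial, onset: float = 0.0,
                 length: float = 4.5, n_times: int = 139):
    """Normalised CWT tensor of the pupil series epoched from ``onset``."""
    pt = _epoch_pupil(trial, onset, length)
    return cwt_features(normalize_pupil(pt), n_times=n_times)


def decode_trial(trial: SynthTrial, plr_model: TCNClassifier,
                 fvep_models: dict | None = None,
                 config: HybridConfig = HybridConfig()) -> DecodingResult:
    """Decode one context trial (EEG/pupil spanning the epoch pairs)."""
    if plr_model is None or not plr_model.trained:
        raise ValueError("a trained PLR model is required")
    eeg = bandpass(trial.eeg, *config.band, family="butterworth", order=3)
    troughs = gfp(eeg)
    series = riemann.epoch_pair_distances(eeg, troughs, config.epoch_pair,
                                          config.window_troughs)
    decision = riemann.detect_onset(series, config.k1, config.k2,
                                    config.jump_floor)
    if decision.excluded:
        return DecodingResult(trial.trial_id, None, "plr", decision, None,
                              excluded=True)
    onset = decision.detected_time
    if decision.adjusted_by_plr:
        # the distance shift looked unrelated to a stimulus response, so the
        # pupil must confirm it: no constriction at all -> invalid trial;
        # a constriction near the index confirms the EEG timing; a grossly
        # different constriction time overrides it
        norm = normalize_pupil(PupilTrial(
            trial.pupil_left, trial.pupil_right,
            trial.confidence_left, trial.confidence_right, trial.pupil_rate))
        fallback = riemann.plr_fallback_onset(
            norm.left, norm.right, trial.pupil_rate, t0=trial.pupil_t0,
            expected_start=config.epoch_pair.target_range[0])
        if fallback is None:
            return DecodingResult(trial.trial_id, None, "plr", decision, None,
                                  excluded=True)
        if abs(fallback - onset) > config.plr_agreement:
            onset = fallback
    tensor = pupil_tensor(trial, onset, config.analysis_length,
                          config.tensor_times)
    led, probs = classify_plr(plr_model, tensor.features)
    source = "plr"
    if fvep_models is not None:
        sub = eeg.pick(list(fvep_mod.FVEP_CHANNELS))
        feats = fvep_mod.extract_trial_features(sub, trial.schedule,
                                                onset_shift=onset)
        margins = np.array([fvep_models[k].margin(feats.pair(k))
                            for k in range(1, 5)])
        probs = fuse(probs, margins, config.fusion_weight)
        led = int(probs.argmax()) + 1
        source = "fused" if config.fusion_weight < 1.0 else "plr"
    return DecodingResult(trial.trial_id, led, source, decision, probs,
                          excluded=False, detected_onset=onset)
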