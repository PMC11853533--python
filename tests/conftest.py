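"""Shared fixtures.

The expensive fixtures (synthetic cohorts and end-to-end pipeline runs) are
session-scoped so the unit tests and the acceptance suite share one
computation.  Problem sizes are kept small enough for the whole suite to run
on one CPU in a few minutes while still giving stable statistics.
"""

from __future__ import annotations

import numpy as np
import pytest

from hybridbci.evalstats import repeated_holdout
from hybridbci.fvep import (FVEP_CHANNELS, combine_decisions,
                            extract_trial_features, train_led_models)
from hybridbci.hybrid import decode_trial, pupil_tensor
from hybridbci.sigproc import MultichannelSegment, bandpass, gfp, rereference
from hybridbci.ssvep import classify_ssvep
from hybridbci.stimuli import build_default_schedule
from hybridbci.synthgen import SynthConfig, synth_dataset, synth_eeg_trial
from hybridbci.tcn import TCNClassifier, TCNSpec
from hybridbci import riemann

#: reduced-width network used wherever a TCN is trained in the suite; the
#: last block keeps 64 filters so the flattened feature size matches the
#: full-width architecture contract
SMALL_TCN = TCNSpec(filters=(16, 16, 64), batch_size=16)


@pytest.fixture(scope="session")
def pattern_schedule():
    return build_default_schedule("pattern")


@pytest.fixture(scope="session")
def frequency_schedule():
    return build_default_schedule("frequency")


@pytest.fixture(scope="session")
def plr_cohort():
    """4 subjects x 24 pattern-mode trials -> CWT tensors with labels."""
    cfg = SynthConfig(seed=7, n_subjects=4, n_trials=24,
                      covariance_shift_scale=0.0)
    ds = synth_dataset(cfg, "pattern")
    x = np.array([pupil_tensor(tr).features for tr in ds.trials],
                 dtype=np.float32)
    y = np.array([tr.target_led - 1 for tr in ds.trials])
    subj = np.array([tr.subject_id for tr in ds.trials])
    return x, y, subj


@pytest.fixture(scope="session")
def plr_losocv_accuracy(plr_cohort):
    """Leave-one-subject-out accuracies of the TCN on the PLR cohort."""
    x, y, subj = plr_cohort
    accs = []
    for s in np.unique(subj):
        model = TCNClassifier(SMALL_TCN, seed=0).fit(
            x[subj != s], y[subj != s], epochs=20)
        accs.append(float((model.predict(x[subj == s]) == y[subj == s]).mean()))
    return accs


@pytest.fixture(scope="session")
def fvep_data():
    """48 single-subject pattern trials -> FVEP feature vectors + labels."""
    cfg = SynthConfig(seed=12, n_subjects=1, n_trials=48,
                      covariance_shift_scale=0.0)
    ds = synth_dataset(cfg, "pattern")
    feats, labels = [], []
    for tr in ds.trials:
        filt = bandpass(tr.eeg, 2.0, 30.0, family="butterworth",
                        order=3).pick(list(FVEP_CHANNELS))
        feats.append(extract_trial_features(filt, tr.schedule))
        labels.append(tr.target_led)
    return feats, labels


@pytest.fixture(scope="session")
def fvep_holdout(fvep_data):
    feats, labels = fvep_data
    return repeated_holdout(
        feats, labels,
        lambda items, ys: train_led_models(list(items), list(ys), seed=0),
        lambda m, item: combine_decisions(m, item),
        repeats=30, seed=0, trial_time=5.0)


@pytest.fixture(scope="session")
def ssvep_accuracy():
    """Single-trial SSVEP accuracy over 100 balanced frequency-mode trials."""
    cfg = SynthConfig(seed=11, n_subjects=1, n_trials=100,
                      eeg_channels=("O1", "Oz", "O2", "Cz"),
                      covariance_shift_scale=0.0)
    ds = synth_dataset(cfg, "frequency")
    hits = 0
    for tr in ds.trials:
        eeg = rereference(tr.eeg, "Cz")
        filt = bandpass(eeg, 2.0, 54.0, family="elliptic", order=4)
        n = int(round(4.5 * filt.rate))
        sub = MultichannelSegment(filt.samples[:, :n], filt.rate,
                                  filt.channel_labels, filt.t0)
        hits += classify_ssvep(sub).predicted_led == tr.target_led
    return hits / len(ds.trials)


@pytest.fixture(scope="session")
def onset_runs():
    """30 high-shift context trials -> (true_onset, decision, iti, series)."""
    sch = build_default_schedule("pattern")
    out = []
    for k in range(30):
        rng = np.random.default_rng(1100 + k)
        onset = float(rng.uniform(0.3, 1.0))
        cfg = SynthConfig(seed=2, covariance_shift_scale=1.5)
        eeg = synth_eeg_trial(cfg, sch, 1 + k % 4, rng,
                              t_start=-4.0, t_stop=8.0, true_onset=onset)
        filt = bandpass(eeg, 0.7, 54.0, family="butterworth", order=3)
        series = riemann.epoch_pair_distances(
            filt, gfp(filt), riemann.DEFAULT_EPOCH_PAIRS[1])
        decision = riemann.detect_onset(series)
        iti = float(np.diff(series.trough_times).mean())
        out.append((onset, decision, iti, series))
    return out


@pytest.fixture(scope="session")
def hybrid_vs_plr():
    """Hybrid vs PLR-alone accuracy on onset-jittered held-out trials."""
    train_cfg = SynthConfig(seed=21, n_subjects=3, n_trials=24)
    train_ds = synth_dataset(train_cfg, "pattern")
    x = np.array([pupil_tensor(tr).features for tr in train_ds.trials],
                 dtype=np.float32)
    y = np.array([tr.target_led - 1 for tr in train_ds.trials])
    model = TCNClassifier(SMALL_TCN, seed=0).fit(x, y, epochs=20)

    test_cfg = SynthConfig(seed=22, n_subjects=1, n_trials=24)
    test_ds = synth_dataset(test_cfg, "pattern", context=True,
                            onset_jitter=(0.3, 1.0))
    plr_hits = 0
    hyb_hits = hyb_total = excluded = 0
    for tr in test_ds.trials:
        pred = int(model.predict(pupil_tensor(tr, 0.0).features[None])[0]) + 1
        plr_hits += pred == tr.target_led
    res_list = [decode_trial(tr, model) for tr in test_ds.trials]
    for tr, res in zip(test_ds.trials, res_list):
        if res.excluded:
            excluded += 1
            continue
        hyb_total += 1
        hyb_hits += res.predicted_led == tr.target_led
    return {
        "plr_accuracy": plr_hits / len(test_ds.trials),
        "hybrid_accuracy": hyb_hits / max(hyb_total, 1),
        "excluded": excluded,
        "n": len(test_ds.trials),
        "results": res_list,
    }
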