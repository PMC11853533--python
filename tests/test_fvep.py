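"""FVEP pipeline: epoch averaging, peak-to-valley features, SVM combination."""

import numpy as np
import pytest

from hybridbci.fvep import (FVEP_CHANNELS, averaged_fvep, combine_decisions,
                            extract_trial_features, peak_to_valley,
                            train_led_models)
from hybridbci.sigproc import MultichannelSegment, bandpass
from hybridbci.synthgen import SynthConfig, synth_eeg_trial, _fvep_kernel


def flat_segment(value=0.0, n=5000, labels=("Pz", "O1", "O2")):
    return MultichannelSegment(np.full((len(labels), n), value), 500.0,
                               list(labels), 0.0)


# -- averaging ----------------------------------------------------------------

def test_average_over_five_onset_epochs(pattern_schedule):
    seg = flat_segment(n=2500)
    avg = averaged_fvep(seg, pattern_schedule, 1, "onset")
    assert avg.n_samples == 225
    assert avg.t0 == pytest.approx(-0.1)


def test_average_of_identical_epochs_is_the_epoch(pattern_schedule):
    rng = np.random.default_rng(0)
    period = 500  # LED1 cycles every 1 s = 500 samples
    block = rng.standard_normal((3, period))
    seg = MultichannelSegment(np.tile(block, (1, 5)), 500.0,
                              list(FVEP_CHANNELS), 0.0)
    avg = averaged_fvep(seg, pattern_schedule, 1, "onset")
    # epochs at 1,2,3,4 s are identical copies (0 s onset needs pre-samples)
    start = int(0.9 * 500) % period
    expected = np.tile(block, (1, 2))[:, start:start + 225]
    assert np.allclose(avg.samples, expected)


def test_zero_usable_epochs_rejected(pattern_schedule):
    short = flat_segment(n=60)  # 0.12 s cannot hold any epoch
    with pytest.raises(ValueError, match="epoch"):
        averaged_fvep(short, pattern_schedule, 1, "onset")
    with pytest.raises(ValueError, match="transition"):
        averaged_fvep(flat_segment(), pattern_schedule, 1, "both")


def test_averaged_waveform_peak_within_latency(pattern_schedule):
    cfg = SynthConfig(seed=13, noise_sd=0.1, covariance_shift_scale=0.0)
    eeg = synth_eeg_trial(cfg, pattern_schedule, 3)
    filt = bandpass(eeg, 2, 30).pick(list(FVEP_CHANNELS))
    avg = averaged_fvep(filt, pattern_schedule, 3, "onset")
    wave = avg.samples.mean(axis=0)
    peak_t = avg.times[np.argmax(np.abs(wave))]
    assert 0.0 < peak_t < 0.2


# -- peak-to-valley -----------------------------------------------------------

def test_p2v_hand_values():
    assert peak_to_valley(flat_segment(n=225)) == 0.0
    x = np.zeros((1, 225))
    x[0, 60:64] = [0.0, 2.0, -1.0, 0.5]
    seg = MultichannelSegment(x, 500.0, ["Pz"], -0.1)
    assert peak_to_valley(seg) == pytest.approx(3.0)


def test_p2v_offset_invariance():
    rng = np.random.default_rng(1)
    x = rng.standard_normal((3, 225))
    a = peak_to_valley(MultichannelSegment(x, 500.0, list(FVEP_CHANNELS), -0.1))
    b = peak_to_valley(MultichannelSegment(x + 7.0, 500.0,
                                           list(FVEP_CHANNELS), -0.1))
    assert a == pytest.approx(b)


def test_p2v_empty_window_rejected():
    with pytest.raises(ValueError, match="window"):
        peak_to_valley(flat_segment(n=225), search_window=(600, 700))


def test_noise_free_amplitude_recovery(pattern_schedule):
    """With noise off, the averaged-onset p2v equals the kernel amplitude."""
    amp = 6.0
    cfg = SynthConfig(seed=14, fvep_amplitude=amp, noise_sd=1e-9,
                      ssvep_amplitude=0.0, covariance_shift_scale=0.0)
    eeg = synth_eeg_trial(cfg, pattern_schedule, 1).pick(["O1"])
    avg = averaged_fvep(eeg, pattern_schedule, 1, "onset")
    # O-channel topography weight is 1.0; kernel p2v is normalised to 1
    assert peak_to_valley(avg) == pytest.approx(amp, rel=0.01)


# -- trial features -----------------------------------------------------------

def test_features_four_pairs_and_counts(pattern_schedule, fvep_data):
    feats, _ = fvep_data
    fv = feats[0]
    assert sorted(fv.per_led) == [1, 2, 3, 4]
    assert fv.n_epochs_used[1] == (5, 5)
    assert fv.n_epochs_used[4] == (4, 4)
    assert all(v >= 0 for pair in fv.per_led.values() for v in pair)


def test_target_led_feature_dominates(pattern_schedule):
    cfg = SynthConfig(seed=15, noise_sd=1.0, covariance_shift_scale=0.0)
    eeg = synth_eeg_trial(cfg, pattern_schedule, 3)
    filt = bandpass(eeg, 2, 30).pick(list(FVEP_CHANNELS))
    fv = extract_trial_features(filt, pattern_schedule)
    target = sum(fv.per_led[3])
    assert all(target > sum(fv.per_led[k]) for k in (1, 2, 4))


def test_features_label_blind(pattern_schedule):
    cfg = SynthConfig(seed=16, covariance_shift_scale=0.0)
    eeg = bandpass(synth_eeg_trial(cfg, pattern_schedule, 2),
                   2, 30).pick(list(FVEP_CHANNELS))
    a = extract_trial_features(eeg, pattern_schedule)
    b = extract_trial_features(eeg, pattern_schedule)
    assert a.per_led == b.per_led


def test_pure_noise_features_similar_across_leds(pattern_schedule):
    cfg = SynthConfig(seed=17, fvep_amplitude=1e-12, ssvep_amplitude=0.0,
                      covariance_shift_scale=0.0)
    sums = np.zeros(4)
    for k in range(25):
        eeg = synth_eeg_trial(SynthConfig(seed=300 + k, fvep_amplitude=1e-12,
                                          ssvep_amplitude=0.0,
                                          covariance_shift_scale=0.0),
                              pattern_schedule, 1)
        filt = bandpass(eeg, 2, 30).pick(list(FVEP_CHANNELS))
        fv = extract_trial_features(filt, pattern_schedule)
        sums += [sum(fv.per_led[k]) for k in range(1, 5)]
    assert sums.max() / sums.min() < 2.0


# -- models -------------------------------------------------------------------

def test_models_fit_separable_features(fvep_data):
    feats, labels = fvep_data
    models = train_led_models(feats, labels, seed=0)
    for led, m in models.items():
        assert m.selected["svc__C"] in m.grid["svc__C"]
    preds = [combine_decisions(models, f) for f in feats]
    assert np.mean([p == l for p, l in zip(preds, labels)]) >= 0.9


def test_shuffled_labels_give_chance_cv(fvep_data):
    feats, labels = fvep_data
    rng = np.random.default_rng(0)
    shuffled = list(rng.permutation(labels))
    models = train_led_models(feats, shuffled, seed=0)
    # binary target-vs-rest base rate is 0.75; CV score should sit near it
    scores = [m.cv_score for m in models.values()]
    assert all(0.5 <= s <= 0.9 for s in scores)


def test_grid_search_deterministic(fvep_data):
    feats, labels = fvep_data
    a = train_led_models(feats[:32], labels[:32], seed=0)
    b = train_led_models(feats[:32], labels[:32], seed=0)
    assert all(a[k].selected == b[k].selected for k in a)


def test_single_class_rejected(fvep_data):
    feats, _ = fvep_data
    with pytest.raises(ValueError, match="LED"):
        train_led_models(feats[:8], [1] * 8)


def test_combination_rules(fvep_data):
    feats, labels = fvep_data
    models = train_led_models(feats, labels, seed=0)

    class Stub:
        def __init__(self, margin):
            self._m = margin

        def margin(self, pair):
            return self._m

    stubs = {1: Stub(-1.0), 2: Stub(0.5), 3: Stub(-0.2), 4: Stub(-2.0)}
    assert combine_decisions(stubs, feats[0]) == 2
    ties = {k: Stub(0.0) for k in range(1, 5)}
    assert combine_decisions(ties, feats[0]) == 1
    with pytest.raises(ValueError, match="missing"):
        combine_decisions({1: Stub(0.0)}, feats[0])
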