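"""Synthetic-signal generator: determinism, locked components, balance."""

import numpy as np
import pytest
from scipy import signal as sps

from hybridbci.mealfsm import emg_chew_trigger
from hybridbci.sigproc import bandpass
from hybridbci.stimuli import build_default_schedule
from hybridbci.synthgen import (SynthConfig, synth_dataset, synth_eeg_trial,
                                synth_emg, synth_pupil_trial)


def test_determinism_same_seed():
    cfg = SynthConfig(seed=9, n_subjects=2, n_trials=8)
    a = synth_dataset(cfg, "pattern")
    b = synth_dataset(cfg, "pattern")
    for ta, tb in zip(a.trials, b.trials):
        assert np.array_equal(ta.eeg.samples, tb.eeg.samples)
        assert np.array_equal(ta.pupil_left, tb.pupil_left)
        assert ta.target_led == tb.target_led
        assert ta.true_onset == tb.true_onset


def test_zero_amplitude_eeg_has_no_locked_component(pattern_schedule):
    cfg = SynthConfig(seed=3, fvep_amplitude=1e-12, ssvep_amplitude=0.0,
                      covariance_shift_scale=0.0)
    eeg = synth_eeg_trial(cfg, pattern_schedule, 1)
    # transition-locked average should be noise-level: correlate the mean
    # channel with an impulse train at LED 1 transitions
    train = np.zeros(eeg.n_samples)
    for t in pattern_schedule.onsets(1) + pattern_schedule.offsets(1):
        train[int(t * eeg.rate)] = 1.0
    m = eeg.samples.mean(axis=0)
    r = np.corrcoef(np.convolve(train, np.ones(50), "same"), m)[0, 1]
    assert abs(r) < 0.1


def test_frequency_mode_psd_peak_at_target(frequency_schedule):
    cfg = SynthConfig(seed=5, eeg_channels=("O1", "Oz", "O2", "Cz"),
                      ssvep_amplitude=6.0, covariance_shift_scale=0.0)
    eeg = synth_eeg_trial(cfg, frequency_schedule, 4)
    oz = eeg.samples[eeg.channel_labels.index("Oz")]
    f, p = sps.periodogram(oz, fs=eeg.rate)
    def power_at(freq):
        return p[np.argmin(np.abs(f - freq))]
    assert power_at(10.0) > power_at(7.5)


def test_pattern_mode_transition_locked_average(pattern_schedule):
    # low background so the locked component dominates the 5-epoch average
    cfg = SynthConfig(seed=6, noise_sd=2.0, covariance_shift_scale=0.0)
    eeg = bandpass(synth_eeg_trial(cfg, pattern_schedule, 1), 2, 30)
    o1 = eeg.samples[eeg.channel_labels.index("O1")]

    def locked_p2v(events):
        eps = [o1[int(t * 500): int(t * 500) + 175]
               for t in events if t * 500 + 175 <= o1.size]
        avg = np.mean(eps, axis=0)
        return avg.max() - avg.min()

    target = locked_p2v(pattern_schedule.onsets(1))
    # LED 3 offsets (0.95, 1.85, ... s) never coincide with LED 1's 0.5 s
    # transition grid, so their locked average holds no coherent transient;
    # LED 2's onsets would, since its 0.5 s start equals an LED 1 offset
    other = locked_p2v(pattern_schedule.offsets(3))
    assert target >= 3 * other


def test_pupil_zero_gain_flat(pattern_schedule):
    cfg = SynthConfig(seed=4, plr_constriction_gain=0.0, blink_rate=0.0)
    l, r, _, _ = synth_pupil_trial(cfg, pattern_schedule, 1)
    assert l.max() - l.min() < 0.3  # hippus + noise only


def test_pupil_constriction_minima_and_divergence(pattern_schedule):
    cfg = SynthConfig(seed=4, blink_rate=0.0)
    l1, _, _, _ = synth_pupil_trial(cfg, pattern_schedule, 1)
    # LED 1 has 5 on-phases in 0-4.5 s: at least 2 distinct minima
    inv = -l1[: int(4.5 * 30)]
    peaks, _ = sps.find_peaks(inv, prominence=0.1)
    assert peaks.size >= 2

    l2, _, _, _ = synth_pupil_trial(cfg, pattern_schedule, 2)
    l3, _, _, _ = synth_pupil_trial(cfg, pattern_schedule, 3)
    # LED 2 goes fully dark at 2.5 s -> sustained redilation afterwards
    late = slice(int(3.0 * 30), int(4.5 * 30))
    assert l2[late].mean() > l3[late].mean()


def test_blinks_lower_confidence(pattern_schedule):
    quiet = SynthConfig(seed=8, blink_rate=0.0)
    noisy = SynthConfig(seed=8, blink_rate=20.0)
    _, _, cq, _ = synth_pupil_trial(quiet, pattern_schedule, 1)
    _, _, cn, _ = synth_pupil_trial(noisy, pattern_schedule, 1)
    assert (cn < 0.6).mean() > (cq < 0.6).mean()


def test_emg_burst_count_and_silence():
    cfg = SynthConfig(seed=5, chew_rate=1.5)
    chew = synth_emg(cfg, True, 10.0)
    quiet = synth_emg(cfg, False, 10.0)
    env = np.convolve(np.abs(chew.samples).mean(axis=0),
                      np.ones(25) / 25, "same")
    thr = 5 * np.abs(quiet.samples).mean(axis=0).std()
    rising = np.diff((env > thr).astype(int)) == 1
    n_bursts = rising.sum()
    assert 12 <= n_bursts <= 18  # 15 +/- 3
    assert emg_chew_trigger(quiet.samples, cfg.eeg_rate) is None


def test_emg_bursts_confined_to_chewing_half():
    cfg = SynthConfig(seed=7)
    first = synth_emg(cfg, True, 5.0).samples
    second = synth_emg(SynthConfig(seed=8), False, 5.0).samples
    x = np.concatenate([first, second], axis=1)
    env = np.convolve(np.abs(x).mean(axis=0), np.ones(25) / 25, "same")
    thr = 5 * np.abs(second).mean(axis=0).std()
    above = np.where(env > thr)[0]
    assert above.size > 0
    assert above.max() < first.shape[1] + 250  # 0.5 s of filter spill


def test_dataset_balance():
    ds = synth_dataset(SynthConfig(seed=1, n_subjects=5, n_trials=12), "pattern")
    assert len(ds.trials) == 60
    targets = [t.target_led for t in ds.trials]
    assert all(targets.count(k) == 15 for k in range(1, 5))
    per_subject = ds.by_subject()
    for trials in per_subject.values():
        counts = [sum(t.target_led == k for t in trials) for k in range(1, 5)]
        assert counts == [3, 3, 3, 3]


def test_tiny_dataset_each_led_once():
    ds = synth_dataset(SynthConfig(seed=2, n_subjects=1, n_trials=4), "pattern")
    assert sorted(t.target_led for t in ds.trials) == [1, 2, 3, 4]


def test_no_lookahead_before_onset(pattern_schedule):
    """Samples before the task onset do not depend on the onset time."""
    cfg = SynthConfig(seed=10)
    rng_a = np.random.default_rng(77)
    rng_b = np.random.default_rng(77)
    a = synth_eeg_trial(cfg, pattern_schedule, 1, rng_a,
                        t_start=-4.0, t_stop=8.0, true_onset=0.5)
    b = synth_eeg_trial(cfg, pattern_schedule, 1, rng_b,
                        t_start=-4.0, t_stop=8.0, true_onset=1.0)
    n_pre = int((0.5 - (-4.0)) * 500)
    assert np.allclose(a.samples[:, :n_pre], b.samples[:, :n_pre])


def test_invalid_configs_rejected(pattern_schedule):
    with pytest.raises(ValueError):
        SynthConfig(fvep_latency=250.0)
    with pytest.raises(ValueError):
        SynthConfig(covariance_shift_scale=-1.0)
    with pytest.raises(ValueError):
        SynthConfig(eeg_channels=())
    with pytest.raises(ValueError):
        synth_eeg_trial(SynthConfig(), pattern_schedule, 5)
    with pytest.raises(ValueError):
        synth_emg(SynthConfig(), True, -1.0)
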