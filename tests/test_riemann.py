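"""SPD geometry, entropy-based reference selection, onset detection."""

import numpy as np
import pytest
from scipy.linalg import fractional_matrix_power, logm

from hybridbci.riemann import (DistanceSeries, air_distance, detect_onset,
                               eigen_entropy, plr_fallback_onset,
                               reference_matrix, sliding_covariances)
from hybridbci.sigproc import GFPSeries, MultichannelSegment, SPDMatrix, gfp


def spd(values):
    return SPDMatrix(np.asarray(values, dtype=float))


def random_spd(rng, dim=4, scale=1.0):
    a = rng.standard_normal((dim, dim))
    return SPDMatrix(a @ a.T + scale * np.eye(dim))


# -- eigen entropy -------------------------------------------------------------

def test_entropy_hand_values():
    assert eigen_entropy(spd(np.eye(2))) == pytest.approx(np.log(2))
    assert eigen_entropy(spd(np.eye(6))) == pytest.approx(np.log(6))
    concentrated = eigen_entropy(spd(np.diag([1.0, 1e-9])))
    assert concentrated < 1e-6


def test_entropy_rejects_indefinite():
    with pytest.raises(ValueError):
        eigen_entropy(spd(np.diag([1.0, -1.0])))


# -- reference selection --------------------------------------------------------

def test_reference_mean_of_identical():
    m = random_spd(np.random.default_rng(0))
    ref = reference_matrix([m] * 5)
    assert np.allclose(ref.values, m.values)


def test_reference_selects_bottom_five_by_entropy():
    rng = np.random.default_rng(1)
    cands = [random_spd(rng) for _ in range(12)]
    ref = reference_matrix(cands)
    ents = np.array([eigen_entropy(m) for m in cands])
    bottom = np.argsort(ents, kind="stable")[:5]
    expected = np.mean([cands[i].values for i in bottom], axis=0)
    assert np.allclose(ref.values, expected)
    # convexity: the mean of SPD matrices is SPD
    assert np.linalg.eigvalsh(ref.values).min() > 0


def test_reference_needs_five():
    rng = np.random.default_rng(2)
    with pytest.raises(ValueError):
        reference_matrix([random_spd(rng)] * 4)


# -- AIR distance ---------------------------------------------------------------

def test_air_distance_hand_values():
    i2 = spd(np.eye(2))
    assert air_distance(i2, i2) == pytest.approx(0.0, abs=1e-10)
    assert air_distance(i2, spd(4 * np.eye(2))) == pytest.approx(
        np.sqrt(2 * np.log(4) ** 2), abs=1e-9)
    assert air_distance(spd(np.diag([1.0, 2.0])), spd(np.diag([2.0, 1.0]))
                        ) == pytest.approx(np.sqrt(2) * np.log(2), abs=1e-9)


def test_air_distance_metric_axioms():
    rng = np.random.default_rng(3)
    for _ in range(20):
        a, b, c = (random_spd(rng) for _ in range(3))
        dab = air_distance(a, b)
        assert dab == pytest.approx(air_distance(b, a), abs=1e-8)
        assert dab >= 0
        assert air_distance(a, a) == pytest.approx(0.0, abs=1e-10)
        assert dab <= air_distance(a, c) + air_distance(c, b) + 1e-8


def test_air_distance_affine_invariance():
    rng = np.random.default_rng(4)
    for _ in range(10):
        a, b = random_spd(rng), random_spd(rng)
        w = rng.standard_normal((4, 4)) + 4 * np.eye(4)
        wa = SPDMatrix(w.T @ a.values @ w)
        wb = SPDMatrix(w.T @ b.values @ w)
        assert air_distance(wa, wb) == pytest.approx(
            air_distance(a, b), abs=1e-8)


def test_air_distance_agrees_with_matrix_log_oracle():
    """Independent route: Frobenius norm of logm of the whitened matrix."""
    rng = np.random.default_rng(5)
    for _ in range(100):
        a, b = random_spd(rng), random_spd(rng)
        isq = fractional_matrix_power(a.values, -0.5)
        oracle = np.linalg.norm(logm(isq @ b.values @ isq), "fro")
        assert air_distance(a, b) == pytest.approx(oracle.real, abs=1e-6)


def test_air_distance_guards():
    with pytest.raises(ValueError):
        air_distance(spd(np.eye(2)), spd(np.eye(3)))
    with pytest.raises(ValueError):
        air_distance(spd(np.eye(2)), spd(np.diag([1.0, -2.0])))


# -- sliding windows -------------------------------------------------------------

def noise_segment(seed=0, n=4000, c=4):
    rng = np.random.default_rng(seed)
    return MultichannelSegment(rng.standard_normal((c, n)), 500.0,
                               [f"c{i}" for i in range(c)], 0.0)


def test_sliding_window_counts():
    seg = noise_segment()
    troughs = gfp(seg)
    k = troughs.trough_indices.size
    mats, ends = sliding_covariances(seg, troughs, window_troughs=k)
    assert len(mats) == 1
    mats40, _ = sliding_covariances(seg, troughs, window_troughs=k - 5)
    assert len(mats40) == 6
    with pytest.raises(ValueError, match="troughs"):
        sliding_covariances(seg, troughs, window_troughs=k + 1)


def test_stationary_windows_closer_than_scaled_matrix():
    seg = noise_segment(seed=1, n=8000)
    troughs = gfp(seg)
    mats, _ = sliding_covariances(seg, troughs, window_troughs=60)
    pairwise = [air_distance(mats[i], mats[i + 1]) for i in range(10)]
    scaled = SPDMatrix(4.0 * mats[0].values)
    assert np.mean(pairwise) < air_distance(mats[0], scaled)


# -- onset detection --------------------------------------------------------------

def series(values):
    v = np.asarray(values, dtype=float)
    return DistanceSeries(v, np.arange(v.size) * 0.025)


def test_constant_series_is_excluded():
    dec = detect_onset(series(np.ones(50)))
    assert dec.excluded and dec.detected_index is None


def test_small_step_detected_without_adjustment():
    v = np.zeros(60)
    v[30:] = 0.05  # step below the 0.1 consistency floor
    v += 0.001 * np.sin(np.arange(60))  # break degeneracy of the SDs
    dec = detect_onset(series(v))
    assert not dec.excluded
    assert abs(dec.detected_index - 30) <= 2
    assert dec.adjusted_by_plr is False


def test_large_step_flagged_for_plr_adjustment():
    v = np.zeros(60)
    v[30:] = 0.15
    v += 0.001 * np.sin(np.arange(60))
    dec = detect_onset(series(v))
    assert not dec.excluded
    assert dec.adjusted_by_plr is True


def test_series_too_short_rejected():
    with pytest.raises(ValueError):
        detect_onset(series(np.zeros(6)))


# -- pupil fallback ----------------------------------------------------------------

def test_fallback_none_on_flat_trace():
    flat = np.ones(150)
    assert plr_fallback_onset(flat, flat, 30.0) is None


def test_fallback_finds_constriction_start():
    t = np.arange(240) / 30.0
    d = np.ones(240)
    onset, latency = 2.0, 0.25
    drive = t > onset + latency
    d -= 0.2 * (1 - np.exp(-(t - onset - latency) / 0.4)) * drive
    est = plr_fallback_onset(d, d, 30.0, expected_start=0.0)
    assert est is not None
    assert abs(est - onset) <= 0.25


def test_fallback_zero_gain_none(pattern_schedule):
    from hybridbci.plr import PupilTrial, normalize_pupil
    from hybridbci.synthgen import SynthConfig, synth_pupil_trial

    cfg = SynthConfig(seed=30, plr_constriction_gain=0.0, blink_rate=0.0)
    l, r, cl, cr = synth_pupil_trial(cfg, pattern_schedule, 1)
    norm = normalize_pupil(PupilTrial(l, r, cl, cr))
    assert plr_fallback_onset(norm.left, norm.right, 30.0) is None


# -- end-to-end onset localisation (uses the session fixture) ----------------------

def test_onset_detected_within_two_intervals(onset_runs):
    detected = [(o, d, iti) for o, d, iti, _ in onset_runs
                if d.detected_time is not None]
    assert len(detected) >= 0.7 * len(onset_runs)
    hits = sum(abs(d.detected_time - o) <= 2 * iti for o, d, iti in detected)
    assert hits / len(detected) >= 0.8


def test_distance_drops_after_onset_on_average(onset_runs):
    """Post-onset synchronized state sits closer to the reference than rest."""
    pre, post = [], []
    for onset, _, _, srs in onset_runs:
        t, v = srs.trough_times, srs.values
        pre.append(v[t < onset].mean())
        post.append(v[t > onset + 1.4].mean())
    assert np.mean(post) < np.mean(pre)
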