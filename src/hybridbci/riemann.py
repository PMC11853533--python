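"""Task-onset detection from dry EEG via SPD-manifold geometry.

Channel covariance matrices live on the manifold of symmetric
positive-definite (SPD) matrices.  The pipeline:

1. local troughs of the global field power segment the recording into
   quasi-stable topography windows; a sliding window of 35 consecutive
   troughs yields a sequence of covariance matrices;
2. a reference matrix is the arithmetic mean of the five lowest
   eigenvalue-entropy covariances from the latter half of a pre-stimulus
   reference epoch (low entropy = variance concentrated in few spatial
   components, i.e. the most "locked-in" rest windows);
3. the affine-invariant Riemannian (AIR) distance from each sliding-window
   covariance to the reference forms a distance series;
4. a change point is the earliest sample whose first AND second
   derivatives exceed 3x / 4x their respective standard deviations.  If the
   level difference across the three troughs flanking that point is >= 0.1
   the shift is deemed unrelated to the stimulus and the caller should fall
   back to pupil-based onset detection; if no candidate exists the trial is
   excluded.

Each distance value is time-stamped at its window's last trough (the
"current time point" of a causal sliding estimate), so a detected index maps
directly onto the time the brain state change entered the window.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .sigproc import GFPSeries, MultichannelSegment, SPDMatrix, covariance
from .stimuli import StimulusSchedule

__all__ = [
    "EpochPair",
    "DistanceSeries",
    "OnsetDecision",
    "DEFAULT_EPOCH_PAIRS",
    "sliding_covariances",
    "eigen_entropy",
    "reference_matrix",
    "air_distance",
    "distance_series",
    "detect_onset",
    "plr_fallback_onset",
]


@dataclass(frozen=True)
class EpochPair:
    """Reference / target time ranges (s, relative to nominal stimulus onset)."""

    ref_range: tuple[float, float]
    target_range: tuple[float, float]


#: Pair 1 compares within-rest, Pair 2 rest vs stimulation (the configuration
#: onset detection runs on), Pair 3 stimulation vs post-stimulus rest.
DEFAULT_EPOCH_PAIRS = (
    EpochPair((-4.0, -3.0), (-3.0, 0.0)),
    EpochPair((-3.0, 0.0), (0.0, 5.0)),
    EpochPair((0.0, 5.0), (5.0, 8.0)),
)


@dataclass
class DistanceSeries:
    values: np.ndarray
    trough_times: np.ndarray  # time of each window's last trough (s)


@dataclass
class OnsetDecision:
    detected_index: int | None
    detected_time: float | None
    adjusted_by_plr: bool
    excluded: bool
    thresholds: tuple[float, float]
    jump_floor: float


# regularization added before any inversion: short 8-channel windows are
# near-singular
_REG_FRACTION = 1e-8


def _window_cov(seg: MultichannelSegment, i0: int, i1: int) -> SPDMatrix:
    x = seg.samples[:, i0:i1]
    n = x.shape[1]
    sigma = x @ x.T / max(n - 1, 1)
    sigma = 0.5 * (sigma + sigma.T)
    reg = _REG_FRACTION * np.trace(sigma) / sigma.shape[0]
    sigma += max(reg, 1e-12) * np.eye(sigma.shape[0])
    return SPDMatrix(sigma)


def sliding_covariances(seg: MultichannelSegment, troughs: GFPSeries,
                        window_troughs: int = 35,
                        ) -> tuple[list[SPDMatrix], np.ndarray]:
    """One covariance per window of ``window_troughs`` consecutive GFP troughs.

    Windows advance one trough at a time; window i spans trough i to trough
    ``i + window_troughs - 1``.  Returns the matrices and each window's last
    trough time.
    """
    idx = troughs.trough_indices
    if idx.size < window_troughs:
        raise ValueError(
            f"need at least {window_troughs} troughs, got {idx.size}")
    mats, ends = [], []
    for i in range(idx.size - window_troughs + 1):
        i0, i1 = int(idx[i]), int(idx[i + window_troughs - 1]) + 1
        mats.append(_window_cov(seg, i0, i1))
        ends.append(seg.t0 + i1 / seg.rate)
    return mats, np.asarray(ends)


def eigen_entropy(m: SPDMatrix) -> float:
    """Shannon entropy of the trace-normalised eigenvalues."""
    lam = m.eigenvalues()
    if lam.min() <= 0:
        raise ValueError("matrix is not positive definite")
    p = lam / lam.sum()
    return float(-np.sum(p * np.log(p)))


def reference_matrix(candidates: list[SPDMatrix]) -> SPDMatrix:
    """Arithmetic mean of the five lowest eigenvalue-entropy candidates."""
    if len(candidates) < 5:
        raise ValueError(f"need >= 5 candidate matrices, got {len(candidates)}")
    entropies = np.array([eigen_entropy(m) for m in candidates])
    order = np.argsort(entropies, kind="stable")[:5]
    mean = np.mean([candidates[i].values for i in order], axis=0)
    return SPDMatrix(mean)


def air_distance(a: SPDMatrix, b: SPDMatrix) -> float:
    """Affine-invariant Riemannian distance between two SPD matrices.

    ``d = || Log(a^{-1/2} b a^{-1/2}) ||_F = sqrt(sum_c log^2 lambda_c)``
    with natural logs, where ``lambda_c`` solve the generalised eigenproblem
    ``b v = lambda a v``.  A true metric on the SPD cone, invariant under
    congruence by any invertible matrix.
    """
    if a.dim != b.dim:
        raise ValueError(f"dimension mismatch: {a.dim} vs {b.dim}")
    from scipy.linalg import eigh
    lam = eigh(b.values, a.values, eigvals_only=True)
    if np.any(lam <= 0):
        raise ValueError("inputs are not positive definite")
    return float(np.sqrt(np.sum(np.log(lam) ** 2)))


def distance_series(seg: MultichannelSegment, ref: SPDMatrix,
                    troughs: GFPSeries,
                    window_troughs: int = 35) -> DistanceSeries:
    """AIR distance of every sliding-window covariance to the reference."""
    mats, ends = sliding_covariances(seg, troughs, window_troughs)
    d = np.array([air_distance(m, ref) for m in mats])
    return DistanceSeries(values=d, trough_times=ends)


def detect_onset(series: DistanceSeries, k1: float = 3.0, k2: float = 4.0,
                 jump_floor: float = 0.1) -> OnsetDecision:
    """Derivative-threshold change detection on the distance series.

    Candidate = earliest index whose first derivative exceeds ``k1`` SDs and
    second derivative exceeds ``k2`` SDs (SDs taken over the whole series).
    The flanking-trough consistency check then compares mean distance over
    the three troughs after vs before the candidate: a level difference of
    at least ``jump_floor`` marks the shift as unrelated to the stimulus
    response, so the pupil-based fallback must re-derive the onset.
    """
    v = series.values
    n = v.size
    if n < 7:
        raise ValueError(f"series too short for detection: {n} < 7")
    # first differences on the trough-indexed series: the series is defined
    # at troughs, so no resampling or central smoothing is applied
    d1 = np.diff(v)
    d2 = np.diff(v, 2)
    s1, s2 = d1.std(), d2.std()
    thresholds = (k1 * s1, k2 * s2)
    # point t carries the change arriving at it: |v[t] - v[t-1]| and the
    # second difference ending at t must both be significant
    mask = np.zeros(n, dtype=bool)
    mask[2:] = (np.abs(d1[1:]) > thresholds[0]) & (np.abs(d2) > thresholds[1])
    # need three flanking troughs on each side for the consistency check
    mask[:3] = False
    mask[n - 3:] = False
    cand = np.where(mask)[0]
    if cand.size == 0:
        return OnsetDecision(None, None, adjusted_by_plr=False, excluded=True,
                             thresholds=thresholds, jump_floor=jump_floor)
    t = int(cand[0])
    # the threshold crossing sits partway up the change; walk back to the
    # foot of the ramp (where the per-step change loses significance) so the
    # index marks where the shift began rather than mid-rise
    sgn = np.sign(d1[t - 1]) or 1.0
    while t > 3 and sgn * (v[t] - v[t - 1]) > 0.5 * s1:
        t -= 1
    before = v[t - 3:t].mean()
    after = v[t + 1:t + 4].mean()
    unrelated = abs(after - before) >= jump_floor
    return OnsetDecision(
        detected_index=t, detected_time=float(series.trough_times[t]),
        adjusted_by_plr=bool(unrelated), excluded=False,
        thresholds=thresholds, jump_floor=jump_floor)


def plr_fallback_onset(left: np.ndarray, right: np.ndarray, rate: float,
                       t0: float = 0.0, expected_start: float = 0.0,
                       velocity_threshold: float = -0.25,
                       reflex_latency: float = 0.3) -> float | None:
    """Pupil-based secondary onset estimate.

    Finds the first time at or after ``expected_start`` where the mean
    normalised pupil diameter constricts faster than ``velocity_threshold``
    (baseline fraction per second) and subtracts ``reflex_latency`` — the
    light reflex lags the stimulus, so the constriction marks the stimulus
    onset that much earlier.  Returns ``None`` if no constriction is found.
    The series should already be baseline-normalised.
    """
    mean = (np.asarray(left, float) + np.asarray(right, float)) / 2.0
    vel = np.gradient(mean) * rate
    times = t0 + np.arange(mean.size) / rate
    hits = np.where((times >= expected_start) & (vel < velocity_threshold))[0]
    if hits.size == 0:
        return None
    return float(max(times[hits[0]] - reflex_latency, expected_start))


def epoch_pair_distances(seg: MultichannelSegment, troughs: GFPSeries,
                         pair: EpochPair,
                         window_troughs: int = 35,
                         warmup: float = 1.2) -> DistanceSeries:
    """Distance series for one reference/target epoch pair.

    The reference matrix comes from the latter half of ``pair.ref_range``;
    distances are computed over causal sliding windows whose *end* falls in
    ``pair.target_range``.  ``warmup`` seconds of data before the target
    range feed the first windows, so a change right at the start of the
    target epoch is still observable.
    """
    from dataclasses import replace as _replace

    def crop(lo: float, hi: float) -> tuple[MultichannelSegment, GFPSeries]:
        i0 = int(round((lo - seg.t0) * seg.rate))
        i1 = int(round((hi - seg.t0) * seg.rate))
        sub = MultichannelSegment(seg.samples[:, i0:i1].copy(), seg.rate,
                                  list(seg.channel_labels), lo)
        tmask = (troughs.trough_indices >= i0) & (troughs.trough_indices < i1)
        sub_troughs = GFPSeries(troughs.values[i0:i1],
                                troughs.trough_indices[tmask] - i0,
                                seg.rate, lo)
        return sub, sub_troughs

    r0, r1 = pair.ref_range
    ref_seg, ref_troughs = crop((r0 + r1) / 2.0, r1)  # latter half
    ref_mats, _ = sliding_covariances(ref_seg, ref_troughs, window_troughs)
    ref = reference_matrix(ref_mats)
    lo, hi = pair.target_range
    tgt_seg, tgt_troughs = crop(max(lo - warmup, seg.t0), hi)
    series = distance_series(tgt_seg, ref, tgt_troughs, window_troughs)
    keep = series.trough_times >= lo
    return DistanceSeries(series.values[keep], series.trough_times[keep])
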