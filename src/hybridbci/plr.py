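"""Pupillary-light-reflex decoding: QC, normalisation, Morse-CWT features.

The four LEDs follow distinct slow luminance patterns, so the pupil traces
they evoke differ in the timing and number of constriction/redilation
cycles.  Features are time-frequency wavelet power maps of the normalised
binocular diameter series, computed with the analytic generalised Morse
wavelet (shape ``gamma = 3``, time-bandwidth ``P^2 = 60``) restricted to
0.5-1.75 Hz — the band containing the slowest and fastest luminance cycle
rates of the pattern bank.  Left- and right-eye maps are stacked along the
frequency axis into a single tensor that feeds the temporal convolutional
classifier in :mod:`hybridbci.tcn`.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

__all__ = [
    "PupilTrial",
    "PupilTrialTensor",
    "reject_invalid_trials",
    "normalize_pupil",
    "morse_cwt",
    "cwt_features",
]


@dataclass
class PupilTrial:
    """Binocular diameter series (mm) with per-sample confidence."""

    left: np.ndarray
    right: np.ndarray
    confidence_left: np.ndarray
    confidence_right: np.ndarray
    rate: float = 30.0
    target_led: int | None = None

    def __post_init__(self) -> None:
        self.left = np.asarray(self.left, dtype=float)
        self.right = np.asarray(self.right, dtype=float)
        self.confidence_left = np.asarray(self.confidence_left, dtype=float)
        self.confidence_right = np.asarray(self.confidence_right, dtype=float)
        n = self.left.size
        if not (self.right.size == self.confidence_left.size
                == self.confidence_right.size == n):
            raise ValueError("all series must have equal length")

    @property
    def n_samples(self) -> int:
        return self.left.size


@dataclass
class PupilTrialTensor:
    """F x T wavelet-power features; F stacks both eyes (left block first)."""

    features: np.ndarray
    freqs_per_eye: np.ndarray
    target_led: int | None = None

    def __post_init__(self) -> None:
        self.features = np.asarray(self.features, dtype=float)
        if self.features.ndim != 2:
            raise ValueError("features must be 2-D (freq x time)")
        if np.any(self.features < 0):
            raise ValueError("wavelet power must be non-negative")


def _low_conf_runs(conf: np.ndarray, floor: float) -> list[tuple[int, int]]:
    low = conf < floor
    runs, start = [], None
    for i, flag in enumerate(low):
        if flag and start is None:
            start = i
        elif not flag and start is not None:
            runs.append((start, i))
            start = None
    if start is not None:
        runs.append((start, low.size))
    return runs


def reject_invalid_trials(trials: list[PupilTrial], confidence_floor: float = 0.6,
                          max_gap: float = 0.5,
                          ) -> tuple[list[PupilTrial], list[PupilTrial]]:
    """Split trials into (kept, rejected) by dropout criteria.

    A trial is rejected when either eye has a contiguous low-confidence run
    longer than ``max_gap`` seconds, or more than 25 % low-confidence samples
    overall — the automated analogue of visually discarding blink-corrupted
    trials.
    """
    kept, rejected = [], []
    for tr in trials:
        max_run_s = max(
            (max((b - a for a, b in _low_conf_runs(conf, confidence_floor)),
                 default=0) / tr.rate)
            for conf in (tr.confidence_left, tr.confidence_right))
        frac = max((tr.confidence_left < confidence_floor).mean(),
                   (tr.confidence_right < confidence_floor).mean())
        if max_run_s > max_gap or frac > 0.25:
            rejected.append(tr)
        else:
            kept.append(tr)
    return kept, rejected


def _interp_gaps(series: np.ndarray, conf: np.ndarray, floor: float) -> np.ndarray:
    good = conf >= floor
    if good.all():
        return series.copy()
    if not good.any():
        return series.copy()
    idx = np.arange(series.size)
    return np.interp(idx, idx[good], series[good])


def normalize_pupil(trial: PupilTrial, baseline: float = 0.5,
                    confidence_floor: float = 0.6) -> PupilTrial:
    """Gap-interpolate, then divide each eye by its own early-baseline mean.

    The first ``baseline`` seconds serve as the reference level, so the
    normalised series starts at ~1 and constrictions dip below it.
    """
    nb = max(1, int(round(baseline * trial.rate)))
    out = {}
    for side in ("left", "right"):
        series = getattr(trial, side)
        conf = getattr(trial, f"confidence_{side}")
        filled = _interp_gaps(series, conf, confidence_floor)
        b = filled[:nb].mean()
        if b <= 0:
            raise ValueError(f"non-positive {side} baseline ({b:.3g} mm)")
        out[side] = filled / b
    return PupilTrial(out["left"], out["right"],
                      trial.confidence_left.copy(), trial.confidence_right.copy(),
                      trial.rate, trial.target_led)


def morse_cwt(x: np.ndarray, rate: float, freqs: np.ndarray,
              gamma: float = 3.0, time_bandwidth: float = 60.0) -> np.ndarray:
    """Analytic generalised-Morse-wavelet CWT of a real 1-D signal.

    Frequency-domain filtering with ``Psi(w) = a * w^beta * exp(-w^gamma)``
    for ``w > 0`` and ``beta = P^2 / gamma``; the amplitude is normalised so
    a unit sinusoid at a wavelet's peak frequency yields unit magnitude.
    The signal is reflect-padded to tame edge effects of the long
    low-frequency wavelets.  Returns complex coefficients (F x N).
    """
    x = np.asarray(x, dtype=float)
    n = x.size
    beta = time_bandwidth / gamma
    wp = (beta / gamma) ** (1.0 / gamma)  # peak radian frequency
    pad = n - 1
    xp = np.pad(x, pad, mode="reflect")
    m = xp.size
    spec = np.fft.fft(xp)
    w = 2 * np.pi * np.fft.fftfreq(m)  # radians / sample
    out = np.empty((freqs.size, n), dtype=complex)
    peak_val = wp ** beta * np.exp(-wp ** gamma)
    for i, f in enumerate(np.asarray(freqs, dtype=float)):
        s = wp / (2 * np.pi * f / rate)
        sw = s * w
        psi = np.zeros(m)
        pos = sw > 0
        psi[pos] = 2.0 * (sw[pos] ** beta * np.exp(-sw[pos] ** gamma)) / peak_val
        conv = np.fft.ifft(spec * psi)
        out[i] = conv[pad:pad + n]
    return out


def cwt_features(trial: PupilTrial, gamma: float = 3.0,
                 time_bandwidth: float = 60.0,
                 freq_range: tuple[float, float] = (0.5, 1.75),
                 rows_per_eye: int = 61, n_times: int = 139) -> PupilTrialTensor:
    """Binocular wavelet-power tensor (2 * rows_per_eye) x n_times.

    The trial must already be normalised.  Frequencies are log-spaced over
    ``freq_range`` (ascending); the time axis is edge-padded symmetrically to
    ``n_times`` so the tensor shape matches the classifier contract.
    """
    if freq_range[1] >= trial.rate / 2:
        raise ValueError(
            f"freq_range {freq_range} exceeds Nyquist {trial.rate / 2} Hz")
    freqs = np.geomspace(freq_range[0], freq_range[1], rows_per_eye)
    blocks = []
    for series in (trial.left, trial.right):
        # remove the DC level; the analytic wavelet has zero mean anyway but
        # this keeps the padded edges well behaved
        coeffs = morse_cwt(series - series.mean(), trial.rate, freqs,
                           gamma, time_bandwidth)
        blocks.append(np.abs(coeffs) ** 2)
    feats = np.vstack(blocks)
    t = feats.shape[1]
    if t > n_times:
        lo = (t - n_times) // 2
        feats = feats[:, lo:lo + n_times]
    elif t < n_times:
        lpad = (n_times - t) // 2
        rpad = n_times - t - lpad
        feats = np.pad(feats, ((0, 0), (lpad, rpad)), mode="edge")
    return PupilTrialTensor(features=feats, freqs_per_eye=freqs,
                            target_led=trial.target_led)
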