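"""Shared signal-processing primitives for multichannel biosignals.

Everything downstream (SSVEP detection, FVEP epoching, Riemannian onset
detection) consumes :class:`MultichannelSegment`, a thin container around a
``C x N`` array with a sampling rate and channel labels.  The operations here
are deliberately small and composable: re-referencing, zero-phase IIR
band-pass filtering, global field power (GFP), sample covariance, and
event-locked epoching.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field, replace

import numpy as np
from scipy import signal as sps

__all__ = [
    "MultichannelSegment",
    "SPDMatrix",
    "GFPSeries",
    "rereference",
    "bandpass",
    "gfp",
    "covariance",
    "epoch",
]


@dataclass
class MultichannelSegment:
    """A window of multichannel data: ``samples`` is channels x time (uV)."""

    samples: np.ndarray
    rate: float
    channel_labels: list[str]
    t0: float = 0.0

    def __post_init__(self) -> None:
        self.samples = np.asarray(self.samples, dtype=float)
        if self.samples.ndim != 2:
            raise ValueError("samples must be a 2-D (channels x time) array")
        c, n = self.samples.shape
        if c < 1 or n < 2:
            raise ValueError(f"need at least 1 channel and 2 samples, got {c}x{n}")
        if len(self.channel_labels) != c:
            raise ValueError(
                f"{len(self.channel_labels)} labels for {c} channels"
            )
        if len(set(self.channel_labels)) != c:
            raise ValueError("channel labels must be unique")
        if self.rate <= 0:
            raise ValueError("sampling rate must be positive")

    @property
    def n_channels(self) -> int:
        return self.samples.shape[0]

    @property
    def n_samples(self) -> int:
        return self.samples.shape[1]

    @property
    def times(self) -> np.ndarray:
        return self.t0 + np.arange(self.n_samples) / self.rate

    def pick(self, labels: list[str]) -> "MultichannelSegment":
        """Return a copy restricted to ``labels``, in the given order."""
        missing = [l for l in labels if l not in self.channel_labels]
        if missing:
            raise KeyError(
                f"channels {missing} not in segment (have {self.channel_labels})"
            )
        idx = [self.channel_labels.index(l) for l in labels]
        return replace(self, samples=self.samples[idx].copy(),
                       channel_labels=list(labels))


@dataclass
class SPDMatrix:
    """Symmetric positive-definite matrix (channel covariance)."""

    values: np.ndarray

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=float)
        v = self.values
        if v.ndim != 2 or v.shape[0] != v.shape[1]:
            raise ValueError("SPD matrix must be square")
        if not np.allclose(v, v.T, atol=1e-10):
            raise ValueError("matrix is not symmetric to 1e-10")

    @property
    def dim(self) -> int:
        return self.values.shape[0]

    def eigenvalues(self) -> np.ndarray:
        return np.linalg.eigvalsh(self.values)

    def is_pd(self, tol: float = 0.0) -> bool:
        return bool(self.eigenvalues().min() > tol)


@dataclass
class GFPSeries:
    """Global field power over time plus the indices of its local troughs."""

    values: np.ndarray
    trough_indices: np.ndarray
    rate: float
    t0: float = 0.0

    @property
    def trough_times(self) -> np.ndarray:
        return self.t0 + self.trough_indices / self.rate


def rereference(seg: MultichannelSegment, ref_label: str) -> MultichannelSegment:
    """Subtract the reference channel from every channel and drop it."""
    if ref_label not in seg.channel_labels:
        raise KeyError(
            f"reference channel {ref_label!r} not present; "
            f"available: {seg.channel_labels}"
        )
    ref_idx = seg.channel_labels.index(ref_label)
    ref = seg.samples[ref_idx]
    keep = [i for i in range(seg.n_channels) if i != ref_idx]
    out = seg.samples[keep] - ref[None, :]
    labels = [seg.channel_labels[i] for i in keep]
    return MultichannelSegment(out, seg.rate, labels, seg.t0)


def _design_sos(low: float, high: float, rate: float, family: str,
                order: int, rp: float, rs: float) -> np.ndarray:
    nyq = rate / 2.0
    if not (0 < low < high):
        raise ValueError(f"need 0 < low < high, got {low}, {high}")
    if high >= nyq:
        raise ValueError(f"high cutoff {high} Hz >= Nyquist {nyq} Hz")
    wn = (low / nyq, high / nyq)
    if family == "butterworth":
        return sps.butter(order, wn, btype="bandpass", output="sos")
    if family == "elliptic":
        return sps.ellip(order, rp, rs, wn, btype="bandpass", output="sos")
    raise ValueError(f"unknown filter family {family!r}")


def bandpass(seg: MultichannelSegment, low: float, high: float,
             family: str = "butterworth", order: int = 3,
             rp: float = 1.0, rs: float = 40.0) -> MultichannelSegment:
    """Zero-phase (forward-backward) IIR band-pass.

    ``family`` is ``"butterworth"`` or ``"elliptic"``; ``rp``/``rs`` are the
    elliptic passband ripple and stopband attenuation in dB.  Zero-phase
    application preserves the latency of transient components, which matters
    because epochs are cut at millisecond offsets around stimulus transitions.
    """
    sos = _design_sos(low, high, seg.rate, family, order, rp, rs)
    out = sps.sosfiltfilt(sos, seg.samples, axis=1)
    return MultichannelSegment(out, seg.rate, list(seg.channel_labels), seg.t0)


def _local_troughs(v: np.ndarray) -> np.ndarray:
    """Strict local minima over a 3-sample neighbourhood.

    A plateau that is a minimum resolves to its first sample, keeping the
    window boundaries deterministic.
    """
    n = v.size
    if n < 3:
        return np.array([], dtype=int)
    cand = np.where((v[1:-1] < v[:-2]) & (v[1:-1] <= v[2:]))[0] + 1
    # drop later members of equal-value plateaus picked by the <= test
    keep = []
    for i in cand:
        if keep and i == keep[-1] + 1 and v[i] == v[keep[-1]]:
            continue
        keep.append(int(i))
    return np.asarray(keep, dtype=int)


def gfp(seg: MultichannelSegment) -> GFPSeries:
    """Global field power: RMS deviation of channels from their mean.

    ``G(t) = sqrt( sum_i (V_i(t) - V_mean(t))^2 / C )``.  Local troughs of G
    mark boundaries of quasi-stable scalp topographies and drive the dynamic
    sliding covariance windows.
    """
    if seg.n_channels < 2:
        raise ValueError("GFP requires at least 2 channels")
    dev = seg.samples - seg.samples.mean(axis=0, keepdims=True)
    g = np.sqrt(np.mean(dev ** 2, axis=0))
    return GFPSeries(g, _local_troughs(g), seg.rate, seg.t0)


def covariance(seg: MultichannelSegment, regularization: float = 0.0,
               center: bool = False) -> SPDMatrix:
    """Sample covariance ``Sigma = X X^T / (N - 1)`` plus ``reg * I``.

    Uncentered by default: band-passed EEG is near zero-mean, and the
    uncentered form is what the onset-detection pipeline is defined on.
    """
    x = seg.samples
    n = x.shape[1]
    if n < 2:
        raise ValueError("covariance needs at least 2 samples")
    if center:
        x = x - x.mean(axis=1, keepdims=True)
    sigma = x @ x.T / (n - 1)
    sigma = 0.5 * (sigma + sigma.T)
    if regularization:
        sigma = sigma + regularization * np.eye(sigma.shape[0])
    return SPDMatrix(sigma)


def epoch(seg: MultichannelSegment, events: list[float],
          window: tuple[float, float]) -> tuple[list[MultichannelSegment], int]:
    """Cut event-locked epochs.

    ``events`` are times on the same clock as ``seg.t0``; ``window`` is
    ``(pre_ms, post_ms)`` with pre typically negative (e.g. ``(-100, 350)``).
    The window is half-open on the sample grid, so every epoch has exactly
    ``round((post - pre) / 1000 * rate)`` samples.  Epochs that would extend
    beyond the segment are dropped; the second return value counts them.
    """
    pre_ms, post_ms = window
    if post_ms <= pre_ms:
        raise ValueError("window must span a positive duration")
    n_ep = int(round((post_ms - pre_ms) / 1000.0 * seg.rate))
    epochs: list[MultichannelSegment] = []
    dropped = 0
    for ev in events:
        start = int(round((ev + pre_ms / 1000.0 - seg.t0) * seg.rate))
        stop = start + n_ep
        if start < 0 or stop > seg.n_samples:
            dropped += 1
            continue
        epochs.append(MultichannelSegment(
            seg.samples[:, start:stop].copy(), seg.rate,
            list(seg.channel_labels), ev + pre_ms / 1000.0))
    if events and not epochs:
        warnings.warn("all events fell outside the segment; no epochs cut",
                      stacklevel=2)
    return epochs, dropped
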