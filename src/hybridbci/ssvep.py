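"""Wet-EEG SSVEP baseline: multivariate synchronization index (MSI) detection.

The gazed flicker frequency is recognised by measuring, for each candidate
frequency, how strongly the occipital channels synchronise with a sin/cos
reference bank at that frequency and its harmonics.  The index is the
entropy-based MSI computed on the joint correlation matrix of the EEG and the
reference set; being correlation-based, it is invariant to channel-wise
scaling.  The classifier simply takes the argmax over the four-frequency
bank, breaking exact ties toward the lowest LED id.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy.linalg import eigh, fractional_matrix_power

from .sigproc import MultichannelSegment
from .stimuli import SSVEP_BANK

__all__ = [
    "SSVEPDecision",
    "reference_bank",
    "synchronization_index",
    "classify_ssvep",
    "OCCIPITAL_CHANNELS",
]

OCCIPITAL_CHANNELS = ("O1", "Oz", "O2")


@dataclass
class SSVEPDecision:
    per_frequency_index: dict[float, float]
    predicted_led: int


def reference_bank(freq: float, n_harmonics: int, rate: float,
                   n_samples: int) -> MultichannelSegment:
    """Sin/cos reference rows at ``freq, 2*freq, ...`` (2 rows per harmonic)."""
    if freq * n_harmonics >= rate / 2:
        raise ValueError(
            f"{n_harmonics} harmonics of {freq} Hz exceed Nyquist ({rate / 2} Hz)")
    t = np.arange(n_samples) / rate
    rows, labels = [], []
    for h in range(1, n_harmonics + 1):
        rows.append(np.sin(2 * np.pi * h * freq * t))
        rows.append(np.cos(2 * np.pi * h * freq * t))
        labels += [f"sin{h}x{freq:g}", f"cos{h}x{freq:g}"]
    return MultichannelSegment(np.vstack(rows), rate, labels)


def synchronization_index(eeg: MultichannelSegment,
                          ref: MultichannelSegment) -> float:
    """Entropy-based MSI between an EEG segment and a reference set.

    Builds the joint correlation matrix of the stacked signals, whitens the
    two diagonal blocks, and returns ``S = 1 + sum(l' log l') / log M`` over
    the normalised eigenvalues ``l'``.  ``S`` is 0 for independent signals
    and grows toward 1 with synchronization.
    """
    if eeg.n_samples != ref.n_samples:
        raise ValueError("EEG and reference must have equal sample counts")
    for seg, name in ((eeg, "eeg"), (ref, "ref")):
        sd = seg.samples.std(axis=1)
        if np.any(sd == 0):
            bad = [seg.channel_labels[i] for i in np.where(sd == 0)[0]]
            raise ValueError(f"zero-variance {name} channel(s): {bad}")
    x = eeg.samples - eeg.samples.mean(axis=1, keepdims=True)
    y = ref.samples - ref.samples.mean(axis=1, keepdims=True)
    x = x / x.std(axis=1, keepdims=True)
    y = y / y.std(axis=1, keepdims=True)
    n = x.shape[1]
    c11 = x @ x.T / n
    c22 = y @ y.T / n
    c12 = x @ y.T / n
    p, q = c11.shape[0], c22.shape[0]
    m = p + q
    c = np.block([[c11, c12], [c12.T, c22]])
    u = np.zeros((m, m))
    u[:p, :p] = fractional_matrix_power(c11, -0.5).real
    u[p:, p:] = fractional_matrix_power(c22, -0.5).real
    r = u @ c @ u.T
    lam = np.linalg.eigvalsh(r)
    lam = np.clip(lam, 0.0, None)
    lam_n = lam / lam.sum()
    nz = lam_n > 0
    entropy = -float(np.sum(lam_n[nz] * np.log(lam_n[nz])))
    return 1.0 - entropy / np.log(m)


def classify_ssvep(eeg: MultichannelSegment,
                   bank: tuple[float, ...] = SSVEP_BANK,
                   n_harmonics: int = 2,
                   channels: tuple[str, ...] = OCCIPITAL_CHANNELS,
                   ) -> SSVEPDecision:
    """Four-class SSVEP decision from occipital channels.

    The EEG should already be referenced and band-passed and restricted to
    the analysis window.  Ties break toward the lowest LED id.
    """
    seg = eeg.pick(list(channels)) if set(channels) != set(eeg.channel_labels) else eeg
    indices: dict[float, float] = {}
    for f in bank:
        ref = reference_bank(f, n_harmonics, seg.rate, seg.n_samples)
        indices[f] = synchronization_index(seg, ref)
    vals = np.array([indices[f] for f in bank])
    led = int(np.argmax(vals)) + 1  # argmax returns first (lowest id) on ties
    return SSVEPDecision(per_frequency_index=indices, predicted_led=led)
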