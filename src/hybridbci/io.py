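"""Readers and writers: delimited EEG, minimal EDF, pupil CSV, manifests.

Delimited EEG text is the primary interchange format (a two-line header with
rate and channel labels, then one column per channel).  EDF is supported for
compatibility with clinical tooling: reading goes through MNE, writing
through a minimal single-record EDF encoder.  Pupil series round-trip via
the common eye-tracker export layout ``(pupil_timestamp, eye_id, confidence,
diameter_3d)`` with eye_id 0 = right, 1 = left.
"""

from __future__ import annotations

import json
from pathlib import Path

import numpy as np
import pandas as pd

from .plr import PupilTrial
from .sigproc import MultichannelSegment

__all__ = [
    "write_eeg_delimited",
    "read_eeg_delimited",
    "write_edf",
    "read_edf",
    "read_eeg",
    "write_pupil_csv",
    "read_pupil",
    "write_manifest",
    "read_manifest",
]


# -- delimited EEG ----------------------------------------------------------

def write_eeg_delimited(seg: MultichannelSegment, path: str | Path) -> None:
    path = Path(path)
    with path.open("w") as fh:
        fh.write(f"# rate_hz={seg.rate} t0_s={seg.t0}\n")
        fh.write("\t".join(seg.channel_labels) + "\n")
        np.savetxt(fh, seg.samples.T, fmt="%.6f", delimiter="\t")


def read_eeg_delimited(path: str | Path) -> MultichannelSegment:
    path = Path(path)
    with path.open() as fh:
        meta = fh.readline()
        if not meta.startswith("#"):
            raise ValueError(f"{path}: missing '# rate_hz=...' header line")
        fields = dict(kv.split("=") for kv in meta[1:].split())
        if "rate_hz" not in fields:
            raise ValueError(f"{path}: header lacks rate_hz field")
        labels = fh.readline().strip().split("\t")
        data = np.loadtxt(fh, delimiter="\t", ndmin=2)
    return MultichannelSegment(data.T, float(fields["rate_hz"]), labels,
                               float(fields.get("t0_s", 0.0)))


# -- EDF --------------------------------------------------------------------

def _pad(s: str, n: int) -> bytes:
    return s[:n].ljust(n).encode("ascii")


def write_edf(seg: MultichannelSegment, path: str | Path) -> None:
    """Minimal EDF writer: one data record holding the whole segment.

    Samples are quantised to 16 bits over each channel's physical range
    (units uV).  Timing metadata beyond the sampling rate is not preserved.
    """
    path = Path(path)
    ns = seg.n_channels
    n = seg.n_samples
    duration = n / seg.rate
    pmins = seg.samples.min(axis=1)
    pmaxs = seg.samples.max(axis=1)
    span = np.where(pmaxs - pmins <= 0, 1.0, pmaxs - pmins)
    dmin, dmax = -32768, 32767
    header = b"".join([
        _pad("0", 8), _pad("X X X X", 80), _pad("Startdate X X X X", 80),
        _pad("01.01.00", 8), _pad("00.00.00", 8),
        _pad(str(256 * (ns + 1)), 8), _pad("", 44),
        _pad("1", 8), _pad(f"{duration:g}", 8), _pad(str(ns), 4),
    ])
    per = [
        b"".join(_pad(l, 16) for l in seg.channel_labels),
        b"".join(_pad("", 80) for _ in range(ns)),
        b"".join(_pad("uV", 8) for _ in range(ns)),
        b"".join(_pad(f"{v:.6g}", 8) for v in pmins),
        b"".join(_pad(f"{v:.6g}", 8) for v in pmaxs),
        b"".join(_pad(str(dmin), 8) for _ in range(ns)),
        b"".join(_pad(str(dmax), 8) for _ in range(ns)),
        b"".join(_pad("", 80) for _ in range(ns)),
        b"".join(_pad(str(n), 8) for _ in range(ns)),
        b"".join(_pad("", 32) for _ in range(ns)),
    ]
    digital = ((seg.samples - pmins[:, None]) / span[:, None]
               * (dmax - dmin) + dmin)
    digital = np.clip(np.round(digital), dmin, dmax).astype("<i2")
    with path.open("wb") as fh:
        fh.write(header)
        for block in per:
            fh.write(block)
        fh.write(digital.tobytes())  # record = channel-sequential


def read_edf(path: str | Path) -> MultichannelSegment:
    """Read an EDF file via MNE; returns samples in uV."""
    import mne

    raw = mne.io.read_raw_edf(str(path), preload=True, verbose="error")
    data = raw.get_data() * 1e6  # volts -> uV
    return MultichannelSegment(data, float(raw.info["sfreq"]),
                               list(raw.ch_names), 0.0)


def read_eeg(path: str | Path, format: str = "delimited") -> MultichannelSegment:
    if format == "delimited":
        return read_eeg_delimited(path)
    if format == "edf":
        return read_edf(path)
    raise ValueError(f"unknown EEG format {format!r}; expected edf|delimited")


# -- pupil ------------------------------------------------------------------

_PUPIL_COLS = ("pupil_timestamp", "eye_id", "confidence", "diameter_3d")


def write_pupil_csv(trial: PupilTrial, path: str | Path,
                    t0: float = 0.0) -> None:
    n = trial.n_samples
    t = t0 + np.arange(n) / trial.rate
    rows = []
    for eye_id, series, conf in ((1, trial.left, trial.confidence_left),
                                 (0, trial.right, trial.confidence_right)):
        for i in range(n):
            rows.append((t[i], eye_id, conf[i], series[i]))
    df = pd.DataFrame(rows, columns=list(_PUPIL_COLS))
    df.to_csv(path, index=False)


def read_pupil(path: str | Path, rate: float = 30.0) -> PupilTrial:
    """Read a pupil export; rows are sorted by timestamp, eyes split by id."""
    df = pd.read_csv(path)
    missing = [c for c in _PUPIL_COLS if c not in df.columns]
    if missing:
        raise ValueError(f"{path}: missing pupil columns {missing}")
    df = df.sort_values("pupil_timestamp", kind="stable")
    eyes = {}
    for eye_id, name in ((1, "left"), (0, "right")):
        sub = df[df.eye_id == eye_id]
        eyes[name] = (sub.diameter_3d.to_numpy(), sub.confidence.to_numpy())
    if eyes["left"][0].size == 0 or eyes["right"][0].size == 0:
        import warnings
        warnings.warn("monocular pupil file: duplicating the available eye")
        have = "left" if eyes["left"][0].size else "right"
        eyes["left"] = eyes["right"] = eyes[have]
    return PupilTrial(eyes["left"][0], eyes["right"][0],
                      eyes["left"][1], eyes["right"][1], rate)


# -- manifests --------------------------------------------------------------

def write_manifest(path: str | Path, entries: list[dict], meta: dict) -> None:
    Path(path).write_text(json.dumps({"meta": meta, "trials": entries},
                                     indent=2))


def read_manifest(path: str | Path) -> tuple[list[dict], dict]:
    d = json.loads(Path(path).read_text())
    return d["trials"], d["meta"]
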