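"""Readers, writers, and pipeline configuration.

Recordings travel in two formats: European Data Format (EDF, 16-bit) and
a flat binary float32 matrix with a JSON sidecar carrying labels,
sampling rate, and eye state.  EDF reading goes through MNE; writing uses
a minimal EDF+-free writer sufficient for continuous uV EEG (one data
record per second, per-channel physical scaling).  Feature tables, group
statistics, and metadata are plain CSV; model reports and run logs are
JSON.
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from .montage import normalize_label
from .preprocess import Recording

# ---------------------------------------------------------------------------
# EDF


def _edf_field(value, width: int) -> bytes:
    s = str(value)[:width]
    return s.ljust(width).encode("ascii")


def _phys_str(v: float) -> str:
    """Format a physical min/max so it fits EDF's 8-character field losslessly."""
    for prec in (6, 5, 4, 3, 2, 1):
        s = f"{v:.{prec}g}"
        if len(s) <= 8:
            return s
    return f"{v:.0e}"[:8]


def write_edf(rec: Recording, path) -> None:
    """Write a recording as 16-bit EDF with 1-s data records.

    Physical ranges are set per channel from the data (padded 1%), so
    quantization error is bounded by range/2^16.  The recording is
    truncated to a whole number of seconds; the sampling rate must be an
    integer.
    """
    fs = rec.sampling_rate_hz
    if abs(fs - round(fs)) > 1e-9:
        raise ValueError("EDF writer requires an integer sampling rate")
    fs = int(round(fs))
    n_ch = rec.n_channels
    n_rec = rec.samples.shape[1] // fs
    if n_rec < 1:
        raise ValueError("recording shorter than one EDF data record (1 s)")
    data = rec.samples[:, : n_rec * fs]

    pmin = data.min(axis=1)
    pmax = data.max(axis=1)
    pad = np.maximum(0.01 * (pmax - pmin), 1e-6)
    # Quantize the ranges to their 8-character header representation first,
    # so the digital scaling matches what a reader will parse back.
    pmin_s = [_phys_str(v) for v in pmin - pad]
    pmax_s = [_phys_str(v) for v in pmax + pad]
    pmin = np.array([float(s) for s in pmin_s])
    pmax = np.array([float(s) for s in pmax_s])
    dmin, dmax = -32768, 32767
    scale = (pmax - pmin) / (dmax - dmin)
    digital = np.clip(np.round((data - pmin[:, None]) / scale[:, None]) + dmin,
                      dmin, dmax).astype("<i2")

    header = b"".join([
        _edf_field("0", 8),
        _edf_field(f"sub {rec.subject_id}", 80),
        _edf_field(f"eeg {rec.eye_state}", 80),
        _edf_field("01.01.20", 8),
        _edf_field("00.00.00", 8),
        _edf_field(256 * (1 + n_ch), 8),
        _edf_field("", 44),
        _edf_field(n_rec, 8),
        _edf_field(1, 8),
        _edf_field(n_ch, 4),
    ])
    sig = b"".join([
        b"".join(_edf_field(f"EEG {c}", 16) for c in rec.channel_labels),
        b"".join(_edf_field("AgAgCl electrode", 80) for _ in range(n_ch)),
        b"".join(_edf_field("uV", 8) for _ in range(n_ch)),
        b"".join(_edf_field(s, 8) for s in pmin_s),
        b"".join(_edf_field(s, 8) for s in pmax_s),
        b"".join(_edf_field(dmin, 8) for _ in range(n_ch)),
        b"".join(_edf_field(dmax, 8) for _ in range(n_ch)),
        b"".join(_edf_field("", 80) for _ in range(n_ch)),
        b"".join(_edf_field(fs, 8) for _ in range(n_ch)),
        b"".join(_edf_field("", 32) for _ in range(n_ch)),
    ])
    with open(path, "wb") as f:
        f.write(header + sig)
        for r in range(n_rec):
            block = digital[:, r * fs:(r + 1) * fs]
            f.write(block.tobytes())


def read_edf(path, subject_id: str | None = None,
             eye_state: str | None = None) -> Recording:
    """Read an EDF recording via MNE, mapping labels to canonical 10-20 names.

    Units are converted to uV (MNE loads EEG in volts).  Unknown channel
    labels raise with the offending names listed.
    """
    import mne

    raw = mne.io.read_raw_edf(path, preload=True, verbose="error")
    labels = []
    unknown = []
    for name in raw.ch_names:
        stripped = name.removeprefix("EEG ").strip()
        try:
            labels.append(normalize_label(stripped))
        except ValueError:
            unknown.append(name)
    if unknown:
        raise ValueError(f"unmappable channel labels in {path}: {unknown}")
    info = json.loads(raw.info["description"] or "{}") if raw.info["description"] else {}
    return Recording(
        subject_id=subject_id or info.get("subject_id", Path(path).stem),
        eye_state=eye_state or info.get("eye_state", "EO"),
        sampling_rate_hz=float(raw.info["sfreq"]),
        channel_labels=tuple(labels),
        samples=raw.get_data() * 1e6,
        provenance=[{"op": "read", "format": "edf", "path": str(path)}],
    )


# ---------------------------------------------------------------------------
# flat matrix + JSON sidecar


def write_matrix(rec: Recording, path) -> None:
    """Write samples as little-endian float64 (channels x time, C order)
    next to a .json sidecar; the round trip is bit-identical."""
    path = Path(path)
    rec.samples.astype("<f8").tofile(path)
    sidecar = {
        "subject_id": rec.subject_id,
        "eye_state": rec.eye_state,
        "sampling_rate_hz": rec.sampling_rate_hz,
        "channel_labels": list(rec.channel_labels),
        "shape": list(rec.samples.shape),
        "dtype": "<f8",
        "units": "uV",
    }
    path.with_suffix(path.suffix + ".json").write_text(json.dumps(sidecar, indent=1))


def read_matrix(path) -> Recording:
    path = Path(path)
    sidecar = json.loads(path.with_suffix(path.suffix + ".json").read_text())
    if sidecar.get("units", "uV") not in ("uV", "mV"):
        raise ValueError(f"unsupported units {sidecar.get('units')!r}; expected uV or mV")
    data = np.fromfile(path, dtype=sidecar["dtype"]).reshape(sidecar["shape"])
    if sidecar.get("units") == "mV":
        data = data * 1000.0
    return Recording(
        subject_id=sidecar["subject_id"], eye_state=sidecar["eye_state"],
        sampling_rate_hz=float(sidecar["sampling_rate_hz"]),
        channel_labels=tuple(sidecar["channel_labels"]),
        samples=np.asarray(data, dtype=np.float64),
        provenance=[{"op": "read", "format": "matrix+json", "path": str(path)}],
    )


def read_recording(path, format: str | None = None, **kwargs) -> Recording:
    """Dispatch on format ("edf" or "matrix"), inferring from the suffix."""
    path = Path(path)
    fmt = format or ("edf" if path.suffix.lower() == ".edf" else "matrix")
    if fmt == "edf":
        return read_edf(path, **kwargs)
    if fmt in ("matrix", "matrix+json"):
        return read_matrix(path)
    raise ValueError(f"unknown recording format {fmt!r}")


# ---------------------------------------------------------------------------
# configuration


@dataclasses.dataclass
class PipelineConfig:
    """End-to-end pipeline settings; defaults follow the clinical protocol."""

    band: tuple[float, float] = (1.0, 40.0)
    notch: tuple[float, float] = (49.0, 51.0)
    resample_hz: float = 500.0
    epoch_s: float = 2.0
    reject_uv: float = 150.0
    ica: bool = True
    seed: int = 0
    t_variant: str = "welch"
    cv_folds: int = 10
    n_boot: int = 2000

    def to_dict(self) -> dict:
        d = dataclasses.asdict(self)
        d["band"] = list(d["band"])
        d["notch"] = list(d["notch"])
        return d

    @classmethod
    def from_dict(cls, d: dict) -> "PipelineConfig":
        d = dict(d)
        for k in ("band", "notch"):
            if k in d:
                d[k] = tuple(d[k])
        return cls(**d)

    def save(self, path) -> None:
        Path(path).write_text(yaml.safe_dump(self.to_dict()))

    @classmethod
    def load(cls, path) -> "PipelineConfig":
        return cls.from_dict(yaml.safe_load(Path(path).read_text()))

    def hash(self) -> str:
        return hashlib.sha256(
            json.dumps(self.to_dict(), sort_keys=True).encode()).hexdigest()[:12]
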