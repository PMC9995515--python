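"""Reading and writing recordings.

Readers cover EDF and BrainVision Core Data Format through MNE, plus a simple
internal fixture format (``.npy`` array with a JSON sidecar) used for exact
round-trips in tests and synthetic cohorts.

The EDF writer emits plain 16-bit EDF (one 1-second data record per second of
signal, physical units microvolts); files it writes are read back with
``mne.io.read_raw_edf``.
"""

from __future__ import annotations

import json
from pathlib import Path

import numpy as np

from .recording import Recording

_EDF_DIGITAL_MIN = -32768
_EDF_DIGITAL_MAX = 32767


def _edf_field(value, width: int) -> bytes:
    s = str(value)
    if len(s) > width:
        # shorten floats that overflow their fixed-width header field
        s = f"{float(value):.{max(width - 8, 1)}g}"
    if len(s) > width:
        raise ValueError(f"EDF header field {value!r} exceeds {width} chars")
    return s.ljust(width).encode("ascii")


def write_edf(recording: Recording, path: str | Path) -> Path:
    """Write a Recording as 16-bit EDF; trailing partial seconds are dropped."""
    path = Path(path)
    fs = recording.sample_rate
    if abs(fs - round(fs)) > 1e-9:
        raise ValueError("EDF writer requires an integer sampling rate")
    fs = int(round(fs))
    n_records = recording.n_samples // fs
    if n_records < 1:
        raise ValueError("recording shorter than one EDF data record (1 s)")
    n_ch = recording.n_channels
    data = recording.data[:, : n_records * fs]

    # per-channel physical scaling to span the 16-bit digital range
    phys_min = data.min(axis=1)
    phys_max = data.max(axis=1)
    flat = phys_max - phys_min < 1e-12
    phys_min = np.where(flat, phys_min - 1.0, phys_min)
    phys_max = np.where(flat, phys_max + 1.0, phys_max)
    scale = (phys_max - phys_min) / (_EDF_DIGITAL_MAX - _EDF_DIGITAL_MIN)
    digital = np.round((data - phys_min[:, None]) / scale[:, None] + _EDF_DIGITAL_MIN)
    digital = digital.clip(_EDF_DIGITAL_MIN, _EDF_DIGITAL_MAX).astype("<i2")

    header = b"".join(
        [
            _edf_field(0, 8),  # version
            _edf_field(f"{recording.subject_id} {recording.group}", 80),
            _edf_field(f"{recording.condition} resting-state EEG", 80),
            _edf_field("01.01.20", 8),
            _edf_field("00.00.00", 8),
            _edf_field(256 * (1 + n_ch), 8),
            _edf_field("", 44),
            _edf_field(n_records, 8),
            _edf_field(1, 8),  # record duration, s
            _edf_field(n_ch, 4),
        ]
    )
    sig = b"".join(
        [
            b"".join(_edf_field(lbl, 16) for lbl in recording.channel_labels),
            b"".join(_edf_field("AgAgCl", 80) for _ in range(n_ch)),
            b"".join(_edf_field("uV", 8) for _ in range(n_ch)),
            b"".join(_edf_field(f"{v:.6g}", 8) for v in phys_min),
            b"".join(_edf_field(f"{v:.6g}", 8) for v in phys_max),
            b"".join(_edf_field(_EDF_DIGITAL_MIN, 8) for _ in range(n_ch)),
            b"".join(_edf_field(_EDF_DIGITAL_MAX, 8) for _ in range(n_ch)),
            b"".join(_edf_field("", 80) for _ in range(n_ch)),
            b"".join(_edf_field(fs, 8) for _ in range(n_ch)),
            b"".join(_edf_field("", 32) for _ in range(n_ch)),
        ]
    )
    records = digital.reshape(n_ch, n_records, fs).transpose(1, 0, 2)
    with open(path, "wb") as fh:
        fh.write(header)
        fh.write(sig)
        fh.write(records.tobytes())
    return path


def _from_mne_raw(raw, subject_id: str, group: str, condition: str) -> Recording:
    data_uv = raw.get_data(picks="eeg") * 1e6  # MNE stores volts
    return Recording(
        subject_id=subject_id,
        group=group,
        condition=condition,
        sample_rate=float(raw.info["sfreq"]),
        channel_labels=tuple(raw.ch_names),
        data=data_uv,
    )


def read_edf(path: str | Path, subject_id: str = "", group: str = "unknown",
             condition: str = "EC") -> Recording:
    import mne

    raw = mne.io.read_raw_edf(str(path), preload=True, verbose="error")
    return _from_mne_raw(raw, subject_id or Path(path).stem, group, condition)


def read_brainvision(vhdr_path: str | Path, subject_id: str = "",
                     group: str = "unknown", condition: str = "EC") -> Recording:
    import mne

    raw = mne.io.read_raw_brainvision(str(vhdr_path), preload=True, verbose="error")
    return _from_mne_raw(raw, subject_id or Path(vhdr_path).stem, group, condition)


# ---------------------------------------------------------------------------
# internal fixture format: <stem>.npy + <stem>.json sidecar (exact round-trip)
# ---------------------------------------------------------------------------

def write_fixture(recording: Recording, directory: str | Path) -> Path:
    directory = Path(directory)
    directory.mkdir(parents=True, exist_ok=True)
    stem = f"{recording.subject_id}_{recording.condition}"
    np.save(directory / f"{stem}.npy", recording.data)
    meta = {
        "subject_id": recording.subject_id,
        "group": recording.group,
        "condition": recording.condition,
        "sample_rate": recording.sample_rate,
        "channel_labels": list(recording.channel_labels),
        "units": "uV",
    }
    (directory / f"{stem}.json").write_text(json.dumps(meta, indent=1))
    return directory / f"{stem}.npy"


def read_fixture(npy_path: str | Path) -> Recording:
    npy_path = Path(npy_path)
    meta = json.loads(npy_path.with_suffix(".json").read_text())
    return Recording(
        subject_id=meta["subject_id"],
        group=meta["group"],
        condition=meta["condition"],
        sample_rate=meta["sample_rate"],
        channel_labels=tuple(meta["channel_labels"]),
        data=np.load(npy_path),
    )


def read_recording(path: str | Path, **kw) -> Recording:
    """Dispatch on extension: .edf, .vhdr (BrainVision) or .npy fixture."""
    path = Path(path)
    ext = path.suffix.lower()
    if ext == ".edf":
        return read_edf(path, **kw)
    if ext == ".vhdr":
        return read_brainvision(path, **kw)
    if ext == ".npy":
        return read_fixture(path)
    raise ValueError(f"unsupported recording format: {path.name}")


def load_directory(directory: str | Path) -> list[Recording]:
    """Load every recording (fixture, EDF, BrainVision) found in a directory."""
    directory = Path(directory)
    paths = sorted(
        p for p in directory.iterdir()
        if p.suffix.lower() in {".npy", ".edf", ".vhdr"}
    )
    if not paths:
        raise FileNotFoundError(f"no recordings (.npy/.edf/.vhdr) in {directory}")
    return [read_recording(p) for p in paths]
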