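"""Readers and writers for referential recordings.

Two on-disk layouts are supported:

* **Columnar text** — one CSV per subject: a header row of electrode
  labels, one row per sample, '.' decimal, UTF-8.  A population
  directory adds a ``manifest.jsonl`` with one JSON object per subject
  (subject_id, group, affected_electrodes, fs, seed, file).
* **EDF** — read-only, through :mod:`mne` when it is installed.

Electrode labels are matched case-insensitively against the canonical
16-name set (legacy temporal names T3/T4/T5/T6 are the canonical ones
here).  Midline leads (Fz, Cz, Pz) are recognized, dropped and logged;
any other unmatched label is an error.
"""

from __future__ import annotations

import json
import logging
from pathlib import Path

import numpy as np
import pandas as pd

from .montage import ELECTRODES, BipolarRecording
from .types import ReferentialRecording

logger = logging.getLogger("epichannel")

_CANONICAL = {e.lower(): e for e in ELECTRODES}
_DROPPABLE = {"fz", "cz", "pz"}


def _normalize_labels(labels) -> tuple[list[str], list[str]]:
    """Map raw labels onto the canonical set; return (kept, dropped)."""
    kept, dropped, unknown = [], [], []
    for raw in labels:
        key = str(raw).strip().lower().replace("eeg ", "").replace("-ref", "")
        if key in _CANONICAL:
            kept.append((raw, _CANONICAL[key]))
        elif key in _DROPPABLE:
            dropped.append(str(raw))
        else:
            unknown.append(str(raw))
    if unknown:
        raise ValueError(
            f"unrecognized electrode label(s): {unknown}; expected the "
            f"10-20 names {list(ELECTRODES)} (Fz/Cz/Pz are dropped)"
        )
    return kept, dropped


def write_recording(recording: ReferentialRecording, path) -> Path:
    """Write one recording as columnar text (electrodes as columns)."""
    path = Path(path)
    path.parent.mkdir(parents=True, exist_ok=True)
    frame = pd.DataFrame(recording.data.T, columns=list(recording.electrodes))
    frame.to_csv(path, index=False, float_format="%.6f")
    return path


def read_recording(
    path,
    format: str = "columnar",
    fs: float | None = None,
    subject_id: str | None = None,
    group: str = "unknown",
    affected_electrodes=(),
) -> ReferentialRecording:
    """Read one referential recording from disk.

    ``format`` is ``"columnar"`` or ``"edf"``.  For columnar files the
    sampling rate must be supplied (there is no header field for it);
    for EDF it is taken from the file header.
    """
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(str(path))
    if format == "columnar":
        frame = pd.read_csv(path)
        labels = list(frame.columns)
        data_by_label = {lab: frame[lab].to_numpy(dtype=float) for lab in labels}
        if fs is None:
            raise ValueError("fs is required for columnar recordings")
        file_fs = float(fs)
    elif format == "edf":
        try:
            import mne
        except ImportError as exc:  # pragma: no cover - optional extra
            raise ImportError(
                "reading EDF requires the 'mne' package "
                "(install epichannel[edf])"
            ) from exc
        raw = mne.io.read_raw_edf(str(path), preload=True, verbose="error")
        labels = list(raw.ch_names)
        data_by_label = dict(zip(labels, raw.get_data() * 1e6))  # V -> uV
        file_fs = float(raw.info["sfreq"])
    else:
        raise ValueError(f"unknown format {format!r}")

    kept, dropped = _normalize_labels(labels)
    if dropped:
        logger.info("dropping midline lead(s) %s from %s", dropped, path.name)
    have = {canonical for _, canonical in kept}
    missing = [e for e in ELECTRODES if e not in have]
    if missing:
        raise ValueError(f"recording {path.name} is missing electrode(s) {missing}")
    by_canonical = {canonical: data_by_label[raw] for raw, canonical in kept}
    data = np.vstack([by_canonical[e] for e in ELECTRODES])
    return ReferentialRecording(
        subject_id=subject_id or path.stem,
        group=group,
        electrodes=ELECTRODES,
        fs=file_fs,
        data=data,
        affected_electrodes=frozenset(affected_electrodes),
    )


def write_population(
    recordings: list[ReferentialRecording], directory, seed: int | None = None
) -> Path:
    """Write a population directory: per-subject CSVs plus manifest.jsonl."""
    directory = Path(directory)
    directory.mkdir(parents=True, exist_ok=True)
    manifest = directory / "manifest.jsonl"
    with manifest.open("w", encoding="utf-8") as fh:
        for rec in recordings:
            fname = f"{rec.subject_id}.csv"
            write_recording(rec, directory / fname)
            fh.write(
                json.dumps(
                    {
                        "subject_id": rec.subject_id,
                        "group": rec.group,
                        "affected_electrodes": sorted(rec.affected_electrodes),
                        "fs": rec.fs,
                        "seed": seed,
                        "file": fname,
                    }
                )
                + "\n"
            )
    return directory


def read_population(directory) -> list[ReferentialRecording]:
    """Read a population directory written by :func:`write_population`."""
    directory = Path(directory)
    manifest = directory / "manifest.jsonl"
    if not manifest.exists():
        raise FileNotFoundError(f"no manifest.jsonl in {directory}")
    recordings = []
    with manifest.open(encoding="utf-8") as fh:
        for line in fh:
            if not line.strip():
                continue
            entry = json.loads(line)
            recordings.append(
                read_recording(
                    directory / entry["file"],
                    fs=entry["fs"],
                    subject_id=entry["subject_id"],
                    group=entry.get("group", "unknown"),
                    affected_electrodes=entry.get("affected_electrodes", ()),
                )
            )
    return recordings


def write_bipolar(recording: BipolarRecording, path) -> Path:
    """Write a bipolar recording as columnar text (LB labels as columns)."""
    path = Path(path)
    path.parent.mkdir(parents=True, exist_ok=True)
    frame = pd.DataFrame(recording.data.T, columns=list(recording.channels))
    frame.to_csv(path, index=False, float_format="%.6f")
    return path
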