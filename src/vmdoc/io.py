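"""Reading and writing cohorts, feature tables and reports.

Cohorts are stored as one CSV per subject (rows = samples, header = channel
names) plus a ``manifest.csv`` carrying subject_id, label, CRS-R, GCS.  EDF
recordings are read through :mod:`mne` when it is installed.
"""

from __future__ import annotations

import json
import warnings
from pathlib import Path
from typing import List, Optional, Sequence

import numpy as np
import pandas as pd

from .preprocess import CHANNELS_17, CLASS_LABELS, Recording

__all__ = ["write_cohort_csv", "read_recordings", "read_recording_csv",
           "write_recording_csv"]

MANIFEST_COLUMNS = ["subject_id", "file", "label", "crs_r", "gcs", "fs"]


def write_recording_csv(rec: Recording, path) -> None:
    df = pd.DataFrame(rec.data.T, columns=rec.channel_names)
    df.to_csv(path, index=False, float_format="%.6g")


def read_recording_csv(path, fs: float = 256.0, **meta) -> Recording:
    df = pd.read_csv(path)
    return Recording(data=df.to_numpy(float).T, fs=fs,
                     channel_names=list(df.columns), **meta)


def write_cohort_csv(cohort: Sequence[Recording], out_dir) -> Path:
    """Write a cohort as per-subject CSVs plus a manifest; returns manifest path."""
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    rows = []
    for rec in cohort:
        fname = f"{rec.subject_id}.csv"
        write_recording_csv(rec, out / fname)
        rows.append({"subject_id": rec.subject_id, "file": fname,
                     "label": rec.label, "crs_r": rec.crs_r, "gcs": rec.gcs,
                     "fs": rec.fs})
    manifest = out / "manifest.csv"
    pd.DataFrame(rows, columns=MANIFEST_COLUMNS).to_csv(manifest, index=False)
    return manifest


def _validate_channels(rec: Recording, wanted: Sequence[str]) -> Recording:
    extra = [ch for ch in rec.channel_names if ch not in wanted]
    missing = [ch for ch in wanted if ch not in rec.channel_names]
    if missing:
        raise ValueError(f"recording {rec.subject_id!r} missing channels: "
                         f"{', '.join(missing)}")
    if extra:
        warnings.warn(f"recording {rec.subject_id!r}: dropping extra channels "
                      f"{', '.join(extra)}", RuntimeWarning, stacklevel=2)
    from .preprocess import select_channels
    return select_channels(rec, wanted)


def read_recordings(path, fmt: str = "csv",
                    channels: Optional[Sequence[str]] = None) -> List[Recording]:
    """Load a labeled cohort from a directory with a ``manifest.csv``.

    ``fmt`` selects the per-subject file reader (``csv`` or ``edf``).  Each
    recording is validated against the expected channel list (default: the
    17-channel subset); extra channels are dropped with a warning, missing
    channels raise.
    """
    if channels is None:
        channels = CHANNELS_17
    root = Path(path)
    manifest = root / "manifest.csv"
    if not manifest.exists():
        raise FileNotFoundError(f"no manifest.csv in {root}")
    df = pd.read_csv(manifest)
    missing_cols = [c for c in ("subject_id", "file", "label") if c not in df.columns]
    if missing_cols:
        raise ValueError(f"manifest missing columns: {missing_cols}")
    out: List[Recording] = []
    for _, row in df.iterrows():
        label = str(row["label"])
        if label not in CLASS_LABELS:
            raise ValueError(f"manifest label {label!r} not in {CLASS_LABELS}")
        meta = dict(subject_id=str(row["subject_id"]), label=label,
                    crs_r=None if pd.isna(row.get("crs_r")) else int(row["crs_r"]),
                    gcs=None if pd.isna(row.get("gcs")) else int(row["gcs"]))
        fpath = root / str(row["file"])
        if fmt == "csv":
            fs = float(row.get("fs", 256.0))
            rec = read_recording_csv(fpath, fs=fs, **meta)
        elif fmt == "edf":
            rec = _read_edf(fpath, **meta)
        else:
            raise ValueError(f"unknown format {fmt!r}")
        out.append(_validate_channels(rec, channels))
    return out


def _read_edf(path, **meta) -> Recording:
    try:
        import mne
    except ImportError as exc:  # pragma: no cover
        raise ImportError("reading EDF requires the optional mne dependency") from exc
    raw = mne.io.read_raw_edf(str(path), preload=True, verbose="error")
    return Recording(data=raw.get_data() * 1e6,  # volts -> microvolts
                     fs=float(raw.info["sfreq"]),
                     channel_names=list(raw.ch_names), **meta)


def write_json(obj, path) -> None:
    Path(path).parent.mkdir(parents=True, exist_ok=True)
    with open(path, "w") as fh:
        json.dump(obj, fh, indent=2, sort_keys=True, default=_json_default)


def _json_default(o):
    if isinstance(o, (np.integer,)):
        return int(o)
    if isinstance(o, (np.floating,)):
        return float(o)
    if isinstance(o, np.ndarray):
        return o.tolist()
    raise TypeError(f"not JSON serializable: {type(o)}")
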