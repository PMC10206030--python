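"""CSV interchange for trials, manifests and feature matrices.

One trial is one CSV with the 13-column header
``t,LOEA_Hb,LOEA_HbO2,...,RES_Hb,RES_HbO2``; missing samples are empty
fields.  A dataset directory holds the trial files plus a
``manifest.csv`` (``trial_id,subject_id,group,label,file``).  Floats are
written with 9 significant digits so reruns with the same seed are
byte-identical.
"""

from __future__ import annotations

import csv
import os
from pathlib import Path
from typing import Dict, Iterable, List, Optional, Sequence, Tuple

import numpy as np
import pandas as pd

from .exceptions import ParseError, SchemaError
from .recording import CHANNELS, CLASSES, NIRSRecording

TRIAL_COLUMNS: Tuple[str, ...] = ("t",) + tuple(
    f"{ch}_{s}" for ch in CHANNELS for s in ("Hb", "HbO2")
)
MANIFEST_COLUMNS: Tuple[str, ...] = ("trial_id", "subject_id", "group", "label", "file")

_FMT = "%.9g"


def _fmt(v: float) -> str:
    return "" if np.isnan(v) else _FMT % v


def write_trial_csv(recording: NIRSRecording, path) -> None:
    """Write one trial in the documented 13-column schema."""
    t = recording.times
    with open(path, "w", newline="") as fh:
        w = csv.writer(fh)
        w.writerow(TRIAL_COLUMNS)
        for i in range(recording.n_samples):
            row = [_FMT % t[i]]
            for ch in CHANNELS:
                row.append(_fmt(recording.hb[ch][i]))
                row.append(_fmt(recording.hbo2[ch][i]))
            w.writerow(row)


def read_trial_csv(
    path,
    trial_id: Optional[str] = None,
    subject_id: str = "unknown",
    group: str = "healthy",
    label: str = "NC",
    sampling_rate: Optional[float] = None,
) -> NIRSRecording:
    """Read one trial CSV; columns are mapped by name, so any complete
    permutation of the header is accepted.

    The sampling rate is inferred from the time column unless given.
    Empty fields become NaN and set the channel's missing mask.
    """
    path = Path(path)
    with open(path, newline="") as fh:
        reader = csv.reader(fh)
        try:
            header = next(reader)
        except StopIteration:
            raise ParseError(f"{path}: empty file") from None
        header = [h.strip() for h in header]
        missing_cols = set(TRIAL_COLUMNS) - set(header)
        if missing_cols:
            raise SchemaError(f"{path}: missing column(s) {sorted(missing_cols)}")
        extra = set(header) - set(TRIAL_COLUMNS)
        if extra:
            raise SchemaError(f"{path}: unexpected column(s) {sorted(extra)}")
        idx = {name: header.index(name) for name in TRIAL_COLUMNS}
        rows: List[List[float]] = []
        for lineno, row in enumerate(reader, start=2):
            if len(row) != len(header):
                raise ParseError(f"{path}:{lineno}: ragged row ({len(row)} fields, expected {len(header)})")
            vals = []
            for name in TRIAL_COLUMNS:
                cell = row[idx[name]].strip()
                if cell == "":
                    if name == "t":
                        raise ParseError(f"{path}:{lineno}: empty time cell")
                    vals.append(np.nan)
                    continue
                try:
                    vals.append(float(cell))
                except ValueError:
                    raise ParseError(
                        f"{path}:{lineno}: non-numeric cell {cell!r} in column {name}"
                    ) from None
            rows.append(vals)
    if not rows:
        raise ParseError(f"{path}: no data rows")
    data = np.asarray(rows, dtype=float)
    t = data[:, 0]
    if sampling_rate is None:
        if len(t) < 2:
            raise ParseError(f"{path}: cannot infer sampling rate from one row")
        sampling_rate = 1.0 / float(np.median(np.diff(t)))
    hb: Dict[str, np.ndarray] = {}
    hbo2: Dict[str, np.ndarray] = {}
    mask: Dict[str, np.ndarray] = {}
    for ch in CHANNELS:
        a = data[:, TRIAL_COLUMNS.index(f"{ch}_Hb")]
        b = data[:, TRIAL_COLUMNS.index(f"{ch}_HbO2")]
        hb[ch], hbo2[ch] = a, b
        mask[ch] = np.isnan(a) | np.isnan(b)
    return NIRSRecording(
        trial_id=trial_id or path.stem,
        subject_id=subject_id,
        group=group,
        label=label,
        sampling_rate=float(sampling_rate),
        hb=hb,
        hbo2=hbo2,
        missing_mask=mask,
    )


def write_dataset(recordings: Iterable[NIRSRecording], out_dir) -> Path:
    """Write trial CSVs plus a manifest into ``out_dir``; returns the
    manifest path."""
    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    manifest_path = out_dir / "manifest.csv"
    with open(manifest_path, "w", newline="") as fh:
        w = csv.writer(fh)
        w.writerow(MANIFEST_COLUMNS)
        for rec in recordings:
            fname = f"{rec.trial_id}.csv"
            write_trial_csv(rec, out_dir / fname)
            w.writerow([rec.trial_id, rec.subject_id, rec.group, rec.label, fname])
    return manifest_path


def read_manifest(path) -> pd.DataFrame:
    """Read and validate a dataset manifest."""
    path = Path(path)
    df = pd.read_csv(path, dtype=str)
    missing = set(MANIFEST_COLUMNS) - set(df.columns)
    if missing:
        raise SchemaError(f"{path}: manifest missing column(s) {sorted(missing)}")
    bad = sorted(set(df["label"]) - set(CLASSES))
    if bad:
        raise SchemaError(f"{path}: unknown label(s) {bad}; allowed: {list(CLASSES)}")
    dup = df["trial_id"][df["trial_id"].duplicated()].tolist()
    if dup:
        raise SchemaError(f"{path}: duplicate trial_id(s) {sorted(set(dup))}")
    for f in df["file"]:
        if not (path.parent / f).exists():
            raise SchemaError(f"{path}: dangling file reference {f!r}")
    return df


def load_dataset(directory) -> List[NIRSRecording]:
    """Load every trial listed in ``<directory>/manifest.csv``."""
    directory = Path(directory)
    manifest = read_manifest(directory / "manifest.csv")
    out = []
    for _, row in manifest.iterrows():
        out.append(
            read_trial_csv(
                directory / row["file"],
                trial_id=row["trial_id"],
                subject_id=row["subject_id"],
                group=row["group"],
                label=row["label"],
            )
        )
    return out


def validate_dataset(directory) -> Dict:
    """Check a dataset directory; returns {'ok': bool, 'n_trials': int,
    'errors': [...]} without raising."""
    directory = Path(directory)
    errors: List[str] = []
    n = 0
    try:
        manifest = read_manifest(directory / "manifest.csv")
        n = len(manifest)
        for _, row in manifest.iterrows():
            try:
                read_trial_csv(directory / row["file"])
            except Exception as exc:  # collect, don't abort
                errors.append(str(exc))
    except Exception as exc:
        errors.append(str(exc))
    return {"ok": not errors, "n_trials": n, "errors": errors}


def write_features_csv(df: pd.DataFrame, path) -> None:
    """Write a feature matrix with fixed float formatting."""
    df.to_csv(path, index=False, float_format=_FMT)


def read_features_csv(path) -> pd.DataFrame:
    return pd.read_csv(path)
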