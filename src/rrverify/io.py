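"""Plain-text readers and writers: RR files, peak files, cohort manifests.

RR files carry one interval (seconds) per line; lines starting with "#" are
header comments recording provenance.  A cohort manifest is a CSV with
columns subject_id, age_months, condition, file_path (relative to the
manifest's directory).
"""

from __future__ import annotations

import os
from pathlib import Path
from typing import List, Sequence

import numpy as np
import pandas as pd

from rrverify.types import RRSeries

MANIFEST_COLUMNS = ["subject_id", "age_months", "condition", "file_path"]


def write_rr_file(series: RRSeries, path: str | Path) -> None:
    path = Path(path)
    path.parent.mkdir(parents=True, exist_ok=True)
    with open(path, "w") as fh:
        fh.write(f"# subject_id: {series.subject_id}\n")
        fh.write(f"# condition: {series.condition}\n")
        fh.write(f"# age_months: {series.age_months:g}\n")
        fh.write("# RR intervals in seconds, one per line\n")
        for v in series.intervals:
            fh.write(f"{v:.9f}\n")


def read_rr_file(
    path: str | Path,
    subject_id: str | None = None,
    condition: str | None = None,
    age_months: float | None = None,
) -> RRSeries:
    """Read an RR text file; header comments supply missing metadata."""
    meta = {"subject_id": "S0", "condition": "basal", "age_months": 0.0}
    values: List[float] = []
    with open(path) as fh:
        for line in fh:
            line = line.strip()
            if not line:
                continue
            if line.startswith("#"):
                body = line.lstrip("#").strip()
                if ":" in body:
                    key, _, val = body.partition(":")
                    key = key.strip()
                    if key in ("subject_id", "condition"):
                        meta[key] = val.strip()
                    elif key == "age_months":
                        meta[key] = float(val)
                continue
            values.append(float(line))
    if subject_id is not None:
        meta["subject_id"] = subject_id
    if condition is not None:
        meta["condition"] = condition
    if age_months is not None:
        meta["age_months"] = float(age_months)
    return RRSeries(intervals=np.asarray(values), **meta)


def read_peak_file(path: str | Path) -> np.ndarray:
    """Read a peak-time text file (one timestamp in seconds per line)."""
    times: List[float] = []
    with open(path) as fh:
        for line in fh:
            line = line.strip()
            if line and not line.startswith("#"):
                times.append(float(line))
    return np.asarray(times)


def write_cohort(series_list: Sequence[RRSeries], outdir: str | Path) -> Path:
    """Write per-segment RR files plus a manifest CSV; returns the manifest path."""
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    rows = []
    for s in series_list:
        rel = f"{s.subject_id}_{s.condition}_{s.age_months:g}mo.rr.txt"
        write_rr_file(s, outdir / rel)
        rows.append(
            {
                "subject_id": s.subject_id,
                "age_months": s.age_months,
                "condition": s.condition,
                "file_path": rel,
            }
        )
    manifest = outdir / "manifest.csv"
    pd.DataFrame(rows, columns=MANIFEST_COLUMNS).to_csv(manifest, index=False)
    return manifest


def load_cohort(manifest_path: str | Path) -> List[RRSeries]:
    """Load every RR series referenced by a cohort manifest CSV."""
    manifest_path = Path(manifest_path)
    df = pd.read_csv(manifest_path)
    missing = set(MANIFEST_COLUMNS) - set(df.columns)
    if missing:
        raise ValueError(f"manifest is missing columns: {sorted(missing)}")
    base = manifest_path.parent
    return [
        read_rr_file(
            base / row.file_path,
            subject_id=str(row.subject_id),
            condition=str(row.condition),
            age_months=float(row.age_months),
        )
        for row in df.itertuples()
    ]
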