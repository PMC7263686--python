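"""Tab-separated table I/O with schema validation.

All pipeline tables are plain TSV with a header; lines starting with ``#``
are metadata comments (the pipeline stamps a config hash and seed there).
Genomic range files (intervals, zones) are BED-like TSV.
"""

from __future__ import annotations

import hashlib
import json
from pathlib import Path
from typing import Iterable, Mapping

import pandas as pd

from .sim import ROLES, CrossRecord, MarkerInterval, SeedCounts

__all__ = [
    "read_cross_table",
    "write_cross_table",
    "read_intervals",
    "write_intervals",
    "read_landscape",
    "write_table",
    "frame_to_records",
    "config_hash",
]

CROSS_COLUMNS = ["line", "role", "age_das", "replicate", "n_r", "n_g", "n_rg", "n_nfs"]
COUNT_COLUMNS = ["n_r", "n_g", "n_rg", "n_nfs"]


def config_hash(config: Mapping) -> str:
    """Short stable hash of a configuration mapping."""
    blob = json.dumps(config, sort_keys=True, default=str).encode()
    return hashlib.sha256(blob).hexdigest()[:12]


def write_table(df: pd.DataFrame, path, metadata: Mapping | None = None) -> None:
    """Write a TSV table, prefixed with ``# key=value`` metadata lines."""
    path = Path(path)
    with open(path, "w") as fh:
        for key, value in (metadata or {}).items():
            fh.write(f"# {key}={value}\n")
        df.to_csv(fh, sep="\t", index=False)


def _read_tsv(path) -> pd.DataFrame:
    return pd.read_csv(path, sep="\t", comment="#")


def read_cross_table(path) -> pd.DataFrame:
    """Read and validate a cross-record table.

    Hard errors (listing offending rows, 1-based over data rows) on missing
    columns, non-integer or negative counts, unknown role labels and
    duplicate (line, role, age, replicate) keys.
    """
    df = _read_tsv(path)
    missing = [c for c in CROSS_COLUMNS if c not in df.columns]
    if missing:
        raise ValueError(f"{path}: missing columns {missing}")
    problems = []
    for col in COUNT_COLUMNS + ["age_das", "replicate"]:
        numeric = pd.to_numeric(df[col], errors="coerce")
        bad = df.index[numeric.isna() | (numeric != numeric.round())].tolist()
        if bad:
            problems.append(f"non-integer {col} in rows {[i + 1 for i in bad]}")
        else:
            df[col] = numeric.astype(int)
    for col in COUNT_COLUMNS:
        if df[col].dtype.kind in "iu":
            bad = df.index[df[col] < 0].tolist()
            if bad:
                problems.append(f"negative {col} in rows {[i + 1 for i in bad]}")
    bad_roles = df.index[~df["role"].isin(ROLES)].tolist()
    if bad_roles:
        problems.append(f"unknown role labels in rows {[i + 1 for i in bad_roles]}")
    dup = df.duplicated(subset=["line", "role", "age_das", "replicate"], keep=False)
    if dup.any():
        problems.append(
            f"duplicate (line, role, age, replicate) keys in rows {[i + 1 for i in df.index[dup].tolist()]}"
        )
    if problems:
        raise ValueError(f"{path}: " + "; ".join(problems))
    return df[CROSS_COLUMNS]


def write_cross_table(records, path, metadata: Mapping | None = None) -> None:
    from .sim import records_to_frame

    df = records if isinstance(records, pd.DataFrame) else records_to_frame(records)
    write_table(df[CROSS_COLUMNS], path, metadata=metadata)


def frame_to_records(df: pd.DataFrame) -> list[CrossRecord]:
    """Typed CrossRecords from a validated cross table."""
    return [
        CrossRecord(
            line_name=str(row.line),
            detector_role=str(row.role),
            age_das=int(row.age_das),
            replicate_id=int(row.replicate),
            seeds=SeedCounts(int(row.n_r), int(row.n_g), int(row.n_rg), int(row.n_nfs)),
        )
        for row in df.itertuples()
    ]


def read_intervals(path) -> dict[str, MarkerInterval]:
    """Read BED-like interval definitions.

    Columns: chrom, pos_egfp, pos_dsred, line_name, optionally pos_mid.
    """
    df = _read_tsv(path)
    required = ["chrom", "pos_egfp", "pos_dsred", "line_name"]
    missing = [c for c in required if c not in df.columns]
    if missing:
        raise ValueError(f"{path}: missing columns {missing}")
    intervals = {}
    for row in df.itertuples():
        mid = None
        if "pos_mid" in df.columns and pd.notna(getattr(row, "pos_mid", None)):
            mid = int(row.pos_mid)
        name = str(row.line_name)
        if name in intervals:
            raise ValueError(f"{path}: duplicate line_name {name!r}")
        intervals[name] = MarkerInterval(
            line_name=name,
            chromosome=int(row.chrom),
            pos_egfp=int(row.pos_egfp),
            pos_dsred=int(row.pos_dsred),
            pos_mid=mid,
        )
    return intervals


def write_intervals(intervals: Mapping[str, MarkerInterval] | Iterable[MarkerInterval], path) -> None:
    ivs = intervals.values() if isinstance(intervals, Mapping) else intervals
    df = pd.DataFrame(
        {
            "chrom": iv.chromosome,
            "pos_egfp": iv.pos_egfp,
            "pos_dsred": iv.pos_dsred,
            "pos_mid": iv.pos_mid if iv.pos_mid is not None else "",
            "line_name": iv.line_name,
        }
        for iv in ivs
    )
    write_table(df, path)


def read_landscape(path) -> pd.DataFrame:
    """Read a location-based CO-rate table (chrom, pos, male_rate, female_rate)."""
    from .landscape import validate_landscape

    return validate_landscape(_read_tsv(path))
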