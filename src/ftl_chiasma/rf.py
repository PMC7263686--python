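"""Recombination-frequency estimation and heterochiasmy summaries.

The recombination frequency of a scored cross is

    RF = 100 * (R + G) / (R + G + RG + NFS)

over the four seed fluorescence classes: a dimensionless percent estimator
of the relative crossover rate in the detector parent's meiosis.  Male
(mCO) and female (fCO) rates for a line are aggregates of RF over the
crosses where the detector was the pollen donor or the seed parent
respectively, and heterochiasmy is their ratio mCO:fCO.

Two ratio conventions are provided because published per-line ratios are
not always consistent with a single aggregation rule: ``ratio_of_means``
(the ratio of the aggregated male and female rates; default) and
``mean_of_ratios`` (the mean over ages of the per-age ratios).  Every
summary echoes the convention used.
"""

from __future__ import annotations

from dataclasses import dataclass
import numpy as np
import pandas as pd

from .sim import FEMALE_DETECTOR, MALE_DETECTOR, ROLES, CrossRecord, SeedCounts, records_to_frame

__all__ = [
    "RecombinationFrequency",
    "ChiasmaSummary",
    "estimate_rf",
    "rf_percent",
    "add_rf_column",
    "summarize_line",
    "summarize_lines",
    "per_age_ratios",
    "RATIO_CONVENTIONS",
    "AGGREGATIONS",
]

RATIO_CONVENTIONS = ("ratio_of_means", "mean_of_ratios")
AGGREGATIONS = ("replicate_mean", "pooled")


@dataclass(frozen=True)
class RecombinationFrequency:
    """Point estimate of RF (percent) with the counts that produced it."""

    value: float
    n_total: int
    n_recombinant: int


@dataclass(frozen=True)
class ChiasmaSummary:
    """Per-line sex-specific rate estimates and their ratio.

    ``ratio`` is NaN (flagged undefined) when fCO is zero.  ``per_age`` is
    the per-age breakdown table when requested.
    """

    line_name: str
    mCO: float
    fCO: float
    ratio: float
    ratio_convention: str
    aggregation: str
    n_male_records: int
    n_female_records: int
    per_age: pd.DataFrame | None = None


def rf_percent(n_r: int, n_g: int, n_rg: int, n_nfs: int) -> float:
    """RF = 100 (R+G)/(R+G+RG+NFS); raises on an empty cross."""
    total = n_r + n_g + n_rg + n_nfs
    if total <= 0:
        raise ValueError("cannot compute RF from a cross with zero scored seeds")
    if min(n_r, n_g, n_rg, n_nfs) < 0:
        raise ValueError("seed counts must be non-negative")
    return 100.0 * (n_r + n_g) / total


def estimate_rf(seeds: SeedCounts) -> RecombinationFrequency:
    """Recombination frequency of one scored cross."""
    value = rf_percent(seeds.n_r, seeds.n_g, seeds.n_rg, seeds.n_nfs)
    return RecombinationFrequency(
        value=value, n_total=seeds.total, n_recombinant=seeds.n_recombinant
    )


def _coerce_frame(records) -> pd.DataFrame:
    if isinstance(records, pd.DataFrame):
        return records.copy()
    return records_to_frame(records)


def add_rf_column(records) -> pd.DataFrame:
    """Record table with ``rf`` (percent) and ``n_total`` columns appended."""
    df = _coerce_frame(records)
    total = df[["n_r", "n_g", "n_rg", "n_nfs"]].sum(axis=1)
    if (total <= 0).any():
        bad = df.index[total <= 0].tolist()
        raise ValueError(f"rows with zero scored seeds: {bad}")
    df["n_total"] = total
    df["rf"] = 100.0 * (df["n_r"] + df["n_g"]) / total
    return df


def _aggregate_rf(df: pd.DataFrame, aggregation: str) -> float:
    if aggregation == "replicate_mean":
        return float(df["rf"].mean())
    if aggregation == "pooled":
        return float(100.0 * (df["n_r"] + df["n_g"]).sum() / df["n_total"].sum())
    raise ValueError(f"aggregation must be one of {AGGREGATIONS}, got {aggregation!r}")


def per_age_ratios(records, aggregation: str = "replicate_mean", strict: bool = True) -> pd.DataFrame:
    """Per-age (mCO, fCO, ratio) table for one line.

    With ``strict=True`` every configured age must be present for both
    roles; with ``strict=False`` missing cells are explicit NaN gap markers
    rather than silently dropped rows.
    """
    df = add_rf_column(records)
    lines = df["line"].unique()
    if len(lines) != 1:
        raise ValueError(f"per_age_ratios expects records from one line, got {list(lines)}")
    ages = sorted(df["age_das"].unique())
    rows = []
    for age in ages:
        row: dict = {"age_das": age}
        for role, col in ((MALE_DETECTOR, "mCO"), (FEMALE_DETECTOR, "fCO")):
            sub = df[(df["age_das"] == age) & (df["role"] == role)]
            if sub.empty:
                if strict:
                    raise ValueError(f"missing cell: age {age}, role {role}")
                row[col] = np.nan
            else:
                row[col] = _aggregate_rf(sub, aggregation)
        mco, fco = row["mCO"], row["fCO"]
        row["ratio"] = mco / fco if (fco and not np.isnan(mco) and fco > 0) else np.nan
        rows.append(row)
    return pd.DataFrame(rows)


def summarize_line(
    records,
    ratio_convention: str = "ratio_of_means",
    aggregation: str = "replicate_mean",
    with_per_age: bool = False,
) -> ChiasmaSummary:
    """Aggregate one line's crosses into mCO, fCO and the mCO:fCO ratio.

    All ages are combined.  ``ratio_of_means`` divides the aggregated male
    rate by the aggregated female rate; ``mean_of_ratios`` averages the
    per-age ratios instead.
    """
    if ratio_convention not in RATIO_CONVENTIONS:
        raise ValueError(f"ratio_convention must be one of {RATIO_CONVENTIONS}")
    df = add_rf_column(records)
    lines = df["line"].unique()
    if len(lines) != 1:
        raise ValueError(f"summarize_line expects records from one line, got {list(lines)}")
    line = lines[0]
    by_role = {}
    for role in ROLES:
        sub = df[df["role"] == role]
        if sub.empty:
            raise ValueError(f"no records with role {role!r} for line {line!r}")
        by_role[role] = sub
    mco = _aggregate_rf(by_role[MALE_DETECTOR], aggregation)
    fco = _aggregate_rf(by_role[FEMALE_DETECTOR], aggregation)
    per_age = None
    if with_per_age or ratio_convention == "mean_of_ratios":
        per_age = per_age_ratios(df, aggregation=aggregation, strict=False)
    if ratio_convention == "ratio_of_means":
        ratio = mco / fco if fco > 0 else np.nan
    else:
        ratio = float(per_age["ratio"].mean()) if per_age["ratio"].notna().any() else np.nan
    return ChiasmaSummary(
        line_name=str(line),
        mCO=mco,
        fCO=fco,
        ratio=ratio,
        ratio_convention=ratio_convention,
        aggregation=aggregation,
        n_male_records=len(by_role[MALE_DETECTOR]),
        n_female_records=len(by_role[FEMALE_DETECTOR]),
        per_age=per_age if with_per_age else None,
    )


def summarize_lines(
    records,
    ratio_convention: str = "ratio_of_means",
    aggregation: str = "replicate_mean",
) -> pd.DataFrame:
    """Per-line summary table over a multi-line record set."""
    df = _coerce_frame(records)
    rows = []
    for line, sub in df.groupby("line", sort=True):
        s = summarize_line(sub, ratio_convention=ratio_convention, aggregation=aggregation)
        rows.append(
            {
                "line": s.line_name,
                "mCO": s.mCO,
                "fCO": s.fCO,
                "ratio": s.ratio,
                "ratio_convention": s.ratio_convention,
                "aggregation": s.aggregation,
            }
        )
    return pd.DataFrame(rows)
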