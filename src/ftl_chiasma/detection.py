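"""Two-marker non-detection: even crossover counts are invisible.

A seed whose gamete took an even number (>= 2) of crossovers between the
two markers shows a parental fluorescence pattern, so additional crossovers
beyond the first can be missed.  This module quantifies that bias three
ways: (i) an accounting adjustment — given per-sex counts of meioses with
0, 1, 2, 3+ crossovers, a fraction ``f`` of the crossovers additional to
the first is treated as undetected and the male:female ratio recomputed;
(ii) the exact odd/even gap of the generative model (how far the
recombinant-gamete probability falls below the per-gamete mean crossover
count); (iii) the spacing of double crossovers, since interference pushes
them apart and makes simultaneous events in a short interval rare.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Sequence

import numpy as np
import pandas as pd

from .sim import (
    MarkerInterval,
    MeiosisModel,
    bivalent_count_pmf,
    recombinant_probability,
    simulate_crossover_positions,
)

__all__ = [
    "CoClassCounts",
    "NonDetectionReport",
    "DoubleCoSpacing",
    "nondetection_adjust",
    "odd_even_gap",
    "double_co_within",
    "ratio_sensitivity_sweep",
    "co_class_counts_from_model",
]


@dataclass(frozen=True)
class CoClassCounts:
    """Per-sex counts (or proportions) of meioses with 0, 1, 2, 3+ crossovers."""

    male: tuple[float, float, float, float]
    female: tuple[float, float, float, float]

    def __post_init__(self) -> None:
        for sex, counts in (("male", self.male), ("female", self.female)):
            if len(counts) != 4 or any(c < 0 for c in counts):
                raise ValueError(f"{sex} class counts must be four non-negative numbers")
            if sum(counts) <= 0:
                raise ValueError(f"{sex} class counts must have a positive total")


@dataclass(frozen=True)
class NonDetectionReport:
    """Effect of a non-detection level f on the male:female crossover ratio."""

    non_detection_level: float
    true_total_m: float
    true_total_f: float
    detected_total_m: float
    detected_total_f: float
    ratio_raw: float
    ratio_adjusted: float
    ratio_change_pct: float


@dataclass(frozen=True)
class DoubleCoSpacing:
    """Fraction of double-crossover meioses with the two events within a distance."""

    fraction_within: float
    std_error: float
    n_double_co: int
    n_meioses: int
    distance_mb: float


def _totals(counts: Sequence[float], f: float) -> tuple[float, float]:
    """(true total crossovers, expected detected) for one sex's class counts.

    Classes are exactly 0, 1, 2 and 3+ crossovers; the open class is scored
    as 3.  Each crossover additional to the first goes undetected with
    probability f, so a k-crossover meiosis contributes 1 + (k-1)(1-f)
    detected crossovers.
    """
    ks = np.array([0, 1, 2, 3], dtype=float)
    n = np.asarray(counts, dtype=float)
    true_total = float((ks * n).sum())
    detected = float((n[1:] * (1.0 + (ks[1:] - 1.0) * (1.0 - f))).sum())
    return true_total, detected


def nondetection_adjust(classes: CoClassCounts, f: float) -> NonDetectionReport:
    """Recompute the male:female crossover ratio under non-detection level f."""
    if not 0.0 <= f <= 1.0:
        raise ValueError(f"non-detection level f must lie in [0, 1], got {f}")
    true_m, det_m = _totals(classes.male, f)
    true_f, det_f = _totals(classes.female, f)
    if true_f <= 0 or det_f <= 0:
        ratio_raw = ratio_adj = change = float("nan")
    else:
        ratio_raw = true_m / true_f
        ratio_adj = det_m / det_f
        change = 100.0 * (ratio_adj - ratio_raw) / ratio_raw
    return NonDetectionReport(
        non_detection_level=f,
        true_total_m=true_m,
        true_total_f=true_f,
        detected_total_m=det_m,
        detected_total_f=det_f,
        ratio_raw=ratio_raw,
        ratio_adjusted=ratio_adj,
        ratio_change_pct=change,
    )


def odd_even_gap(model: MeiosisModel, sex: str, age_das: int) -> tuple[float, float, float]:
    """(lambda, p_rec, gap): the shortfall of RF below the mean CO count.

    ``lambda`` is the per-gamete mean crossover count, ``p_rec`` the
    probability of a recombinant (odd-count) gamete, and
    ``gap = (lambda - p_rec) / lambda`` the fractional undercount of
    RF-based estimation relative to the per-gamete mean; gap -> 0 for short
    intervals (where RF ~ lambda) and is defined as 0 at lambda = 0.
    """
    lam = model.lambda_at(sex, age_das)
    if lam == 0:
        return 0.0, 0.0, 0.0
    p_rec = recombinant_probability(model, sex, age_das)
    return lam, p_rec, (lam - p_rec) / lam


def double_co_within(
    model: MeiosisModel,
    sex: str,
    distance_mb: float,
    interval: MarkerInterval,
    age_das: int = 40,
    n_meioses: int = 200_000,
    rng_seed: int | np.random.Generator = 0,
) -> DoubleCoSpacing:
    """P(|x1 - x2| <= distance) among meioses with exactly two crossovers.

    Crossovers are placed by the stationary renewal process mapped
    uniformly (constant rate) to physical coordinates.  Under nu = 1 the
    two positions are independent uniforms, with closed form
    2 d/L - (d/L)^2.  Raises if the sample contains no double-crossover
    meiosis (reporting the sample size in the message).
    """
    L = interval.length_mb
    if distance_mb < 0 or distance_mb > L:
        raise ValueError(f"distance_mb must lie in [0, {L}] Mb")
    lam = model.lambda_at(sex, age_das)
    nu = model.nu_at(sex)
    counts, pos, _ = simulate_crossover_positions(2.0 * lam, nu, n_meioses, rng_seed)
    two = counts == 2
    n2 = int(two.sum())
    if n2 == 0:
        raise ValueError(
            f"no double-crossover meioses among {n_meioses} simulated; "
            "increase n_meioses or lambda"
        )
    gap_mb = np.abs(pos[two, 1] - pos[two, 0]) * L
    p = float((gap_mb <= distance_mb).mean())
    se = float(np.sqrt(max(p * (1.0 - p), 1e-300) / n2))
    return DoubleCoSpacing(
        fraction_within=p,
        std_error=se,
        n_double_co=n2,
        n_meioses=n_meioses,
        distance_mb=distance_mb,
    )


def ratio_sensitivity_sweep(classes: CoClassCounts, f_grid: Sequence[float]) -> pd.DataFrame:
    """Ratio change over a grid of non-detection levels f."""
    rows = []
    for f in f_grid:
        rep = nondetection_adjust(classes, f)
        rows.append(
            {
                "f": f,
                "ratio_raw": rep.ratio_raw,
                "ratio_adjusted": rep.ratio_adjusted,
                "ratio_change_pct": rep.ratio_change_pct,
            }
        )
    return pd.DataFrame(rows)


def co_class_counts_from_model(
    model: MeiosisModel, age_das: int = 40, scale: float = 1000.0
) -> CoClassCounts:
    """Expected 0/1/2/3+ meiosis class counts implied by a generative model."""
    out = {}
    for sex in ("male", "female"):
        pmf = bivalent_count_pmf(2.0 * model.lambda_at(sex, age_das), model.nu_at(sex))
        padded = np.concatenate([pmf, np.zeros(max(0, 4 - len(pmf)))])
        out[sex] = tuple(scale * np.array([padded[0], padded[1], padded[2], padded[3:].sum()]))
    return CoClassCounts(male=out["male"], female=out["female"])
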