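"""Generative model of two-marker fluorescent-tagged-line (FTL) crosses.

A detector line carries two linked seed-fluorescence transgenes (eGFP and
dsRed) in coupling (cis) phase.  Crossed to wild type, the doubly
heterozygous F1 transmits, per gamete, one of four marker patterns; seeds
scored under a fluorescence microscope therefore fall into four classes
(dsRed-only R, eGFP-only G, both RG, non-fluorescent NFS).  A gamete is
recombinant — carries exactly one marker — iff an odd number of crossovers
hit the chromatid between the two insertion sites.

Crossovers along the bivalent are modelled as a stationary gamma-renewal
point process on the genetic scale with integer shape ``nu`` (the
chi-square / Housworth–Stahl counting model; ``nu = 1`` is the
no-interference Poisson case).  Each crossover involves a given chromatid
with probability 1/2, independently (no chromatid interference), so the
gamete-level crossover count is a binomial 1/2-thinning of the bivalent
count.  Under ``nu = 1`` this yields Haldane's mapping function
``P(recombinant) = (1 - exp(-2*lambda)) / 2`` where ``lambda`` is the mean
crossover count per gamete in the interval.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Iterable, Mapping

import numpy as np
import pandas as pd
from scipy import optimize, stats

__all__ = [
    "FEMALE_DETECTOR",
    "MALE_DETECTOR",
    "ROLES",
    "MarkerInterval",
    "MeiosisModel",
    "GameteClassProbs",
    "SeedCounts",
    "CrossRecord",
    "StudyDesign",
    "crossover_count_distribution",
    "bivalent_count_pmf",
    "gamete_class_probs",
    "recombinant_probability",
    "lambda_for_recombinant_probability",
    "simulate_cross",
    "simulate_study",
    "simulate_crossover_positions",
    "simulate_three_marker_cross",
    "collapse_three_marker",
    "records_to_frame",
    "default_intervals",
    "default_models",
]

FEMALE_DETECTOR = "female_detector"
MALE_DETECTOR = "male_detector"
ROLES = (FEMALE_DETECTOR, MALE_DETECTOR)

# role -> sex of the meiosis being scored (the detector parent's meiosis)
ROLE_SEX = {FEMALE_DETECTOR: "female", MALE_DETECTOR: "male"}

_PMF_TAIL = 1e-9


@dataclass(frozen=True)
class MarkerInterval:
    """A two-marker (optionally three-marker) interval on one chromosome.

    Positions are 1-based base pairs.  ``pos_mid`` enables three-marker
    simulation and must lie strictly between the outer markers.
    """

    line_name: str
    chromosome: int
    pos_egfp: int
    pos_dsred: int
    pos_mid: int | None = None

    def __post_init__(self) -> None:
        if not 1 <= self.chromosome <= 5:
            raise ValueError(f"chromosome must be 1-5, got {self.chromosome}")
        if self.pos_egfp == self.pos_dsred:
            raise ValueError("marker positions must differ")
        if self.pos_egfp < 1 or self.pos_dsred < 1:
            raise ValueError("marker positions are 1-based and must be >= 1")
        if self.pos_mid is not None:
            lo, hi = sorted((self.pos_egfp, self.pos_dsred))
            if not lo < self.pos_mid < hi:
                raise ValueError("pos_mid must lie strictly between the outer markers")

    @property
    def start(self) -> int:
        return min(self.pos_egfp, self.pos_dsred)

    @property
    def end(self) -> int:
        return max(self.pos_egfp, self.pos_dsred)

    @property
    def length_mb(self) -> float:
        return abs(self.pos_dsred - self.pos_egfp) / 1e6


def _check_age_effect(mapping: Mapping[int, float], label: str) -> None:
    for age, fac in mapping.items():
        if fac <= 0:
            raise ValueError(f"{label}[{age}] must be > 0, got {fac}")


@dataclass(frozen=True)
class MeiosisModel:
    """Per-line generative parameters.

    lambda_m / lambda_f
        Mean crossover count per gamete in the interval for male / female
        meiosis (the genetic length in Morgans).  The bivalent mean is
        twice this.
    nu_m / nu_f
        Integer interference shape per sex (1 = no interference).  Female
        interference in *Arabidopsis* is reported stronger than male, hence
        per-sex shapes.
    age_effect_m / age_effect_f
        Multiplicative factor on lambda per parental age (days after
        sowing); ages absent from the mapping get factor 1.0.
    phase
        Marker configuration on the detector homolog; only ``"coupling"``
        (both markers in cis) is supported, matching detector lines that
        are homozygous for both markers crossed to wild type.
    """

    lambda_m: float
    lambda_f: float
    nu_m: int = 1
    nu_f: int = 1
    age_effect_m: Mapping[int, float] = field(default_factory=dict)
    age_effect_f: Mapping[int, float] = field(default_factory=dict)
    phase: str = "coupling"

    def __post_init__(self) -> None:
        if self.lambda_m < 0 or self.lambda_f < 0:
            raise ValueError("lambda_m and lambda_f must be >= 0")
        for nu in (self.nu_m, self.nu_f):
            if int(nu) != nu or nu < 1:
                raise ValueError(f"interference shape nu must be an integer >= 1, got {nu}")
        if self.phase != "coupling":
            raise ValueError("only coupling (cis) marker phase is supported")
        _check_age_effect(self.age_effect_m, "age_effect_m")
        _check_age_effect(self.age_effect_f, "age_effect_f")

    def lambda_at(self, sex: str, age_das: int) -> float:
        """Effective per-gamete mean crossover count for one sex and age."""
        if sex == "male":
            return self.lambda_m * self.age_effect_m.get(age_das, 1.0)
        if sex == "female":
            return self.lambda_f * self.age_effect_f.get(age_das, 1.0)
        raise ValueError(f"sex must be 'male' or 'female', got {sex!r}")

    def nu_at(self, sex: str) -> int:
        if sex == "male":
            return int(self.nu_m)
        if sex == "female":
            return int(self.nu_f)
        raise ValueError(f"sex must be 'male' or 'female', got {sex!r}")


@dataclass(frozen=True)
class GameteClassProbs:
    """Probabilities of the four gamete marker patterns (coupling phase)."""

    p_both: float
    p_none: float
    p_r_only: float
    p_g_only: float

    def __post_init__(self) -> None:
        probs = (self.p_both, self.p_none, self.p_r_only, self.p_g_only)
        if any(p < -1e-15 or p > 1 + 1e-15 for p in probs):
            raise ValueError("class probabilities must lie in [0, 1]")
        if abs(sum(probs) - 1.0) > 1e-12:
            raise ValueError("class probabilities must sum to 1")

    @property
    def p_recombinant(self) -> float:
        return self.p_r_only + self.p_g_only

    def as_array(self) -> np.ndarray:
        """Order (R, G, RG, NFS), matching SeedCounts."""
        return np.array([self.p_r_only, self.p_g_only, self.p_both, self.p_none])


@dataclass(frozen=True)
class SeedCounts:
    """Counts of the four seed fluorescence classes from one scored cross."""

    n_r: int
    n_g: int
    n_rg: int
    n_nfs: int

    def __post_init__(self) -> None:
        for name in ("n_r", "n_g", "n_rg", "n_nfs"):
            v = getattr(self, name)
            if int(v) != v or v < 0:
                raise ValueError(f"{name} must be a non-negative integer, got {v}")

    @property
    def total(self) -> int:
        return self.n_r + self.n_g + self.n_rg + self.n_nfs

    @property
    def n_recombinant(self) -> int:
        return self.n_r + self.n_g


@dataclass(frozen=True)
class CrossRecord:
    """One replicate cross: which parent was the detector, its age, the seed counts."""

    line_name: str
    detector_role: str
    age_das: int
    replicate_id: int
    seeds: SeedCounts

    def __post_init__(self) -> None:
        if self.detector_role not in ROLES:
            raise ValueError(
                f"detector_role must be one of {ROLES}, got {self.detector_role!r}"
            )


@dataclass(frozen=True)
class StudyDesign:
    """Crossing design: ages x roles x replicates, with a per-cell seed budget.

    ``seeds_per_cell`` is the total seed count for one line x role x age
    cell, split as evenly as possible across replicates (the study scale is
    ~2200 seeds per cell).
    """

    ages: tuple[int, ...] = (40, 45, 50, 55)
    n_replicates: int = 3
    seeds_per_cell: int = 2200
    roles: tuple[str, ...] = ROLES

    def __post_init__(self) -> None:
        if len(set(self.ages)) != len(self.ages):
            raise ValueError("duplicate ages in design")
        if len(set(self.roles)) != len(self.roles):
            raise ValueError("duplicate roles in design")
        if self.n_replicates < 1:
            raise ValueError("n_replicates must be >= 1")
        if self.seeds_per_cell < self.n_replicates:
            raise ValueError("seeds_per_cell must be >= n_replicates")

    def replicate_seed_counts(self) -> list[int]:
        base, extra = divmod(self.seeds_per_cell, self.n_replicates)
        return [base + (1 if i < extra else 0) for i in range(self.n_replicates)]


# ---------------------------------------------------------------------------
# Crossover count distributions (stationary gamma renewal, integer shape)
# ---------------------------------------------------------------------------


def bivalent_count_pmf(mean_count: float, nu: int, tail: float = _PMF_TAIL) -> np.ndarray:
    """Exact pmf of the bivalent crossover count in the interval.

    Uses the Poisson-skip construction of the stationary integer-shape
    gamma renewal process: with M ~ Poisson(nu * mean_count) underlying
    points and a uniform phase U on {0, ..., nu-1}, the crossover count is
    floor((M + U) / nu), which has mean exactly ``mean_count``.  The
    returned vector omits a tail of mass < ``tail``.
    """
    nu = int(nu)
    if nu < 1:
        raise ValueError("nu must be an integer >= 1")
    if mean_count < 0:
        raise ValueError("mean_count must be >= 0")
    if mean_count == 0:
        return np.array([1.0])
    lam = nu * mean_count
    m_hi = int(stats.poisson.ppf(1 - min(tail, 1e-12), lam)) + nu
    n_max = (m_hi + nu - 1) // nu + 1
    # P(N <= n) = (1/nu) * sum_u F_M((n+1)*nu - 1 - u),  u = 0..nu-1
    n = np.arange(n_max + 1)
    args = (n[:, None] + 1) * nu - 1 - np.arange(nu)[None, :]
    cdf = stats.poisson.cdf(np.maximum(args, -1), lam)
    cdf[args < 0] = 0.0
    cdf_n = cdf.mean(axis=1)
    pmf = np.diff(np.concatenate([[0.0], cdf_n]))
    # trim trailing tail below requested mass
    keep = len(pmf)
    while keep > 1 and 1.0 - pmf[:keep - 1].sum() < tail:
        keep -= 1
    return np.clip(pmf[:keep], 0.0, 1.0)


def _thin_pmf(pmf: np.ndarray) -> np.ndarray:
    """Binomial(n, 1/2) thinning of a count pmf (bivalent -> one chromatid)."""
    n_max = len(pmf) - 1
    k = np.arange(n_max + 1)
    thin = stats.binom.pmf(k[:, None], k[None, :], 0.5)  # [k, n]
    return thin @ pmf


def crossover_count_distribution(
    model: MeiosisModel,
    sex: str,
    age_das: int,
    level: str = "gamete",
    tail: float = _PMF_TAIL,
) -> np.ndarray:
    """Pmf over crossover counts in the interval for one sex and age.

    ``level="gamete"`` (default) returns the distribution of crossovers on
    a transmitted chromatid (mean = lambda * age factor); ``level="meiosis"``
    returns the bivalent-level distribution (mean twice that).
    """
    lam = model.lambda_at(sex, age_das)
    nu = model.nu_at(sex)
    biv = bivalent_count_pmf(2.0 * lam, nu, tail=tail)
    if level == "meiosis":
        return biv
    if level == "gamete":
        return _thin_pmf(biv)
    raise ValueError(f"level must be 'gamete' or 'meiosis', got {level!r}")


def recombinant_probability(model: MeiosisModel, sex: str, age_das: int) -> float:
    """P(gamete carries exactly one marker) = P(odd gamete crossover count).

    A Binomial(n, 1/2) count is odd with probability 1/2 for any n >= 1, so
    this reduces to (1 - P(bivalent count = 0)) / 2; under nu = 1 that is
    Haldane's (1 - exp(-2*lambda)) / 2.
    """
    lam = model.lambda_at(sex, age_das)
    nu = model.nu_at(sex)
    if lam == 0:
        return 0.0
    p0 = bivalent_count_pmf(2.0 * lam, nu)[0]
    return (1.0 - p0) / 2.0


def gamete_class_probs(model: MeiosisModel, sex: str, age_das: int) -> GameteClassProbs:
    """Four-class gamete pattern probabilities under coupling phase.

    Parental patterns (both markers / neither) each get half of the
    non-recombinant mass; recombinant single-marker patterns split the
    recombinant mass equally.
    """
    p_rec = recombinant_probability(model, sex, age_das)
    return GameteClassProbs(
        p_both=(1.0 - p_rec) / 2.0,
        p_none=(1.0 - p_rec) / 2.0,
        p_r_only=p_rec / 2.0,
        p_g_only=p_rec / 2.0,
    )


def lambda_for_recombinant_probability(p_rec: float, nu: int = 1) -> float:
    """Invert P(recombinant) -> per-gamete mean crossover count lambda.

    For nu = 1 this is the inverse Haldane map -ln(1 - 2p)/2; for nu > 1 the
    inversion is numerical.  Requires 0 <= p_rec < 0.5.
    """
    if not 0 <= p_rec < 0.5:
        raise ValueError("recombinant probability must lie in [0, 0.5)")
    if p_rec == 0:
        return 0.0
    if nu == 1:
        return -0.5 * np.log1p(-2.0 * p_rec)
    def f(lam: float) -> float:
        p0 = bivalent_count_pmf(2.0 * lam, nu)[0]
        return (1.0 - p0) / 2.0 - p_rec
    hi = 1.0
    while f(hi) < 0:
        hi *= 2.0
    return float(optimize.brentq(f, 0.0, hi, xtol=1e-12))


# ---------------------------------------------------------------------------
# Sampling
# ---------------------------------------------------------------------------


def _as_rng(seed) -> np.random.Generator:
    if isinstance(seed, np.random.Generator):
        return seed
    return np.random.default_rng(seed)


def simulate_cross(
    model: MeiosisModel,
    interval: MarkerInterval,
    detector_role: str,
    age_das: int,
    n_seeds: int,
    rng_seed,
    replicate_id: int = 1,
) -> CrossRecord:
    """Draw one scored cross: multinomial seed counts over the four classes."""
    if n_seeds < 1:
        raise ValueError(f"n_seeds must be >= 1, got {n_seeds}")
    if detector_role not in ROLES:
        raise ValueError(f"detector_role must be one of {ROLES}")
    sex = ROLE_SEX[detector_role]
    probs = gamete_class_probs(model, sex, age_das).as_array()
    rng = _as_rng(rng_seed)
    n_r, n_g, n_rg, n_nfs = rng.multinomial(n_seeds, probs)
    return CrossRecord(
        line_name=interval.line_name,
        detector_role=detector_role,
        age_das=age_das,
        replicate_id=replicate_id,
        seeds=SeedCounts(int(n_r), int(n_g), int(n_rg), int(n_nfs)),
    )


def simulate_study(
    models: Mapping[str, MeiosisModel],
    intervals: Mapping[str, MarkerInterval],
    design: StudyDesign,
    rng_seed: int,
) -> tuple[list[CrossRecord], pd.DataFrame]:
    """Simulate a full crossing study; returns records plus a truth table.

    One CrossRecord per line x role x age x replicate, deterministic under
    ``rng_seed``.  The truth table carries the generating per-gamete lambda
    and recombinant probability for every cell, for parameter-recovery
    checks.
    """
    if not models:
        raise ValueError("empty design: no lines")
    missing = sorted(set(models) - set(intervals))
    if missing:
        raise ValueError(f"lines without interval definitions: {missing}")
    ss = np.random.SeedSequence(rng_seed)
    records: list[CrossRecord] = []
    truth_rows = []
    rep_seeds = design.replicate_seed_counts()
    children = iter(ss.spawn(len(models) * len(design.roles) * len(design.ages)))
    for line in sorted(models):
        model = models[line]
        interval = intervals[line]
        for role in design.roles:
            sex = ROLE_SEX[role]
            for age in design.ages:
                rng = np.random.default_rng(next(children))
                for rep, n_seeds in enumerate(rep_seeds, start=1):
                    records.append(
                        simulate_cross(model, interval, role, age, n_seeds, rng, rep)
                    )
                truth_rows.append(
                    {
                        "line": line,
                        "role": role,
                        "age_das": age,
                        "lambda_gamete": model.lambda_at(sex, age),
                        "nu": model.nu_at(sex),
                        "p_recombinant": recombinant_probability(model, sex, age),
                    }
                )
    return records, pd.DataFrame(truth_rows)


def records_to_frame(records: Iterable[CrossRecord]) -> pd.DataFrame:
    """Tabulate CrossRecords (columns: line, role, age_das, replicate, counts)."""
    return pd.DataFrame(
        {
            "line": r.line_name,
            "role": r.detector_role,
            "age_das": r.age_das,
            "replicate": r.replicate_id,
            "n_r": r.seeds.n_r,
            "n_g": r.seeds.n_g,
            "n_rg": r.seeds.n_rg,
            "n_nfs": r.seeds.n_nfs,
        }
        for r in records
    )


def simulate_crossover_positions(
    mean_count: float,
    nu: int,
    n_meioses: int,
    rng_seed,
) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    """Simulate bivalent crossover counts and positions for many meioses.

    Positions are fractions of the interval (constant crossover rate per
    physical unit within the interval).  Returns ``(counts, pos, valid)``
    where ``pos`` is an (n_meioses, max_count) array padded with NaN and
    ``valid`` is the corresponding mask.
    """
    nu = int(nu)
    if nu < 1 or mean_count < 0 or n_meioses < 1:
        raise ValueError("need nu >= 1, mean_count >= 0, n_meioses >= 1")
    rng = _as_rng(rng_seed)
    if mean_count == 0:
        counts = np.zeros(n_meioses, dtype=int)
        return counts, np.empty((n_meioses, 0)), np.empty((n_meioses, 0), dtype=bool)
    m = rng.poisson(nu * mean_count, size=n_meioses)
    u = rng.integers(0, nu, size=n_meioses)
    counts = (m + u) // nu
    max_m = int(m.max()) if len(m) else 0
    # sorted uniform underlying points, padded with +inf beyond each row's m
    pts = rng.random((n_meioses, max_m))
    pts[np.arange(max_m)[None, :] >= m[:, None]] = np.inf
    pts.sort(axis=1)
    # crossover = underlying point with 1-based index i such that (i + u) % nu == 0
    idx1 = np.arange(1, max_m + 1)
    is_co = ((idx1[None, :] + u[:, None]) % nu == 0) & np.isfinite(pts)
    max_c = int(counts.max())
    pos = np.full((n_meioses, max_c), np.nan)
    valid = np.zeros((n_meioses, max_c), dtype=bool)
    if max_c:
        rows, cols = np.nonzero(is_co)
        order = np.lexsort((cols, rows))
        rows, cols = rows[order], cols[order]
        within = np.concatenate([np.arange(c) for c in counts if c]) if counts.any() else []
        pos[rows, within] = pts[rows, cols]
        valid[rows, within] = True
    return counts, pos, valid


THREE_MARKER_CLASSES = [
    "+/+/+", "+/+/-", "+/-/+", "+/-/-", "-/+/+", "-/+/-", "-/-/+", "-/-/-",
]


def simulate_three_marker_cross(
    model: MeiosisModel,
    interval: MarkerInterval,
    detector_role: str,
    age_das: int,
    n_seeds: int,
    rng_seed,
) -> pd.Series:
    """Simulate seed counts over the 8 classes of a three-marker detector.

    Class labels are eGFP/mid/dsRed presence patterns, e.g. ``"+/-/+"``.
    Crossovers are placed by the bivalent renewal process, thinned to the
    transmitted chromatid with probability 1/2 each, and the chromatid's
    marker content read off at the three insertion sites.  Collapsing over
    the middle marker recovers the two-marker class distribution.
    """
    if interval.pos_mid is None:
        raise ValueError("three-marker simulation requires interval.pos_mid")
    if n_seeds < 1:
        raise ValueError(f"n_seeds must be >= 1, got {n_seeds}")
    sex = ROLE_SEX[detector_role]
    lam = model.lambda_at(sex, age_das)
    nu = model.nu_at(sex)
    rng = _as_rng(rng_seed)
    counts, pos, valid = simulate_crossover_positions(2.0 * lam, nu, n_seeds, rng)
    kept = valid & (rng.random(pos.shape) < 0.5) if pos.size else valid
    # genetic fraction of the middle marker (constant rate within interval)
    frac_mid = (interval.pos_mid - interval.start) / (interval.end - interval.start)
    with np.errstate(invalid="ignore"):
        n_left = (kept & (pos < frac_mid)).sum(axis=1)
        n_total = kept.sum(axis=1)
    start_detector = rng.random(n_seeds) < 0.5  # chromatid haplotype at the left end
    at_egfp = start_detector
    at_mid = start_detector ^ (n_left % 2 == 1)
    at_dsred = start_detector ^ (n_total % 2 == 1)
    # eGFP is at interval.start iff pos_egfp < pos_dsred, else swap ends
    if interval.pos_egfp > interval.pos_dsred:
        at_egfp, at_dsred = at_dsred, at_egfp
    code = 4 * at_egfp.astype(int) + 2 * at_mid.astype(int) + at_dsred.astype(int)
    tallies = np.bincount(7 - code, minlength=8)  # index 0 = "+/+/+"
    return pd.Series(tallies, index=THREE_MARKER_CLASSES, name="n_seeds")


def collapse_three_marker(counts8: pd.Series) -> SeedCounts:
    """Marginalize the 8 three-marker classes over the middle marker."""
    get = lambda pat: int(counts8[pat])
    n_rg = get("+/+/+") + get("+/-/+")
    n_nfs = get("-/+/-") + get("-/-/-")
    n_g = get("+/+/-") + get("+/-/-")
    n_r = get("-/+/+") + get("-/-/+")
    return SeedCounts(n_r=n_r, n_g=n_g, n_rg=n_rg, n_nfs=n_nfs)


# ---------------------------------------------------------------------------
# Default study configuration (synthetic stand-ins for the real lines)
# ---------------------------------------------------------------------------

# Printed per-line average male/female recombination frequencies (percent)
# that the default generator reproduces in expectation.
LINE_RATES_PCT: dict[str, tuple[int, float, float]] = {
    # line: (chromosome, male RF %, female RF %)
    "CTL1.2": (1, 33.44, 28.24),
    "CTL1.18": (1, 17.95, 7.81),
    "CTL2.4": (2, 17.84, 13.41),
    "Col3-4/20": (3, 24.04, 8.90),
    "3158": (3, 25.66, 10.88),
    "CTL4.7": (4, 23.17, 8.67),
    "3162": (5, 19.33, 14.73),
    "CTL5.17": (5, 16.62, 5.21),
}

# Synthetic interval coordinates (bp).  The real insertion sites are not in
# any machine-readable source here, so these are constructed placeholders
# honouring the documented geometry: CTL1.2 spans the chromosome-1
# centromere with a 10.5 Mb interval; the other seven average 4.71 Mb; the
# low-ratio lines (CTL1.2, CTL2.4, 3162) avoid subtelomeric zones.
_DEFAULT_INTERVALS_BP: dict[str, tuple[int, int, int]] = {
    "CTL1.2": (1, 10_000_000, 20_500_000),
    "CTL1.18": (1, 24_000_000, 28_500_000),
    "CTL2.4": (2, 8_000_000, 12_500_000),
    "Col3-4/20": (3, 500_000, 5_700_000),
    "3158": (3, 18_000_000, 23_000_000),
    "CTL4.7": (4, 13_500_000, 18_300_000),
    "3162": (5, 8_000_000, 12_200_000),
    "CTL5.17": (5, 22_500_000, 26_770_000),
}


def default_intervals() -> dict[str, MarkerInterval]:
    """Synthetic default marker intervals for the eight detector lines."""
    return {
        line: MarkerInterval(line, chrom, start, end)
        for line, (chrom, start, end) in _DEFAULT_INTERVALS_BP.items()
    }


def default_models(nu_m: int = 2, nu_f: int = 4) -> dict[str, MeiosisModel]:
    """Default generative models: per-line lambdas matched to the observed
    male/female recombination frequencies, stronger female interference,
    no age effect (the study's finding)."""
    models = {}
    for line, (_, m_pct, f_pct) in LINE_RATES_PCT.items():
        models[line] = MeiosisModel(
            lambda_m=lambda_for_recombinant_probability(m_pct / 100.0, nu_m),
            lambda_f=lambda_for_recombinant_probability(f_pct / 100.0, nu_f),
            nu_m=nu_m,
            nu_f=nu_f,
        )
    return models
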