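"""Pipeline configuration and orchestration: simulate -> estimate ->
test-age -> bias -> predict, with deterministic seeding and a run manifest.

Every output table is stamped with the configuration hash and master seed,
so a run is reproducible byte for byte from its config file.
"""

from __future__ import annotations

import json
from dataclasses import asdict, dataclass
from pathlib import Path
from typing import Mapping

import numpy as np
import pandas as pd
import yaml

from . import age_tests, detection, io as ftl_io, landscape as lsc, rf, sim

__all__ = ["PipelineConfig", "PipelineError", "load_config", "run_pipeline"]


class PipelineError(RuntimeError):
    """A pipeline stage failed; carries the stage name."""

    def __init__(self, stage: str, cause: Exception):
        super().__init__(f"stage {stage!r} failed: {cause}")
        self.stage = stage
        self.cause = cause


@dataclass
class PipelineConfig:
    """Full-run configuration (see docs for field semantics)."""

    seed: int = 1
    ages: tuple[int, ...] = (40, 45, 50, 55)
    replicates: int = 3
    seeds_per_cell: int = 2200
    alpha: float = 0.05
    ratio_convention: str = "ratio_of_means"
    aggregation: str = "replicate_mean"
    mc_draws: int = 100_000
    nondetection_f: float = 0.10
    f_grid: tuple[float, ...] = (0.0, 0.05, 0.10, 0.20)
    distance_mb: float = 5.0
    cross_table: str | None = None
    intervals: str | None = None
    landscape: str | None = None
    models: Mapping[str, Mapping[str, float]] | None = None

    def __post_init__(self) -> None:
        if not 0.0 < self.alpha < 1.0:
            raise ValueError(f"alpha must lie in (0, 1), got {self.alpha}")
        ages = tuple(self.ages)
        if any(b <= a for a, b in zip(ages, ages[1:])):
            raise ValueError(f"ages must be strictly increasing, got {ages}")
        self.ages = ages
        self.f_grid = tuple(self.f_grid)
        for name in ("cross_table", "intervals", "landscape"):
            path = getattr(self, name)
            if path is not None and not Path(path).exists():
                raise FileNotFoundError(f"config references missing {name} file: {path}")

    def as_dict(self) -> dict:
        d = asdict(self)
        d["ages"] = list(self.ages)
        d["f_grid"] = list(self.f_grid)
        return d


def load_config(path) -> PipelineConfig:
    with open(path) as fh:
        raw = yaml.safe_load(fh) or {}
    known = set(PipelineConfig.__dataclass_fields__)
    unknown = set(raw) - known
    if unknown:
        raise ValueError(f"{path}: unknown config keys {sorted(unknown)}")
    return PipelineConfig(**raw)


def _build_models(config: PipelineConfig) -> dict[str, sim.MeiosisModel]:
    if config.models is None:
        return sim.default_models()
    models = {}
    for line, params in config.models.items():
        params = dict(params)
        for key in ("age_effect_m", "age_effect_f"):
            if key in params:
                params[key] = {int(a): float(v) for a, v in params[key].items()}
        models[line] = sim.MeiosisModel(**params)
    return models


def run_pipeline(config: PipelineConfig, out_dir) -> dict:
    """Run all stages; returns the manifest dict (also written to disk)."""
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    chash = ftl_io.config_hash(config.as_dict())
    meta = {"config_hash": chash, "seed": config.seed}
    ss = np.random.SeedSequence(config.seed)
    seed_sim, seed_age, seed_bias = (int(s.generate_state(1)[0]) % (2**31) for s in ss.spawn(3))
    manifest: dict = {"config": config.as_dict(), "config_hash": chash, "outputs": {}, "warnings": []}

    def _emit(name: str, df: pd.DataFrame) -> None:
        ftl_io.write_table(df, out / name, metadata=meta)
        manifest["outputs"][name] = name  # relative to the run directory

    # --- stage: simulate (or load) -----------------------------------------
    try:
        intervals = ftl_io.read_intervals(config.intervals) if config.intervals else sim.default_intervals()
        models = _build_models(config)
        if config.cross_table:
            records = ftl_io.read_cross_table(config.cross_table)
        else:
            design = sim.StudyDesign(
                ages=config.ages,
                n_replicates=config.replicates,
                seeds_per_cell=config.seeds_per_cell,
            )
            recs, truth = sim.simulate_study(models, intervals, design, seed_sim)
            records = sim.records_to_frame(recs)
            _emit("truth.tsv", truth)
        _emit("cross_records.tsv", records)
    except Exception as exc:  # noqa: BLE001 - stage boundary
        raise PipelineError("simulate", exc) from exc

    # --- stage: estimate ----------------------------------------------------
    try:
        summary = rf.summarize_lines(
            records, ratio_convention=config.ratio_convention, aggregation=config.aggregation
        )
        _emit("line_summary.tsv", summary)
        per_age_tables = []
        for line, sub in records.groupby("line", sort=True):
            t = rf.per_age_ratios(sub, aggregation=config.aggregation, strict=False)
            t.insert(0, "line", line)
            per_age_tables.append(t)
        _emit("per_age_ratios.tsv", pd.concat(per_age_tables, ignore_index=True))
    except Exception as exc:
        raise PipelineError("estimate", exc) from exc

    # --- stage: test-age ----------------------------------------------------
    try:
        rng = np.random.default_rng(seed_age)
        reports = []
        for line, sub in records.groupby("line", sort=True):
            for role in sim.ROLES:
                reports.append(
                    age_tests.run_age_analysis(
                        sub, role, alpha=config.alpha, mc_draws=config.mc_draws, rng_seed=rng
                    )
                )
        _emit("age_contrasts.tsv", pd.concat(reports, ignore_index=True))
    except Exception as exc:
        raise PipelineError("test-age", exc) from exc

    # --- stage: bias ----------------------------------------------------
    try:
        sweep_rows, gap_rows = [], []
        for line in sorted(models):
            model = models[line]
            classes = detection.co_class_counts_from_model(model, age_das=config.ages[0])
            sweep = detection.ratio_sensitivity_sweep(classes, config.f_grid)
            sweep.insert(0, "line", line)
            sweep_rows.append(sweep)
            for sex in ("male", "female"):
                lam, p_rec, gap = detection.odd_even_gap(model, sex, config.ages[0])
                gap_rows.append(
                    {"line": line, "sex": sex, "lambda_gamete": lam, "p_recombinant": p_rec, "undercount_gap": gap}
                )
        _emit("bias_sweep.tsv", pd.concat(sweep_rows, ignore_index=True))
        _emit("odd_even_gap.tsv", pd.DataFrame(gap_rows))
        spacing_rows = []
        rng_bias = np.random.default_rng(seed_bias)
        for line in sorted(models):
            iv = intervals[line]
            d = min(config.distance_mb, iv.length_mb)
            spacing = detection.double_co_within(
                models[line], "male", d, iv, age_das=config.ages[0],
                n_meioses=50_000, rng_seed=rng_bias,
            )
            spacing_rows.append(
                {
                    "line": line,
                    "distance_mb": spacing.distance_mb,
                    "fraction_within": spacing.fraction_within,
                    "std_error": spacing.std_error,
                    "n_double_co": spacing.n_double_co,
                }
            )
        _emit("double_co_spacing.tsv", pd.DataFrame(spacing_rows))
    except Exception as exc:
        raise PipelineError("bias", exc) from exc

    # --- stage: predict ----------------------------------------------------
    try:
        if config.landscape:
            land = ftl_io.read_landscape(config.landscape)
        else:
            land = lsc.synthetic_landscape(rng_seed=0)
        predictions = lsc.predict_intervals(land, intervals.values())
        _emit("predictions.tsv", predictions)
        zones = lsc.default_zones()
        overlaps = pd.DataFrame([lsc.zone_overlap(iv, zones) for iv in intervals.values()])
        _emit("zone_overlap.tsv", overlaps)
        paired, rho = lsc.compare_estimated_predicted(summary, predictions)
        _emit("concordance.tsv", paired)
        manifest["spearman_estimated_vs_predicted"] = rho
    except Exception as exc:
        raise PipelineError("predict", exc) from exc

    manifest["outputs"]["manifest.json"] = "manifest.json"
    with open(out / "manifest.json", "w") as fh:
        json.dump(manifest, fh, indent=2, sort_keys=True)
    return manifest
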