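"""End-to-end orchestration: filter -> quadrats -> subject GLMs -> cohort
models -> survival, with every intermediate persisted as delimited text so
the stages compose and a run is auditable.

Stages communicate through files in the output directory:

    cells.csv, clinical.csv      inputs (read or simulated)
    patterns_mm.csv              normalized mm coordinates after TIL filter
    exclusions.csv               dropped subjects with rule that fired
    quadrats.csv                 long-format grid counts
    quadrat_summaries.csv        per-subject quadrat-wise means / SDs
    slopes.csv                   per-subject NB-GLM fits + median split
    cohort_models.json           log-slope OLS, heterogeneity OLS, NB GLMM
    km_overall.csv / km_groups.csv / cox_forest.csv / survival.json
    report.txt, MANIFEST.json
"""

from __future__ import annotations

import dataclasses
import json
import logging
from dataclasses import dataclass, field, asdict
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from . import io as til_io
from . import spatial
from .models.subject import (
    SubjectSlopeModel, arm_medians, cohort_slope_table, fold_change, median_split,
)
from .models.cohort import (
    HeterogeneityModel, LogSlopeModel, NegativeBinomialMixedModel, glmm_long_table,
)
from .models.survival import CoxModel, km_fit
from .simulate import SyntheticTruth, simulate_cohort, cohort_to_cell_table

logger = logging.getLogger(__name__)


@dataclass
class RunConfig:
    """All pipeline knobs; round-trips through YAML unchanged."""

    cells: str | None = None  # input cell table; None => simulate
    clinical: str | None = None
    out: str = "tilspatial_out"
    seed: int = 0
    quadrat_size_mm: float = 0.5
    til_threshold_um: float = 50.0
    min_cancer: int = 10
    min_cd8: int = 10
    til_filter: bool = True
    inclusion_after_filter: bool = True
    log_slope_policy: str = "exclude"  # or "shift"
    log_slope_shift: float = 0.01
    glmm_method: str = "laplace"
    glmm_nodes: int = 7
    cox_age_as_category: bool = True
    cox_collapse_sparse: bool = False
    density_bandwidth_mm: float = 0.25
    write_density: bool = False

    def __post_init__(self) -> None:
        for name in ("quadrat_size_mm", "til_threshold_um", "min_cancer", "min_cd8"):
            if getattr(self, name) <= 0:
                raise ValueError(f"{name} must be positive")

    def to_yaml(self, path) -> None:
        Path(path).write_text(yaml.safe_dump(asdict(self), sort_keys=True))

    @classmethod
    def from_yaml(cls, path) -> "RunConfig":
        data = yaml.safe_load(Path(path).read_text()) or {}
        known = {f.name for f in dataclasses.fields(cls)}
        unknown = set(data) - known
        if unknown:
            raise ValueError(f"unknown config keys: {sorted(unknown)}")
        return cls(**data)


def _outdir(config: RunConfig) -> Path:
    out = Path(config.out)
    out.mkdir(parents=True, exist_ok=True)
    return out


def stage_simulate(config: RunConfig, truth: SyntheticTruth | None = None) -> None:
    """Generate a synthetic cohort into the output directory."""
    out = _outdir(config)
    cohort = simulate_cohort(truth, seed=config.seed)
    til_io.write_cell_table(cohort_to_cell_table(cohort), out / "cells.csv")
    cohort.clinical.to_csv(out / "clinical.csv", index=False)
    cohort.truth.to_json(out / "truth.json", cohort.subject_params)
    logger.info("simulated %d subjects into %s", len(cohort.patterns), out)


def stage_prep(config: RunConfig) -> None:
    """Read cells, TIL-filter, apply inclusion, build quadrat grids."""
    out = _outdir(config)
    cells_path = config.cells or out / "cells.csv"
    records = til_io.read_cell_table(cells_path)
    patterns = til_io.build_all_patterns(records)
    if config.til_filter:
        filtered = [spatial.filter_tils(p, config.til_threshold_um) for p in patterns]
    else:
        filtered = patterns
    basis = filtered if config.inclusion_after_filter else patterns
    keep_ids = {p.subject_id for p in
                til_io.apply_subject_inclusion(basis, config.min_cancer,
                                               config.min_cd8)[0]}
    kept = [p for p in filtered if p.subject_id in keep_ids]
    excluded = [e for e in til_io.apply_subject_inclusion(
        basis, config.min_cancer, config.min_cd8)[1]]
    til_io.write_pattern_csv(kept, out / "patterns_mm.csv")
    til_io.write_exclusions_csv(excluded, out / "exclusions.csv")
    grids = [spatial.make_quadrat_grid(p, config.quadrat_size_mm) for p in kept]
    pd.concat([g.to_long() for g in grids], ignore_index=True).to_csv(
        out / "quadrats.csv", index=False)
    summaries = [spatial.quadrat_summaries(g) for g in grids]
    pd.DataFrame([dataclasses.asdict(s) for s in summaries]).to_csv(
        out / "quadrat_summaries.csv", index=False, float_format="%.6f")
    if config.write_density:
        for p in kept:
            dm = spatial.density_map(p.cancer, p.window,
                                     bandwidth=config.density_bandwidth_mm)
            spatial.write_density_raster(dm, out / f"density_cancer_{p.subject_id}.tsv")
    logger.info("prep: kept %d subjects, excluded %d", len(kept), len(excluded))


def _load_grids(out: Path) -> list[spatial.QuadratGrid]:
    long = pd.read_csv(out / "quadrats.csv")
    grids = []
    for sid, sub in long.groupby("subject_id", sort=False):
        n_rows = int(sub["row"].max()) + 1
        n_cols = int(sub["col"].max()) + 1
        cancer = np.zeros((n_rows, n_cols), dtype=int)
        cd8 = np.zeros((n_rows, n_cols), dtype=int)
        cancer[sub["row"], sub["col"]] = sub["cancer_count"]
        cd8[sub["row"], sub["col"]] = sub["cd8_count"]
        grids.append(spatial.QuadratGrid(
            subject_id=str(sid), origin=(0.0, 0.0), cell_size=0.5,
            n_rows=n_rows, n_cols=n_cols,
            cancer_counts=cancer, cd8_counts=cd8))
    return grids


def stage_slopes(config: RunConfig) -> None:
    """Per-subject NB GLM slopes, cohort join, median split."""
    out = _outdir(config)
    clinical = til_io.read_clinical_table(config.clinical or out / "clinical.csv")
    grids = _load_grids(out)
    results = []
    for g in grids:
        try:
            results.append(SubjectSlopeModel.from_grid(g).fit())
        except ValueError as exc:
            logger.warning("subject %s: slope fit skipped (%s)", g.subject_id, exc)
    table = cohort_slope_table(results, clinical)
    table = median_split(table)
    table.to_csv(out / "slopes.csv", index=False, float_format="%.6g")
    meds = arm_medians(table)
    (out / "arm_medians.json").write_text(json.dumps(
        {
            "medians": meds,
            "fold_change_per_10_cells": {a: round(fold_change(m, 10), 2)
                                         for a, m in meds.items()},
        }, indent=2))


def stage_cohort(config: RunConfig) -> None:
    """Cohort contrasts: log-slope OLS, heterogeneity OLS, NB GLMM."""
    out = _outdir(config)
    clinical = til_io.read_clinical_table(config.clinical or out / "clinical.csv")
    table = pd.read_csv(out / "slopes.csv")
    table["subject_id"] = table["subject_id"].astype(str)
    report: dict = {}

    ls = LogSlopeModel(table, policy=config.log_slope_policy,
                       shift=config.log_slope_shift).fit()
    report["log_slope_model"] = {
        "treatment_coef_log_scale": ls.treatment_coef,
        "implied_slope_ratio_NAT_vs_naive": ls.slope_ratio,
        "treatment_pvalue": ls.treatment_pvalue,
        "n_used": ls.n_used,
        "excluded_nonpositive": ls.excluded_nonpositive,
        "coefficients": {k: float(v) for k, v in ls.params.items()},
        "pvalues": {k: float(v) for k, v in ls.pvalues.items()},
    }

    summaries = pd.read_csv(out / "quadrat_summaries.csv")
    summaries["subject_id"] = summaries["subject_id"].astype(str)
    het_table = summaries.merge(clinical, on="subject_id", how="inner")
    het_table = het_table[het_table["subject_id"].isin(table["subject_id"])]
    het = HeterogeneityModel(het_table).fit()
    report["heterogeneity_model"] = {
        "treatment_effect_on_cancer_quadrat_sd": het.treatment_effect,
        "treatment_pvalue": het.treatment_pvalue,
        "n_used": het.n_used,
    }

    grids = [g for g in _load_grids(out)
             if g.subject_id in set(table["subject_id"])]
    long = glmm_long_table(grids, clinical)
    glmm = NegativeBinomialMixedModel(long).fit(
        method=config.glmm_method, agq_nodes=config.glmm_nodes, seed=config.seed)
    report["nb_glmm"] = {
        "fixed_effects": {k: float(v) for k, v in glmm.fe_params.items()},
        "fixed_effects_se": {k: float(v) for k, v in glmm.fe_bse.items()},
        "pvalues": {k: float(v) for k, v in glmm.fe_pvalues.items()},
        "theta": glmm.theta,
        "random_intercept_sd": glmm.sigma_u,
        "fold_changes_per_100_cancer_cells": {
            k: round(v, 2) for k, v in glmm.fold_changes(100).items()},
        "converged": glmm.converged,
        "method": glmm.method,
    }
    (out / "cohort_models.json").write_text(json.dumps(report, indent=2))


def stage_survive(config: RunConfig) -> None:
    """KM curves and the multivariate Cox model on the slope groups."""
    out = _outdir(config)
    table = pd.read_csv(out / "slopes.csv")
    overall = km_fit(table)
    overall.to_csv(out / "km_overall.csv")
    groups = km_fit(table, group_by="slope_group")
    groups.to_csv(out / "km_groups.csv")
    cox = CoxModel(table, age_as_category=config.cox_age_as_category,
                   collapse_sparse=config.cox_collapse_sparse).fit()
    cox.forest_csv(out / "cox_forest.csv")
    curve = overall.curves["all"]
    payload = {
        "overall_median_days": curve.median,
        "overall_median_ci_days": list(curve.median_ci),
        "n": curve.n,
        "n_events": curve.n_events,
        "group_medians_days": {k: c.median for k, c in groups.curves.items()},
        "cox": cox.table.to_dict(orient="records"),
        "cox_slope_group_hr": cox.hr(cox.slope_group_term),
        "cox_slope_group_ci": list(cox.ci(cox.slope_group_term)),
        "cox_slope_group_p": cox.pvalue(cox.slope_group_term),
    }
    (out / "survival.json").write_text(json.dumps(payload, indent=2, default=float))


def stage_report(config: RunConfig) -> str:
    """Plain-text roll-up of all fitted models."""
    out = _outdir(config)
    lines = ["tilspatial pipeline report", "=" * 30]
    slopes = pd.read_csv(out / "slopes.csv")
    meds = json.loads((out / "arm_medians.json").read_text())
    lines.append(f"subjects analysed: {len(slopes)}")
    exclusions = pd.read_csv(out / "exclusions.csv") \
        if (out / "exclusions.csv").stat().st_size > 0 else pd.DataFrame()
    lines.append(f"subjects excluded: {len(exclusions)}")
    for arm, m in meds["medians"].items():
        fc = meds["fold_change_per_10_cells"][arm]
        lines.append(f"  median slope ({arm}): {m:.4f} "
                     f"-> fold change {fc:.2f} per 10 cancer cells")
    cohort = json.loads((out / "cohort_models.json").read_text())
    lines.append(f"log-slope NAT/naive ratio: "
                 f"{cohort['log_slope_model']['implied_slope_ratio_NAT_vs_naive']:.2f}"
                 f" (p={cohort['log_slope_model']['treatment_pvalue']:.3g})")
    lines.append("heterogeneity (cancer quadrat SD, NAT - naive): "
                 f"{cohort['heterogeneity_model']['treatment_effect_on_cancer_quadrat_sd']:.2f}"
                 f" (p={cohort['heterogeneity_model']['treatment_pvalue']:.3g})")
    fc = cohort["nb_glmm"]["fold_changes_per_100_cancer_cells"]
    lines.append(f"GLMM fold change per 100 cancer cells: naive {fc['naive']:.2f}, "
                 f"NAT {fc['NAT']:.2f}, ratio {fc['ratio']:.2f}")
    surv = json.loads((out / "survival.json").read_text())
    lines.append(f"overall median survival: {surv['overall_median_days']} days "
                 f"(95% CI {surv['overall_median_ci_days']})")
    lines.append(f"Cox HR HigherSlope vs LowerSlope: "
                 f"{surv['cox_slope_group_hr']:.2f} "
                 f"(95% CI {surv['cox_slope_group_ci'][0]:.2f}-"
                 f"{surv['cox_slope_group_ci'][1]:.2f}, "
                 f"p={surv['cox_slope_group_p']:.3g})")
    text = "\n".join(lines) + "\n"
    (out / "report.txt").write_text(text)
    return text


_STAGES = ("simulate", "prep", "slopes", "cohort", "survive", "report")


def run_pipeline(config: RunConfig, truth: SyntheticTruth | None = None) -> str:
    """Run every stage in order; deterministic given inputs + seed.

    On a stage failure the MANIFEST records which stages completed and the
    error, partial outputs are retained, and the exception propagates.
    """
    out = _outdir(config)
    config.to_yaml(out / "config.yaml")
    completed = []
    manifest = {"stages_completed": completed, "complete": False}
    try:
        if config.cells is None:
            stage_simulate(config, truth)
            completed.append("simulate")
        stage_prep(config); completed.append("prep")
        stage_slopes(config); completed.append("slopes")
        stage_cohort(config); completed.append("cohort")
        stage_survive(config); completed.append("survive")
        text = stage_report(config); completed.append("report")
        manifest["complete"] = True
        return text
    except Exception as exc:
        manifest["error"] = f"{type(exc).__name__}: {exc}"
        raise
    finally:
        (out / "MANIFEST.json").write_text(json.dumps(manifest, indent=2))
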