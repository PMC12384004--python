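"""End-to-end orchestration: simulate/load -> extract -> select -> model -> report.

A :class:`PipelineConfig` (usually loaded from YAML) names exactly one
input source — a synthetic cohort specification or a directory of written
volumes — plus extraction, selection and modeling settings.  Every stage
serializes its outputs under the run directory so later stages can resume
from intermediates, and the configuration hash and seed are recorded in
every artifact for provenance.
"""

from __future__ import annotations

import hashlib
import json
import logging
from pathlib import Path

import pandas as pd
from pydantic import BaseModel, Field, model_validator

from .features import ExtractionConfig, delta_features, extract_cohort_features
from .filters import FilterConfig
from .modeling import (
    DlcoRadiomicsModel,
    EvaluationData,
    clinical_association_table,
    dlco_abnormal,
    paired_wilcoxon_signed_rank,
)
from .selection import SelectionConfig, iterative_cluster_select, near_zero_variance_filter, prune_high_correlation
from .synthetic import CohortConfig, generate_cohort, read_cohort, write_cohort

__all__ = ["PipelineConfig", "run_pipeline"]

log = logging.getLogger("dlcoradiomics.pipeline")


class SyntheticSettings(BaseModel):
    n_patients: int
    grid_shape: tuple[int, int, int] = (48, 48, 32)
    spacing_mm: tuple[float, float, float] = (1.0, 1.0, 2.5)
    frac_abnormal: float = 0.4
    texture_effect: float = 1.0
    clinical_effect: float = 1.0
    n_lesions_range: tuple[int, int] = (1, 3)
    lesion_radius_mm_range: tuple[float, float] = (4.0, 10.0)
    phase_compression: float = 0.85
    noise_sd_hu: float = 20.0
    frac_with_post: float = 0.6
    write_images: bool = False

    def to_cohort_config(self, seed: int) -> CohortConfig:
        return CohortConfig(
            n_patients=self.n_patients,
            grid_shape=tuple(self.grid_shape),
            spacing_mm=tuple(self.spacing_mm),
            frac_abnormal=self.frac_abnormal,
            texture_effect=self.texture_effect,
            clinical_effect=self.clinical_effect,
            n_lesions_range=tuple(self.n_lesions_range),
            lesion_radius_mm_range=tuple(self.lesion_radius_mm_range),
            phase_compression=self.phase_compression,
            noise_sd_hu=self.noise_sd_hu,
            frac_with_post=self.frac_with_post,
            seed=seed,
        )


class ExtractionSettings(BaseModel):
    filters: tuple[str, ...] = (
        "original", "wavelet", "log", "gradient",
        "square", "squareroot", "logarithm", "exponential",
    )
    wavelet_family: str = "coif1"
    log_sigmas_mm: tuple[float, ...] = (2.0, 4.0)
    bin_width_hu: float = 25.0
    gtv_margin_mm: float = 0.5
    glcm_distance: int = 1
    glcm_pooling: str = "sum"
    gldm_alpha: int = 0
    normalize: bool = False  # histogram-normalize against the first patient

    def to_extraction_config(self, normalization=None) -> ExtractionConfig:
        return ExtractionConfig(
            filters=FilterConfig(
                enabled=tuple(self.filters),
                wavelet_family=self.wavelet_family,
                log_sigmas_mm=tuple(self.log_sigmas_mm),
            ),
            bin_width_hu=self.bin_width_hu,
            gtv_margin_mm=self.gtv_margin_mm,
            glcm_distance=self.glcm_distance,
            glcm_pooling=self.glcm_pooling,
            gldm_alpha=self.gldm_alpha,
            normalization=normalization,
        )


class SelectionSettings(BaseModel):
    prune_rho: float = 0.95
    cluster_rho: float = 0.75
    nzv_freq_ratio: float = 19.0
    nzv_unique_frac: float = 0.1

    def to_selection_config(self) -> SelectionConfig:
        return SelectionConfig(
            prune_rho=self.prune_rho,
            cluster_rho=self.cluster_rho,
            nzv_freq_ratio=self.nzv_freq_ratio,
            nzv_unique_frac=self.nzv_unique_frac,
        )


class ModelingSettings(BaseModel):
    k: int = 3
    reps: int = 100
    covariates: tuple[str, ...] = ("cci",)


class PipelineConfig(BaseModel):
    """Validated pipeline configuration (exactly one input source)."""

    seed: int
    output_dir: str
    synthetic: SyntheticSettings | None = None
    input_dir: str | None = None
    extraction: ExtractionSettings = Field(default_factory=ExtractionSettings)
    selection: SelectionSettings = Field(default_factory=SelectionSettings)
    modeling: ModelingSettings = Field(default_factory=ModelingSettings)

    @model_validator(mode="after")
    def _one_source(self):
        if (self.synthetic is None) == (self.input_dir is None):
            raise ValueError(
                "exactly one input source required: set either 'synthetic' or 'input_dir'"
            )
        return self

    def config_hash(self) -> str:
        payload = json.dumps(self.model_dump(), sort_keys=True, default=str)
        return hashlib.sha256(payload.encode()).hexdigest()[:16]


def _json_dump(obj, path: Path) -> None:
    with open(path, "w") as fh:
        json.dump(obj, fh, indent=2, sort_keys=True)
        fh.write("\n")


def stage_cohort(config: PipelineConfig, outdir: Path):
    """Simulate or load the cohort."""
    if config.synthetic is not None:
        cohort_cfg = config.synthetic.to_cohort_config(config.seed)
        patients, table = generate_cohort(cohort_cfg)
        log.info("simulated %d patients (%d abnormal baseline DLCO)",
                 len(patients), int(dlco_abnormal(table["dlco_baseline_pct"]).sum()))
        if config.synthetic.write_images:
            write_cohort(patients, table, outdir / "cohort")
        else:
            (outdir / "cohort").mkdir(exist_ok=True, parents=True)
            table.to_csv(outdir / "cohort" / "clinical.csv", index=False, float_format="%.6f")
    else:
        patients, table = read_cohort(config.input_dir)
        log.info("loaded %d patients from %s", len(patients), config.input_dir)
    return patients, table


def stage_extract(config: PipelineConfig, patients, outdir: Path) -> dict[str, pd.DataFrame]:
    """Phase 0 / Phase 50 extraction plus the Δ table; all written as CSV."""
    extraction = config.extraction.to_extraction_config()
    tables = {}
    for phase in ("phase0", "phase50"):
        tables[phase] = extract_cohort_features(patients, phase, extraction)
        log.info("extracted %d features x %d patients for %s",
                 tables[phase].shape[1], tables[phase].shape[0], phase)
    tables["delta"] = delta_features(tables["phase0"], tables["phase50"])
    fdir = outdir / "features"
    fdir.mkdir(exist_ok=True, parents=True)
    for name, tab in tables.items():
        tab.to_csv(fdir / f"{name}.csv", float_format="%.10g")
    _json_dump(
        {"config_hash": config.config_hash(), "seed": config.seed,
         "extraction": extraction.to_dict()},
        fdir / "extraction_config.json",
    )
    return tables


def stage_select(config: PipelineConfig, tables, cohort: pd.DataFrame, outdir: Path) -> dict:
    """Descriptive full-cohort selection per phase design (audit trail kept)."""
    sel_cfg = config.selection.to_selection_config()
    y = dlco_abnormal(cohort["dlco_baseline_pct"].to_numpy()).astype(int)
    out = {}
    for phase, table in tables.items():
        nzv = near_zero_variance_filter(table, sel_cfg)
        log.info("%s: %d features survive near-zero-variance screening", phase, nzv.shape[1])
        pruned = prune_high_correlation(nzv, y, sel_cfg.prune_rho)
        log.info("%s: %d features survive |rho|>%.2f pruning", phase, pruned.shape[1], sel_cfg.prune_rho)
        result = iterative_cluster_select(pruned, y, sel_cfg)
        log.info("%s: %d features selected after %d clustering iterations",
                 phase, len(result.selected), result.iterations)
        out[phase] = result.to_dict()
        out[phase]["n_input_features"] = int(table.shape[1])
        out[phase]["n_after_nzv"] = int(nzv.shape[1])
        out[phase]["n_after_prune"] = int(pruned.shape[1])
    _json_dump({"config_hash": config.config_hash(), "seed": config.seed,
                "selection": out}, outdir / "selection.json")
    return out


def stage_model(config: PipelineConfig, tables, cohort: pd.DataFrame, outdir: Path):
    """Fit and evaluate the thirteen-model design."""
    cohort_ix = cohort.set_index("patient_id", drop=False)
    data = EvaluationData(tables, cohort_ix, tuple(config.modeling.covariates))
    model = DlcoRadiomicsModel(
        data,
        k=config.modeling.k,
        reps=config.modeling.reps,
        selection=config.selection.to_selection_config(),
    )
    results = model.fit(seed=config.seed)
    payload = results.to_dict()
    payload["config_hash"] = config.config_hash()
    _json_dump(payload, outdir / "model_results.json")
    results.to_frame().to_csv(outdir / "model_results.csv", index=False, float_format="%.6g")
    return results


def stage_report(config: PipelineConfig, cohort: pd.DataFrame, results, outdir: Path) -> Path:
    """Markdown report: clinical associations and the per-model AUC table."""
    y = dlco_abnormal(cohort["dlco_baseline_pct"].to_numpy())
    assoc = clinical_association_table(cohort, y)
    lines = [
        "# DLCO radiomics pipeline report",
        "",
        f"- configuration hash: `{config.config_hash()}`",
        f"- seed: {config.seed}",
        f"- patients: {len(cohort)} ({int(y.sum())} abnormal baseline DLCO)",
        "",
        "## Clinical associations with abnormal baseline DLCO",
        "",
        "| variable | test | p-value |",
        "| --- | --- | --- |",
    ]
    for _, row in assoc.iterrows():
        lines.append(f"| {row.variable} | {row.test} | {row.p_value:.4g} |")
    paired = cohort[cohort["dlco_post_pct"].notna()]
    if len(paired) >= 1:
        p_paired = paired_wilcoxon_signed_rank(
            paired["dlco_baseline_pct"].to_numpy(), paired["dlco_post_pct"].to_numpy()
        )
        lines += ["", f"Baseline vs post-treatment DLCO (paired signed-rank, "
                      f"n={len(paired)}): p = {p_paired:.4g}"]
    lines += ["", "## Repeated cross-validated AUC (median, IQR)", "",
              "| model | median AUC | IQR |", "| --- | --- | --- |"]
    for _, row in results.to_frame().iterrows():
        lines.append(
            f"| {row.model} | {row.median_auc:.3f} | ({row.auc_q1:.3f}-{row.auc_q3:.3f}) |"
        )
    lines.append("")
    report_path = outdir / "report.md"
    report_path.write_text("\n".join(lines))
    assoc.to_csv(outdir / "clinical_associations.csv", index=False, float_format="%.6g")
    return report_path


def run_pipeline(config: PipelineConfig):
    """Execute all stages in order; returns the fitted results object."""
    outdir = Path(config.output_dir)
    outdir.mkdir(parents=True, exist_ok=True)
    log.info("pipeline start: config hash %s, seed %d", config.config_hash(), config.seed)
    stage = "cohort"
    try:
        patients, cohort = stage_cohort(config, outdir)
        stage = "extract"
        tables = stage_extract(config, patients, outdir)
        stage = "select"
        stage_select(config, tables, cohort, outdir)
        stage = "model"
        results = stage_model(config, tables, cohort, outdir)
        stage = "report"
        stage_report(config, cohort, results, outdir)
    except Exception as exc:
        raise RuntimeError(f"pipeline failed in stage '{stage}': {exc}") from exc
    log.info("pipeline complete: %s", outdir)
    return results
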