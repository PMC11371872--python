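"""Cohort filtering, configuration, and end-to-end orchestration.

The pipeline chains the stages on synthetic (or deposited) inputs:
heatmap quantification -> subject summaries -> rating validation ->
region association models -> quantitative-vs-semi-quantitative comparison ->
surface cluster inference, writing tidy CSV outputs, a PLY t-map surface and
a run manifest (seed, config hash, package versions).
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
import logging
from dataclasses import dataclass
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from . import __version__
from .association import (REGIONS, RegionAssociationModel, compare_models,
                          run_cohort_analyses)
from .heatmap import (DEFAULT_TARGET_AREA_UM2, SamplingBox, partition_roi,
                      segment_averages)
from .simulate import (MeshSpec, SeverityModel, generate_cohort,
                       generate_heatmap, generate_surface_dataset,
                       generate_validation_boxes)
from .summary import (HIPPOCAMPAL_ROIS, hippocampal_summary, pool_roi_measure,
                      rescale_summary)
from .surface import SurfaceGLM
from .validation import spearman_assoc, stagewise_auc, statistic_selection

__all__ = ["PipelineConfig", "apply_inclusion_filters", "run_pipeline"]

log = logging.getLogger("mtlpath")


@dataclass
class PipelineConfig:
    """All pipeline parameters; round-trips losslessly through YAML/JSON."""

    # synthetic-input sizes
    n_subjects: int = 60
    n_quantified_subjects: int = 12  # subjects run through heatmap stage
    heatmap_shape_px: tuple = (96, 96)
    pixel_size_um: float = 10.0
    # analysis parameters
    target_segment_area_um2: float = DEFAULT_TARGET_AREA_UM2
    statistic: str = "q99"
    threshold: float = 2.0
    n_perm: int = 10000
    alpha: float = 0.05
    n_regions: int = 6
    max_antemortem_years: float = 10.0
    surface_n_subjects: int = 40
    surface_grid: tuple = (24, 24)
    surface_effect_mm: float = 0.6
    seed: int = 42
    # optional real-data paths (synthetic inputs are generated when empty)
    heatmap_dir: str = ""
    cohort_csv: str = ""
    mesh_path: str = ""

    def to_dict(self) -> dict:
        d = dataclasses.asdict(self)
        for key in ("heatmap_shape_px", "surface_grid"):
            d[key] = list(d[key])
        return d

    @classmethod
    def from_dict(cls, d: dict) -> "PipelineConfig":
        d = dict(d)
        for key in ("heatmap_shape_px", "surface_grid"):
            if key in d:
                d[key] = tuple(d[key])
        return cls(**d)

    def to_yaml(self, path) -> None:
        Path(path).write_text(yaml.safe_dump(self.to_dict()))

    @classmethod
    def from_yaml(cls, path) -> "PipelineConfig":
        return cls.from_dict(yaml.safe_load(Path(path).read_text()))

    def config_hash(self) -> str:
        blob = json.dumps(self.to_dict(), sort_keys=True).encode()
        return hashlib.sha256(blob).hexdigest()[:16]


def apply_inclusion_filters(cohort: pd.DataFrame, config: PipelineConfig,
                            require_quant: bool = False):
    """Apply the imaging-cohort inclusion filters.

    Excludes subjects whose antemortem interval exceeds the configured limit
    (inclusive boundary: exactly 10.0 years is included) and subjects whose
    MRI failed segmentation/image QC in the hemisphere ipsilateral to the one
    used for neuropathology.  Returns the filtered table plus per-subject
    eligibility flags with exclusion reasons.
    """
    required = ["subject_id", "antemortem_interval", "qc_ipsilateral"]
    for col in required:
        if col not in cohort.columns:
            raise ValueError(f"required column missing: {col!r}")
    flags = pd.DataFrame({
        "subject_id": cohort["subject_id"],
        "antemortem_interval_ok":
            cohort["antemortem_interval"] <= config.max_antemortem_years,
        "ipsilateral_qc_ok": cohort["qc_ipsilateral"].astype(bool),
        "has_quant_tau": cohort.get(
            "tangles_q", pd.Series(np.nan, index=cohort.index)).notna(),
        "has_quant_tdp": cohort.get(
            "neuronal_glial_q", pd.Series(np.nan, index=cohort.index)).notna(),
        "braak_stage": cohort.get("braak_stage"),
        "late_stage": cohort.get("late_stage"),
    })
    ok = flags["antemortem_interval_ok"] & flags["ipsilateral_qc_ok"]
    if require_quant:
        ok &= flags["has_quant_tau"] & flags["has_quant_tdp"]

    def reason(row):
        r = []
        if not row["antemortem_interval_ok"]:
            r.append(f"antemortem interval > {config.max_antemortem_years}y")
        if not row["ipsilateral_qc_ok"]:
            r.append("failed ipsilateral QC")
        if require_quant and not (row["has_quant_tau"]
                                  and row["has_quant_tdp"]):
            r.append("missing quantitative measures")
        return "; ".join(r)

    flags["excluded_reason"] = flags.apply(reason, axis=1)
    filtered = cohort[ok.to_numpy()]
    log.info("inclusion filters: %d in, %d kept, %d excluded",
             len(cohort), len(filtered), len(cohort) - len(filtered))
    return filtered, flags


# ---------------------------------------------------------------------------
# stages


def quantify_stage(config: PipelineConfig, severities: np.ndarray,
                   seed: int) -> pd.DataFrame:
    """Heatmap -> ROI quantification for a set of subjects.

    For each subject and eligible hippocampal ROI, simulate an attention
    heatmap from the subject's latent severity, partition the sampling box,
    average per segment, and pool with the configured statistic.
    """
    model = SeverityModel()
    rows = []
    ss = np.random.SeedSequence(seed)
    for subj_idx, severity in enumerate(severities):
        for roi_idx, roi in enumerate(HIPPOCAMPAL_ROIS):
            hm_seed = int(ss.spawn(1)[0].generate_state(1)[0] % 2**31)
            hm = generate_heatmap(severity, config.heatmap_shape_px,
                                  config.pixel_size_um, model, seed=hm_seed)
            box = SamplingBox(box_id=f"S{subj_idx}_{roi}", slide_id="sim",
                              anatomical_label=roi,
                              mask=np.ones(config.heatmap_shape_px, bool),
                              pixel_size_um=config.pixel_size_um)
            part = partition_roi(box, config.target_segment_area_um2)
            seg = segment_averages(hm, part)
            value = pool_roi_measure([seg], config.statistic)
            rows.append({"subject_idx": subj_idx, "anatomical_label": roi,
                         "inclusion_class": "tangles", "value": value,
                         "n_segments": part.n_segments})
    return pd.DataFrame(rows)


def summarize_stage(roi_measures: pd.DataFrame,
                    ratings: np.ndarray) -> pd.DataFrame:
    """ROI measures -> per-subject hippocampal summary, recalibrated 0-3."""
    rows = []
    for subj_idx, grp in roi_measures.groupby("subject_idx"):
        measures = dict(zip(grp["anatomical_label"], grp["value"]))
        rows.append({"subject_idx": subj_idx,
                     "raw_summary": hippocampal_summary(measures, "tangles")})
    out = pd.DataFrame(rows)
    out["mtl_rating"] = ratings[out["subject_idx"].to_numpy()]
    transformed, intercept, slope = rescale_summary(
        out["raw_summary"].to_numpy(), out["mtl_rating"].to_numpy())
    out["summary_0_3"] = transformed
    out.attrs["rescale"] = {"intercept": intercept, "slope": slope}
    return out


def run_pipeline(config: PipelineConfig, outdir) -> dict:
    """Execute all stages on synthetic inputs and write the report bundle.

    Returns a dict of the output DataFrames/objects; all randomness derives
    from ``config.seed`` through a single seed sequence split in fixed stage
    order, so two runs with the same config are byte-identical.
    """
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    ss = np.random.SeedSequence(config.seed)
    seeds = [int(s.generate_state(1)[0] % 2**31) for s in ss.spawn(6)]
    outputs: dict = {}

    # stage 0: cohort simulation + inclusion filtering
    cohort = generate_cohort(config.n_subjects, seed=seeds[0])
    cohort.to_csv(outdir / "cohort.csv", index=False)
    filtered, flags = apply_inclusion_filters(cohort, config)
    flags.to_csv(outdir / "eligibility.csv", index=False)
    outputs["cohort"], outputs["eligibility"] = cohort, flags
    log.info("cohort: %d subjects, %d pass filters", len(cohort),
             len(filtered))

    # stage 1: heatmap quantification on a subset of subjects
    nq = min(config.n_quantified_subjects, len(filtered))
    sub = filtered.iloc[:nq]
    roi_measures = quantify_stage(config, sub["latent_tau"].to_numpy(),
                                  seeds[1])
    roi_measures.to_csv(outdir / "roi_measures.csv", index=False)
    outputs["roi_measures"] = roi_measures

    # stage 2: hippocampal summaries recalibrated to the 0-3 scale
    summaries = summarize_stage(roi_measures,
                                sub["mtl_ptau_rating"].to_numpy())
    summaries.to_csv(outdir / "summaries.csv", index=False)
    outputs["summaries"] = summaries

    # stage 3: validation (statistic selection, stagewise AUC, Spearman)
    seg_values, box_ratings = generate_validation_boxes(seed=seeds[2])
    selection = statistic_selection(seg_values, box_ratings)
    selection.to_csv(outdir / "statistic_selection.csv", index=False)
    auc_braak = stagewise_auc(filtered["tangles_q"],
                              filtered["braak_stage"])
    auc_braak.to_csv(outdir / "auc_braak.csv", index=False)
    rho, p = spearman_assoc(filtered["tangles_q"],
                            filtered["mtl_ptau_rating"])
    outputs.update(statistic_selection=selection, auc_braak=auc_braak,
                   spearman=(rho, p))

    # stage 4: region association models, whole cohort + subgroups
    tables = [run_cohort_analyses(filtered, sg, alpha=config.alpha,
                                  n_regions=config.n_regions)
              for sg in ("whole", "advanced_adnc", "late")]
    assoc = pd.concat(tables, ignore_index=True)
    assoc.to_csv(outdir / "associations.csv", index=False)
    outputs["associations"] = assoc

    # stage 5: quantitative vs semi-quantitative model comparison
    comp_rows = []
    for region in REGIONS:
        fq = RegionAssociationModel(
            filtered, region, ["tangles_q", "threads_q"],
            covariates=_comparison_covariates(region)).fit()
        fs = RegionAssociationModel(
            filtered, region, ["mtl_ptau_rating"],
            covariates=_comparison_covariates(region)).fit()
        comp_rows.append(dataclasses.asdict(compare_models(fq, fs)))
    comparison = pd.DataFrame(comp_rows)
    comparison.to_csv(outdir / "model_comparison.csv", index=False)
    outputs["comparison"] = comparison

    # stage 6: surface cluster inference
    nx, ny = config.surface_grid
    spec = MeshSpec(nx=nx, ny=ny, effect_mm_per_sd=config.surface_effect_mm,
                    cluster_radius_mm=0.15 * nx)
    ns = config.surface_n_subjects
    pathology = generate_cohort(ns, effects=[],
                                seed=seeds[3])["tangles_q"].to_numpy()
    sdata, planted = generate_surface_dataset(ns, spec, pathology,
                                              seed=seeds[4])
    sres = SurfaceGLM(sdata).fit(threshold=config.threshold,
                                 n_perm=config.n_perm, seed=seeds[5])
    clusters = pd.DataFrame(
        [{"cluster": i + 1, "n_vertices": len(c.vertex_ids),
          "area_mm2": c.area_mm2, "peak_t": c.peak_t,
          "p_corrected": c.p_corrected}
         for i, c in enumerate(sres.clusters)])
    clusters.to_csv(outdir / "surface_clusters.csv", index=False)
    cluster_id = np.full(len(sdata.vertices), -1.0)
    for i, c in enumerate(sres.clusters):
        cluster_id[c.vertex_ids] = i
    from .io import write_mesh_ply
    write_mesh_ply(outdir / "surface_tmap.ply", sdata.vertices,
                   sdata.triangles,
                   {"tmap": sres.tmap, "cluster_id": cluster_id})
    outputs["surface"] = sres
    outputs["planted_cluster"] = planted

    manifest = {
        "config": config.to_dict(),
        "config_hash": config.config_hash(),
        "seed": config.seed,
        "mtlpath_version": __version__,
        "numpy_version": np.__version__,
        "outputs": sorted(p.name for p in outdir.iterdir()),
    }
    (outdir / "manifest.json").write_text(json.dumps(manifest, indent=1))
    outputs["manifest"] = manifest
    return outputs


def _comparison_covariates(region: str) -> list:
    cov = ["age_at_death", "sex", "field_strength", "antemortem_interval",
           "mtl_ptdp_rating"]
    if region in ("AH", "PH"):
        cov.append("icv")
    return cov
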