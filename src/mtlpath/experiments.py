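"""Simulation studies validating the pipeline end to end.

Each function runs a self-contained experiment at the package's reference
study conditions and returns the measured quantity: analytically forced
constants (Bonferroni threshold, model degrees of freedom, staging rates),
parameter-recovery bias, familywise error and power of the cluster
permutation test, the summary-statistic selection experiment, and the
quantitative-vs-semi-quantitative model-comparison preference rate.
"""

from __future__ import annotations

import warnings

import numpy as np
import pandas as pd

from .association import (RegionAssociationModel, bonferroni_threshold,
                          compare_models, run_cohort_analyses)
from .simulate import (EffectSpec, MeshSpec, generate_cohort,
                       generate_surface_dataset, generate_validation_boxes)
from .summary import late_stage
from .surface import SurfaceGLM
from .validation import statistic_selection

PATHOLOGY_PREDICTORS = ("tangles_q", "threads_q", "mtl_ptdp_rating")


def reference_bonferroni(alpha: float = 0.05, n_regions: int = 6) -> float:
    """Per-region threshold for the six-region analysis."""
    return bonferroni_threshold(alpha, n_regions)


def _exact_subgroup_cohort(n_total: int, n_in: int, stage_col: str,
                           stage_min: int, seed: int) -> pd.DataFrame:
    """Cohort with an exact subgroup size drawn from a large simulation."""
    pool = generate_cohort(6 * n_total, seed=seed)
    members = pool[pool[stage_col] >= stage_min].head(n_in)
    others = pool[pool[stage_col] < stage_min].head(n_total - n_in)
    if len(members) < n_in or len(others) < n_total - n_in:
        raise RuntimeError("simulation pool too small for subgroup sizes")
    return pd.concat([members, others]).reset_index(drop=True)


def model_degrees_of_freedom(seed: int = 0) -> dict:
    """Residual df of the region models at the three cohort sizes.

    Whole cohort n=140, LATE-NC subgroup n=31, advanced-ADNC subgroup n=85;
    each model has three pathology predictors, four nuisance covariates, and
    ICV additionally for the volume outcomes.
    """
    out = {}
    whole = generate_cohort(140, seed=seed)
    out["whole_volume"] = RegionAssociationModel(
        whole, "AH", PATHOLOGY_PREDICTORS).fit().df_resid
    out["whole_thickness"] = RegionAssociationModel(
        whole, "ERC", PATHOLOGY_PREDICTORS).fit().df_resid

    late = _exact_subgroup_cohort(140, 31, "late_stage", 1, seed + 1)
    tab = run_cohort_analyses(late, "late",
                              pathology_predictors=PATHOLOGY_PREDICTORS)
    df = tab.groupby("region")["df_resid"].first()
    out["late_volume"], out["late_thickness"] = int(df["AH"]), int(df["ERC"])

    adv = _exact_subgroup_cohort(140, 85, "braak_stage", 5, seed + 2)
    tab = run_cohort_analyses(adv, "advanced_adnc",
                              pathology_predictors=PATHOLOGY_PREDICTORS)
    df = tab.groupby("region")["df_resid"].first()
    out["advanced_volume"] = int(df["AH"])
    out["advanced_thickness"] = int(df["ERC"])
    return out


def late_nc_rate(n_total: int = 140, n_positive: int = 31) -> float:
    """LATE-NC prevalence (%) in a cohort with the reference staging counts.

    Builds regional pTDP-43 rating profiles for ``n_total`` subjects of whom
    ``n_positive`` have amygdala involvement, runs them through the staging
    rules, and reports the percentage staged 1 or higher.
    """
    stages = [late_stage(1.0, 0.0, 0.0, 0.0, 0.0)] * n_positive
    stages += [late_stage(0.0, 0.0, 0.0, 0.0, 0.0)] * (n_total - n_positive)
    stages = np.asarray(stages)
    return 100.0 * float((stages >= 1).mean())


def recovery_study(n_reps: int = 200, n: int = 140, beta: float = -0.4,
                   seed: int = 0) -> dict:
    """Parameter recovery: planted standardized tangles effect at n=140.

    Returns the mean recovered beta, its bias, and 95% CI coverage across
    replicate cohorts.
    """
    spec = [EffectSpec(
        region="ERC",
        beta={"tangles_q": beta, "threads_q": 0.0, "mtl_ptdp_rating": -0.2},
        covariate_effects={"age_at_death": -0.2, "sex": -0.1,
                           "field_strength": 0.05,
                           "antemortem_interval": -0.05})]
    from scipy import stats
    betas, covered = [], 0
    for rep in range(n_reps):
        cohort = generate_cohort(n, effects=spec, seed=seed + rep)
        fit = RegionAssociationModel(cohort, "ERC",
                                     list(PATHOLOGY_PREDICTORS)).fit()
        b = float(fit.params["tangles_q"])
        betas.append(b)
        se = abs(b / fit.tvalues["tangles_q"]) if fit.tvalues["tangles_q"] \
            else np.inf
        half = stats.t.ppf(0.975, fit.df_resid) * se
        covered += (b - half) <= beta <= (b + half)
    mean_beta = float(np.mean(betas))
    return {"mean_beta": mean_beta, "bias": mean_beta - beta,
            "coverage": covered / n_reps}


# ---------------------------------------------------------------------------
# cluster permutation studies (64 x 64 grid template)


def _null_surface(n_subjects, seed, noise_sd=0.25, nx=64, ny=64):
    spec = MeshSpec(nx=nx, ny=ny, effect_mm_per_sd=0.0, noise_sd=noise_sd)
    rng = np.random.default_rng(seed)
    return generate_surface_dataset(n_subjects, spec, rng.normal(size=n_subjects),
                                    seed=seed + 1)


def cluster_fwer_study(n_datasets: int = 200, n_perm: int = 500,
                       n_subjects: int = 40, seed: int = 0) -> dict:
    """Familywise type-I error of the cluster permutation test.

    Null thickness datasets on the 64x64 grid template; the familywise error
    is the fraction of datasets with any cluster at corrected p < 0.05.
    """
    hits = 0
    for d in range(n_datasets):
        data, _ = _null_surface(n_subjects, seed=seed + 1000 * d)
        res = SurfaceGLM(data).fit(n_perm=n_perm, seed=seed + 1000 * d + 7)
        hits += bool(res.significant_clusters(0.05))
    return {"fwer": hits / n_datasets, "n_datasets": n_datasets}


def cluster_power_study(n_reps: int = 100, n_perm: int = 500,
                        n_subjects: int = 60, standardized_effect: float = 0.8,
                        noise_sd: float = 0.25, seed: int = 0) -> dict:
    """Power to detect a planted deficit cluster.

    The planted disc loses ``standardized_effect * noise_sd`` mm of
    thickness per SD of pathology.  Detection requires corrected p < 0.05
    and Jaccard overlap > 0.5 between the top cluster and the planted set.
    """
    spec = MeshSpec(nx=64, ny=64, cluster_radius_mm=8.0,
                    effect_mm_per_sd=standardized_effect * noise_sd,
                    noise_sd=noise_sd)
    detected = 0
    for rep in range(n_reps):
        rng = np.random.default_rng(seed + 100 * rep)
        data, planted = generate_surface_dataset(
            n_subjects, spec, rng.normal(size=n_subjects),
            seed=seed + 100 * rep + 3)
        res = SurfaceGLM(data).fit(n_perm=n_perm, seed=seed + 100 * rep + 5)
        if not res.clusters:
            continue
        top = res.clusters[0]
        inter = np.intersect1d(top.vertex_ids, planted).size
        union = len(top.vertex_ids) + planted.size - inter
        if top.p_corrected < 0.05 and inter / union > 0.5:
            detected += 1
    return {"power": detected / n_reps, "n_reps": n_reps}


def statistic_selection_study(seed: int = 0) -> pd.DataFrame:
    """Summary-statistic ranking on boxes where only the extreme activation
    tail tracks severity."""
    seg, ratings = generate_validation_boxes(seed=seed)
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        return statistic_selection(seg, ratings)


def model_comparison_study(n_reps: int = 200, n: int = 140,
                           seed: int = 0) -> dict:
    """Preference for the quantitative model when it holds the true driver.

    The outcome is driven by the continuous tangles measure; the competing
    semi-quantitative model carries its 5-level ordinal coarsening (the ERC
    p-tau rating).  Returns the fraction of replicates where the BIC delta
    favors the quantitative model.
    """
    spec = [EffectSpec(region="ERC", beta={"tangles_q": -0.5},
                       covariate_effects={"age_at_death": -0.2, "sex": -0.1,
                                          "field_strength": 0.05,
                                          "antemortem_interval": -0.05})]
    covariates = ["age_at_death", "sex", "field_strength",
                  "antemortem_interval"]
    wins = 0
    for rep in range(n_reps):
        cohort = generate_cohort(n, effects=spec, seed=seed + rep)
        fq = RegionAssociationModel(cohort, "ERC", ["tangles_q"],
                                    covariates=covariates).fit()
        fs = RegionAssociationModel(cohort, "ERC", ["ptau_erc"],
                                    covariates=covariates).fit()
        wins += compare_models(fq, fs).delta_bic < 0
    return {"quant_preferred": wins / n_reps, "n_reps": n_reps}
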