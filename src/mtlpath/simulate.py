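"""Synthetic inputs with known ground truth for every pipeline stage.

The generators emulate, at the statistical level, the four kinds of data the
pipeline consumes: classifier attention heatmaps whose blob density is driven by a latent
pathology severity, ordinal expert ratings obtained by thresholding that
severity, cohorts with planted linear pathology-to-morphometry effects under
covariate confounding, and template surfaces with a planted contiguous
thickness-deficit cluster.  No attempt is made to simulate histology
appearance or stain chemistry; only activation-map and cohort statistics.

All generators are deterministic given their seed.
"""

from __future__ import annotations

from dataclasses import dataclass, field as dc_field

import numpy as np
import pandas as pd
from scipy import stats

from .heatmap import HeatMap
from .summary import RATING_LEVELS, late_stage, mtl_average_rating
from .surface import SurfaceDataset, make_grid_mesh, vertex_adjacency

__all__ = [
    "SeverityModel",
    "EffectSpec",
    "MeshSpec",
    "generate_heatmap",
    "generate_ordinal_rating",
    "generate_cohort",
    "generate_surface_dataset",
    "generate_validation_boxes",
    "default_effects",
    "COHORT_COLUMNS",
]


@dataclass
class SeverityModel:
    """Forward model from a latent severity to heatmaps and ordinal ratings.

    ``blob_rate_per_severity`` sets the expected inclusion-blob density
    (blobs per mm^2 per unit severity; the rate is linear, hence
    non-decreasing, in severity).  Blobs are Gaussian bumps of amplitude
    ``blob_amplitude`` and spatial sd ``blob_sigma_um``, truncated at three
    sigma, combined by maximum so activations stay in [0, 1]; background
    noise is Gaussian with sd ``noise_sd``, and the grid is clipped to
    [0, 1].  ``rating_thresholds`` are four increasing severity cutpoints
    mapping severity to the ordinal rating scale {0, 0.5, 1, 2, 3}.
    """

    blob_rate_per_severity: float = 2.0
    blob_amplitude: float = 0.8
    blob_sigma_um: float = 6.0
    noise_sd: float = 0.02
    rating_thresholds: tuple = (0.5, 1.5, 3.0, 5.0)

    def __post_init__(self) -> None:
        if self.blob_rate_per_severity < 0:
            raise ValueError("blob rate must be non-negative")
        t = np.asarray(self.rating_thresholds, dtype=float)
        if len(t) != 4 or not np.all(np.diff(t) > 0):
            raise ValueError("rating_thresholds must be 4 strictly "
                             "increasing cutpoints")
        if not (0 < self.blob_amplitude <= 1):
            raise ValueError("blob_amplitude must be in (0, 1]")

    def blob_rate(self, severity: float) -> float:
        """Expected blobs per mm^2 at a given severity."""
        return self.blob_rate_per_severity * severity


def generate_heatmap(severity: float, box_shape_px: tuple,
                     pixel_size_um: float, model: SeverityModel = None,
                     seed: int = 0,
                     inclusion_class: str = "tangles") -> HeatMap:
    """Simulated attention heatmap for one sampling box.

    Blob centres follow a homogeneous Poisson process with intensity
    ``model.blob_rate(severity)`` per mm^2; overlapping Gaussian bumps
    combine by maximum.
    """
    if not np.isfinite(severity) or severity < 0:
        raise ValueError("severity must be a finite non-negative real")
    h, w = box_shape_px
    if h <= 0 or w <= 0:
        raise ValueError("box_shape_px must be positive")
    if not (pixel_size_um > 0):
        raise ValueError("pixel_size_um must be positive")
    model = model or SeverityModel()
    rng = np.random.default_rng(seed)

    area_mm2 = h * w * pixel_size_um**2 / 1e6
    n_blobs = rng.poisson(model.blob_rate(severity) * area_mm2)
    values = np.zeros((h, w))
    sigma_px = model.blob_sigma_um / pixel_size_um
    reach = int(np.ceil(3 * sigma_px))
    for _ in range(n_blobs):
        cy, cx = rng.uniform(0, h), rng.uniform(0, w)
        y0, y1 = max(0, int(cy) - reach), min(h, int(cy) + reach + 1)
        x0, x1 = max(0, int(cx) - reach), min(w, int(cx) + reach + 1)
        yy, xx = np.mgrid[y0:y1, x0:x1]
        d2 = (yy - cy) ** 2 + (xx - cx) ** 2
        bump = model.blob_amplitude * np.exp(-d2 / (2 * sigma_px**2))
        bump[d2 > (3 * sigma_px) ** 2] = 0.0  # truncate at 3 sigma
        np.maximum(values[y0:y1, x0:x1], bump, out=values[y0:y1, x0:x1])
    if model.noise_sd > 0:
        values = values + rng.normal(0, model.noise_sd, size=values.shape)
    return HeatMap(values=np.clip(values, 0.0, 1.0),
                   pixel_size_um=pixel_size_um,
                   inclusion_class=inclusion_class)


def generate_ordinal_rating(severity: float,
                            model: SeverityModel = None) -> float:
    """Ordinal expert rating {0, 0.5, 1, 2, 3} from a latent severity.

    The rating is the count of ``rating_thresholds`` at or below the
    severity, mapped onto the rating scale; it is non-decreasing in severity.
    """
    model = model or SeverityModel()
    idx = int(np.searchsorted(model.rating_thresholds, severity, side="right"))
    return RATING_LEVELS[idx]


# ---------------------------------------------------------------------------
# cohorts


@dataclass
class EffectSpec:
    """Planted linear effect structure for one region's outcome.

    ``beta`` maps predictor columns to standardized effect sizes (effects on
    the z-scored outcome of the z-scored predictor; binary covariates enter
    as 0/1).  ``noise_sd`` is the residual sd on the standardized scale, or
    ``"auto"`` to set the total outcome variance to 1 so the planted betas
    are directly recoverable as standardized coefficients.
    """

    region: str
    beta: dict = dc_field(default_factory=dict)
    noise_sd: float | str = "auto"
    covariate_effects: dict = dc_field(default_factory=dict)

    def __post_init__(self) -> None:
        if self.noise_sd != "auto" and not (self.noise_sd >= 0):
            raise ValueError("noise_sd must be >= 0 or 'auto'")


#: Morphometry scale (mean, sd) per region: volumes in mm^3, thickness in mm.
REGION_SCALES = {
    "AH": (2300.0, 450.0), "PH": (1900.0, 400.0), "ERC": (2.6, 0.5),
    "BA35": (2.5, 0.45), "BA36": (2.7, 0.45), "PHC": (2.4, 0.4),
}

#: Whole-cohort standardized tangles effects for a realistic aging cohort
#: (strongest in ERC/PH); threads carry no independent effect and the
#: semi-quantitative pTDP-43 rating a weaker negative effect.
_DEFAULT_BETAS = {
    "AH": {"tangles_q": -0.30, "threads_q": 0.0, "mtl_ptdp_rating": -0.28},
    "PH": {"tangles_q": -0.44, "threads_q": 0.0, "mtl_ptdp_rating": -0.30},
    "ERC": {"tangles_q": -0.47, "threads_q": 0.0, "mtl_ptdp_rating": -0.26},
    "BA35": {"tangles_q": -0.31, "threads_q": 0.0, "mtl_ptdp_rating": -0.04},
    "BA36": {"tangles_q": -0.23, "threads_q": 0.0, "mtl_ptdp_rating": -0.16},
    "PHC": {"tangles_q": -0.27, "threads_q": 0.0, "mtl_ptdp_rating": -0.08},
}


def default_effects() -> list:
    """One EffectSpec per region with reference effect sizes and mild
    covariate confounding (age, and head size for the volume outcomes)."""
    effects = []
    for region, betas in _DEFAULT_BETAS.items():
        cov = {"age_at_death": -0.20, "sex": -0.10, "field_strength": 0.05,
               "antemortem_interval": -0.05}
        if region in ("AH", "PH"):
            cov["icv"] = 0.30
        effects.append(EffectSpec(region=region, beta=dict(betas),
                                  covariate_effects=cov))
    return effects


#: Braak-stage severity cutpoints: population quantiles of the latent tau
#: severity chosen so stage shares match the reference cohort (60.7% stage V/VI).
_BRAAK_CUM_PROBS = (0.03, 0.08, 0.15, 0.27, 0.393, 0.693)
_TAU_SHAPE, _TAU_SCALE = 2.0, 1.5
_BRAAK_CUTPOINTS = tuple(
    stats.gamma.ppf(p, _TAU_SHAPE, scale=_TAU_SCALE) for p in _BRAAK_CUM_PROBS)

#: Latent pTDP-43 severity is exponential with unit scale: the amygdala
#: rating crosses positivity (rating >= 1, severity >= 1.5) in
#: exp(-1.5) = 22.3% of subjects, matching the reference LATE-NC rate (31/140).
_TDP_SCALE = 1.0

#: Regional severity weights: amygdala is affected earliest, hippocampal
#: regions later, middle frontal gyrus last (drives LATE-NC staging); p-tau
#: spreads ERC -> CA1/subiculum -> dentate gyrus.
_TDP_WEIGHTS = {"amygdala": 1.0, "dg": 0.55, "ca1_sub": 0.60, "erc": 0.65,
                "mfg": 0.25}
_TAU_WEIGHTS = {"erc": 1.0, "ca1_sub": 0.9, "dg": 0.6}

COHORT_COLUMNS = [
    "subject_id", "age_at_death", "sex", "field_strength",
    "antemortem_interval", "icv", "latent_tau", "latent_tdp",
    "tangles_q", "threads_q", "neuronal_glial_q", "neuritic_q",
    "ptau_erc", "ptau_ca1_sub", "ptau_dg",
    "ptdp_amygdala", "ptdp_dg", "ptdp_ca1_sub", "ptdp_erc", "ptdp_mfg",
    "mtl_ptau_rating", "mtl_ptdp_rating", "neuronal_loss_rating",
    "braak_stage", "late_stage", "qc_ipsilateral",
    "vol_AH", "vol_PH", "thk_ERC", "thk_BA35", "thk_BA36", "thk_PHC",
]


def generate_cohort(n_subjects: int, effects: list = None, seed: int = 0,
                    severity_model: SeverityModel = None) -> pd.DataFrame:
    """Synthetic cohort table with planted pathology-to-morphometry effects.

    Covariates: age ~ N(75, 8) years, sex ~ Bernoulli(0.5), field strength
    ~ Bernoulli(0.7) for 3T, antemortem interval ~ U(0, 10) years, ICV ~
    N(1.4e6, 1.5e5) mm^3.  Latent tau and pTDP-43 severities drive the
    quantitative summary measures, the regional ordinal ratings (via the
    severity model's thresholds), and the Braak / LATE-NC stage labels.
    Each regional outcome is a linear combination of z-scored predictors per
    its :class:`EffectSpec` plus Gaussian noise, then mapped to natural units.

    ``n_subjects=0`` returns an empty table with the full schema.
    """
    if effects is None:
        effects = default_effects()
    model = severity_model or SeverityModel()
    rng = np.random.default_rng(seed)
    n = int(n_subjects)
    if n < 0:
        raise ValueError("n_subjects must be >= 0")
    if n == 0:
        return pd.DataFrame({c: pd.Series(dtype=float)
                             for c in COHORT_COLUMNS})

    d = pd.DataFrame({"subject_id": [f"S{i:04d}" for i in range(n)]})
    d["age_at_death"] = rng.normal(75.0, 8.0, n)
    d["sex"] = rng.binomial(1, 0.5, n)
    d["field_strength"] = rng.binomial(1, 0.7, n)  # 1 = 3T
    d["antemortem_interval"] = rng.uniform(0.0, 10.0, n)
    d["icv"] = rng.normal(1.4e6, 1.5e5, n)

    tau = rng.gamma(_TAU_SHAPE, _TAU_SCALE, n)
    tdp = rng.exponential(_TDP_SCALE, n)
    d["latent_tau"], d["latent_tdp"] = tau, tdp

    # quantitative summary measures: latent severity + measurement noise
    d["tangles_q"] = np.maximum(tau + rng.normal(0, 0.15, n), 0.0)
    d["threads_q"] = np.maximum(
        0.6 * tau + 0.8 * rng.gamma(2.0, 1.0, n), 0.0)
    d["neuronal_glial_q"] = np.maximum(tdp + rng.normal(0, 0.15, n), 0.0)
    d["neuritic_q"] = np.maximum(
        0.7 * tdp + 0.3 * rng.exponential(1.0, n), 0.0)

    # regional ordinal ratings via severity thresholds
    def rate(sev):
        return np.array([generate_ordinal_rating(s, model) for s in sev])

    for reg, w in _TAU_WEIGHTS.items():
        d[f"ptau_{reg}"] = rate(w * tau)
    for reg, w in _TDP_WEIGHTS.items():
        d[f"ptdp_{reg}"] = rate(w * tdp)

    d["mtl_ptau_rating"] = [
        mtl_average_rating(e, c, g) for e, c, g in
        zip(d["ptau_erc"], d["ptau_ca1_sub"], d["ptau_dg"])]
    d["mtl_ptdp_rating"] = [
        mtl_average_rating(e, c, g) for e, c, g in
        zip(d["ptdp_erc"], d["ptdp_ca1_sub"], d["ptdp_dg"])]
    d["neuronal_loss_rating"] = rate(0.5 * tau + 0.3 * tdp)

    d["braak_stage"] = np.searchsorted(_BRAAK_CUTPOINTS, tau, side="right")
    d["late_stage"] = [
        late_stage(a, g, c, e, m) for a, g, c, e, m in
        zip(d["ptdp_amygdala"], d["ptdp_dg"], d["ptdp_ca1_sub"],
            d["ptdp_erc"], d["ptdp_mfg"])]
    d["qc_ipsilateral"] = rng.binomial(1, 0.95, n).astype(bool)

    # planted regional outcomes
    for spec in effects:
        signal = np.zeros(n)
        for col, beta in {**spec.beta, **spec.covariate_effects}.items():
            x = d[col].to_numpy(dtype=float)
            if col not in ("sex", "field_strength"):
                sd = x.std(ddof=1)
                x = (x - x.mean()) / sd if sd > 0 else x * 0.0
            signal = signal + beta * x
        if spec.noise_sd == "auto":
            noise_sd = float(np.sqrt(max(0.05, 1.0 - signal.var(ddof=1))))
        else:
            noise_sd = float(spec.noise_sd)
            if noise_sd == 0:
                import warnings
                warnings.warn(f"{spec.region}: noise_sd=0 gives a degenerate "
                              "(noise-free) outcome", stacklevel=2)
        y_std = signal + rng.normal(0, noise_sd, n)
        mean, sd = REGION_SCALES[spec.region]
        col = ("vol_" if spec.region in ("AH", "PH") else "thk_") + spec.region
        d[col] = mean + sd * y_std

    for col in COHORT_COLUMNS:  # stable schema even with partial effects
        if col not in d.columns:
            d[col] = np.nan
    return d[COHORT_COLUMNS]


# ---------------------------------------------------------------------------
# surfaces


@dataclass
class MeshSpec:
    """Template-surface specification with a planted deficit cluster.

    A planar triangulated ``nx x ny`` grid (spacing in mm) carries a disc of
    vertices around ``cluster_center`` (fractional grid coordinates) of
    radius ``cluster_radius_mm``; inside it, thickness decreases by
    ``effect_mm_per_sd`` millimetres per standard deviation of the pathology
    predictor.  Per-vertex noise is Gaussian with sd ``noise_sd`` mm.
    """

    nx: int = 64
    ny: int = 64
    spacing_mm: float = 1.0
    cluster_center: tuple = (0.5, 0.5)
    cluster_radius_mm: float = 8.0
    effect_mm_per_sd: float = 0.0
    noise_sd: float = 0.25
    baseline_mm: float = 2.5

    def build(self):
        """Mesh arrays and the planted (edge-connected) cluster vertex ids."""
        vertices, triangles = make_grid_mesh(self.nx, self.ny,
                                             self.spacing_mm)
        cx = self.cluster_center[0] * (self.nx - 1) * self.spacing_mm
        cy = self.cluster_center[1] * (self.ny - 1) * self.spacing_mm
        dist = np.hypot(vertices[:, 0] - cx, vertices[:, 1] - cy)
        planted = np.flatnonzero(dist <= self.cluster_radius_mm)
        if self.effect_mm_per_sd != 0 and planted.size:
            adj = vertex_adjacency(len(vertices), triangles)
            from scipy.sparse.csgraph import connected_components
            ncomp, _ = connected_components(adj[planted][:, planted],
                                            directed=False)
            if ncomp > 1:
                raise ValueError("planted cluster is not edge-connected")
        return vertices, triangles, planted


def generate_surface_dataset(n_subjects: int, spec: MeshSpec,
                             pathology: np.ndarray, seed: int = 0):
    """Surface dataset with a planted contiguous thickness-deficit cluster.

    Per-vertex thickness is ``baseline - effect * z(pathology)`` inside the
    planted cluster plus Gaussian noise everywhere.  The design matrix is
    [intercept, z(pathology), z(age)] with age an independent nuisance
    covariate; the contrast is the pathology column with negative direction.

    Returns
    -------
    (SurfaceDataset, planted_vertex_ids)
    """
    pathology = np.asarray(pathology, dtype=float)
    if len(pathology) != n_subjects:
        raise ValueError("pathology length must equal n_subjects")
    rng = np.random.default_rng(seed)
    vertices, triangles, planted = spec.build()

    z = (pathology - pathology.mean()) / pathology.std(ddof=1)
    age = rng.normal(75.0, 8.0, n_subjects)
    z_age = (age - age.mean()) / age.std(ddof=1)

    thickness = np.full((n_subjects, len(vertices)), spec.baseline_mm)
    if planted.size:
        thickness[:, planted] -= spec.effect_mm_per_sd * z[:, None]
    thickness += rng.normal(0, spec.noise_sd,
                            size=(n_subjects, len(vertices)))

    design = np.column_stack([np.ones(n_subjects), z, z_age])
    data = SurfaceDataset(vertices=vertices, triangles=triangles,
                          thickness=thickness, design=design,
                          design_names=["const", "pathology", "age"],
                          contrast="pathology", direction=-1)
    return data, planted


# ---------------------------------------------------------------------------
# validation boxes for the summary-statistic selection experiment


def generate_validation_boxes(n_per_rating: int = 16, seed: int = 0,
                              n_segments: int = 100,
                              inclusion_classes=("tangles", "threads"),
                              signal_per_rating: float = 0.18,
                              n_signal_segments: int = 3):
    """Expert-rated boxes where only the extreme activation tail tracks
    severity.

    Each box carries ``n_segments`` segment averages: half-normal background
    noise on a random per-box baseline, ``n_signal_segments`` segments whose
    activation grows with the expert rating, and one spurious rating-
    independent spike.  The baseline defeats mean/median-type statistics, the
    sparse signal defeats mid quantiles, and the spike corrupts the maximum,
    so upper-tail quantiles (q99) discriminate ratings best.

    Returns
    -------
    segment_values : dict  ``(box_id, inclusion_class) -> ndarray``
    ratings : DataFrame with columns box_id, inclusion_class, rating
    """
    rng = np.random.default_rng(seed)
    segment_values, rows = {}, []
    for cls in inclusion_classes:
        box_no = 0
        for rating in (0.0, 1.0, 2.0, 3.0):
            for _ in range(n_per_rating):
                box_id = f"{cls}_box{box_no:03d}"
                box_no += 1
                baseline = rng.uniform(0.0, 0.10)
                vals = baseline + np.abs(rng.normal(0, 0.05, n_segments))
                sig = rng.choice(n_segments, n_signal_segments, replace=False)
                vals[sig] = (baseline + signal_per_rating * rating
                             + np.abs(rng.normal(0, 0.02, n_signal_segments)))
                spike = rng.integers(n_segments)
                vals[spike] = baseline + rng.uniform(0.5, 0.9)
                segment_values[(box_id, cls)] = np.clip(vals, 0.0, 1.0)
                rows.append({"box_id": box_id, "inclusion_class": cls,
                             "rating": rating})
    return segment_values, pd.DataFrame(rows)
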