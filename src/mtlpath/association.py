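"""ROI-level linear models of antemortem morphometry on pathology burden.

For each MTL subregion, ordinary least squares relates the regional
morphometric measure (anterior/posterior hippocampal volume, or median
cortical thickness of ERC/BA35/BA36/PHC) to pathology predictors plus
nuisance covariates (age at death, sex, MRI field strength, antemortem
interval, and intracranial volume for the volume outcomes).  The outcome and
all continuous predictors are z-scored, so pathology coefficients are
standardized betas; inference on the pathology contrasts is one-sided for
negative associations (pathology is expected to reduce volume/thickness).

Quantitative and semi-quantitative pathology models fitted to the same
subjects are compared by adjusted R^2, L1 prediction error, AICc and BIC,
with BIC differences of 2/6/10 read as positive/strong/very strong evidence.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
import statsmodels.api as sm
from scipy import stats

__all__ = [
    "REGIONS",
    "VOLUME_REGIONS",
    "NUISANCE_COVARIATES",
    "RegionAssociationModel",
    "RegionModelResults",
    "ComparisonResult",
    "bonferroni_threshold",
    "prediction_error_l1",
    "information_criteria",
    "compare_models",
    "run_cohort_analyses",
]

#: MTL subregions analysed, and which use volume (with ICV covariate).
REGIONS = ("AH", "PH", "ERC", "BA35", "BA36", "PHC")
VOLUME_REGIONS = frozenset({"AH", "PH"})

#: Outcome column per region in a cohort table.
OUTCOME_COLUMNS = {
    "AH": "vol_AH", "PH": "vol_PH", "ERC": "thk_ERC",
    "BA35": "thk_BA35", "BA36": "thk_BA36", "PHC": "thk_PHC",
}

NUISANCE_COVARIATES = ("age_at_death", "sex", "field_strength",
                       "antemortem_interval")

#: Covariates entered as 0/1 indicators, not z-scored.
BINARY_COVARIATES = frozenset({"sex", "field_strength"})

_T_CAP = 1e8  # cap for t statistics of numerically perfect fits


def bonferroni_threshold(alpha: float, m: int) -> float:
    """Per-test significance threshold controlling FWER over m tests."""
    if not (0 < alpha < 1):
        raise ValueError("alpha must be in (0, 1)")
    if m < 1:
        raise ValueError("m must be >= 1")
    return alpha / m


def information_criteria(rss, n: int | None = None,
                         n_coefficients: int | None = None):
    """AICc and BIC of a fitted model, or from (rss, n, n_coefficients).

    Uses ``AIC = n ln(RSS/n) + 2k`` and ``BIC = n ln(RSS/n) + k ln(n)`` with
    ``k = n_coefficients + 1`` (the error variance counts as a parameter);
    the small-sample correction is ``AICc = AIC + 2k(k+1)/(n-k-1)``.
    Constant likelihood terms are omitted: only differences between models
    fitted to identical data are interpreted, and those are offset-free.
    """
    if n is None:  # a fitted RegionModelResults
        fit = rss
        rss = float(fit.resid @ fit.resid)
        n, n_coefficients = fit.n, len(fit.predictor_names)
    k = n_coefficients + 1
    if n <= k + 1:
        raise ValueError(f"AICc undefined: n={n} <= k+1={k + 1}")
    base = n * np.log(rss / n) if rss > 0 else -np.inf
    aic = base + 2 * k
    aicc = aic + 2 * k * (k + 1) / (n - k - 1)
    bic = base + k * np.log(n)
    return float(aicc), float(bic)


class RegionAssociationModel:
    """OLS model of one region's morphometry on pathology + covariates.

    Parameters
    ----------
    data : DataFrame
        Cohort table with outcome, pathology and covariate columns.
        Listwise deletion is applied over the columns used.
    region : str
        One of :data:`REGIONS`; selects the outcome column and whether ICV is
        added as a covariate (volume regions only).
    pathology_predictors : sequence of str
        Pathology columns of interest (z-scored; one-sided inference).
    covariates : sequence of str, optional
        Nuisance covariates; defaults to age, sex, field strength and
        antemortem interval, plus ``icv`` for AH/PH.
    one_sided : {"negative", "positive"}
        Direction of the one-sided pathology tests.
    """

    def __init__(self, data: pd.DataFrame, region: str,
                 pathology_predictors, covariates=None,
                 one_sided: str = "negative"):
        if region not in REGIONS:
            raise ValueError(f"unknown region {region!r}")
        if one_sided not in ("negative", "positive"):
            raise ValueError("one_sided must be 'negative' or 'positive'")
        self.region = region
        self.pathology_predictors = list(pathology_predictors)
        if covariates is None:
            covariates = list(NUISANCE_COVARIATES)
            if region in VOLUME_REGIONS:
                covariates.append("icv")
        self.covariates = list(covariates)
        self.one_sided = one_sided

        outcome = OUTCOME_COLUMNS[region]
        cols = [outcome, *self.pathology_predictors, *self.covariates]
        missing = [c for c in cols if c not in data.columns]
        if missing:
            raise ValueError(f"missing columns: {missing}")
        frame = data[cols].dropna()
        n_params = len(cols) + 1  # + intercept
        if len(frame) < n_params + 1:
            raise ValueError(
                f"only {len(frame)} complete cases for {n_params} parameters")
        self.data = frame
        self.subjects = frame.index

        def zscore(v):
            s = v.std(ddof=1)
            if s == 0:
                raise ValueError(f"zero variance in {v.name!r}")
            return (v - v.mean()) / s

        self.endog = zscore(frame[outcome]).to_numpy()
        design = {"const": np.ones(len(frame))}
        for c in self.pathology_predictors + self.covariates:
            col = frame[c]
            design[c] = (col.to_numpy(dtype=float)
                         if c in BINARY_COVARIATES else zscore(col).to_numpy())
        self.exog = pd.DataFrame(design, index=frame.index)
        rank = np.linalg.matrix_rank(self.exog.to_numpy())
        if rank < self.exog.shape[1]:
            bad = _collinear_columns(self.exog)
            raise ValueError(f"rank-deficient design; collinear columns: {bad}")

    def fit(self) -> "RegionModelResults":
        res = sm.OLS(self.endog, self.exog).fit()
        t = np.clip(res.tvalues, -_T_CAP, _T_CAP)
        df = int(res.df_resid)
        if self.one_sided == "negative":
            p_one = stats.t.cdf(t, df)
        else:
            p_one = stats.t.sf(t, df)
        return RegionModelResults(
            region=self.region,
            predictor_names=list(self.exog.columns),
            pathology_predictors=self.pathology_predictors,
            params=res.params,
            tvalues=pd.Series(t, index=self.exog.columns),
            pvalues_one_sided=pd.Series(p_one, index=self.exog.columns),
            df_resid=df,
            n=int(res.nobs),
            rsquared_adj=float(res.rsquared_adj),
            resid=np.asarray(res.resid),
            model=self,
        )


def _collinear_columns(exog: pd.DataFrame) -> list[str]:
    cols = []
    X = exog.to_numpy()
    base_rank = np.linalg.matrix_rank(X)
    for j, name in enumerate(exog.columns):
        reduced = np.delete(X, j, axis=1)
        if np.linalg.matrix_rank(reduced) == base_rank:
            cols.append(name)
    return cols


@dataclass
class RegionModelResults:
    """Fitted region model: standardized betas, one-sided inference and
    information criteria."""

    region: str
    predictor_names: list
    pathology_predictors: list
    params: pd.Series
    tvalues: pd.Series
    pvalues_one_sided: pd.Series
    df_resid: int
    n: int
    rsquared_adj: float
    resid: np.ndarray
    model: RegionAssociationModel = field(repr=False)
    aicc: float = field(init=False)
    bic: float = field(init=False)

    def __post_init__(self) -> None:
        rss = float(self.resid @ self.resid)
        self.aicc, self.bic = information_criteria(
            rss, self.n, len(self.predictor_names))

    @property
    def coefficients(self) -> pd.Series:
        """Standardized betas for the pathology predictors."""
        return self.params[self.pathology_predictors]

    def compare(self, other: "RegionModelResults") -> "ComparisonResult":
        return compare_models(self, other)

    def summary(self) -> str:
        lines = [
            f"Region model: {self.region} "
            f"(n={self.n}, df_resid={self.df_resid})",
            f"adj R2 = {self.rsquared_adj:.3f}   "
            f"AICc = {self.aicc:.2f}   BIC = {self.bic:.2f}",
            f"{'predictor':<22}{'beta':>9}{'t':>9}{'p(1-sided)':>12}",
        ]
        for name in self.predictor_names:
            tag = " *" if name in self.pathology_predictors else ""
            lines.append(
                f"{name:<22}{self.params[name]:>9.3f}"
                f"{self.tvalues[name]:>9.2f}"
                f"{self.pvalues_one_sided[name]:>12.3g}{tag}")
        lines.append("* pathology contrast (one-sided "
                     f"{self.model.one_sided} test)")
        return "\n".join(lines)


def prediction_error_l1(fit: RegionModelResults) -> float:
    """Sum of absolute residuals (L1 norm) of a fitted model."""
    return float(np.abs(fit.resid).sum())


#: BIC-difference evidence thresholds.
_EVIDENCE = ((10.0, "very_strong"), (6.0, "strong"), (2.0, "positive"))


@dataclass
class ComparisonResult:
    """Quantitative-vs-semi-quantitative model comparison for one region.

    Deltas are quantitative minus semi-quantitative, so a negative difference
    in prediction error, AICc and BIC (and a positive difference in adjusted
    R^2) favors the quantitative model.
    """

    region: str
    delta_r2_adj: float
    delta_pred_error: float
    delta_aicc: float
    delta_bic: float
    evidence_label: str = field(init=False)
    favors: str = field(init=False)

    def __post_init__(self) -> None:
        self.evidence_label = "none"
        for cut, label in _EVIDENCE:
            if abs(self.delta_bic) > cut:
                self.evidence_label = label
                break
        self.favors = ("quantitative" if self.delta_bic < 0
                       else "semiquantitative" if self.delta_bic > 0
                       else "neither")


def compare_models(fit_quant: RegionModelResults,
                   fit_semiquant: RegionModelResults) -> ComparisonResult:
    """Compare a quantitative-pathology model against the semi-quantitative
    model fitted to the same outcome and subjects."""
    if fit_quant.region != fit_semiquant.region:
        raise ValueError("models fit different regions")
    if not fit_quant.model.subjects.equals(fit_semiquant.model.subjects):
        raise ValueError("models fit different subject sets")
    return ComparisonResult(
        region=fit_quant.region,
        delta_r2_adj=fit_quant.rsquared_adj - fit_semiquant.rsquared_adj,
        delta_pred_error=(prediction_error_l1(fit_quant)
                          - prediction_error_l1(fit_semiquant)),
        delta_aicc=fit_quant.aicc - fit_semiquant.aicc,
        delta_bic=fit_quant.bic - fit_semiquant.bic,
    )


SUBGROUPS = ("whole", "advanced_adnc", "late")


def _subgroup_mask(data: pd.DataFrame, subgroup: str) -> pd.Series:
    if subgroup == "whole":
        return pd.Series(True, index=data.index)
    if subgroup == "advanced_adnc":
        return data["braak_stage"] >= 5
    if subgroup == "late":
        return data["late_stage"] >= 1
    raise ValueError(f"unknown subgroup {subgroup!r}")


def run_cohort_analyses(data: pd.DataFrame, subgroup: str = "whole",
                        pathology_predictors=("tangles_q", "threads_q",
                                              "mtl_ptdp_rating"),
                        alpha: float = 0.05,
                        n_regions: int = len(REGIONS)) -> pd.DataFrame:
    """Fit all six region models within a cohort subgroup.

    Subgroups: ``whole`` (all subjects), ``advanced_adnc`` (Braak stage V or
    VI), ``late`` (LATE-NC stage 1 or greater).  Each pathology contrast is
    flagged at uncorrected p < alpha and at the Bonferroni threshold
    alpha / n_regions separately.

    Returns a tidy table (region x pathology predictor) of standardized beta,
    t, one-sided p, df, n and significance flags.  Regions whose complete-case
    count is too small for the design are skipped with a warning.
    """
    mask = _subgroup_mask(data, subgroup)
    sub = data[mask]
    bonf = bonferroni_threshold(alpha, n_regions)
    rows = []
    for region in REGIONS:
        try:
            fit = RegionAssociationModel(
                sub, region, pathology_predictors).fit()
        except ValueError as err:
            warnings.warn(f"{subgroup}/{region}: {err}; skipped", stacklevel=2)
            continue
        for pred in pathology_predictors:
            p = float(fit.pvalues_one_sided[pred])
            rows.append({
                "subgroup": subgroup, "region": region, "predictor": pred,
                "beta": float(fit.params[pred]),
                "t": float(fit.tvalues[pred]),
                "p_one_sided": p, "df_resid": fit.df_resid, "n": fit.n,
                "sig_uncorrected": p < alpha, "sig_bonferroni": p < bonf,
            })
    return pd.DataFrame(rows)
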