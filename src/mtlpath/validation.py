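"""Validation of quantitative burden measures against ordinal expert ratings.

The central statistic is the Mann-Whitney AUC between adjacent ordinal
categories: the probability (with ties counted half) that a measurement from
the higher category exceeds one from the lower category.  One-sided tests ask
whether the upper category is stochastically greater.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats

from .heatmap import SUMMARY_STATISTICS, box_summary

__all__ = [
    "AdjacentComparison",
    "adjacent_auc",
    "stagewise_auc",
    "spearman_assoc",
    "statistic_selection",
]

#: Above this product of group sizes the Mann-Whitney p-value switches from
#: exact enumeration to the tie-corrected normal approximation.
EXACT_PAIR_LIMIT = 100


@dataclass
class AdjacentComparison:
    """Mann-Whitney comparison of one adjacent ordinal-category pair."""

    lower_group: np.ndarray
    upper_group: np.ndarray
    auc: float
    u_statistic: float
    p_one_sided: float

    @property
    def n_lower(self) -> int:
        return len(self.lower_group)

    @property
    def n_upper(self) -> int:
        return len(self.upper_group)


def adjacent_auc(lower, upper) -> AdjacentComparison:
    """AUC and one-sided Mann-Whitney test of upper vs lower category values.

    AUC = (wins + 0.5 * ties) / (n_lower * n_upper), counting pairs where the
    upper-category value exceeds the lower-category value.  The one-sided p
    tests the alternative "upper stochastically greater": exact when
    ``n_lower * n_upper <=`` :data:`EXACT_PAIR_LIMIT` and the data are
    tie-free, tie-corrected normal approximation otherwise.
    """
    lo = np.asarray(lower, dtype=float)
    up = np.asarray(upper, dtype=float)
    if lo.size == 0 or up.size == 0:
        raise ValueError("both rating groups must be non-empty")
    diff = up[:, None] - lo[None, :]
    u = float(np.sum(diff > 0) + 0.5 * np.sum(diff == 0))
    auc = u / (lo.size * up.size)

    pooled = np.concatenate([lo, up])
    has_ties = np.unique(pooled).size < pooled.size
    method = ("exact" if lo.size * up.size <= EXACT_PAIR_LIMIT and not has_ties
              else "asymptotic")
    p = stats.mannwhitneyu(up, lo, alternative="greater", method=method).pvalue
    return AdjacentComparison(lo, up, auc, u, float(p))


def stagewise_auc(values, stages) -> pd.DataFrame:
    """Adjacent-stage Mann-Whitney comparisons of a measure across an ordinal
    staging system (e.g. Braak for p-tau, LATE-NC for pTDP-43).

    Subjects are grouped by stage; one comparison is produced per adjacent
    pair of occupied stages.  Missing values are dropped pairwise; a constant
    stage vector yields an empty table.
    """
    values = np.asarray(values, dtype=float)
    stages = np.asarray(stages)
    ok = ~np.isnan(values)
    values, stages = values[ok], stages[ok]
    occupied = np.unique(stages)
    rows = []
    for lo_stage, up_stage in zip(occupied[:-1], occupied[1:]):
        lo = values[stages == lo_stage]
        up = values[stages == up_stage]
        cmp = adjacent_auc(lo, up)
        rows.append({
            "lower_stage": lo_stage, "upper_stage": up_stage,
            "n_lower": cmp.n_lower, "n_upper": cmp.n_upper,
            "auc": cmp.auc, "u_statistic": cmp.u_statistic,
            "p_one_sided": cmp.p_one_sided,
        })
    return pd.DataFrame(
        rows, columns=["lower_stage", "upper_stage", "n_lower", "n_upper",
                       "auc", "u_statistic", "p_one_sided"])


def spearman_assoc(x, y) -> tuple[float, float]:
    """Spearman rank correlation (midranks for ties) with two-sided p."""
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    ok = ~(np.isnan(x) | np.isnan(y))
    if ok.sum() < 3:
        raise ValueError("need at least 3 complete pairs")
    if np.unique(x[ok]).size < 2 or np.unique(y[ok]).size < 2:
        warnings.warn("zero rank variance: Spearman correlation undefined",
                      stacklevel=2)
        return float("nan"), float("nan")
    rho, p = stats.spearmanr(x[ok], y[ok])
    return float(rho), float(p)


def statistic_selection(
    segment_values: dict,
    ratings: pd.DataFrame,
    candidates=SUMMARY_STATISTICS,
) -> pd.DataFrame:
    """Rank candidate summary statistics by agreement with expert box ratings.

    For each candidate, box-level summaries are computed from the per-box
    segment averages, grouped by the expert rating (0-3 scale), and all
    adjacent-category AUCs are computed within each inclusion class.
    Candidates are ranked by mean AUC across category pairs and classes, with
    the minimum AUC reported as a tiebreaker.

    Parameters
    ----------
    segment_values : dict
        ``(box_id, inclusion_class) -> 1D array`` of segment averages.
    ratings : DataFrame
        Columns ``box_id``, ``inclusion_class``, ``rating``.

    Returns
    -------
    DataFrame with columns ``statistic``, ``mean_auc``, ``min_auc``,
    ``n_pairs``, ``rank``, sorted best-first.  A warning is raised if the
    ranking is unstable (all candidates within 0.02 mean AUC).
    """
    rows = []
    for cand in candidates:
        aucs = []
        for cls, grp in ratings.groupby("inclusion_class"):
            summaries = np.array([
                box_summary(segment_values[(b, cls)], cand)
                for b in grp["box_id"]
            ])
            tab = stagewise_auc(summaries, grp["rating"].to_numpy())
            aucs.extend(tab["auc"].tolist())
        if not aucs:
            raise ValueError("no adjacent rating categories to compare")
        rows.append({"statistic": cand, "mean_auc": float(np.mean(aucs)),
                     "min_auc": float(np.min(aucs)), "n_pairs": len(aucs)})
    out = pd.DataFrame(rows).sort_values(
        ["mean_auc", "min_auc"], ascending=False, kind="stable")
    out["rank"] = np.arange(1, len(out) + 1)
    if out["mean_auc"].max() < 0.6:
        warnings.warn("summary-statistic ranking is unstable: no candidate "
                      "discriminates ratings much better than chance",
                      stacklevel=2)
    return out.reset_index(drop=True)
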