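"""Subject-level pathology summaries: ROI pooling, hippocampal summary scores,
0-3 recalibration, MTL average ratings and LATE-NC staging.

Semi-quantitative ratings use the ordinal scale absent (0), rare (0.5),
mild (1), moderate (2), severe (3).  LATE-NC stages 0-3 follow the regional
spread of pTDP-43: amygdala (stage 1), hippocampus/entorhinal cortex
(stage 2), middle frontal gyrus (stage 3), with positivity defined as a
rating of 1 (mild) or greater.
"""

from __future__ import annotations

import math
import warnings
from typing import Mapping, Sequence

import numpy as np
from scipy import stats

from .heatmap import box_summary

__all__ = [
    "RATING_LEVELS",
    "HIPPOCAMPAL_ROIS",
    "pool_roi_measure",
    "hippocampal_summary",
    "rescale_summary",
    "mtl_average_rating",
    "late_stage",
]

#: Allowed semi-quantitative rating values.
RATING_LEVELS = (0.0, 0.5, 1.0, 2.0, 3.0)

#: Hippocampal ROIs eligible for the subject-level summary measure.
HIPPOCAMPAL_ROIS = ("CA1", "CA2", "CA3", "DG-GCL", "DG-H", "CA1-SUB", "SUB-PrS")

#: Rating at or above which a region counts as positive for LATE-NC staging.
LATE_POSITIVITY = 1.0


def _is_missing(x) -> bool:
    return x is None or (isinstance(x, float) and math.isnan(x))


def _check_rating(x, name: str) -> float:
    if float(x) not in RATING_LEVELS:
        raise ValueError(f"{name} rating {x!r} not in {RATING_LEVELS}")
    return float(x)


def pool_roi_measure(segment_values_by_box: Sequence[np.ndarray],
                     statistic: str = "q99") -> float:
    """Summary statistic over segment averages pooled across sampling boxes.

    Anatomical ROIs are usually sampled by several boxes; the statistic is
    applied to the concatenation of all their segment averages.  Returns NaN
    (missing) if no segment values are available.
    """
    vecs = [np.asarray(v, dtype=float) for v in segment_values_by_box]
    if not vecs or all(v.size == 0 for v in vecs):
        return float("nan")
    return box_summary(np.concatenate([v for v in vecs if v.size]), statistic)


def hippocampal_summary(roi_measures: Mapping[str, float],
                        inclusion_class: str = "tangles") -> float:
    """Average ROI-level burden over the seven hippocampal subregions.

    Rules:

    * Only the labels in :data:`HIPPOCAMPAL_ROIS` are eligible.
    * For the ``threads`` class, the dentate-gyrus hilus (DG-H) measure is
      excluded before averaging (mossy fibres are misclassified as threads).
    * The summary is missing (NaN) if fewer than three anatomical regions are
      available, where the two dentate-gyrus subregions (DG-GCL, DG-H)
      jointly count as a single region; when eligible, both their measures
      still enter the average separately.

    The region count is taken after the threads DG-H exclusion.
    """
    available = {
        lab: float(v) for lab, v in roi_measures.items()
        if lab in HIPPOCAMPAL_ROIS and not _is_missing(v)
    }
    unknown = set(roi_measures) - set(HIPPOCAMPAL_ROIS)
    if unknown:
        raise ValueError(f"labels not eligible for the hippocampal summary: "
                         f"{sorted(unknown)}")
    if inclusion_class == "threads":
        available.pop("DG-H", None)
    if not available:
        return float("nan")
    n_regions = len(available)
    if "DG-GCL" in available and "DG-H" in available:
        n_regions -= 1  # the two DG subregions count as one region
    if n_regions < 3:
        return float("nan")
    # canonical summation order: exact invariance to input ordering
    ordered = [available[lab] for lab in HIPPOCAMPAL_ROIS if lab in available]
    return float(np.mean(ordered))


def rescale_summary(raw: np.ndarray, semiquant: np.ndarray):
    """Linearly recalibrate raw quantitative summaries to the 0-3 rating scale.

    Ordinary least squares of the matching semi-quantitative MTL ratings on
    the raw summaries gives an intercept and slope; the raw values are mapped
    through the fitted line.  The transform is monotone for positive slope and
    leaves every correlation/association with other variables unchanged; it
    only makes the scale interpretable.

    Returns
    -------
    transformed : ndarray (NaNs propagate)
    intercept, slope : float
    """
    raw = np.asarray(raw, dtype=float)
    sq = np.asarray(semiquant, dtype=float)
    ok = ~(np.isnan(raw) | np.isnan(sq))
    if ok.sum() < 3:
        raise ValueError("need at least 3 complete (raw, rating) pairs")
    if np.var(raw[ok]) == 0:
        raise ValueError("raw summaries have zero variance; cannot rescale")
    res = stats.linregress(raw[ok], sq[ok])
    if res.slope < 0:
        warnings.warn("negative rescaling slope: quantitative summaries "
                      "decrease with expert ratings", stacklevel=2)
    return res.intercept + res.slope * raw, float(res.intercept), float(res.slope)


def mtl_average_rating(erc, ca1_sub, dg) -> float:
    """Average semi-quantitative rating over the three MTL regions
    (entorhinal cortex, CA1/subiculum, dentate gyrus).

    Used both for pathology ratings and for neuronal-loss ratings.  Any
    missing component makes the average missing: the measure is defined as
    the mean of exactly these three regions.
    """
    vals = (erc, ca1_sub, dg)
    if any(_is_missing(v) for v in vals):
        return float("nan")
    return float(np.mean([_check_rating(v, n)
                          for v, n in zip(vals, ("erc", "ca1_sub", "dg"))]))


def late_stage(amygdala, dg, ca1_sub, erc, mfg, with_flag: bool = False):
    """LATE-NC stage (0-3) from regional pTDP-43 ratings.

    Stage criteria (positivity = rating >= 1):

    * stage 1 — amygdala positive;
    * stage 2 — any of dentate gyrus, CA1/subiculum, entorhinal cortex
      positive;
    * stage 3 — middle frontal gyrus positive.

    The stage is the highest k whose criterion and all lower-stage criteria
    are met (hierarchical).  Non-contiguous positivity (e.g. hippocampus
    positive with a negative amygdala) cannot raise the stage; such cases are
    flagged when ``with_flag=True``.
    """
    if _is_missing(amygdala):
        warnings.warn("missing amygdala rating: LATE-NC stage indeterminate",
                      stacklevel=2)
        return (None, True) if with_flag else None
    amygdala = _check_rating(amygdala, "amygdala")
    hippo = [r for r in (dg, ca1_sub, erc) if not _is_missing(r)]
    s1 = amygdala >= LATE_POSITIVITY
    s2 = any(_check_rating(r, "hippocampal") >= LATE_POSITIVITY for r in hippo)
    s3 = (not _is_missing(mfg)) and _check_rating(mfg, "mfg") >= LATE_POSITIVITY

    if s1 and s2 and s3:
        stage = 3
    elif s1 and s2:
        stage = 2
    elif s1:
        stage = 1
    else:
        stage = 0
    noncontiguous = (not s1 and (s2 or s3)) or (s1 and s3 and not s2)
    return (stage, noncontiguous) if with_flag else stage
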