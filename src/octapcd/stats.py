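"""Cohort-level statistics: clustered group contrasts, method agreement, ROC.

The study design measures up to two eyes per subject, so eye-level values are
correlated within subject.  Group comparisons therefore use a linear mixed
model with a per-subject random intercept (Wald z inference on the group
contrast) with Bonferroni adjustment over the pairwise contrasts.  Method
agreement between the commercial-style total vascular density and the custom
capillary density is summarised with Bland–Altman bias and 95% limits of
agreement; diagnostic accuracy with the empirical (Mann–Whitney) AUC and a
DeLong confidence interval.  Eye-level ROC ignores intra-subject clustering,
as is conventional in this literature; results say so in their metadata.
"""

from __future__ import annotations

import logging
import math
import warnings
from dataclasses import dataclass, field
from typing import Dict, List, Optional, Sequence, Tuple

import numpy as np
import pandas as pd
import statsmodels.formula.api as smf
from scipy import stats as sps
from sklearn.metrics import roc_auc_score

from .errors import UndefinedStatisticError, ValidationError

logger = logging.getLogger(__name__)


def format_p(p: float) -> str:
    """Display convention for p-values: '<0.001' and '>0.99' at the extremes."""
    if p < 0.001:
        return "<0.001"
    if p > 0.99:
        return ">0.99"
    return f"{p:.2f}" if p >= 0.01 else f"{p:.3f}"


# --------------------------------------------------------------------------
# clustered group comparison
# --------------------------------------------------------------------------

@dataclass
class PairwiseContrast:
    group_a: str
    group_b: str
    estimate: float  # mean(group_a) - mean(group_b)
    se: float
    z: float
    p_raw: float
    p_adjusted: float
    p_display: str
    method: str  # "mixed" or "ols"


@dataclass
class GroupComparisonResult:
    metric: str
    contrasts: List[PairwiseContrast]
    adjustment: str
    n_pairs: int
    notes: List[str] = field(default_factory=list)

    def contrast(self, group_a: str, group_b: str) -> PairwiseContrast:
        for c in self.contrasts:
            if {c.group_a, c.group_b} == {group_a, group_b}:
                return c
        raise KeyError(f"no contrast for {group_a} vs {group_b}")


def _pair_contrast(data: pd.DataFrame, a: str, b: str) -> Tuple[float, float, float, str]:
    """Estimate mean(a) - mean(b), its SE and reference df on a two-group subset.

    Uses a random-intercept mixed model when any subject contributes two
    eyes; with one eye per subject everywhere the model is singular and the
    contrast degrades to an ordinary least-squares comparison (logged).
    The Wald statistic is referred to a t distribution on the
    between-subject degrees of freedom (#subjects - 2), the standard
    two-level approximation for a between-subject contrast.
    """
    data = data.copy()
    data["is_a"] = (data["group"] == a).astype(float)
    singular = data.groupby("subject_id").size().max() == 1
    if not singular:
        try:
            with warnings.catch_warnings():
                warnings.simplefilter("ignore")
                model = smf.mixedlm("value ~ is_a", data, groups=data["subject_id"])
                fit = model.fit(reml=True)
            df = float(data["subject_id"].nunique() - 2)
            return float(fit.params["is_a"]), float(fit.bse["is_a"]), df, "mixed"
        except Exception as exc:  # singular/non-converging fit
            logger.info("mixed model failed (%s); using ordinary contrast", exc)
    else:
        logger.info("one eye per subject everywhere; using ordinary contrast")
    fit = smf.ols("value ~ is_a", data).fit()
    return float(fit.params["is_a"]), float(fit.bse["is_a"]), float(fit.df_resid), "ols"


def compare_groups(
    table: pd.DataFrame,
    metric: str,
    adjustment: str = "bonferroni",
) -> GroupComparisonResult:
    """Pairwise group contrasts of one metric with intereye clustering.

    Fits ``value ~ group`` with a per-subject random intercept on each pair
    of groups, tests the contrast with a Wald statistic on between-subject
    degrees of freedom, and Bonferroni-adjusts across the number of pairwise
    contrasts.
    """
    data = table[table["metric"] == metric].copy()
    if data.empty:
        raise ValidationError(f"metric {metric!r} absent from table")
    groups = sorted(data["group"].unique())
    if len(groups) < 2:
        raise ValidationError("at least two groups are required for comparison")
    sizes = data.groupby("group")["subject_id"].nunique()
    if (sizes < 2).any():
        raise ValidationError("every group needs at least two subjects")

    pairs = [(a, b) for i, a in enumerate(groups) for b in groups[i + 1 :]]
    n_pairs = len(pairs)
    contrasts = []
    notes = []
    for a, b in pairs:
        sub = data[data["group"].isin([a, b])]
        est, se, df, method = _pair_contrast(sub, a, b)
        if method == "ols":
            notes.append(f"{a} vs {b}: ordinary contrast (singular clustering)")
        z = est / se
        p_raw = 2.0 * sps.t.sf(abs(z), df)
        p_adj = min(1.0, p_raw * n_pairs) if adjustment == "bonferroni" else p_raw
        contrasts.append(
            PairwiseContrast(
                group_a=a,
                group_b=b,
                estimate=est,
                se=se,
                z=z,
                p_raw=p_raw,
                p_adjusted=p_adj,
                p_display=format_p(p_adj),
                method=method,
            )
        )
    return GroupComparisonResult(
        metric=metric,
        contrasts=contrasts,
        adjustment=adjustment,
        n_pairs=n_pairs,
        notes=notes,
    )


# --------------------------------------------------------------------------
# Bland–Altman agreement
# --------------------------------------------------------------------------

@dataclass
class BlandAltmanResult:
    """Agreement of two paired measurements; difference = second - first.

    ``(loa_low + loa_high) / 2 == bias`` exactly by construction.
    """

    n: int
    bias: float
    sd_diff: float
    loa_low: float
    loa_high: float
    loa_low_ci: Tuple[float, float]
    loa_high_ci: Tuple[float, float]
    bias_ci: Tuple[float, float]
    bias_p: float
    r_bias_vs_magnitude: float
    r_p: float
    direction: str = "second - first"

    def to_dict(self) -> Dict:
        return {
            "n": self.n,
            "bias": self.bias,
            "sd_diff": self.sd_diff,
            "loa_low": self.loa_low,
            "loa_high": self.loa_high,
            "loa_low_ci": list(self.loa_low_ci),
            "loa_high_ci": list(self.loa_high_ci),
            "bias_ci": list(self.bias_ci),
            "bias_p": self.bias_p,
            "r_bias_vs_magnitude": self.r_bias_vs_magnitude,
            "r_p": self.r_p,
            "direction": self.direction,
        }


def bland_altman(
    custom: Sequence[float],
    commercial: Sequence[float],
) -> BlandAltmanResult:
    """Bland–Altman agreement between custom capillary and commercial-style
    densities, per eye.

    Difference = commercial - custom, so the reported bias is positive when
    the total-vasculature measurement exceeds the capillary-only one (it
    always does once large vessels are removed from the numerator only).
    Limits of agreement are bias +- 1.96 SD with CIs via the standard
    ``sqrt(3/n) * SD`` standard error; proportional bias is the Pearson
    correlation of the differences with the pairwise means.
    """
    a = np.asarray(custom, dtype=float)
    b = np.asarray(commercial, dtype=float)
    if a.shape != b.shape or a.ndim != 1:
        raise ValidationError("custom and commercial must be 1-D arrays of equal length")
    n = len(a)
    if n < 3:
        raise ValidationError("Bland-Altman analysis needs at least 3 pairs")
    diff = b - a
    mean_pair = (a + b) / 2.0
    bias = float(np.mean(diff))
    sd = float(np.std(diff, ddof=1))
    half = 1.96 * sd
    se_bias = sd / math.sqrt(n)
    se_loa = sd * math.sqrt(3.0 / n)
    if sd > 0:
        with warnings.catch_warnings():
            warnings.simplefilter("ignore", RuntimeWarning)
            t, p_bias = sps.ttest_1samp(diff, 0.0)
        p_bias = float(p_bias)
    else:
        p_bias = 0.0 if bias != 0 else 1.0
    if np.std(diff) > 0 and np.std(mean_pair) > 0:
        r, r_p = sps.pearsonr(diff, mean_pair)
        r, r_p = float(r), float(r_p)
    else:
        r, r_p = float("nan"), float("nan")
    return BlandAltmanResult(
        n=n,
        bias=bias,
        sd_diff=sd,
        loa_low=bias - half,
        loa_high=bias + half,
        loa_low_ci=(bias - half - 1.96 * se_loa, bias - half + 1.96 * se_loa),
        loa_high_ci=(bias + half - 1.96 * se_loa, bias + half + 1.96 * se_loa),
        bias_ci=(bias - 1.96 * se_bias, bias + 1.96 * se_bias),
        bias_p=p_bias,
        r_bias_vs_magnitude=r,
        r_p=r_p,
        direction="commercial - custom",
    )


# --------------------------------------------------------------------------
# ROC / AUC
# --------------------------------------------------------------------------

@dataclass
class CutoffPoint:
    cutoff: float
    sensitivity: float
    specificity: float


@dataclass
class ROCResult:
    auc: float
    auc_ci: Tuple[float, float]
    auc_se: float
    positive_group: str
    direction: str  # positive class tends "higher" or "lower"
    n_positive: int
    n_negative: int
    cutoff_points: List[CutoffPoint] = field(default_factory=list)
    clustering_note: str = "eye-level; intra-subject clustering ignored"

    def to_dict(self) -> Dict:
        return {
            "auc": self.auc,
            "auc_ci": list(self.auc_ci),
            "auc_se": self.auc_se,
            "positive_group": self.positive_group,
            "direction": self.direction,
            "n_positive": self.n_positive,
            "n_negative": self.n_negative,
            "cutoffs": [
                {"cutoff": c.cutoff, "sensitivity": c.sensitivity, "specificity": c.specificity}
                for c in self.cutoff_points
            ],
            "clustering_note": self.clustering_note,
        }


def _delong_se(pos_scores: np.ndarray, neg_scores: np.ndarray) -> float:
    """DeLong standard error of the empirical AUC (higher score = positive)."""
    m, n = len(pos_scores), len(neg_scores)
    all_scores = np.concatenate([pos_scores, neg_scores])
    ranks = sps.rankdata(all_scores)  # midranks
    pos_ranks = ranks[:m]
    neg_ranks = ranks[m:]
    pos_internal = sps.rankdata(pos_scores)
    neg_internal = sps.rankdata(neg_scores)
    auc = (pos_ranks.sum() - m * (m + 1) / 2.0) / (m * n)
    # structural components (Sun & Xu midrank formulation)
    v10 = (pos_ranks - pos_internal) / n
    v01 = 1.0 - (neg_ranks - neg_internal) / m
    s10 = np.var(v10, ddof=1) if m > 1 else 0.0
    s01 = np.var(v01, ddof=1) if n > 1 else 0.0
    return math.sqrt(s10 / m + s01 / n)


def roc_from_values(
    positive_values: Sequence[float],
    negative_values: Sequence[float],
    direction: str = "higher",
    positive_group: str = "positive",
    cutoffs: Optional[Sequence[float]] = None,
) -> ROCResult:
    """Empirical AUC for separating two groups of eye-level values.

    The AUC equals the Mann–Whitney statistic ``U / (n_pos * n_neg)`` with
    ties counted 1/2, oriented so the stated direction ("higher": positive
    class tends to larger values; "lower": smaller) gives AUC >= 0.5 when
    the direction is correct.  The CI is DeLong's (normal on the AUC scale,
    clipped to [0, 1]).  For each requested cutoff, sensitivity is the
    fraction of the positive class beyond the cutoff in the stated direction
    (strictly greater / strictly less) and specificity the fraction of the
    negative class that is not.
    """
    if direction not in ("higher", "lower"):
        raise ValidationError("direction must be 'higher' or 'lower'")
    pos = np.asarray(positive_values, dtype=float)
    neg = np.asarray(negative_values, dtype=float)
    if len(pos) == 0 or len(neg) == 0:
        raise ValidationError("both classes need at least one value")
    sign = 1.0 if direction == "higher" else -1.0
    scores = np.concatenate([sign * pos, sign * neg])
    labels = np.concatenate([np.ones(len(pos)), np.zeros(len(neg))])
    auc = float(roc_auc_score(labels, scores))
    se = _delong_se(sign * pos, sign * neg)
    lo = max(0.0, auc - 1.96 * se)
    hi = min(1.0, auc + 1.96 * se)
    points = []
    for cut in cutoffs or []:
        if direction == "lower":
            sens = float(np.mean(pos < cut))
            spec = float(np.mean(neg >= cut))
        else:
            sens = float(np.mean(pos > cut))
            spec = float(np.mean(neg <= cut))
        points.append(CutoffPoint(cutoff=float(cut), sensitivity=sens, specificity=spec))
    return ROCResult(
        auc=auc,
        auc_ci=(lo, hi),
        auc_se=se,
        positive_group=positive_group,
        direction=direction,
        n_positive=len(pos),
        n_negative=len(neg),
        cutoff_points=points,
    )


def roc_analysis(
    table: pd.DataFrame,
    metric: str,
    positive_group: str,
    negative_group: str,
    direction: str = "higher",
    cutoffs: Optional[Sequence[float]] = None,
) -> ROCResult:
    """ROC discrimination of two groups on one metric of a cohort table."""
    data = table[table["metric"] == metric]
    if data.empty:
        raise ValidationError(f"metric {metric!r} absent from table")
    pos = data.loc[data["group"] == positive_group, "value"].to_numpy()
    neg = data.loc[data["group"] == negative_group, "value"].to_numpy()
    if len(pos) == 0 or len(neg) == 0:
        raise ValidationError("both selected groups must be present in the table")
    return roc_from_values(
        pos, neg, direction=direction, positive_group=positive_group, cutoffs=cutoffs
    )


# --------------------------------------------------------------------------
# image-quality vs disagreement
# --------------------------------------------------------------------------

def quality_disagreement_correlation(
    differences: Sequence[float],
    ssi: Sequence[float],
) -> Tuple[float, float]:
    """Pearson correlation of method disagreement with signal strength index.

    ``differences`` are the per-eye (commercial - custom) density gaps.
    Returns ``(r, p)``.  A constant SSI (or fewer than 3 eyes) leaves the
    correlation undefined.
    """
    d = np.asarray(differences, dtype=float)
    s = np.asarray(ssi, dtype=float)
    if d.shape != s.shape or d.ndim != 1:
        raise ValidationError("differences and ssi must be 1-D arrays of equal length")
    if len(d) < 3:
        raise UndefinedStatisticError("correlation needs at least 3 eyes")
    if np.std(s) == 0:
        raise UndefinedStatisticError("ssi is constant; correlation undefined")
    if np.std(d) == 0:
        raise UndefinedStatisticError("differences are constant; correlation undefined")
    r, p = sps.pearsonr(d, s)
    return float(r), float(p)
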