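"""Empirical ROC analysis: AUC, the DeLong paired test, Youden operating
points, and stratified bootstrap confidence intervals.

Conventions used throughout:

* higher score = more suspicious; a case is "recalled" at threshold ``t``
  iff its score is >= ``t``;
* only biopsy-proven malignant cases are positive — benign and normal cases
  are pooled as negatives (see :func:`binary_labels`);
* ties receive half credit (midranks), consistent with the Mann–Whitney
  interpretation of the AUC and with DeLong's structural components.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from typing import Callable, Sequence

import numpy as np
import pandas as pd
from scipy.stats import norm, rankdata

from .cohort import CLASSES, validate_case_table

__all__ = [
    "ROCCurve",
    "OperatingPoint",
    "DeLongResult",
    "IntervalEstimate",
    "binary_labels",
    "empirical_roc",
    "auc",
    "youden_index",
    "delong_variance",
    "delong_paired_test",
    "max_youden",
    "bootstrap_ci",
]


@dataclass(frozen=True)
class ROCCurve:
    """Ordered operating points of a score against binary truth.

    Thresholds are ascending and include -inf / +inf endpoints, so
    sensitivity is non-increasing and specificity non-decreasing along the
    arrays, with (sens=1, spec=0) first and (sens=0, spec=1) last.
    """

    thresholds: np.ndarray
    sensitivity: np.ndarray
    specificity: np.ndarray
    n_pos: int
    n_neg: int

    def __len__(self) -> int:
        return len(self.thresholds)

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            {
                "threshold": self.thresholds,
                "sensitivity": self.sensitivity,
                "specificity": self.specificity,
            }
        )

    def trapezoidal_auc(self) -> float:
        """Area under the curve in (1 - specificity, sensitivity) space."""
        fpr = 1.0 - self.specificity[::-1]
        tpr = self.sensitivity[::-1]
        return float(np.trapezoid(tpr, fpr))


@dataclass(frozen=True)
class OperatingPoint:
    """A single ROC operating point with its Youden index J = sens + spec - 1."""

    threshold: float
    sensitivity: float
    specificity: float
    youden_j: float
    degenerate: bool = False


@dataclass(frozen=True)
class DeLongResult:
    """Paired comparison of two AUCs on the same cases (DeLong z-test)."""

    auc_a: float
    auc_b: float
    var_a: float
    var_b: float
    cov_ab: float
    z: float
    p_value: float


@dataclass(frozen=True)
class IntervalEstimate:
    """Percentile-bootstrap interval around a point estimate."""

    point: float
    lower: float
    upper: float
    level: float = 0.95
    n_replicates: int = 0
    seed: int = 0
    n_redraws: int = 0


def binary_labels(cases: pd.DataFrame) -> np.ndarray:
    """Map truth classes to binary labels: malignant -> 1, benign/normal -> 0."""
    classes = cases["truth_class"].to_numpy()
    bad = set(classes) - set(CLASSES)
    if bad:
        raise ValueError(f"unknown truth_class values: {sorted(bad)}")
    return (classes == "malignant").astype(int)


def _check_two_classes(labels: np.ndarray) -> tuple[int, int]:
    labels = np.asarray(labels)
    n_pos = int((labels == 1).sum())
    n_neg = int((labels == 0).sum())
    if n_pos == 0:
        raise ValueError("no positive (malignant) cases in input")
    if n_neg == 0:
        raise ValueError("no negative (benign/normal) cases in input")
    return n_pos, n_neg


def empirical_roc(scores: Sequence[float], labels: Sequence[int]) -> ROCCurve:
    """Empirical ROC curve with one operating point per distinct score value.

    A case is recalled at threshold ``t`` iff score >= t; tied scores
    collapse to a single point.  The -inf / +inf endpoints (sens=1, spec=0)
    and (sens=0, spec=1) are always present.
    """
    scores = np.asarray(scores, dtype=float)
    labels = np.asarray(labels)
    if scores.shape != labels.shape:
        raise ValueError("scores and labels must be aligned")
    n_pos, n_neg = _check_two_classes(labels)
    pos = np.sort(scores[labels == 1])
    neg = np.sort(scores[labels == 0])
    uniq = np.unique(scores)
    thresholds = np.concatenate([[-np.inf], uniq, [np.inf]])
    # sens(t) = P(pos >= t); spec(t) = P(neg < t)
    sens = 1.0 - np.searchsorted(pos, thresholds, side="left") / n_pos
    spec = np.searchsorted(neg, thresholds, side="left") / n_neg
    return ROCCurve(
        thresholds=thresholds,
        sensitivity=sens,
        specificity=spec,
        n_pos=n_pos,
        n_neg=n_neg,
    )


def auc(scores: Sequence[float], labels: Sequence[int]) -> float:
    """Mann–Whitney AUC with midrank tie handling.

    Equals the mean over all (positive, negative) pairs of 1 if the positive
    scores higher, 0.5 on a tie, 0 otherwise; also equals the trapezoidal
    area under :func:`empirical_roc`.
    """
    scores = np.asarray(scores, dtype=float)
    labels = np.asarray(labels)
    n_pos, n_neg = _check_two_classes(labels)
    ranks = rankdata(scores)
    pos_ranks = ranks[labels == 1]
    return float((pos_ranks.sum() - n_pos * (n_pos + 1) / 2) / (n_pos * n_neg))


def youden_index(sensitivity: float, specificity: float) -> float:
    """Youden's J statistic, J = sensitivity + specificity - 1."""
    return sensitivity + specificity - 1.0


def _delong_components(scores: np.ndarray, labels: np.ndarray) -> tuple[float, np.ndarray, np.ndarray]:
    """AUC plus DeLong structural components (V10 over positives, V01 over
    negatives), computed with midranks."""
    pos = scores[labels == 1]
    neg = scores[labels == 0]
    m, n = len(pos), len(neg)
    tx = rankdata(pos)
    ty = rankdata(neg)
    tz = rankdata(np.concatenate([pos, neg]))
    v10 = (tz[:m] - tx) / n
    v01 = 1.0 - (tz[m:] - ty) / m
    a = float((tz[:m].sum() / m - (m + 1) / 2) / n)
    return a, v10, v01


def delong_variance(scores: Sequence[float], labels: Sequence[int]) -> float:
    """DeLong variance of the empirical AUC: S10/n_pos + S01/n_neg, where
    S10 and S01 are the sample variances of the structural components."""
    scores = np.asarray(scores, dtype=float)
    labels = np.asarray(labels)
    n_pos, n_neg = _check_two_classes(labels)
    if n_pos < 2 or n_neg < 2:
        raise ValueError(
            "DeLong variance requires at least 2 positives and 2 negatives "
            f"(got {n_pos} and {n_neg})"
        )
    _, v10, v01 = _delong_components(scores, labels)
    return float(np.var(v10, ddof=1) / n_pos + np.var(v01, ddof=1) / n_neg)


def delong_paired_test(
    scores_a: Sequence[float],
    scores_b: Sequence[float],
    labels: Sequence[int],
) -> DeLongResult:
    """DeLong paired z-test for the difference of two correlated AUCs.

    Both score vectors must be aligned on the same cases.  The covariance of
    the two AUC estimators comes from the paired structural components;
    z = (AUC_a - AUC_b) / sqrt(var_a + var_b - 2 cov), with a two-sided
    normal p-value.  When the variance of the difference is zero and the
    AUCs are equal (e.g. identical or rank-equivalent scores), z = 0, p = 1.
    """
    scores_a = np.asarray(scores_a, dtype=float)
    scores_b = np.asarray(scores_b, dtype=float)
    labels = np.asarray(labels)
    if scores_a.shape != scores_b.shape or scores_a.shape != labels.shape:
        raise ValueError("scores_a, scores_b and labels must be aligned (paired design)")
    n_pos, n_neg = _check_two_classes(labels)
    if n_pos < 2 or n_neg < 2:
        raise ValueError("paired test requires at least 2 positives and 2 negatives")
    auc_a, v10_a, v01_a = _delong_components(scores_a, labels)
    auc_b, v10_b, v01_b = _delong_components(scores_b, labels)
    var_a = float(np.var(v10_a, ddof=1) / n_pos + np.var(v01_a, ddof=1) / n_neg)
    var_b = float(np.var(v10_b, ddof=1) / n_pos + np.var(v01_b, ddof=1) / n_neg)
    cov_ab = float(
        np.cov(v10_a, v10_b, ddof=1)[0, 1] / n_pos
        + np.cov(v01_a, v01_b, ddof=1)[0, 1] / n_neg
    )
    var_diff = var_a + var_b - 2.0 * cov_ab
    diff = auc_a - auc_b
    if var_diff <= 1e-15:
        if abs(diff) <= 1e-12:
            z, p = 0.0, 1.0
        else:
            z = float(np.sign(diff) * np.inf)
            p = 0.0
    else:
        z = float(diff / np.sqrt(var_diff))
        p = float(2.0 * norm.sf(abs(z)))
    return DeLongResult(
        auc_a=auc_a, auc_b=auc_b, var_a=var_a, var_b=var_b, cov_ab=cov_ab, z=z, p_value=p
    )


def max_youden(curve: ROCCurve) -> OperatingPoint:
    """Operating point maximizing J = sensitivity + specificity - 1.

    Ties are broken toward higher specificity, then lower threshold.  A
    degenerate (uninformative) curve yields J = 0 and sets the
    ``degenerate`` flag.
    """
    j = curve.sensitivity + curve.specificity - 1.0
    best_j = j.max()
    candidates = np.flatnonzero(j >= best_j - 1e-12)
    # prefer higher specificity, then lower threshold
    order = sorted(
        candidates,
        key=lambda i: (-curve.specificity[i], curve.thresholds[i]),
    )
    i = order[0]
    degenerate = best_j <= 1e-12
    if degenerate:
        warnings.warn("ROC curve is uninformative; returning a J = 0 operating point")
    return OperatingPoint(
        threshold=float(curve.thresholds[i]),
        sensitivity=float(curve.sensitivity[i]),
        specificity=float(curve.specificity[i]),
        youden_j=float(j[i]),
        degenerate=degenerate,
    )


def bootstrap_ci(
    metric: Callable[[pd.DataFrame], float],
    cases: pd.DataFrame,
    n_replicates: int = 2000,
    level: float = 0.95,
    seed: int = 0,
    stratify: bool = True,
    max_redraws_per_replicate: int = 100,
) -> IntervalEstimate:
    """Percentile bootstrap interval for any case-table metric.

    Cases are resampled with replacement, stratified by truth class by
    default (so each replicate keeps the class composition, guaranteeing
    e.g. positives in every resample).  A replicate on which the metric
    raises is redrawn; the redraw count is recorded on the result.
    """
    validate_case_table(cases)
    if n_replicates < 1:
        raise ValueError("n_replicates must be >= 1")
    if not 0.0 < level < 1.0:
        raise ValueError("level must lie in (0, 1)")
    rng = np.random.default_rng(seed)
    point = float(metric(cases))
    classes = cases["truth_class"].to_numpy()
    if stratify:
        strata = [np.flatnonzero(classes == cls) for cls in CLASSES]
        strata = [s for s in strata if len(s)]
    else:
        strata = [np.arange(len(cases))]
    values = np.empty(n_replicates)
    n_redraws = 0
    for b in range(n_replicates):
        for _ in range(max_redraws_per_replicate):
            idx = np.concatenate([rng.choice(s, size=len(s), replace=True) for s in strata])
            try:
                values[b] = metric(cases.iloc[idx].reset_index(drop=True))
                break
            except (ValueError, ZeroDivisionError):
                n_redraws += 1
        else:
            raise RuntimeError(
                f"metric failed on {max_redraws_per_replicate} consecutive resamples"
            )
    alpha = 1.0 - level
    lower, upper = np.quantile(values, [alpha / 2, 1 - alpha / 2])
    return IntervalEstimate(
        point=point,
        lower=float(lower),
        upper=float(upper),
        level=level,
        n_replicates=n_replicates,
        seed=seed,
        n_redraws=n_redraws,
    )
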