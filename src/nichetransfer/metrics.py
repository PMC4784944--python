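"""Accuracy, calibration, transferability and range-mismatch statistics.

All statistics are rank- or threshold-based, so any monotone transform
of the model's suitability output leaves them unchanged:

* AUC              rank probability that a presence outscores a background point
* Swets grade      conventional AUC quality bins
* IE, AUC_Diff     internal evaluation (over-parameterization / over-fit flags)
* TI_H, TI_W       AUC ratios of the projected (Em) vs interpolative (Im) model
* equal sens-spec  threshold for binary range maps
* RRS, OI          over/under-prediction and overlap of binary ranges
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
from scipy import stats

__all__ = [
    "auc",
    "swets_grade",
    "internal_evaluation",
    "transferability_indices",
    "equal_ss_threshold",
    "BinaryRange",
    "binary_range",
    "relative_range_size",
    "overlap_index",
    "EvaluationRecord",
    "evaluate",
    "paired_t",
    "two_sample_t",
]


def auc(presence_scores: np.ndarray, background_scores: np.ndarray) -> float:
    """Rank AUC: P(presence score > background score) + 0.5 P(tie).

    Computed from the Mann-Whitney U statistic via midranks, which is
    exactly the pair-counting definition.
    """
    p = np.asarray(presence_scores, dtype=float)
    b = np.asarray(background_scores, dtype=float)
    if p.size == 0 or b.size == 0:
        raise ValueError("score sets must be non-empty")
    ranks = stats.rankdata(np.concatenate([p, b]))
    u = ranks[:p.size].sum() - p.size * (p.size + 1) / 2.0
    return float(u / (p.size * b.size))


def swets_grade(auc_value: float) -> str:
    """Conventional AUC quality bins (higher is better); each bin is
    closed on its lower boundary's side, so e.g. exactly 0.9 is 'good'."""
    if not 0.0 <= auc_value <= 1.0:
        raise ValueError("AUC must lie in [0, 1]")
    if auc_value > 0.9:
        return "excellent"
    if auc_value > 0.8:
        return "good"
    if auc_value > 0.7:
        return "fair"
    if auc_value > 0.6:
        return "poor"
    return "fail"


def internal_evaluation(auc_train: float, auc_test: float,
                        ) -> tuple[float, float]:
    """(IE, AUC_Diff) = (AUC_test/AUC_train, AUC_train - AUC_test).

    IE > 1 flags possible over-parameterization; AUC_Diff > 0 flags
    over-fit.
    """
    if auc_train <= 0.0:
        raise ValueError("AUC_train must be positive")
    return auc_test / auc_train, auc_train - auc_test


def transferability_indices(im: "EvaluationRecord", em: "EvaluationRecord",
                            use_train_auc: bool = False,
                            ) -> tuple[float, float]:
    """TI_H = AUC(Em)/AUC(Im) and TI_W = (1 - AUC_Diff(Em)) / (1 - AUC_Diff(Im)).

    Both use the test AUC by default; values below one mean the
    interpolative model is the more accurate one.
    """
    a_im = im.auc_train if use_train_auc else im.auc_test
    a_em = em.auc_train if use_train_auc else em.auc_test
    if a_im <= 0.0:
        raise ValueError("Im AUC must be positive")
    if im.auc_diff >= 1.0:
        raise ValueError("Im AUC_Diff must be below 1")
    ti_h = a_em / a_im
    ti_w = (1.0 - em.auc_diff) / (1.0 - im.auc_diff)
    return ti_h, ti_w


def equal_ss_threshold(presence_scores: np.ndarray,
                       absence_scores: np.ndarray) -> float:
    """Threshold equalizing sensitivity and specificity.

    Candidates are the sorted unique scores; sensitivity is the presence
    fraction scoring >= t, specificity the absence fraction scoring < t.
    The lowest candidate minimizing |sens - spec| is returned.
    """
    p = np.sort(np.asarray(presence_scores, dtype=float))
    a = np.sort(np.asarray(absence_scores, dtype=float))
    if p.size == 0 or a.size == 0:
        raise ValueError("score sets must be non-empty")
    cand = np.unique(np.concatenate([p, a]))
    sens = 1.0 - np.searchsorted(p, cand, side="left") / p.size
    spec = np.searchsorted(a, cand, side="left") / a.size
    gap = np.abs(sens - spec)
    return float(cand[int(np.argmin(gap))])


@dataclass
class BinaryRange:
    """A thresholded suitability grid standing in for a range map."""

    grid: np.ndarray
    threshold: float
    rule: str = "equal sensitivity-specificity"

    @property
    def area(self) -> int:
        return int(self.grid.sum())


def binary_range(score_grid: np.ndarray, threshold: float,
                 rule: str = "equal sensitivity-specificity") -> BinaryRange:
    """Cells scoring >= threshold are predicted presence."""
    return BinaryRange(grid=np.asarray(score_grid) >= threshold,
                       threshold=threshold, rule=rule)


def relative_range_size(im: BinaryRange, em: BinaryRange) -> float:
    """Signed over/under-prediction of Em area relative to Im area.

    RRS = Em/Im - 1 when Im < Em, else -(Im/Em - 1). Positive values
    mean the projected model over-predicts the range.
    """
    a_im, a_em = im.area, em.area
    if a_im == 0:
        raise ValueError("Im range has zero area")
    if a_em == 0:
        raise ValueError("Em range has zero area")
    if a_im < a_em:
        return a_em / a_im - 1.0
    return -(a_im / a_em - 1.0)


def overlap_index(im: BinaryRange, em: BinaryRange) -> float:
    """OI = |Im intersect Em| / |Im|, in [0, 1]; blind to Em
    over-prediction (pair with RRS)."""
    a_im = im.area
    if a_im == 0:
        raise ValueError("Im range has zero area")
    overlap = int((im.grid & em.grid).sum())
    return overlap / a_im


@dataclass
class EvaluationRecord:
    """Internal evaluation of one model (Im or Em)."""

    auc_train: float
    auc_test: float

    @property
    def ie(self) -> float:
        return internal_evaluation(self.auc_train, self.auc_test)[0]

    @property
    def auc_diff(self) -> float:
        return internal_evaluation(self.auc_train, self.auc_test)[1]

    @property
    def grade(self) -> str:
        return swets_grade(self.auc_test)


def evaluate(train_scores: np.ndarray, test_scores: np.ndarray,
             background_scores: np.ndarray) -> EvaluationRecord:
    return EvaluationRecord(auc_train=auc(train_scores, background_scores),
                            auc_test=auc(test_scores, background_scores))


def paired_t(a: np.ndarray, b: np.ndarray) -> tuple[float, float, int]:
    """Two-sided paired t-test; zero-variance differences give an
    infinite t (with a warning) rather than an exception."""
    a = np.asarray(a, dtype=float)
    b = np.asarray(b, dtype=float)
    if a.shape != b.shape or a.size < 2:
        raise ValueError("need equal-length series with >= 2 pairs")
    d = a - b
    df = d.size - 1
    if np.ptp(d) == 0:
        warnings.warn("paired differences have zero variance; t is infinite")
        t = 0.0 if d[0] == 0 else np.copysign(np.inf, d[0])
        return float(t), (1.0 if d[0] == 0 else 0.0), df
    res = stats.ttest_rel(a, b)
    return float(res.statistic), float(res.pvalue), df


def two_sample_t(a: np.ndarray, b: np.ndarray, equal_var: bool = False,
                 ) -> tuple[float, float, float]:
    """Two-sided two-sample t-test (Welch by default)."""
    a = np.asarray(a, dtype=float)
    b = np.asarray(b, dtype=float)
    if a.size < 2 or b.size < 2:
        raise ValueError("each group needs >= 2 observations")
    res = stats.ttest_ind(a, b, equal_var=equal_var)
    return float(res.statistic), float(res.pvalue), float(res.df)
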