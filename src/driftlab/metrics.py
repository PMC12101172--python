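"""Evaluation statistics for drift correction.

* line-assignment accuracy against ground truth (the fraction of
  fixations restored to the line they occupied before distortion);
* per-fixation multi-rater agreement (the fraction of raters assigning a
  fixation to its modal line — three of four raters agreeing gives 75% —
  with the overall agreement being the mean over fixations);
* ICC(3,1): the two-way mixed-model, consistency-definition,
  single-rater intra-class correlation, for a fixed set of raters;
* a Mann-Whitney U + Cohen's d comparison between two groups of
  per-trial accuracies.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass
from typing import List, Sequence, Tuple, Union

import numpy as np
import pandas as pd
from scipy import stats

from .core import CorrectionResult, RaterMatrix

__all__ = [
    "AccuracyReport",
    "AgreementReport",
    "ICCReport",
    "GroupComparison",
    "line_accuracy",
    "per_fixation_agreement",
    "icc3",
    "compare_groups",
]


# ---------------------------------------------------------------------------
# accuracy
# ---------------------------------------------------------------------------


@dataclass(frozen=True)
class AccuracyReport:
    """Line-assignment accuracy of one corrected trial."""

    trial_id: str
    algorithm_or_rater: str
    n_fixations: int
    n_correct: int

    @property
    def accuracy(self) -> float:
        """Fraction of fixations restored to their ground-truth line."""
        return self.n_correct / self.n_fixations

    @property
    def percent(self) -> float:
        return 100.0 * self.accuracy


def line_accuracy(
    corrected: Union[CorrectionResult, np.ndarray, Sequence[int]],
    ground_truth_line: Union[np.ndarray, Sequence[int]],
    trial_id: str = "",
    algorithm_or_rater: str = "",
) -> AccuracyReport:
    """Fraction of fixations whose assigned line equals the ground truth."""
    if isinstance(corrected, CorrectionResult):
        assignment = corrected.line_assignment
        algorithm_or_rater = algorithm_or_rater or corrected.algorithm
        trial_id = trial_id or (corrected.corrected.trial_id or "")
    else:
        assignment = np.asarray(corrected, int)
    truth = np.asarray(ground_truth_line, int)
    if assignment.shape != truth.shape:
        raise ValueError(
            f"assignment ({assignment.shape}) and ground truth ({truth.shape}) lengths differ"
        )
    if truth.size == 0:
        raise ValueError("cannot score an empty trial")
    return AccuracyReport(
        trial_id=trial_id,
        algorithm_or_rater=algorithm_or_rater,
        n_fixations=int(truth.size),
        n_correct=int(np.sum(assignment == truth)),
    )


# ---------------------------------------------------------------------------
# agreement
# ---------------------------------------------------------------------------


@dataclass(frozen=True)
class AgreementReport:
    """Per-fixation modal agreement among raters and its mean."""

    per_fixation_agreement: List[float]
    fixation_ids: List
    n_raters: int

    @property
    def overall_agreement(self) -> float:
        return float(np.mean(self.per_fixation_agreement))


def per_fixation_agreement(matrix: RaterMatrix) -> AgreementReport:
    """Modal-count agreement per fixation; the overall value is the mean.

    A fixation's agreement is the number of raters assigning its most
    common line divided by the number of raters who assigned it at all.
    Fixations rated by fewer than two raters are excluded with a warning.
    """
    if matrix.n_raters < 2:
        raise ValueError("agreement requires at least two raters")
    values: List[float] = []
    ids: List = []
    df = matrix.assignments
    for fid, row in zip(df.index, df.to_numpy()):
        ratings = row[np.isfinite(row)].astype(int)
        if ratings.size < 2:
            warnings.warn(
                f"fixation {fid!r} has fewer than two ratings and is excluded from agreement",
                UserWarning,
                stacklevel=2,
            )
            continue
        modal_count = int(np.bincount(ratings).max())
        values.append(modal_count / ratings.size)
        ids.append(fid)
    if not values:
        raise ValueError("no fixation was rated by at least two raters")
    return AgreementReport(per_fixation_agreement=values, fixation_ids=ids, n_raters=matrix.n_raters)


# ---------------------------------------------------------------------------
# ICC(3,1)
# ---------------------------------------------------------------------------


@dataclass(frozen=True)
class ICCReport:
    """ICC(3,1) with its ANOVA F test."""

    icc3: float
    F: float
    df1: int
    df2: int
    p_value: float
    n_subjects: int
    n_raters: int


def icc3(matrix: RaterMatrix) -> ICCReport:
    """Single-rater, consistency-definition ICC from a two-way mixed model.

    Fixations are the subjects, raters the fixed measurement conditions;
    rater effects are removed (consistency) and ICC(3,1) =
    (MS_subjects - MS_error) / (MS_subjects + (k - 1) MS_error) from the
    two-way ANOVA without interaction.  Fixations with any missing rating
    are dropped (listwise deletion).
    """
    df = matrix.assignments.dropna(axis=0, how="any")
    data = df.to_numpy(float)
    n, k = data.shape
    if n < 2 or k < 2:
        raise ValueError(f"ICC needs at least 2 complete fixations and 2 raters, got {n}x{k}")
    grand = data.mean()
    if np.allclose(data, grand):
        raise ValueError("ICC is undefined: the rater matrix has zero total variance")
    subject_means = data.mean(axis=1)
    rater_means = data.mean(axis=0)
    ss_subjects = k * float(((subject_means - grand) ** 2).sum())
    ss_raters = n * float(((rater_means - grand) ** 2).sum())
    ss_total = float(((data - grand) ** 2).sum())
    ss_error = ss_total - ss_subjects - ss_raters
    df1 = n - 1
    df2 = (n - 1) * (k - 1)
    ms_subjects = ss_subjects / df1
    ms_error = ss_error / df2
    if ms_error <= 0:
        # raters agree exactly (after removing rater offsets): perfect consistency
        return ICCReport(icc3=1.0, F=np.inf, df1=df1, df2=df2, p_value=0.0, n_subjects=n, n_raters=k)
    icc = (ms_subjects - ms_error) / (ms_subjects + (k - 1) * ms_error)
    F = ms_subjects / ms_error
    p = float(stats.f.sf(F, df1, df2))
    return ICCReport(icc3=float(icc), F=float(F), df1=df1, df2=df2, p_value=p, n_subjects=n, n_raters=k)


# ---------------------------------------------------------------------------
# group comparison
# ---------------------------------------------------------------------------


@dataclass(frozen=True)
class GroupComparison:
    U: float
    p_value: float
    cohens_d: float


def compare_groups(acc_a: Sequence[float], acc_b: Sequence[float]) -> GroupComparison:
    """Two-sided Mann-Whitney U (tie-corrected) plus pooled-SD Cohen's d.

    ``U`` is the statistic for the first group against the second; d > 0
    means the first group scores higher.  With zero pooled variance d is
    undefined and returned as NaN with a warning.
    """
    a = np.asarray(acc_a, float)
    b = np.asarray(acc_b, float)
    if a.size == 0 or b.size == 0:
        raise ValueError("both groups must be non-empty")
    res = stats.mannwhitneyu(a, b, alternative="two-sided")
    na, nb = a.size, b.size
    if na + nb <= 2:
        pooled = 0.0
    else:
        pooled = np.sqrt(((na - 1) * a.var(ddof=1) + (nb - 1) * b.var(ddof=1)) / (na + nb - 2))
    if pooled == 0:
        warnings.warn("Cohen's d is undefined for constant groups", UserWarning, stacklevel=2)
        d = np.nan
    else:
        d = (a.mean() - b.mean()) / pooled
    return GroupComparison(U=float(res.statistic), p_value=float(res.pvalue), cohens_d=float(d))
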