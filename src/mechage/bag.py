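"""Brain-age gap (BAG) computation, Theil-Sen bias correction and group tests.

The BAG is predicted minus chronological age. Because regression heads
shrink predictions toward the training mean, raw BAGs show a spurious
negative trend with age; this is removed by fitting a robust Theil-Sen line
of predicted vs chronological age on healthy controls and subtracting the
line's prediction. Group comparisons follow the normality-gated protocol:
Shapiro-Wilk decides between t-tests and their rank-based counterparts,
always two-sided.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Mapping, Sequence

import numpy as np
from scipy import stats

from .types import Cohort, SubjectRecord

__all__ = ["BiasModel", "BAGRecord", "GroupComparison", "compute_bag",
           "fit_bias_correction", "apply_bias_correction", "compare_groups"]

EXACT_RANK_TEST_MAX_N = 12


@dataclass
class BiasModel:
    """Theil-Sen fit of predicted vs chronological age on controls."""

    slope: float
    intercept: float
    n_controls: int


@dataclass
class BAGRecord:
    subject_id: str
    cohort: Cohort
    chronological_age: float
    predicted_age: float
    raw_bag: float
    corrected_bag: float | None = None


@dataclass
class GroupComparison:
    test_name: str
    statistic: float
    p_value: float
    normality_p: tuple[float, ...]
    group_sizes: tuple[int, ...]
    paired: bool
    alpha: float = 0.05


def compute_bag(predictions: Mapping[str, float],
                records: Sequence[SubjectRecord]) -> list[BAGRecord]:
    """Raw BAG per subject; ``predictions`` maps subject id to predicted age."""
    out = []
    for r in records:
        if r.subject_id not in predictions:
            raise KeyError(f"no prediction for subject {r.subject_id}")
        pred = float(predictions[r.subject_id])
        out.append(BAGRecord(subject_id=r.subject_id, cohort=r.cohort,
                             chronological_age=r.age, predicted_age=pred,
                             raw_bag=pred - r.age))
    return out


def fit_bias_correction(controls: Sequence[BAGRecord]) -> BiasModel:
    """Theil-Sen regression of predicted on chronological age over controls.

    Slope is the median of all pairwise slopes; the intercept is
    median(pred - slope * age).
    """
    if len(controls) < 3:
        raise ValueError("need at least 3 controls")
    ages = np.array([c.chronological_age for c in controls])
    preds = np.array([c.predicted_age for c in controls])
    if np.unique(ages).size < 2:
        raise ValueError("all control ages identical")
    res = stats.theilslopes(preds, ages, method="joint")
    return BiasModel(slope=float(res.slope), intercept=float(res.intercept),
                     n_controls=len(controls))


def apply_bias_correction(model: BiasModel,
                          records: Sequence[BAGRecord]) -> list[BAGRecord]:
    """corrected_bag = predicted - (intercept + slope * chronological)."""
    out = []
    for r in records:
        expected = model.intercept + model.slope * r.chronological_age
        out.append(BAGRecord(subject_id=r.subject_id, cohort=r.cohort,
                             chronological_age=r.chronological_age,
                             predicted_age=r.predicted_age, raw_bag=r.raw_bag,
                             corrected_bag=r.predicted_age - expected))
    return out


def _shapiro_p(x: np.ndarray) -> float:
    if np.ptp(x) == 0:
        raise ValueError("zero-variance input to Shapiro-Wilk")
    return float(stats.shapiro(x).pvalue)


def compare_groups(a: Sequence[float], b: Sequence[float], paired: bool = False,
                   alpha: float = 0.05,
                   force_nonparametric: bool = False) -> GroupComparison:
    """Two-sided comparison with a Shapiro-Wilk normality gate at ``alpha``.

    Paired data: Shapiro-Wilk on the differences, then paired t or Wilcoxon
    signed-rank. Independent data: Shapiro-Wilk on each group, then
    independent t or Mann-Whitney U. Rank tests use exact p-values when both
    groups have at most 12 samples and no ties, the tie-corrected normal
    approximation otherwise. ``force_nonparametric`` bypasses the gate and
    always runs the rank-based branch.
    """
    a = np.asarray(a, dtype=np.float64)
    b = np.asarray(b, dtype=np.float64)
    if a.size < 3 or b.size < 3:
        raise ValueError("each group needs at least 3 values")
    if paired:
        if a.size != b.size:
            raise ValueError("paired comparison needs equal lengths")
        diffs = a - b
        gate = (_shapiro_p(diffs),)
        if gate[0] > alpha and not force_nonparametric:
            res = stats.ttest_rel(a, b)
            name = "paired_t"
        else:
            small = a.size <= EXACT_RANK_TEST_MAX_N
            no_ties = np.unique(np.abs(diffs[diffs != 0])).size == np.count_nonzero(diffs)
            method = "exact" if small and no_ties and np.all(diffs != 0) else "approx"
            res = stats.wilcoxon(a, b, method=method)
            name = "wilcoxon_signed_rank"
    else:
        gate = (_shapiro_p(a), _shapiro_p(b))
        if min(gate) > alpha and not force_nonparametric:
            res = stats.ttest_ind(a, b)
            name = "independent_t"
        else:
            pooled = np.concatenate([a, b])
            no_ties = np.unique(pooled).size == pooled.size
            small = a.size <= EXACT_RANK_TEST_MAX_N and b.size <= EXACT_RANK_TEST_MAX_N
            method = "exact" if small and no_ties else "asymptotic"
            res = stats.mannwhitneyu(a, b, alternative="two-sided", method=method)
            name = "mann_whitney_u"
    return GroupComparison(test_name=name, statistic=float(res.statistic),
                           p_value=float(res.pvalue), normality_p=gate,
                           group_sizes=(a.size, b.size), paired=paired,
                           alpha=alpha)
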