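"""Attainable AUC-PR extremes, normalized AUC-PR, and random baselines.

For a fixed set of weights, which scoring maximizes (or minimizes) the
weighted AUC-PR?  The answer is an ordering condition: the maximum is
attained exactly when the points, read from the highest score down, are
monotonically ordered from high to low foreground confidence
w_fg / (w_fg + w_bg); the minimum when that order is reversed.  For
unweighted data the optimal ordering separates the classes perfectly and
the maximum is 1; for genuinely soft weights the maximum is strictly
below 1 (full recall forces every point's background weight into the
denominator of the final precision) and the minimum is strictly above 0.

The extremes anchor the normalized AUC-PR, (auc - min) / (max - min), and
bracket the Monte-Carlo random-classifier baseline, whose median AUC-PR
is approximately the class ratio.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from softpr.core import InputError, WeightedSample, supporting_points
from softpr.interpolate import auc_pr_continuous

__all__ = [
    "ExtremeResult",
    "BaselineSummary",
    "max_auc_pr",
    "min_auc_pr",
    "extreme_aucs",
    "normalized_auc_pr",
    "random_baseline",
]


@dataclass(frozen=True)
class ExtremeResult:
    """Extreme AUC-PR values for a weighting, with realizing orderings.

    ``max_order`` / ``min_order`` list data-point indices from the
    highest assigned score to the lowest; either side may be absent when
    only one extreme was requested.
    """

    class_ratio: float
    max_auc: float | None = None
    min_auc: float | None = None
    max_order: np.ndarray | None = None
    min_order: np.ndarray | None = None

    def merged(self, other: "ExtremeResult") -> "ExtremeResult":
        return ExtremeResult(
            class_ratio=self.class_ratio,
            max_auc=self.max_auc if self.max_auc is not None else other.max_auc,
            min_auc=self.min_auc if self.min_auc is not None else other.min_auc,
            max_order=self.max_order if self.max_order is not None else other.max_order,
            min_order=self.min_order if self.min_order is not None else other.min_order,
        )


@dataclass(frozen=True)
class BaselineSummary:
    """Ensemble of random-classifier AUC-PR values with quartile summary."""

    m: int
    aucs: np.ndarray
    median: float
    q25: float
    q75: float
    seed: int


def confidence_ratio(sample: WeightedSample) -> np.ndarray:
    """Per-point foreground confidence w_fg / (w_fg + w_bg), in [0, 1]."""
    return sample.w_fg / (sample.w_fg + sample.w_bg)


def auc_pr_of_order(sample: WeightedSample, order: np.ndarray) -> float:
    """Continuous AUC-PR of the scoring that ranks ``order[0]`` highest.

    ``order`` is a permutation of point indices; scores are strictly
    decreasing along it, so every point is its own threshold step.
    """
    scores = np.empty(sample.n)
    scores[order] = np.arange(sample.n, 0, -1, dtype=float)
    return auc_pr_continuous(supporting_points(sample.with_scores(scores))).auc


def _check_fg(sample: WeightedSample) -> float:
    ratio = float(sample.w_fg.sum()) / float(sample.w_fg.sum() + sample.w_bg.sum())
    if ratio <= 0:
        raise InputError("no foreground mass; AUC-PR undefined")
    return ratio


def max_auc_pr(sample: WeightedSample) -> ExtremeResult:
    """Maximal AUC-PR over all scorings of the sample.

    Attained by ranking points by descending foreground confidence; ties
    are broken by input index (equal-confidence points lie on a common
    constant-precision hyperbola, so their internal order is irrelevant).
    """
    class_ratio = _check_fg(sample)
    order = np.argsort(-confidence_ratio(sample), kind="stable")
    return ExtremeResult(
        class_ratio=class_ratio,
        max_auc=auc_pr_of_order(sample, order),
        max_order=order,
    )


def min_auc_pr(sample: WeightedSample) -> ExtremeResult:
    """Minimal AUC-PR over all scorings: ascending foreground confidence."""
    class_ratio = _check_fg(sample)
    order = np.argsort(confidence_ratio(sample), kind="stable")
    return ExtremeResult(
        class_ratio=class_ratio,
        min_auc=auc_pr_of_order(sample, order),
        min_order=order,
    )


def extreme_aucs(sample: WeightedSample) -> ExtremeResult:
    """Both extremes in one result (see :func:`max_auc_pr`, :func:`min_auc_pr`)."""
    return max_auc_pr(sample).merged(min_auc_pr(sample))


def normalized_auc_pr(auc: float, extremes: ExtremeResult) -> float:
    """(auc - min) / (max - min), mapping the attainable range onto [0, 1]."""
    if extremes.max_auc is None or extremes.min_auc is None:
        raise ValueError("extremes must carry both max_auc and min_auc")
    lo, hi = extremes.min_auc, extremes.max_auc
    if hi <= lo:
        raise InputError("degenerate sample, normalization undefined")
    z = (auc - lo) / (hi - lo)
    if z < -1e-9 or z > 1 + 1e-9:
        raise ValueError(
            f"auc {auc} outside the attainable range [{lo}, {hi}]: "
            "extremes do not belong to this sample"
        )
    return min(max(z, 0.0), 1.0)


def random_baseline(sample: WeightedSample, m: int = 1000, seed: int = 0) -> BaselineSummary:
    """AUC-PR ensemble of ``m`` random classifiers (i.i.d. uniform scores).

    Continuous i.i.d. scores are almost surely distinct, so each draw is a
    random total order of the points.  The median of the ensemble sits
    near the class ratio.  Quartiles use linear interpolation between
    order statistics.
    """
    if m < 1:
        raise ValueError("m must be >= 1")
    _check_fg(sample)
    rng = np.random.default_rng(seed)
    aucs = np.empty(m)
    for i in range(m):
        scored = sample.with_scores(rng.random(sample.n))
        aucs[i] = auc_pr_continuous(supporting_points(scored)).auc
    q25, med, q75 = np.quantile(aucs, [0.25, 0.5, 0.75])
    return BaselineSummary(
        m=m, aucs=aucs, median=float(med), q25=float(q25), q75=float(q75), seed=seed
    )
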