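"""Shared fixtures and independent oracles.

The oracles deliberately avoid the package's closed-form segment math:
quadrature integrates the linearly interpolated confusion matrices
directly, and the rank-statistic AUC-ROC counts pairwise score
comparisons.  They exist so the implementation can be checked against
something it does not share code with.
"""

from __future__ import annotations

import numpy as np
import pytest

from softpr.core import WeightedSample
from softpr.datasets import (
    worked_example_table,
    worked_example_unweighted,
    worked_example_weighted,
)


@pytest.fixture
def example_table():
    return worked_example_table()


@pytest.fixture
def weighted_example() -> WeightedSample:
    return worked_example_weighted()


@pytest.fixture
def unweighted_example() -> WeightedSample:
    return worked_example_unweighted()


def simpson_segment_auc(
    tp_a: float, fp_a: float, tp_b: float, fp_b: float, r_fg: float, n: int = 100_000
) -> float:
    """Quadrature oracle for the area under one PR-curve piece.

    Linearly interpolates the confusion matrices between the endpoints
    and integrates precision over recall with Simpson's rule; no use of
    the closed form.
    """
    from scipy.integrate import simpson

    u = np.linspace(0.0, 1.0, n + 1)
    tp = tp_a + u * (tp_b - tp_a)
    fp = fp_a + u * (fp_b - fp_a)
    denom = tp + fp
    prec = np.divide(tp, denom, out=np.zeros_like(tp), where=denom > 0)
    if denom[0] == 0:
        # limit along the ray from the origin: constant precision
        prec[0] = (tp_b - tp_a) / ((tp_b - tp_a) + (fp_b - fp_a))
    recall = tp / r_fg
    return float(simpson(prec, x=recall))


def simpson_auc_pr(points, n: int = 100_000) -> float:
    """Sum of the quadrature oracle over all tp-increasing segment pairs."""
    total = 0.0
    for i in range(len(points) - 1):
        if points.tp[i + 1] > points.tp[i]:
            total += simpson_segment_auc(
                points.tp[i], points.fp[i], points.tp[i + 1], points.fp[i + 1],
                points.r_fg, n=n,
            )
    return total


def pairwise_auc_roc(sample: WeightedSample) -> float:
    """Rank-statistic AUC-ROC: weighted probability that a foreground
    point outscores a background point, ties counting one half."""
    s = sample.scores
    gt = (s[:, None] > s[None, :]).astype(float)
    eq = (s[:, None] == s[None, :]).astype(float)
    num = sample.w_fg @ (gt + 0.5 * eq) @ sample.w_bg
    return float(num / (sample.w_fg.sum() * sample.w_bg.sum()))


def count_confusion(scores, labels, t):
    """Direct count-based confusion matrix for hard-labeled data."""
    scores = np.asarray(scores)
    labels = np.asarray(labels)
    pred = scores >= t
    return (
        int(np.sum(pred & (labels == 1))),
        int(np.sum(pred & (labels == 0))),
        int(np.sum(~pred & (labels == 1))),
        int(np.sum(~pred & (labels == 0))),
    )


def random_weighted_sample(rng: np.random.Generator, n: int) -> WeightedSample:
    """A generic weighted sample: soft labels in (0,1), distinct-ish scores."""
    w_fg = rng.uniform(0.0, 1.0, n)
    return WeightedSample(rng.normal(size=n), w_fg, 1.0 - w_fg)
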