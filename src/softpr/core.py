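"""Weighted samples and threshold-indexed confusion matrices.

A test data point i has a classifier score s_i and a pair of non-negative
class weights (w_fg,i, w_bg,i).  Hard-labeled (unweighted) data is the
special case w_fg, w_bg in {0, 1} with w_fg + w_bg = 1.  Sweeping the
classification threshold over the distinct scores yields a series of
real-valued confusion matrices -- the supporting points from which every
PR and ROC curve in this package is built.

The prediction rule is fixed package-wide: a point is predicted foreground
iff its score is >= the threshold.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from typing import Iterator, Literal, Sequence

import numpy as np
import pandas as pd

logger = logging.getLogger(__name__)

__all__ = [
    "WeightedSample",
    "ClassTotals",
    "ConfusionMatrix",
    "SupportingPoints",
    "load_sample",
    "confusion_at_threshold",
    "supporting_points",
    "curve_points",
]


class InputError(ValueError):
    """Invalid input data (bad weights, non-finite scores, empty sample)."""


@dataclass(frozen=True)
class ClassTotals:
    """Weight mass per class: the margins of every confusion matrix."""

    r_fg: float  # total foreground weight (the number of positives)
    w_bg_total: float  # total background weight
    n_total: float = field(init=False)

    def __post_init__(self) -> None:
        object.__setattr__(self, "n_total", self.r_fg + self.w_bg_total)

    @property
    def class_ratio(self) -> float:
        """Foreground fraction r_fg / (r_fg + w_bg_total)."""
        return self.r_fg / self.n_total


@dataclass(frozen=True)
class WeightedSample:
    """Per-point classifier scores with per-class non-negative weights."""

    scores: np.ndarray
    w_fg: np.ndarray
    w_bg: np.ndarray

    def __post_init__(self) -> None:
        scores = np.asarray(self.scores, dtype=float)
        w_fg = np.asarray(self.w_fg, dtype=float)
        w_bg = np.asarray(self.w_bg, dtype=float)
        if not (scores.shape == w_fg.shape == w_bg.shape) or scores.ndim != 1:
            raise InputError("scores, w_fg, w_bg must be 1-d arrays of equal length")
        if scores.size == 0:
            raise InputError("empty sample")
        if not np.all(np.isfinite(scores)):
            bad = int(np.flatnonzero(~np.isfinite(scores))[0])
            raise InputError(f"non-finite score at row {bad}")
        for name, w in (("w_fg", w_fg), ("w_bg", w_bg)):
            if not np.all(np.isfinite(w)):
                bad = int(np.flatnonzero(~np.isfinite(w))[0])
                raise InputError(f"non-finite {name} at row {bad}")
            if np.any(w < 0):
                bad = int(np.flatnonzero(w < 0)[0])
                raise InputError(f"negative {name} at row {bad}")
        if np.any(w_fg + w_bg == 0):
            bad = int(np.flatnonzero(w_fg + w_bg == 0)[0])
            raise InputError(
                f"point {bad} has zero total weight; filter such points before "
                "constructing a sample (load_sample does this automatically)"
            )
        object.__setattr__(self, "scores", scores)
        object.__setattr__(self, "w_fg", w_fg)
        object.__setattr__(self, "w_bg", w_bg)

    @property
    def n(self) -> int:
        return self.scores.size

    def totals(self) -> ClassTotals:
        return ClassTotals(float(self.w_fg.sum()), float(self.w_bg.sum()))

    @property
    def is_unweighted(self) -> bool:
        """True iff every point is hard-labeled: weights in {0,1}, summing to 1."""
        in01 = np.isin(self.w_fg, (0.0, 1.0)) & np.isin(self.w_bg, (0.0, 1.0))
        return bool(np.all(in01 & (self.w_fg + self.w_bg == 1.0)))

    def with_scores(self, scores: Sequence[float] | np.ndarray) -> "WeightedSample":
        """Same weights, different scoring (used for re-scoring experiments)."""
        return WeightedSample(np.asarray(scores, dtype=float), self.w_fg, self.w_bg)

    @classmethod
    def from_labels(
        cls, scores: Sequence[float] | np.ndarray, labels: Sequence[int] | np.ndarray
    ) -> "WeightedSample":
        """Build an unweighted sample from 0/1 hard labels (1 = foreground)."""
        labels = np.asarray(labels)
        if not np.all(np.isin(labels, (0, 1))):
            raise InputError("labels must be 0 or 1")
        w_fg = labels.astype(float)
        return cls(np.asarray(scores, dtype=float), w_fg, 1.0 - w_fg)


@dataclass(frozen=True)
class ConfusionMatrix:
    """Real-valued confusion matrix at one classification threshold.

    Entries are accumulated weights: for unweighted data they are counts.
    """

    tp: float
    fp: float
    fn: float
    tn: float
    threshold: float

    def __post_init__(self) -> None:
        for name in ("tp", "fp", "fn", "tn"):
            v = getattr(self, name)
            if v < 0:
                raise ValueError(f"{name} = {v} < 0")

    @property
    def r_fg(self) -> float:
        return self.tp + self.fn

    @property
    def w_bg_total(self) -> float:
        return self.fp + self.tn

    @property
    def recall(self) -> float:
        """tp / (tp + fn); NaN when there is no foreground mass."""
        return self.tp / self.r_fg if self.r_fg > 0 else float("nan")

    @property
    def precision(self) -> float:
        """tp / (tp + fp); NaN for the empty prediction set."""
        denom = self.tp + self.fp
        return self.tp / denom if denom > 0 else float("nan")

    tpr = recall

    @property
    def fpr(self) -> float:
        return self.fp / self.w_bg_total if self.w_bg_total > 0 else float("nan")


@dataclass(frozen=True)
class SupportingPoints:
    """Cumulative (tp, fp) over all distinct-score thresholds, descending.

    ``thresholds[0]`` is a sentinel strictly above the maximum score with
    tp = fp = 0; ``tp[-1] = r_fg`` and ``fp[-1] = w_bg_total`` exactly.
    Tied scores are merged into a single threshold step.
    """

    thresholds: np.ndarray
    tp: np.ndarray
    fp: np.ndarray

    @property
    def r_fg(self) -> float:
        return float(self.tp[-1])

    @property
    def w_bg_total(self) -> float:
        return float(self.fp[-1])

    def __len__(self) -> int:
        return self.thresholds.size

    def __iter__(self) -> Iterator[ConfusionMatrix]:
        r_fg, w_bg = self.r_fg, self.w_bg_total
        for t, tp, fp in zip(self.thresholds, self.tp, self.fp):
            yield ConfusionMatrix(
                tp=float(tp),
                fp=float(fp),
                fn=max(r_fg - float(tp), 0.0),
                tn=max(w_bg - float(fp), 0.0),
                threshold=float(t),
            )

    @property
    def entries_are_integral(self) -> bool:
        """True iff every tp/fp entry is an integer (unweighted-style data)."""
        return bool(
            np.allclose(self.tp, np.round(self.tp), atol=1e-9)
            and np.allclose(self.fp, np.round(self.fp), atol=1e-9)
        )


def load_sample(
    rows: pd.DataFrame,
    mode: Literal["weighted", "unweighted"] = "weighted",
) -> WeightedSample:
    """Validate a table of score/weight records into a :class:`WeightedSample`.

    Parameters
    ----------
    rows
        Weighted mode: columns ``score``, ``w_fg``, ``w_bg``.
        Unweighted mode: columns ``score``, ``label`` with label in
        {fg, bg, 1, 0} (1/fg = foreground).
    mode
        Which schema to expect.

    Points with w_fg = w_bg = 0 carry no information; they are dropped with
    a logged warning rather than rejected.
    """
    if mode == "weighted":
        missing = {"score", "w_fg", "w_bg"} - set(rows.columns)
        if missing:
            raise InputError(f"weighted input lacks columns: {sorted(missing)}")
        scores = pd.to_numeric(rows["score"], errors="coerce").to_numpy(dtype=float)
        w_fg = pd.to_numeric(rows["w_fg"], errors="coerce").to_numpy(dtype=float)
        w_bg = pd.to_numeric(rows["w_bg"], errors="coerce").to_numpy(dtype=float)
    elif mode == "unweighted":
        missing = {"score", "label"} - set(rows.columns)
        if missing:
            raise InputError(f"unweighted input lacks columns: {sorted(missing)}")
        scores = pd.to_numeric(rows["score"], errors="coerce").to_numpy(dtype=float)
        mapping = {"fg": 1.0, "bg": 0.0, "1": 1.0, "0": 0.0, 1: 1.0, 0: 0.0}
        labels = rows["label"].map(
            lambda v: mapping.get(v if not isinstance(v, str) else v.strip().lower())
        )
        if labels.isna().any():
            bad = int(labels.index[labels.isna()][0])
            raise InputError(f"unrecognized label at row {bad} (expected fg/bg/1/0)")
        w_fg = labels.to_numpy(dtype=float)
        w_bg = 1.0 - w_fg
    else:
        raise InputError(f"unknown mode {mode!r}")

    for name, col in (("score", scores), ("w_fg", w_fg), ("w_bg", w_bg)):
        if np.any(~np.isfinite(col)):
            bad = int(np.flatnonzero(~np.isfinite(col))[0])
            raise InputError(f"non-finite or unparseable {name} at row {bad}")
        if name != "score" and np.any(col < 0):
            bad = int(np.flatnonzero(col < 0)[0])
            raise InputError(f"negative {name} at row {bad}")

    keep = (w_fg + w_bg) > 0
    n_dropped = int((~keep).sum())
    if n_dropped:
        logger.warning("dropped %d point(s) with zero total weight", n_dropped)
    if not keep.any():
        raise InputError("no data points remain after filtering zero-weight rows")
    return WeightedSample(scores[keep], w_fg[keep], w_bg[keep])


def confusion_at_threshold(sample: WeightedSample, t: float) -> ConfusionMatrix:
    """Confusion matrix for the prediction rule score >= t."""
    if not np.isfinite(t):
        raise InputError("threshold must be finite")
    predicted = sample.scores >= t
    tp = float(sample.w_fg[predicted].sum())
    fp = float(sample.w_bg[predicted].sum())
    fn = float(sample.w_fg[~predicted].sum())
    tn = float(sample.w_bg[~predicted].sum())
    return ConfusionMatrix(tp=tp, fp=fp, fn=fn, tn=tn, threshold=t)


def supporting_points(sample: WeightedSample) -> SupportingPoints:
    """All confusion matrices realized by sweeping the threshold.

    One matrix per distinct score (ties merged), ordered by decreasing
    threshold, preceded by a sentinel above the maximum score at which
    nothing is predicted foreground.  Computed in one pass via cumulative
    weight sums over the score-sorted points, so tp and fp are exactly
    non-decreasing and the final entries equal the class totals.
    """
    if float(sample.w_fg.sum()) <= 0:
        raise InputError("no foreground mass; recall undefined")
    order = np.argsort(-sample.scores, kind="stable")
    s = sample.scores[order]
    cum_fg = np.cumsum(sample.w_fg[order])
    cum_bg = np.cumsum(sample.w_bg[order])
    # last index of each tie group of equal scores
    last_of_group = np.flatnonzero(np.append(np.diff(s) != 0, True))
    thresholds = np.concatenate(([s[0] + 1.0], s[last_of_group]))
    tp = np.concatenate(([0.0], cum_fg[last_of_group]))
    fp = np.concatenate(([0.0], cum_bg[last_of_group]))
    return SupportingPoints(thresholds=thresholds, tp=tp, fp=fp)


def curve_points(
    points: SupportingPoints, kind: Literal["pr", "roc"]
) -> list[tuple[float, float]]:
    """Supporting points as (x, y) pairs: (recall, precision) or (fpr, tpr).

    For the PR curve the tp = fp = 0 sentinel is omitted (precision 0/0 is
    undefined); for the ROC curve it is emitted as (0, 0).
    """
    r_fg, w_bg = points.r_fg, points.w_bg_total
    if kind == "pr":
        if r_fg <= 0:
            raise InputError("PR curve requires positive foreground mass")
        return [
            (tp / r_fg, tp / (tp + fp))
            for tp, fp in zip(points.tp, points.fp)
            if tp + fp > 0
        ]
    if kind == "roc":
        if w_bg <= 0:
            raise InputError("ROC curve requires positive background mass")
        return [(fp / w_bg, tp / r_fg) for tp, fp in zip(points.tp, points.fp)]
    raise InputError(f"unknown curve kind {kind!r}")
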