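"""AUC computation: continuous closed form, discrete interpolations, ROC.

Between two adjacent supporting points A and B (tp_A < tp_B) the linear
interpolation of the underlying confusion matrices makes fp a linear
function of tp with slope s = (fp_B - fp_A) / (tp_B - tp_A).  Writing the
recall as p = tp / R_fg, the precision along the piece is the hyperbola

    prec(p) = p / (a*p + b),   a = 1 + s,   b = (fp_A - s*tp_A) / R_fg,

and the exact area under the piece is

    (pB - pA - b/a * (ln(a*pB + b) - ln(a*pA + b))) / a      (b != 0)
    (pB - pA) / a                                            (b  = 0).

This closed form needs no step size and therefore applies to real-valued
(weighted) confusion matrices.  The classical discrete interpolations --
intermediate points at unit steps of tp (discrete-TP) or of fp
(discrete-FP), followed by the trapezoidal rule -- are provided for
integer-valued confusion matrices, where a unit step corresponds to one
data point.  ROC curves interpolate linearly, so trapezoidal AUC-ROC is
exact for weighted and unweighted data alike.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from typing import Literal

import numpy as np

from softpr.core import ConfusionMatrix, InputError, SupportingPoints, curve_points

__all__ = [
    "Segment",
    "CurveResult",
    "segment_auc",
    "auc_pr_continuous",
    "auc_pr_discrete_tp",
    "auc_pr_discrete_fp",
    "auc_roc",
    "dense_pr_curve",
]

# |b| below this (relative to the segment scale) switches to the b = 0
# formula: the logarithmic form loses all precision as b -> 0 while the
# limit is simply (pB - pA)/a.
_B_ZERO_RTOL = 1e-12


@dataclass(frozen=True)
class Segment:
    """One piece of the PR curve between adjacent supporting points.

    On the piece, precision(p) = p / (a*p + b) for recall p in [pA, pB].
    """

    a: float
    b: float
    pA: float
    pB: float

    def __post_init__(self) -> None:
        if not 0 <= self.pA < self.pB <= 1 + 1e-12:
            raise ValueError(f"invalid recall bounds [{self.pA}, {self.pB}]")
        if self.a * self.pA + self.b < -1e-12:
            raise ValueError("a*pA + b < 0: inconsistent segment")

    def precision(self, p: np.ndarray | float) -> np.ndarray | float:
        return p / (self.a * p + self.b)

    @property
    def is_degenerate_b(self) -> bool:
        return abs(self.b) <= _B_ZERO_RTOL * max(1.0, abs(self.a * self.pB))

    def area(self) -> float:
        """Exact integral of precision over [pA, pB] (natural logarithm)."""
        a, b, pA, pB = self.a, self.b, self.pA, self.pB
        if self.is_degenerate_b:
            return (pB - pA) / a
        return (pB - pA - b / a * (math.log(a * pB + b) - math.log(a * pA + b))) / a


@dataclass(frozen=True)
class CurveResult:
    """A PR or ROC curve with its area and the points that define it."""

    kind: Literal["pr", "roc"]
    method: Literal["continuous", "discrete_tp", "discrete_fp", "trapezoid"]
    auc: float
    points: list[tuple[float, float]]
    n_segments: int

    def __post_init__(self) -> None:
        if not -1e-12 <= self.auc <= 1 + 1e-12:
            raise ValueError(f"AUC {self.auc} outside [0, 1]")


def _make_segment(
    tp_a: float, fp_a: float, tp_b: float, fp_b: float, r_fg: float
) -> Segment:
    if tp_b <= tp_a:
        raise ValueError("segment requires tp_A < tp_B")
    s = (fp_b - fp_a) / (tp_b - tp_a)
    return Segment(
        a=1.0 + s,
        b=(fp_a - s * tp_a) / r_fg,
        pA=tp_a / r_fg,
        pB=tp_b / r_fg,
    )


def segment_auc(B: ConfusionMatrix, A: ConfusionMatrix, r_fg: float) -> float:
    """Closed-form area under one PR-curve piece from recall of A up to B.

    A is the lower-recall point (tp_A < tp_B); fp may not decrease from A
    to B.  Both matrices must originate from the same sample, whose total
    foreground weight is ``r_fg``.
    """
    if A.tp >= B.tp:
        raise ValueError("tp_A >= tp_B: zero-recall-width pair, caller must skip")
    if B.fp < A.fp - 1e-12:
        raise ValueError("fp must be non-decreasing from A to B")
    return _make_segment(A.tp, A.fp, B.tp, B.fp, r_fg).area()


def auc_pr_continuous(points: SupportingPoints) -> CurveResult:
    """AUC-PR by exact piecewise integration of the hyperbolic precision.

    Walks adjacent supporting-point pairs; pairs with equal tp bound a
    vertical PR segment of zero area but still advance the anchor, so the
    curve's lower envelope is preserved.  Valid for weighted and
    unweighted data.
    """
    r_fg = points.r_fg
    if r_fg <= 0:
        raise InputError("no foreground mass; AUC-PR undefined")
    auc = 0.0
    n_segments = 0
    tp, fp = points.tp, points.fp
    for i in range(len(points) - 1):
        if tp[i + 1] > tp[i]:
            auc += _make_segment(tp[i], fp[i], tp[i + 1], fp[i + 1], r_fg).area()
            n_segments += 1
    auc = min(max(auc, 0.0), 1.0)
    return CurveResult(
        kind="pr",
        method="continuous",
        auc=auc,
        points=curve_points(points, "pr"),
        n_segments=n_segments,
    )


def _require_integral(points: SupportingPoints) -> None:
    if not points.entries_are_integral:
        raise InputError(
            "discrete interpolation undefined for weighted data: confusion-matrix "
            "entries are not integers, so there is no natural unit step"
        )


def _expand_discrete(
    points: SupportingPoints, along: Literal["tp", "fp"]
) -> list[tuple[float, float]]:
    """Supporting points plus intermediate points at unit steps of tp or fp."""
    out: list[tuple[float, float]] = [(float(points.tp[0]), float(points.fp[0]))]
    for i in range(len(points) - 1):
        tp_a, fp_a = float(points.tp[i]), float(points.fp[i])
        tp_b, fp_b = float(points.tp[i + 1]), float(points.fp[i + 1])
        d_tp, d_fp = tp_b - tp_a, fp_b - fp_a
        span = d_tp if along == "tp" else d_fp
        n_steps = int(round(span))
        for x in range(1, n_steps):
            frac = x / n_steps
            out.append((tp_a + frac * d_tp, fp_a + frac * d_fp))
        out.append((tp_b, fp_b))
    return out


def _trapezoid_pr(
    expanded: list[tuple[float, float]], r_fg: float
) -> tuple[float, list[tuple[float, float]]]:
    """Trapezoidal area over (recall, precision) of an expanded point list.

    The tp = 0 points themselves have undefined precision and are dropped;
    integration still starts at recall 0 by anchoring with the limiting
    precision there (0 if false positives accrue before the first true
    positive, else the constant precision of the initial ray from the
    origin), matching the continuous interpolation's limit.
    """
    first = next(i for i, (tp, _) in enumerate(expanded) if tp > 0)
    tp0, fp0 = expanded[first]
    _, fp_prev = expanded[first - 1]
    limit = 0.0 if fp_prev > 0 else tp0 / (tp0 + fp0)
    pr = [(0.0, limit)] + [
        (tp / r_fg, tp / (tp + fp)) for tp, fp in expanded[first:]
    ]
    recall = np.array([r for r, _ in pr])
    prec = np.array([p for _, p in pr])
    return float(np.trapezoid(prec, recall)), pr


def _auc_pr_discrete(
    points: SupportingPoints, along: Literal["tp", "fp"]
) -> CurveResult:
    r_fg = points.r_fg
    if r_fg <= 0:
        raise InputError("no foreground mass; AUC-PR undefined")
    _require_integral(points)
    expanded = _expand_discrete(points, along)
    auc, pr = _trapezoid_pr(expanded, r_fg)
    return CurveResult(
        kind="pr",
        method="discrete_tp" if along == "tp" else "discrete_fp",
        auc=min(max(auc, 0.0), 1.0),
        points=pr,
        n_segments=len(points) - 1,
    )


def auc_pr_discrete_tp(points: SupportingPoints) -> CurveResult:
    """Davis-Goadrich AUC-PR: unit steps of tp, fp interpolated linearly."""
    return _auc_pr_discrete(points, "tp")


def auc_pr_discrete_fp(points: SupportingPoints) -> CurveResult:
    """AUC-PR with unit steps of fp and tp interpolated linearly."""
    return _auc_pr_discrete(points, "fp")


def auc_roc(points: SupportingPoints) -> CurveResult:
    """Trapezoidal AUC-ROC; exact because ROC interpolation is linear."""
    if points.r_fg <= 0:
        raise InputError("no foreground mass; TPR undefined")
    if points.w_bg_total <= 0:
        raise InputError("no background mass; FPR undefined")
    roc = curve_points(points, "roc")
    fpr = np.array([x for x, _ in roc])
    tpr = np.array([y for _, y in roc])
    auc = float(np.trapezoid(tpr, fpr))
    return CurveResult(
        kind="roc",
        method="trapezoid",
        auc=min(max(auc, 0.0), 1.0),
        points=roc,
        n_segments=len(points) - 1,
    )


def dense_pr_curve(
    points: SupportingPoints, per_segment: int = 20
) -> list[tuple[float, float]]:
    """PR curve sampled on the continuous interpolation, for plotting.

    Each tp-increasing segment is split into ``per_segment`` equal recall
    intervals and the hyperbola evaluated at the interior points as well
    as at every supporting point; ``per_segment = 1`` returns supporting
    points only.  Vertical (equal-recall) segments contribute both
    endpoints.
    """
    if per_segment < 1:
        raise ValueError("per_segment must be >= 1")
    r_fg = points.r_fg
    if r_fg <= 0:
        raise InputError("no foreground mass")
    tp, fp = points.tp, points.fp
    out: list[tuple[float, float]] = []
    for i in range(len(points) - 1):
        if tp[i + 1] > tp[i]:
            seg = _make_segment(tp[i], fp[i], tp[i + 1], fp[i + 1], r_fg)
            ps = np.linspace(seg.pA, seg.pB, per_segment + 1)
            if not out and tp[i] + fp[i] > 0:
                out.append((seg.pA, float(seg.precision(seg.pA))))
            for p in ps[1:]:
                out.append((float(p), float(seg.precision(float(p)))))
        elif tp[i + 1] + fp[i + 1] > 0:
            r = float(tp[i + 1] / r_fg)
            out.append((r, float(tp[i + 1] / (tp[i + 1] + fp[i + 1]))))
    return out
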