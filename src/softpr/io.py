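"""Tab-separated input/output for score tables and curves.

Input dialects
--------------
weighted:    ``score<TAB>w_fg<TAB>w_bg``
unweighted:  ``score<TAB>label`` with label in {fg, bg, 1, 0}

Lines starting with ``#`` are comments.  Curve output carries its
metadata (kind, method, auc, seed, version) in ``# key: value`` header
comments and numbers with 17 significant digits, so a write/read
round-trip is exact for double precision.
"""

from __future__ import annotations

import os
from typing import Literal

import pandas as pd

from softpr.core import InputError, SupportingPoints, WeightedSample, load_sample
from softpr.interpolate import CurveResult

__all__ = ["read_sample", "read_table", "write_curve", "read_curve", "write_supporting_curve"]

_FMT = "%.17g"


def read_table(path: str | os.PathLike) -> pd.DataFrame:
    """Read a TSV with ``#`` comments into a DataFrame."""
    try:
        return pd.read_csv(path, sep="\t", comment="#", float_precision="round_trip")
    except FileNotFoundError:
        raise
    except Exception as e:  # malformed table
        raise InputError(f"cannot parse {path}: {e}") from e


def read_sample(
    path: str | os.PathLike, mode: Literal["weighted", "unweighted"] = "weighted"
) -> WeightedSample:
    """Read and validate a score table (see module docstring for dialects)."""
    return load_sample(read_table(path), mode=mode)


def _axis_names(kind: str) -> tuple[str, str]:
    return ("recall", "precision") if kind == "pr" else ("fpr", "tpr")


def write_curve(curve: CurveResult, path: str | os.PathLike, seed: int | None = None) -> None:
    """Write a curve as TSV with metadata header comments."""
    from softpr import __version__

    xname, yname = _axis_names(curve.kind)
    with open(path, "w") as fh:
        fh.write(f"# softpr version: {__version__}\n")
        fh.write(f"# kind: {curve.kind}\n")
        fh.write(f"# method: {curve.method}\n")
        fh.write(f"# auc: {_FMT % curve.auc}\n")
        fh.write(f"# n_segments: {curve.n_segments}\n")
        if seed is not None:
            fh.write(f"# seed: {seed}\n")
        fh.write(f"{xname}\t{yname}\n")
        for x, y in curve.points:
            fh.write(f"{_FMT % x}\t{_FMT % y}\n")


def read_curve(path: str | os.PathLike) -> pd.DataFrame:
    """Read back a curve TSV written by :func:`write_curve`."""
    return read_table(path)


def write_supporting_curve(
    points: SupportingPoints,
    kind: Literal["pr", "roc"],
    path: str | os.PathLike,
) -> None:
    """Write supporting points as ``threshold<TAB>x<TAB>y`` TSV.

    The PR curve omits the sentinel point (undefined precision); the ROC
    curve includes it as (0, 0).
    """
    from softpr import __version__
    from softpr.core import curve_points

    xname, yname = _axis_names(kind)
    xy = curve_points(points, kind)
    thresholds = points.thresholds if kind == "roc" else points.thresholds[-len(xy):]
    with open(path, "w") as fh:
        fh.write(f"# softpr version: {__version__}\n")
        fh.write(f"# kind: {kind}\n")
        fh.write(f"threshold\t{xname}\t{yname}\n")
        for t, (x, y) in zip(thresholds, xy):
            fh.write(f"{_FMT % t}\t{_FMT % x}\t{_FMT % y}\n")
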