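"""Small packaged datasets used in the documentation and tests."""

from __future__ import annotations

from importlib import resources

import pandas as pd

from softpr.core import WeightedSample, load_sample

__all__ = ["worked_example_table", "worked_example_weighted", "worked_example_unweighted"]


def worked_example_table() -> pd.DataFrame:
    """The packaged six-point example: score, hard label, soft weights."""
    with resources.files("softpr.data").joinpath("worked_example.tsv").open() as fh:
        return pd.read_csv(fh, sep="\t", comment="#")


def worked_example_weighted() -> WeightedSample:
    """The six-point example with its soft weights."""
    return load_sample(worked_example_table(), mode="weighted")


def worked_example_unweighted() -> WeightedSample:
    """The six-point example with hard labels only."""
    return load_sample(worked_example_table(), mode="unweighted")
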