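"""Core in-memory containers shared across pipeline stages."""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

#: Canonical column order of the sample design table (structure of a paired
#: activated/control dissection design: one activated and one control sample
#: per individual per experiment).
DESIGN_COLUMNS = ["sample_id", "experiment", "hemisphere", "condition", "individual"]


@dataclass
class CountMatrix:
    """Raw contig x sample counts plus per-contig effective lengths.

    Parameters
    ----------
    counts
        Integer count matrix, rows indexed by contig id, columns by sample id.
    lengths
        Effective length (nt) per contig, indexed like ``counts``.
    """

    counts: pd.DataFrame
    lengths: pd.Series

    def __post_init__(self) -> None:
        if self.counts.columns.duplicated().any():
            raise ValueError("duplicate sample ids")
        if self.counts.index.duplicated().any():
            raise ValueError("duplicate contig ids")
        if (np.asarray(self.counts) < 0).any():
            raise ValueError("negative counts")
        self.lengths = self.lengths.reindex(self.counts.index)
        if self.lengths.isna().any():
            raise ValueError("missing effective length for some contigs")
        if (self.lengths <= 0).any():
            raise ValueError("effective lengths must be strictly positive")

    @property
    def contig_ids(self) -> pd.Index:
        return self.counts.index

    @property
    def sample_ids(self) -> pd.Index:
        return self.counts.columns

    def subset_contigs(self, contig_ids) -> "CountMatrix":
        return CountMatrix(self.counts.loc[contig_ids], self.lengths.loc[contig_ids])

    def subset_samples(self, sample_ids) -> "CountMatrix":
        return CountMatrix(self.counts[list(sample_ids)], self.lengths)

    def library_sizes(self) -> pd.Series:
        return self.counts.sum(axis=0)


def samples_for(design: pd.DataFrame, experiment: str | None = None,
                condition: str | None = None) -> list[str]:
    """Sample ids matching an experiment and/or condition in a design table."""
    mask = pd.Series(True, index=design.index)
    if experiment is not None:
        mask &= design["experiment"] == experiment
    if condition is not None:
        mask &= design["condition"] == condition
    return design.loc[mask, "sample_id"].tolist()
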