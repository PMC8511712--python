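"""Shared tabular containers for the pipeline."""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd


@dataclass
class ContigTable:
    """Per-contig lengths, fragment counts and annotations.

    Attributes
    ----------
    lengths:
        Series indexed by contig_id, length in bp (> 0).
    counts:
        DataFrame contig_id x sample_id of non-negative integer fragment
        counts; the sample set is identical for every contig.
    annotations:
        DataFrame indexed by contig_id with columns ``taxon_id`` and
        ``gene_family_id``; either may be null (NaN). Contigs without a
        taxon cannot join any bin but still count toward library totals.
    """

    lengths: pd.Series
    counts: pd.DataFrame
    annotations: pd.DataFrame

    def __post_init__(self) -> None:
        if not self.lengths.index.equals(self.counts.index):
            raise ValueError("lengths and counts must share the contig index")
        if not self.annotations.index.equals(self.counts.index):
            raise ValueError("annotations and counts must share the contig index")
        if (self.lengths <= 0).any():
            raise ValueError("contig lengths must be positive")
        if (self.counts.to_numpy() < 0).any():
            raise ValueError("fragment counts must be non-negative")

    @property
    def sample_ids(self) -> list[str]:
        return list(self.counts.columns)

    @property
    def contig_ids(self) -> pd.Index:
        return self.counts.index


@dataclass
class BinAbundance:
    """Bin-denominated FPKM tensor, stored long-in-rows.

    ``values`` is a DataFrame with a 2-level index (bin taxon_id, unit) and
    one column per sample, where *unit* is a contig_id at contig level or a
    gene_family_id after functional aggregation. ``m_bin`` holds the FPKM
    denominator M (total fragments mapped to the bin) per (bin, sample);
    (bin, sample) cells where M = 0 are flagged in ``zero_m``.
    """

    values: pd.DataFrame
    m_bin: pd.DataFrame
    level: str  # "contig" or "family"
    zero_m: set = field(default_factory=set)
    unannotated: pd.DataFrame | None = None

    @property
    def bins(self) -> list[str]:
        return list(self.values.index.get_level_values(0).unique())

    @property
    def sample_ids(self) -> list[str]:
        return list(self.values.columns)

    def bin_matrix(self, bin_id: str) -> pd.DataFrame:
        """units x samples matrix for one bin."""
        return self.values.xs(bin_id, level=0)

    def families_detected(self, bin_id: str) -> set[str]:
        """Gene families with at least one positive value in any sample."""
        if self.level != "family":
            raise ValueError("detection is defined on family-level abundances")
        mat = self.values.xs(bin_id, level=0)
        mask = (mat.to_numpy() > 0).any(axis=1)
        return set(np.asarray(mat.index)[mask])
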