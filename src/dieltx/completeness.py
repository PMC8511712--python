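"""Core gene-family sets and taxonomic-bin completeness.

Completeness of an environmental bin is scored against a "core" set of gene
families — families present in at least ~95% of reference proteomes
(a BUSCO-like yardstick). Bins are retained for downstream time-series
analysis only if they exceed a minimum number of detected families
(strictly more than 900 in the reference study design).
"""

from __future__ import annotations

from dataclasses import dataclass

import pandas as pd

from .containers import BinAbundance


@dataclass(frozen=True)
class CoreSet:
    gene_family_ids: frozenset[str]
    prevalence_threshold: float
    n_reference_taxa: int

    def __len__(self) -> int:
        return len(self.gene_family_ids)


@dataclass(frozen=True)
class BinCompleteness:
    taxon_id: str
    n_families_detected: int
    core_detected: int
    core_percent: float
    passes_filter: bool


def derive_core_set(
    presence_matrix: pd.DataFrame, prevalence_threshold: float = 0.95
) -> CoreSet:
    """Families present in >= threshold (inclusive) of reference taxa.

    ``presence_matrix`` is reference taxon x gene family, boolean/0-1.
    """
    if presence_matrix.shape[0] < 1 or presence_matrix.shape[1] < 1:
        raise ValueError("presence matrix must have at least one taxon and one family")
    prev = presence_matrix.astype(bool).mean(axis=0)
    core = frozenset(prev.index[prev >= prevalence_threshold])
    return CoreSet(
        gene_family_ids=core,
        prevalence_threshold=prevalence_threshold,
        n_reference_taxa=presence_matrix.shape[0],
    )


def presence_from_long(long: pd.DataFrame) -> pd.DataFrame:
    """Pivot a (ref_taxon_id, gene_family_id, present) frame to a matrix."""
    return (
        long.pivot(index="ref_taxon_id", columns="gene_family_id", values="present")
        .fillna(0)
        .astype(int)
    )


def score_bin(
    taxon_id: str,
    bin_families: set[str],
    core_set: CoreSet,
    min_families: int = 900,
) -> BinCompleteness:
    """core_percent = 100 * |bin families ∩ core| / |core|."""
    if len(core_set) == 0:
        raise ValueError("core set is empty")
    core_detected = len(bin_families & core_set.gene_family_ids)
    return BinCompleteness(
        taxon_id=taxon_id,
        n_families_detected=len(bin_families),
        core_detected=core_detected,
        core_percent=100.0 * core_detected / len(core_set),
        passes_filter=len(bin_families) > min_families,
    )


def score_all_bins(
    abund: BinAbundance, core_set: CoreSet, min_families: int = 900
) -> list[BinCompleteness]:
    """Score every bin of a family-level abundance tensor.

    A family counts as detected in a bin when it has a positive value in
    any sample (after daughter-node roll-up implied by bin construction).
    """
    return [
        score_bin(b, abund.families_detected(b), core_set, min_families)
        for b in abund.bins
    ]


def filter_bins(
    completeness: list[BinCompleteness], min_families: int = 900
) -> list[str]:
    """Bin ids with strictly more than ``min_families`` detected families."""
    return [c.taxon_id for c in completeness if c.n_families_detected > min_families]


def completeness_frame(completeness: list[BinCompleteness]) -> pd.DataFrame:
    return pd.DataFrame(
        [
            {
                "taxon_id": c.taxon_id,
                "n_families": c.n_families_detected,
                "core_detected": c.core_detected,
                "core_percent": c.core_percent,
                "passes_filter": c.passes_filter,
            }
            for c in completeness
        ]
    )
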