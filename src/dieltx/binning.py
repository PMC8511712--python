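"""Environmental taxon bins and bin-denominated FPKM.

A contig belongs to the bin of taxonomic node B (at a chosen rank) iff its
annotation is B itself or any descendant of B. Abundance is normalized to
fragments per kilobase per million (FPKM) where the "million" denominator M
is the total fragments mapped to the *bin* in that sample, not the whole
library:

    FPKM(c, s) = (fragments_cs / (length_c / 1000)) / (M_bin(c),s / 1e6)

M counts fragments of every contig in the bin, including contigs without a
gene-family annotation; those contigs are excluded from the family-level
tensor but reported in an "unannotated" total.
"""

from __future__ import annotations

import logging

import numpy as np
import pandas as pd

from .containers import BinAbundance, ContigTable
from .taxonomy import RANK_DEPTH, TaxonomyTree

logger = logging.getLogger(__name__)


def build_bins(
    contig_table: ContigTable, taxonomy: TaxonomyTree, target_rank: str
) -> dict[str, list[str]]:
    """Map each target-rank node with >=1 contig to its member contigs.

    Contigs whose taxon_id is missing from the taxonomy are counted and
    skipped with a warning; contigs annotated above the target rank join
    no bin at that rank.
    """
    if target_rank not in RANK_DEPTH:
        raise ValueError(f"unknown rank {target_rank!r}")
    bins: dict[str, list[str]] = {}
    n_unknown = 0
    ann = contig_table.annotations["taxon_id"]
    # cache ancestor lookups: many contigs share a taxon
    cache: dict[str, str | None] = {}
    for contig_id, taxon in ann.items():
        if pd.isna(taxon):
            continue
        if taxon not in cache:
            if taxon not in taxonomy:
                cache[taxon] = None
                n_unknown += 1
                logger.warning("contig taxon %r absent from taxonomy", taxon)
            else:
                cache[taxon] = taxonomy.ancestor_at_rank(taxon, target_rank)
        anc = cache[taxon]
        if anc is not None:
            bins.setdefault(anc, []).append(contig_id)
    if n_unknown:
        logger.warning("%d taxon ids were absent from the taxonomy", n_unknown)
    return {b: sorted(c) for b, c in sorted(bins.items())}


def compute_fpkm(contig_table: ContigTable, bins: dict[str, list[str]]) -> BinAbundance:
    """Contig-level FPKM with per-(bin, sample) denominators.

    (bin, sample) cells with M = 0 get FPKM 0 everywhere and are flagged
    in ``zero_m`` rather than producing NaN.
    """
    samples = contig_table.sample_ids
    value_frames = []
    m_rows = {}
    zero_m: set[tuple[str, str]] = set()
    for bin_id, contigs in bins.items():
        cnt = contig_table.counts.loc[contigs]
        m = cnt.sum(axis=0).astype(float)
        m_rows[bin_id] = m
        kb = contig_table.lengths.loc[contigs].to_numpy()[:, None] / 1000.0
        denom = m.to_numpy()[None, :] / 1e6
        with np.errstate(divide="ignore", invalid="ignore"):
            fpkm = (cnt.to_numpy() / kb) / denom
        zero_cols = denom[0] == 0
        if zero_cols.any():
            fpkm[:, zero_cols] = 0.0
            for s in np.asarray(samples)[zero_cols]:
                zero_m.add((bin_id, s))
        df = pd.DataFrame(fpkm, columns=samples)
        df.index = pd.MultiIndex.from_product(
            [[bin_id], contigs], names=["taxon_id", "contig_id"]
        )
        value_frames.append(df)
    values = (
        pd.concat(value_frames)
        if value_frames
        else pd.DataFrame(
            columns=samples,
            index=pd.MultiIndex.from_arrays([[], []], names=["taxon_id", "contig_id"]),
        )
    )
    m_bin = pd.DataFrame(m_rows).T
    m_bin.index.name = "taxon_id"
    if m_bin.empty:
        m_bin = pd.DataFrame(columns=samples)
    return BinAbundance(values=values, m_bin=m_bin, level="contig", zero_m=zero_m)


def aggregate_by_function(
    contig_abund: BinAbundance, annotations: pd.DataFrame
) -> BinAbundance:
    """Sum contig FPKM into (bin, gene family, sample) cells.

    Contigs without a gene_family_id are dropped from the tensor; their
    FPKM and contig counts are tallied per bin in ``unannotated``.
    """
    if contig_abund.level != "contig":
        raise ValueError("expected a contig-level BinAbundance")
    vals = contig_abund.values
    if vals.empty:
        fam_vals = pd.DataFrame(
            columns=vals.columns,
            index=pd.MultiIndex.from_arrays(
                [[], []], names=["taxon_id", "gene_family_id"]
            ),
        )
        return BinAbundance(
            values=fam_vals,
            m_bin=contig_abund.m_bin,
            level="family",
            zero_m=set(contig_abund.zero_m),
            unannotated=pd.DataFrame(columns=["n_contigs", "fpkm_total"]),
        )
    fam = annotations["gene_family_id"].reindex(vals.index.get_level_values("contig_id"))
    fam_values = fam.to_numpy()
    has_fam = ~pd.isna(fam_values)
    annotated = vals[has_fam].copy()
    annotated.index = pd.MultiIndex.from_arrays(
        [annotated.index.get_level_values("taxon_id"), fam_values[has_fam]],
        names=["taxon_id", "gene_family_id"],
    )
    fam_vals = annotated.groupby(level=[0, 1], sort=True).sum()

    dropped = vals[~has_fam]
    unannot = pd.DataFrame(
        {
            "n_contigs": dropped.groupby(level=0).size(),
            "fpkm_total": dropped.sum(axis=1).groupby(level=0).sum(),
        }
    ).fillna(0)
    return BinAbundance(
        values=fam_vals,
        m_bin=contig_abund.m_bin,
        level="family",
        zero_m=set(contig_abund.zero_m),
        unannotated=unannot,
    )


def rollup(
    abund: BinAbundance,
    taxonomy: TaxonomyTree,
    from_rank: str,
    to_rank: str,
) -> BinAbundance:
    """Integrate abundances up the taxonomy by summing descendant bins.

    Every input bin is mapped to its ancestor at ``to_rank`` (a bin already
    at that rank maps to itself, so directly assigned values are kept) and
    values are summed per (family, sample). M denominators are summed the
    same way. Bins with no ancestor at ``to_rank`` are dropped.
    """
    for r in (from_rank, to_rank):
        if r not in RANK_DEPTH:
            raise ValueError(f"unknown rank {r!r}")
    if RANK_DEPTH[to_rank] > RANK_DEPTH[from_rank]:
        raise ValueError(
            f"cannot roll up from {from_rank!r} to the deeper rank {to_rank!r}"
        )
    if to_rank == from_rank and all(
        taxonomy.rank.get(b) == to_rank for b in abund.bins
    ):
        return BinAbundance(
            values=abund.values.copy(),
            m_bin=abund.m_bin.copy(),
            level=abund.level,
            zero_m=set(abund.zero_m),
            unannotated=abund.unannotated,
        )
    mapping = {}
    for b in abund.bins:
        if b not in taxonomy:
            raise ValueError(f"bin {b!r} absent from taxonomy")
        mapping[b] = taxonomy.ancestor_at_rank(b, to_rank)
    vals = abund.values
    keep = vals.index.get_level_values(0).map(lambda b: mapping[b] is not None)
    kept = vals[np.asarray(keep)]
    new_bins = kept.index.get_level_values(0).map(mapping)
    kept = kept.copy()
    kept.index = pd.MultiIndex.from_arrays(
        [new_bins, kept.index.get_level_values(1)],
        names=vals.index.names,
    )
    new_vals = kept.groupby(level=[0, 1], sort=True).sum()

    m = abund.m_bin
    m_map = pd.Series({b: mapping[b] for b in m.index if mapping.get(b) is not None})
    new_m = m.loc[m_map.index].groupby(m_map).sum()
    new_m.index.name = "taxon_id"
    zero_m = {
        (mapping[b], s) for (b, s) in abund.zero_m if mapping.get(b) is not None
    }
    # a rolled-up (bin, sample) only stays flagged if *all* children were zero
    zero_m = {(b, s) for (b, s) in zero_m if new_m.loc[b, s] == 0}
    return BinAbundance(
        values=new_vals,
        m_bin=new_m,
        level=abund.level,
        zero_m=zero_m,
        unannotated=abund.unannotated,
    )


def quantify(
    contig_table: ContigTable, taxonomy: TaxonomyTree, rank: str = "genus"
) -> BinAbundance:
    """Convenience: bins at ``rank`` -> contig FPKM -> family aggregation."""
    bins = build_bins(contig_table, taxonomy, rank)
    contig_abund = compute_fpkm(contig_table, bins)
    return aggregate_by_function(contig_abund, contig_table.annotations)
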