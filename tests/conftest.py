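"""Shared fixtures: a tiny taxonomy, contig table and simulated community."""

from __future__ import annotations

import numpy as np
import pandas as pd
import pytest

from dieltx import ContigTable, GenusSpec, TaxonomyTree, default_design, make_design
from dieltx.simulate import simulate_study


@pytest.fixture(scope="session")
def design48():
    """The default 6 times x 4 days x 2 replicates field design."""
    return default_design()


@pytest.fixture(scope="session")
def design_small():
    """A 3 times x 1 day x 1 replicate design (3 samples)."""
    return make_design([0, 8, 16], n_days=1, n_replicates=1)


@pytest.fixture(scope="session")
def toy_taxonomy():
    """root -> lin1 -> cls1 -> ord1 -> (gA, gB); gA -> (spA1, spA2)."""
    return TaxonomyTree(
        parent={
            "root": "root",
            "lin1": "root",
            "cls1": "lin1",
            "ord1": "cls1",
            "gA": "ord1",
            "gB": "ord1",
            "spA1": "gA",
            "spA2": "gA",
        },
        rank={
            "root": "root",
            "lin1": "lineage",
            "cls1": "class",
            "ord1": "order",
            "gA": "genus",
            "gB": "genus",
            "spA1": "species",
            "spA2": "species",
        },
        name={},
        root="root",
    )


def _contig_table(rows, samples):
    """rows: list of (contig_id, length, taxon, family, counts per sample)."""
    ids = [r[0] for r in rows]
    lengths = pd.Series([r[1] for r in rows], index=ids)
    counts = pd.DataFrame([r[4] for r in rows], index=ids, columns=samples)
    ann = pd.DataFrame(
        {"taxon_id": [r[2] for r in rows], "gene_family_id": [r[3] for r in rows]},
        index=ids,
    )
    ann.index.name = counts.index.name = lengths.index.name = "contig_id"
    return ContigTable(lengths=lengths, counts=counts, annotations=ann)


@pytest.fixture(scope="session")
def toy_contigs():
    """Six contigs over two samples exercising species/genus/null annotation."""
    samples = ["s1", "s2"]
    rows = [
        ("c1", 1000, "spA1", "K00001", [10, 0]),
        ("c2", 500, "spA2", "K00001", [3, 4]),
        ("c3", 2000, "gA", "K00002", [7, 0]),
        ("c4", 1000, "gA", None, [5, 5]),  # annotated taxon, no family
        ("c5", 1000, "gB", "K00002", [2, 6]),
        ("c6", 300, None, "K00003", [9, 9]),  # no taxon: joins no bin
    ]
    return _contig_table(rows, samples)


@pytest.fixture(scope="session")
def make_contig_table():
    return _contig_table


@pytest.fixture(scope="session")
def small_study(design48):
    """A 3-genus community with pathways, planting and a reference matrix."""
    specs = [
        GenusSpec(taxon_id=f"g{i + 1:03d}", n_gene_families=60, diel_fraction=0.2)
        for i in range(3)
    ]
    return simulate_study(
        design48,
        specs,
        seed=42,
        n_pathways=6,
        pathway_size_range=(5, 12),
        planted_enrichments=[("g001", "pw002", 6.0)],
        n_reference_taxa=40,
        core_fraction=0.1,
        non_core_prevalence=0.5,
    )


@pytest.fixture(scope="session")
def rng():
    return np.random.default_rng(20240615)
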