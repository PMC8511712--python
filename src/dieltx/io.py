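"""Readers and writers for the pipeline's flat-file dialects.

All tables are tab-delimited UTF-8 with a header row and no quoting:

* counts.tsv           contig_id, length_bp, <one integer column per sample>
* annotations.tsv      contig_id, taxon_id, gene_family_id ('' when absent)
* taxonomy.tsv         taxon_id, parent_id, rank, name (NCBI nodes-like)
* samples.tsv          sample_id, day, hour, replicate
* pathways.tsv         pathway_id, gene_family_id
* reference_presence.tsv  ref_taxon_id, gene_family_id, present in {0,1}
* truth.json           the simulation truth ledger
"""

from __future__ import annotations

from pathlib import Path

import pandas as pd

from .containers import BinAbundance, ContigTable
from .design import SamplingDesign, make_design
from .simulate import SimulatedStudy, TruthLedger
from .taxonomy import TaxonomyTree

_TSV = dict(sep="\t", index=False)


def write_study(study: SimulatedStudy, out_dir: str | Path) -> dict[str, Path]:
    """Write every input table of a simulated study; returns the paths."""
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    paths = {k: out / f"{k}.tsv" for k in
             ("counts", "annotations", "taxonomy", "samples", "pathways",
              "reference_presence")}
    counts = study.contigs.counts.copy()
    counts.insert(0, "length_bp", study.contigs.lengths)
    counts.insert(0, "contig_id", counts.index)
    counts.to_csv(paths["counts"], **_TSV)

    ann = study.contigs.annotations.reset_index()
    ann.to_csv(paths["annotations"], **_TSV, na_rep="")
    study.taxonomy.to_csv(paths["taxonomy"], **_TSV)
    study.samples.to_csv(paths["samples"], **_TSV)
    study.pathways.to_csv(paths["pathways"], **_TSV)
    study.reference_presence.to_csv(paths["reference_presence"], **_TSV)
    study.ledger.to_json(out / "truth.json")
    paths["truth"] = out / "truth.json"
    return paths


def read_contig_table(counts_path: str | Path, annotations_path: str | Path) -> ContigTable:
    counts = pd.read_csv(counts_path, sep="\t", dtype={"contig_id": str})
    counts = counts.set_index("contig_id")
    lengths = counts.pop("length_bp")
    ann = pd.read_csv(
        annotations_path, sep="\t", dtype={"contig_id": str, "taxon_id": str, "gene_family_id": str}
    ).set_index("contig_id")
    ann = ann.reindex(counts.index)
    return ContigTable(lengths=lengths, counts=counts, annotations=ann)


def read_taxonomy(path: str | Path) -> TaxonomyTree:
    df = pd.read_csv(path, sep="\t", dtype=str)
    return TaxonomyTree.from_frame(df)


def read_samples(path: str | Path) -> pd.DataFrame:
    return pd.read_csv(
        path, sep="\t", dtype={"sample_id": str, "day": int, "hour": float, "replicate": int}
    )


def design_from_samples(samples: pd.DataFrame, period_hours: float = 24.0) -> SamplingDesign:
    hours = sorted(samples["hour"].unique())
    n_days = samples["day"].nunique()
    n_replicates = samples["replicate"].nunique()
    design = make_design(hours, n_days, n_replicates, period_hours)
    if set(design.sample_names) != set(samples["sample_id"]):
        raise ValueError("samples.tsv does not enumerate a full factorial design")
    return design


def read_pathways(path: str | Path) -> pd.DataFrame:
    return pd.read_csv(path, sep="\t", dtype=str)


def read_reference_presence(path: str | Path) -> pd.DataFrame:
    return pd.read_csv(
        path, sep="\t", dtype={"ref_taxon_id": str, "gene_family_id": str, "present": int}
    )


def read_truth(path: str | Path) -> TruthLedger:
    return TruthLedger.from_json(path)


def write_bin_abundance(abund: BinAbundance, out_dir: str | Path) -> dict[str, Path]:
    """bin_fpkm.tsv (taxon_id, gene_family_id, <samples>) and bin_totals.tsv."""
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    fpkm_path = out / "bin_fpkm.tsv"
    vals = abund.values.reset_index()
    vals.to_csv(fpkm_path, **_TSV)
    totals = abund.m_bin.stack().rename("m_bin").reset_index()
    totals.columns = ["taxon_id", "sample_id", "m_bin"]
    totals_path = out / "bin_totals.tsv"
    totals.to_csv(totals_path, **_TSV)
    return {"bin_fpkm": fpkm_path, "bin_totals": totals_path}


def read_bin_abundance(fpkm_path: str | Path, totals_path: str | Path) -> BinAbundance:
    vals = pd.read_csv(fpkm_path, sep="\t", dtype={"taxon_id": str, "gene_family_id": str})
    vals = vals.set_index(["taxon_id", "gene_family_id"])
    totals = pd.read_csv(totals_path, sep="\t", dtype={"taxon_id": str, "sample_id": str})
    m_bin = totals.pivot(index="taxon_id", columns="sample_id", values="m_bin")
    m_bin = m_bin[list(vals.columns)]
    m_bin.columns.name = None
    zero_m = {
        (b, s) for b in m_bin.index for s in m_bin.columns if m_bin.loc[b, s] == 0
    }
    return BinAbundance(values=vals, m_bin=m_bin, level="family", zero_m=zero_m)
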