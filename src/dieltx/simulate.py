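"""Synthetic diel metatranscriptome generator.

Every table the pipeline consumes — contig counts, annotations, taxonomy,
sample metadata, pathway membership, reference presence — is generated here
from explicit parameters and a seed, together with a truth ledger recording
which gene families are truly diel (and their peak hour), which
(taxon, pathway, hour) triples were planted as enriched, and which families
are core. Truly diel families follow a 24-h cosine in expectation,

    E[count at hour t] = base_mean * (1 + a * cos(2*pi*(t - phi)/period)),

with negative-binomial noise (var = mu + dispersion * mu^2); non-diel
families have flat expectation. Replicates and days are independent draws.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from .containers import ContigTable
from .design import SamplingDesign
from .taxonomy import TaxonomyTree


@dataclass(frozen=True)
class GenusSpec:
    """Parameters of one simulated genus-level taxon.

    amplitude is the relative cosine amplitude (must be <= 1 so the
    expectation stays non-negative); nb_dispersion is the quadratic
    overdispersion coefficient (var = mu + d*mu^2); base_mean is the
    expected fragment count per gene family per sample.
    """

    taxon_id: str
    n_gene_families: int
    diel_fraction: float = 0.0
    peak_phase_distribution: dict[float, float] | None = None
    amplitude: float = 1.0
    base_mean: float = 100.0
    nb_dispersion: float = 0.3
    n_contigs_per_family: int = 2
    contig_length_range: tuple[int, int] = (300, 3000)

    def __post_init__(self) -> None:
        if not 0.0 <= self.diel_fraction <= 1.0:
            raise ValueError("diel_fraction must be in [0, 1]")
        if self.amplitude < 0:
            raise ValueError("amplitude must be >= 0")
        if self.amplitude > 1:
            raise ValueError(
                f"amplitude {self.amplitude} makes the expected count negative "
                "at the trough; must be <= 1"
            )
        if self.nb_dispersion <= 0:
            raise ValueError("nb_dispersion must be > 0")
        if self.n_contigs_per_family < 1:
            raise ValueError("n_contigs_per_family must be >= 1")
        if self.n_gene_families < 1:
            raise ValueError("n_gene_families must be >= 1")


@dataclass
class TruthLedger:
    """Ground truth for a simulated study.

    families: one row per generated (taxon_id, gene_family_id) with
        is_diel, true_peak_hour (NaN when not diel) and amplitude.
    enrichments: planted (taxon_id, pathway_id, hour) triples.
    core: per gene_family_id, whether it was planted as core.
    hours: the sampling hours diel peaks are drawn from.
    """

    families: pd.DataFrame
    enrichments: pd.DataFrame = field(
        default_factory=lambda: pd.DataFrame(
            columns=["taxon_id", "pathway_id", "hour", "is_enriched"]
        )
    )
    core: dict[str, bool] = field(default_factory=dict)
    hours: tuple[float, ...] = ()

    def diel_lookup(self) -> pd.DataFrame:
        return self.families.set_index(["taxon_id", "gene_family_id"])

    def to_json(self, path: str | Path) -> None:
        payload = {
            "hours": list(self.hours),
            "families": self.families.to_dict(orient="list"),
            "enrichments": self.enrichments.to_dict(orient="list"),
            "core": self.core,
        }
        Path(path).write_text(json.dumps(payload, indent=1, sort_keys=True))

    @classmethod
    def from_json(cls, path: str | Path) -> "TruthLedger":
        payload = json.loads(Path(path).read_text())
        return cls(
            families=pd.DataFrame(payload["families"]),
            enrichments=pd.DataFrame(
                payload["enrichments"],
                columns=["taxon_id", "pathway_id", "hour", "is_enriched"],
            ),
            core={k: bool(v) for k, v in payload["core"].items()},
            hours=tuple(payload["hours"]),
        )


def gene_family_ids(n: int) -> list[str]:
    """Shared gene-family universe: K00001, K00002, ..."""
    return [f"K{i:05d}" for i in range(1, n + 1)]


def plan_community(
    design: SamplingDesign, genus_specs: list[GenusSpec], seed: int
) -> TruthLedger:
    """Draw the diel truth (flags, peak hours) for every (taxon, family)."""
    rng = np.random.default_rng([int(seed), 101])
    hours = np.array(design.times_of_day)
    rows = []
    for spec in genus_specs:
        fams = gene_family_ids(spec.n_gene_families)
        n_diel = int(round(spec.diel_fraction * spec.n_gene_families))
        diel_idx = set(
            rng.choice(spec.n_gene_families, size=n_diel, replace=False).tolist()
        )
        if spec.peak_phase_distribution is None:
            probs = np.full(len(hours), 1.0 / len(hours))
        else:
            probs = np.array([spec.peak_phase_distribution.get(h, 0.0) for h in hours])
            if probs.sum() <= 0:
                raise ValueError("peak_phase_distribution has no mass on design hours")
            probs = probs / probs.sum()
        for i, fam in enumerate(fams):
            diel = i in diel_idx
            rows.append(
                {
                    "taxon_id": spec.taxon_id,
                    "gene_family_id": fam,
                    "is_diel": diel,
                    "true_peak_hour": float(rng.choice(hours, p=probs))
                    if diel
                    else np.nan,
                    "amplitude": spec.amplitude if diel else 0.0,
                }
            )
    return TruthLedger(families=pd.DataFrame(rows), hours=tuple(design.times_of_day))


def _build_taxonomy(genus_specs: list[GenusSpec]) -> TaxonomyTree:
    """Nest genera under order/class/lineage nodes (2 children per node)."""
    parent = {"root": "root"}
    rank = {"root": "root"}
    name = {"root": "root"}
    genera = [s.taxon_id for s in genus_specs]
    n_orders = (len(genera) + 1) // 2
    n_classes = (n_orders + 1) // 2
    n_lineages = (n_classes + 1) // 2
    for i in range(n_lineages):
        nid = f"lin{i + 1}"
        parent[nid], rank[nid], name[nid] = "root", "lineage", nid
    for i in range(n_classes):
        nid = f"cls{i + 1}"
        parent[nid], rank[nid], name[nid] = f"lin{i // 2 + 1}", "class", nid
    for i in range(n_orders):
        nid = f"ord{i + 1}"
        parent[nid], rank[nid], name[nid] = f"cls{i // 2 + 1}", "order", nid
    for i, g in enumerate(genera):
        parent[g], rank[g], name[g] = f"ord{i // 2 + 1}", "genus", g
        for k in (1, 2):
            sid = f"{g}_sp{k}"
            parent[sid], rank[sid], name[sid] = g, "species", sid
    return TaxonomyTree(parent=parent, rank=rank, name=name, root="root")


def generate_community(
    design: SamplingDesign,
    genus_specs: list[GenusSpec],
    seed: int,
    ledger: TruthLedger | None = None,
    species_fraction: float = 0.3,
) -> tuple[ContigTable, pd.DataFrame, pd.DataFrame, TruthLedger]:
    """Generate contig counts, taxonomy and sample metadata for a community.

    If a pre-planted ``ledger`` is supplied (e.g. after pathway planting),
    counts are drawn to match its diel flags; otherwise a fresh truth is
    planned from the specs. A ``species_fraction`` of contigs is annotated
    one rank below the genus so bin construction exercises daughter nodes.
    Identical (seed, parameters) give identical outputs.
    """
    if not genus_specs:
        raise ValueError("genus_specs must be non-empty")
    if ledger is None:
        ledger = plan_community(design, genus_specs, seed)
    truth = ledger.diel_lookup()

    rng = np.random.default_rng([int(seed), 202])
    taxonomy = _build_taxonomy(genus_specs)
    sample_names = design.sample_names
    hours = np.array([s.hour for s in design.samples])

    frames_counts = []
    lengths_all = []
    annot_rows = []
    for spec in genus_specs:
        fams = gene_family_ids(spec.n_gene_families)
        nf, nc = spec.n_gene_families, spec.n_contigs_per_family
        sub = truth.loc[spec.taxon_id]
        is_diel = sub.loc[fams, "is_diel"].to_numpy(dtype=bool)
        peak = sub.loc[fams, "true_peak_hour"].to_numpy(dtype=float)
        amp = sub.loc[fams, "amplitude"].to_numpy(dtype=float)

        # waveform factor per (family, sample)
        wave = np.ones((nf, len(sample_names)))
        if is_diel.any():
            ph = peak[is_diel][:, None]
            a = amp[is_diel][:, None]
            wave[is_diel] = 1.0 + a * np.cos(
                2.0 * np.pi * (hours[None, :] - ph) / design.period_hours
            )
        lo, hi = spec.contig_length_range
        lengths = rng.integers(lo, hi + 1, size=(nf, nc))
        weights = lengths / lengths.sum(axis=1, keepdims=True)
        mu = spec.base_mean * wave[:, None, :] * weights[:, :, None]
        size = 1.0 / spec.nb_dispersion
        p = size / (size + mu)
        counts = rng.negative_binomial(size, p)

        contig_ids = [f"{spec.taxon_id}_f{i + 1}_c{j + 1}" for i in range(nf) for j in range(nc)]
        frames_counts.append(
            pd.DataFrame(
                counts.reshape(nf * nc, -1), index=contig_ids, columns=sample_names
            )
        )
        lengths_all.append(pd.Series(lengths.reshape(-1), index=contig_ids))
        # place some contigs at a species node under the genus
        at_species = rng.random(nf * nc) < species_fraction
        sp_choice = rng.integers(1, 3, size=nf * nc)
        for k, cid in enumerate(contig_ids):
            tax = (
                f"{spec.taxon_id}_sp{sp_choice[k]}" if at_species[k] else spec.taxon_id
            )
            annot_rows.append(
                {
                    "contig_id": cid,
                    "taxon_id": tax,
                    "gene_family_id": fams[k // nc],
                }
            )

    counts_df = pd.concat(frames_counts)
    lengths_s = pd.concat(lengths_all)
    annots = pd.DataFrame(annot_rows).set_index("contig_id")
    table = ContigTable(lengths=lengths_s, counts=counts_df, annotations=annots)

    samples_df = pd.DataFrame(
        {
            "sample_id": sample_names,
            "day": [s.day for s in design.samples],
            "hour": [s.hour for s in design.samples],
            "replicate": [s.replicate for s in design.samples],
        }
    )
    return table, taxonomy.to_frame(), samples_df, ledger


def generate_pathway_map(
    gene_family_universe: list[str],
    n_pathways: int,
    pathway_size_range: tuple[int, int],
    planted_enrichments: list[tuple[str, str, float]],
    seed: int,
    ledger: TruthLedger | None = None,
    planting_rate: float = 0.8,
) -> tuple[pd.DataFrame, TruthLedger]:
    """Draw pathway membership and plant (taxon, pathway, hour) enrichments.

    Pathways are random subsets of the gene-family universe (they may
    overlap). For each planted triple, the pathway's member families in
    that taxon are re-assigned diel status peaking at the planted hour with
    probability ``planting_rate``, which must exceed the background diel
    rate for the enrichment to be real; the ledger records the triple.
    Planting mutates the ledger, so call this *before* generating counts
    (see :func:`simulate_study`).
    """
    lo, hi = pathway_size_range
    if hi > len(gene_family_universe):
        raise ValueError(
            f"pathway size up to {hi} exceeds universe of {len(gene_family_universe)}"
        )
    if lo < 1 or lo > hi:
        raise ValueError("invalid pathway_size_range")
    rng = np.random.default_rng([int(seed), 303])
    universe = np.array(gene_family_universe)
    rows = []
    members: dict[str, list[str]] = {}
    for i in range(n_pathways):
        pid = f"pw{i + 1:03d}"
        size = int(rng.integers(lo, hi + 1))
        mem = rng.choice(universe, size=size, replace=False).tolist()
        members[pid] = mem
        rows.extend({"pathway_id": pid, "gene_family_id": f} for f in sorted(mem))
    pathways_df = pd.DataFrame(rows)

    if ledger is None:
        ledger = TruthLedger(
            families=pd.DataFrame(
                columns=["taxon_id", "gene_family_id", "is_diel", "true_peak_hour", "amplitude"]
            )
        )
    enr_rows = []
    fam = ledger.families
    for taxon, pid, hour in planted_enrichments:
        if pid not in members:
            raise ValueError(f"planted pathway {pid!r} was not generated")
        if not (fam["taxon_id"] == taxon).any():
            raise ValueError(f"planted taxon {taxon!r} not in truth ledger")
        if ledger.hours and float(hour) not in ledger.hours:
            raise ValueError(f"planted hour {hour!r} is not a sampling hour")
        mask = (fam["taxon_id"] == taxon) & fam["gene_family_id"].isin(members[pid])
        idx = fam.index[mask]
        hit = rng.random(len(idx)) < planting_rate
        sel = idx[hit]
        fam.loc[sel, "is_diel"] = True
        fam.loc[sel, "true_peak_hour"] = float(hour)
        # planted families need a non-zero amplitude to actually oscillate
        fam.loc[sel, "amplitude"] = fam.loc[sel, "amplitude"].where(
            fam.loc[sel, "amplitude"] > 0, 1.0
        )
        enr_rows.append(
            {"taxon_id": taxon, "pathway_id": pid, "hour": float(hour), "is_enriched": True}
        )
    ledger.enrichments = pd.DataFrame(
        enr_rows, columns=["taxon_id", "pathway_id", "hour", "is_enriched"]
    )
    return pathways_df, ledger


def generate_reference_presence(
    n_reference_taxa: int,
    n_gene_families: int,
    core_fraction: float,
    non_core_prevalence: float,
    seed: int,
    ledger: TruthLedger | None = None,
    core_prevalence_range: tuple[float, float] = (0.96, 1.0),
) -> tuple[pd.DataFrame, TruthLedger]:
    """Reference taxon x gene family presence matrix with a planted core set.

    Core families are present in ceil(q * n_taxa) reference taxa with q
    drawn from ``core_prevalence_range`` (>= 0.95 by construction);
    non-core families are present in exactly
    round(non_core_prevalence * n_taxa) taxa, so the planted core is
    recoverable at any threshold between the two prevalences.
    Returns a long-format frame (ref_taxon_id, gene_family_id, present).
    """
    if not 0.0 <= core_fraction <= 1.0:
        raise ValueError("core_fraction must be in [0, 1]")
    if not 0.0 <= non_core_prevalence <= 1.0:
        raise ValueError("non_core_prevalence must be in [0, 1]")
    if n_reference_taxa < 1:
        raise ValueError("need at least one reference taxon")
    rng = np.random.default_rng([int(seed), 404])
    fams = gene_family_ids(n_gene_families)
    n_core = int(round(core_fraction * n_gene_families))
    core_set = set(rng.choice(n_gene_families, size=n_core, replace=False).tolist())
    taxa = [f"ref{i + 1:04d}" for i in range(n_reference_taxa)]
    present = np.zeros((n_reference_taxa, n_gene_families), dtype=np.int8)
    for j in range(n_gene_families):
        if j in core_set:
            q = rng.uniform(*core_prevalence_range)
            k = min(n_reference_taxa, int(np.ceil(q * n_reference_taxa)))
        else:
            k = int(round(non_core_prevalence * n_reference_taxa))
        if k > 0:
            rows = rng.choice(n_reference_taxa, size=k, replace=False)
            present[rows, j] = 1
    matrix = pd.DataFrame(present, index=taxa, columns=fams)
    long = matrix.stack().rename("present").reset_index()
    long.columns = ["ref_taxon_id", "gene_family_id", "present"]

    if ledger is None:
        ledger = TruthLedger(
            families=pd.DataFrame(
                columns=["taxon_id", "gene_family_id", "is_diel", "true_peak_hour", "amplitude"]
            )
        )
    ledger.core = {f: (j in core_set) for j, f in enumerate(fams)}
    return long, ledger


@dataclass
class SimulatedStudy:
    """Every input table of one synthetic study plus its truth ledger."""

    contigs: ContigTable
    taxonomy: pd.DataFrame
    samples: pd.DataFrame
    pathways: pd.DataFrame
    reference_presence: pd.DataFrame
    ledger: TruthLedger
    design: SamplingDesign


def simulate_study(
    design: SamplingDesign,
    genus_specs: list[GenusSpec],
    seed: int,
    n_pathways: int = 20,
    pathway_size_range: tuple[int, int] = (10, 30),
    planted_enrichments: list[tuple[str, str, float]] | None = None,
    planting_rate: float = 0.8,
    n_reference_taxa: int = 366,
    core_fraction: float = 0.1,
    non_core_prevalence: float = 0.5,
) -> SimulatedStudy:
    """Orchestrate a full consistent simulation.

    Order matters: the diel truth is planned first, pathway planting then
    adjusts it, and only afterwards are counts drawn — so realized counts
    always reflect the final ledger.
    """
    ledger = plan_community(design, genus_specs, seed)
    universe = gene_family_ids(max(s.n_gene_families for s in genus_specs))
    pathways, ledger = generate_pathway_map(
        universe,
        n_pathways,
        pathway_size_range,
        planted_enrichments or [],
        seed,
        ledger=ledger,
        planting_rate=planting_rate,
    )
    contigs, taxonomy, samples, ledger = generate_community(
        design, genus_specs, seed, ledger=ledger
    )
    reference, ledger = generate_reference_presence(
        n_reference_taxa,
        len(universe),
        core_fraction,
        non_core_prevalence,
        seed,
        ledger=ledger,
    )
    return SimulatedStudy(
        contigs=contigs,
        taxonomy=taxonomy,
        samples=samples,
        pathways=pathways,
        reference_presence=reference,
        ledger=ledger,
        design=design,
    )
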