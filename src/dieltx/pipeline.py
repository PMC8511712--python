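"""Configuration, validation, and the end-to-end pipeline driver.

Stages run in order: simulate? -> bin quantification -> completeness filter
-> rhythmicity -> enrichment -> ordination. Every stage writes its table
under the output directory and the manifest records row counts, seeds and
the effective configuration. All randomness flows from one master seed via
named substreams so stages are individually reproducible.
"""

from __future__ import annotations

import dataclasses
import json
import logging
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from . import binning, completeness, enrichment, io, ordination, rhythm
from .design import SamplingDesign, make_design
from .simulate import GenusSpec, simulate_study
from .taxonomy import RANK_DEPTH

logger = logging.getLogger(__name__)

_STAGE_OFFSETS = {"simulate": 1, "rhythm": 2, "ordination": 3}


def substream_seed(master_seed: int, stage: str) -> int:
    """Deterministic per-stage seed below 2^31."""
    ss = np.random.SeedSequence([int(master_seed), _STAGE_OFFSETS.get(stage, 99)])
    return int(ss.generate_state(1)[0] & 0x7FFFFFFF)


@dataclass
class RunConfig:
    """Everything a run needs; serializable and echoed into the output."""

    out_dir: str = "run_out"
    seed: int = 0
    # sampling design
    times_of_day: list[float] = field(default_factory=lambda: [6, 10, 14, 18, 22, 2])
    n_days: int = 4
    n_replicates: int = 2
    period_hours: float = 24.0
    # simulation (used when simulate=True, otherwise inputs are read)
    simulate: bool = True
    input_dir: str | None = None
    n_genera: int = 6
    n_gene_families: int = 200
    diel_fraction: float = 0.2
    amplitude: float = 1.0
    base_mean: float = 100.0
    nb_dispersion: float = 0.3
    n_contigs_per_family: int = 2
    n_pathways: int = 20
    pathway_size_min: int = 10
    pathway_size_max: int = 30
    n_reference_taxa: int = 366
    core_fraction: float = 0.1
    non_core_prevalence: float = 0.5
    # thresholds
    rank: str = "genus"
    core_prevalence: float = 0.95
    min_families: int = 900
    alpha: float = 0.05
    n_perm: int = 10000
    prevalence: float = 0.05
    k: int = 3
    trymax: int = 100
    per_bin_k: int = 2
    enrichment_mode: str = "peak"  # or "any"
    bh_scope: str = "global"  # or "per_bin"
    combine: str = "maxt"  # or "bonferroni"
    run_nmds: bool = True
    run_per_bin_nmds: bool = False

    def validate(self) -> None:
        if self.rank not in RANK_DEPTH:
            raise ValueError(f"unknown rank {self.rank!r}")
        if not self.simulate and self.input_dir is None:
            raise ValueError("input_dir is required when simulate=False")
        if self.enrichment_mode not in ("peak", "any"):
            raise ValueError("enrichment_mode must be 'peak' or 'any'")
        if self.bh_scope not in ("global", "per_bin"):
            raise ValueError("bh_scope must be 'global' or 'per_bin'")

    def design(self) -> SamplingDesign:
        return make_design(
            self.times_of_day, self.n_days, self.n_replicates, self.period_hours
        )

    @classmethod
    def from_yaml(cls, path: str | Path) -> "RunConfig":
        data = yaml.safe_load(Path(path).read_text()) or {}
        known = {f.name for f in dataclasses.fields(cls)}
        unknown = set(data) - known
        if unknown:
            raise ValueError(f"unknown config keys: {sorted(unknown)}")
        return cls(**data)

    def to_yaml(self, path: str | Path) -> None:
        Path(path).write_text(yaml.safe_dump(dataclasses.asdict(self), sort_keys=True))


def validate_inputs(paths: dict[str, str | Path]) -> list[dict]:
    """Schema and referential-integrity checks; returns machine-readable issues."""
    issues: list[dict] = []

    def issue(table: str, message: str, **context) -> None:
        issues.append({"table": table, "message": message, **context})

    required_cols = {
        "annotations": ["contig_id", "taxon_id", "gene_family_id"],
        "taxonomy": ["taxon_id", "parent_id", "rank", "name"],
        "samples": ["sample_id", "day", "hour", "replicate"],
        "pathways": ["pathway_id", "gene_family_id"],
        "reference_presence": ["ref_taxon_id", "gene_family_id", "present"],
    }
    frames: dict[str, pd.DataFrame] = {}
    for name in ("counts", "annotations", "taxonomy", "samples", "pathways", "reference_presence"):
        path = paths.get(name)
        if path is None or not Path(path).exists():
            issue(name, "file missing", path=str(path))
            continue
        frames[name] = pd.read_csv(path, sep="\t", dtype=str)
        for col in required_cols.get(name, []):
            if col not in frames[name].columns:
                issue(name, f"missing column {col!r}")

    if "counts" in frames:
        cdf = frames["counts"]
        if "contig_id" not in cdf.columns or "length_bp" not in cdf.columns:
            issue("counts", "missing contig_id/length_bp columns")
        else:
            sample_cols = [c for c in cdf.columns if c not in ("contig_id", "length_bp")]
            if "samples" in frames and "sample_id" in frames["samples"]:
                known = set(frames["samples"]["sample_id"])
                for c in sample_cols:
                    if c not in known:
                        issue("counts", "count column not in samples.tsv", column=c)
                for s in known - set(sample_cols):
                    issue("samples", "sample has no count column", sample_id=s)
            lengths = pd.to_numeric(cdf["length_bp"], errors="coerce")
            if (lengths <= 0).any() or lengths.isna().any():
                bad = cdf.loc[(lengths <= 0) | lengths.isna(), "contig_id"].tolist()[:5]
                issue("counts", "non-positive contig lengths", contig_ids=bad)

    if "annotations" in frames and "taxonomy" in frames and "taxon_id" in frames["taxonomy"]:
        known_taxa = set(frames["taxonomy"]["taxon_id"])
        ann = frames["annotations"]
        if "taxon_id" in ann.columns:
            bad = ann[ann["taxon_id"].notna() & ~ann["taxon_id"].isin(known_taxa)]
            for _, r in bad.head(20).iterrows():
                issue(
                    "annotations",
                    "taxon_id absent from taxonomy",
                    contig_id=r.get("contig_id"),
                    taxon_id=r["taxon_id"],
                )

    if "pathways" in frames and "annotations" in frames:
        fams = set(frames["annotations"]["gene_family_id"].dropna())
        unknown = set(frames["pathways"]["gene_family_id"]) - fams
        if unknown:
            issue(
                "pathways",
                "pathway references gene families never annotated",
                n=len(unknown),
            )

    if "reference_presence" in frames:
        pres = set(frames["reference_presence"]["present"].unique())
        if not pres <= {"0", "1"}:
            issue("reference_presence", "present values outside {0,1}", values=sorted(pres))
    return issues


def run_pipeline(config: RunConfig) -> dict:
    """Run all stages; returns the manifest (also written to manifest.json)."""
    config.validate()
    out = Path(config.out_dir)
    out.mkdir(parents=True, exist_ok=True)
    config.to_yaml(out / "config.yaml")
    design = config.design()
    manifest: dict = {"stages": {}, "seed": config.seed}

    # --- inputs -----------------------------------------------------------
    if config.simulate:
        sim_seed = substream_seed(config.seed, "simulate")
        specs = [
            GenusSpec(
                taxon_id=f"g{i + 1:03d}",
                n_gene_families=config.n_gene_families,
                diel_fraction=config.diel_fraction,
                amplitude=config.amplitude,
                base_mean=config.base_mean,
                nb_dispersion=config.nb_dispersion,
                n_contigs_per_family=config.n_contigs_per_family,
            )
            for i in range(config.n_genera)
        ]
        study = simulate_study(
            design,
            specs,
            sim_seed,
            n_pathways=config.n_pathways,
            pathway_size_range=(config.pathway_size_min, config.pathway_size_max),
            n_reference_taxa=config.n_reference_taxa,
            core_fraction=config.core_fraction,
            non_core_prevalence=config.non_core_prevalence,
        )
        input_dir = out / "inputs"
        paths = io.write_study(study, input_dir)
        manifest["stages"]["simulate"] = {
            "seed": sim_seed,
            "n_contigs": int(len(study.contigs.contig_ids)),
            "n_samples": int(len(study.samples)),
        }
    else:
        input_dir = Path(config.input_dir)
        paths = {
            k: input_dir / f"{k}.tsv"
            for k in ("counts", "annotations", "taxonomy", "samples", "pathways", "reference_presence")
        }

    issues = validate_inputs(paths)
    if issues:
        raise RuntimeError(f"input validation failed with {len(issues)} issue(s): {issues[:3]}")

    contigs = io.read_contig_table(paths["counts"], paths["annotations"])
    taxonomy = io.read_taxonomy(paths["taxonomy"])
    samples = io.read_samples(paths["samples"])
    design = io.design_from_samples(samples, config.period_hours)
    logger.info("inputs: %d contigs x %d samples", len(contigs.contig_ids), len(samples))

    # --- bin quantification ----------------------------------------------
    abund = binning.quantify(contigs, taxonomy, config.rank)
    io.write_bin_abundance(abund, out)
    manifest["stages"]["quantify"] = {
        "n_bins": len(abund.bins),
        "n_series": int(len(abund.values)),
    }
    logger.info("quantify: %d bins, %d (bin, family) series", len(abund.bins), len(abund.values))

    # --- completeness filter ----------------------------------------------
    reference = io.read_reference_presence(paths["reference_presence"])
    presence = completeness.presence_from_long(reference)
    core = completeness.derive_core_set(presence, config.core_prevalence)
    scores = completeness.score_all_bins(abund, core, config.min_families)
    completeness.completeness_frame(scores).to_csv(out / "completeness.tsv", sep="\t", index=False)
    retained = completeness.filter_bins(scores, config.min_families)
    manifest["stages"]["completeness"] = {
        "core_set_size": len(core),
        "bins_scored": len(scores),
        "bins_retained": len(retained),
    }
    logger.info("completeness: %d/%d bins pass >%d families", len(retained), len(scores), config.min_families)
    kept = abund.values.index.get_level_values(0).isin(retained)
    abund_kept = type(abund)(
        values=abund.values[kept],
        m_bin=abund.m_bin.loc[[b for b in abund.m_bin.index if b in retained]],
        level="family",
        zero_m={(b, s) for b, s in abund.zero_m if b in retained},
        unannotated=abund.unannotated,
    )

    # --- rhythmicity --------------------------------------------------------
    rhythm_seed = substream_seed(config.seed, "rhythm")
    if len(abund_kept.values):
        rres = rhythm.run_rhythmicity(
            abund_kept,
            design,
            n_perm=config.n_perm,
            seed=rhythm_seed,
            alpha=config.alpha,
            combine=config.combine,
            scope=config.bh_scope,
        )
    else:
        rres = pd.DataFrame(
            columns=["taxon_id", "gene_family_id", "statistic", "max_statistic",
                     "p_raw", "p_adjusted", "is_diel", "peak_hour", "n_perm", "seed"]
        )
    rres.to_csv(out / "rhythm_results.tsv", sep="\t", index=False)
    manifest["stages"]["rhythm"] = {
        "seed": rhythm_seed,
        "n_tested": int(len(rres)),
        "n_diel": int(rres["is_diel"].sum()) if len(rres) else 0,
    }
    logger.info("rhythm: %d tested, %d diel", len(rres), manifest["stages"]["rhythm"]["n_diel"])

    # --- enrichment ---------------------------------------------------------
    pathways = io.read_pathways(paths["pathways"])
    pmap = enrichment.pathway_map_from_frame(pathways)
    universes = {b: abund_kept.families_detected(b) for b in retained}
    eres, esummary = enrichment.enrich_all(
        universes,
        pmap,
        rres,
        tuple(design.times_of_day),
        alpha=config.alpha,
        mode=config.enrichment_mode,
        rank=config.rank,
    )
    eres.to_csv(out / "enrichment.tsv", sep="\t", index=False)
    (out / "enrichment_summary.json").write_text(json.dumps(esummary, indent=1))
    manifest["stages"]["enrichment"] = esummary
    logger.info("enrichment: %(enumerated)d enumerated -> %(retained)d tested -> %(enriched)d enriched", esummary)

    # --- ordination -----------------------------------------------------------
    ord_seed = substream_seed(config.seed, "ordination")
    if retained:
        obs = ordination.build_observation_matrix(abund_kept, design, retained, config.prevalence)
        obs.values.reset_index().to_csv(out / "observations.tsv", sep="\t", index=False)
        manifest["stages"]["ordination"] = {
            "seed": ord_seed,
            "n_rows": obs.n_rows,
            "n_features": int(obs.values.shape[1]),
            "n_zero_rows": len(obs.zero_rows),
        }
        if config.run_nmds:
            d = ordination.bray_curtis(obs)
            d.to_csv(out / "braycurtis.tsv", sep="\t")
            res = ordination.nmds(d, k=config.k, trymax=config.trymax, seed=ord_seed)
            coords = pd.DataFrame(
                res.coordinates,
                columns=[f"dim{i + 1}" for i in range(config.k)],
                index=pd.MultiIndex.from_tuples(res.row_labels, names=["taxon_id", "day", "hour"]),
            )
            coords.reset_index().to_csv(out / "ordination.tsv", sep="\t", index=False)
            manifest["stages"]["ordination"]["stress"] = res.stress
            manifest["stages"]["ordination"]["converged"] = res.converged
        if config.run_per_bin_nmds:
            per_bin = ordination.per_bin_ordinations(
                abund_kept, design, retained, k=config.per_bin_k,
                trymax=config.trymax, prevalence=config.prevalence, seed=ord_seed,
            )
            manifest["stages"]["ordination"]["per_bin"] = ordination.stress_summary(per_bin)
        logger.info("ordination: %d rows x %d features", obs.n_rows, obs.values.shape[1])
    else:
        manifest["stages"]["ordination"] = {"seed": ord_seed, "n_rows": 0, "n_features": 0}

    (out / "manifest.json").write_text(json.dumps(manifest, indent=1, sort_keys=True))
    return manifest
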