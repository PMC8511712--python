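#!/usr/bin/env python
"""Stage 5: Fisher enrichment of pathways among diel families per peak hour.

Writes results/enrichment.tsv (one row per retained bin x hour x pathway
contingency test) and results/enrichment_summary.json.
"""

import json
from pathlib import Path

import pandas as pd

from common import input_paths, load_config, load_inputs

from dieltx import enrich_all, quantify
from dieltx import io as dio
from dieltx.enrichment import pathway_map_from_frame


def main() -> None:
    cfg = load_config()
    contigs, taxonomy, _, design = load_inputs(cfg)
    abund = quantify(contigs, taxonomy, cfg.rank)

    out = Path(cfg.out_dir)
    retained = (out / "retained_bins.txt").read_text().split()
    rres = pd.read_csv(out / "rhythm_results.tsv", sep="\t")

    pathways = dio.read_pathways(input_paths(cfg)["pathways"])
    pmap = pathway_map_from_frame(pathways)
    universes = {b: abund.families_detected(b) for b in retained}

    eres, summary = enrich_all(
        universes, pmap, rres, tuple(design.times_of_day),
        alpha=cfg.alpha, mode=cfg.enrichment_mode, rank=cfg.rank,
    )
    eres.to_csv(out / "enrichment.tsv", sep="\t", index=False)
    (out / "enrichment_summary.json").write_text(json.dumps(summary, indent=1))
    print(json.dumps(summary))
    hits = eres[eres["enriched"]]
    if len(hits):
        print(hits[["taxon_id", "pathway_id", "hour", "odds_ratio", "p_adjusted"]]
              .to_string(index=False))


if __name__ == "__main__":
    main()
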