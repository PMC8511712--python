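#!/usr/bin/env python
"""Stage 3: score bin completeness against the core gene-family set.

Writes results/completeness.tsv and results/retained_bins.txt (bins that
detect more than the minimum number of gene families).
"""

from pathlib import Path

from common import input_paths, load_config, load_inputs

from dieltx import completeness, quantify
from dieltx import io as dio


def main() -> None:
    cfg = load_config()
    contigs, taxonomy, _, _ = load_inputs(cfg)
    abund = quantify(contigs, taxonomy, cfg.rank)

    reference = dio.read_reference_presence(input_paths(cfg)["reference_presence"])
    presence = completeness.presence_from_long(reference)
    core = completeness.derive_core_set(presence, cfg.core_prevalence)
    scores = completeness.score_all_bins(abund, core, cfg.min_families)

    out = Path(cfg.out_dir)
    completeness.completeness_frame(scores).to_csv(
        out / "completeness.tsv", sep="\t", index=False
    )
    retained = completeness.filter_bins(scores, cfg.min_families)
    (out / "retained_bins.txt").write_text("\n".join(retained) + "\n")
    print(f"core set: {len(core)} families at >= {cfg.core_prevalence:.0%} prevalence")
    for s in scores:
        flag = "kept" if s.passes_filter else "dropped"
        print(f"  {s.taxon_id}: {s.n_families_detected} families, "
              f"core {s.core_detected}/{len(core)} = {s.core_percent:.1f}% [{flag}]")


if __name__ == "__main__":
    main()
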