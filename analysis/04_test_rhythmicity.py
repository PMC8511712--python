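#!/usr/bin/env python
"""Stage 4: umbrella rhythmicity test on every retained (bin, family) series.

Writes results/rhythm_results.tsv (statistic, permutation p, BH-adjusted p,
diel call and assigned peak hour per series) and results/diel_summary.tsv
(per-bin diel counts and percentages).
"""

from pathlib import Path

import pandas as pd

from common import load_config, load_inputs

from dieltx import quantify, run_rhythmicity, substream_seed


def main() -> None:
    cfg = load_config()
    contigs, taxonomy, _, design = load_inputs(cfg)
    abund = quantify(contigs, taxonomy, cfg.rank)

    out = Path(cfg.out_dir)
    retained = (out / "retained_bins.txt").read_text().split()
    kept = abund.values.index.get_level_values(0).isin(retained)
    abund = type(abund)(
        values=abund.values[kept],
        m_bin=abund.m_bin.loc[retained],
        level="family",
        zero_m={(b, s) for b, s in abund.zero_m if b in retained},
        unannotated=abund.unannotated,
    )

    seed = substream_seed(cfg.seed, "rhythm")
    rres = run_rhythmicity(
        abund, design, n_perm=cfg.n_perm, seed=seed,
        alpha=cfg.alpha, combine=cfg.combine, scope=cfg.bh_scope,
    )
    rres.to_csv(out / "rhythm_results.tsv", sep="\t", index=False)

    summary = (
        rres.groupby("taxon_id")
        .agg(n_tested=("is_diel", "size"), n_diel=("is_diel", "sum"))
        .assign(pct_diel=lambda d: 100 * d["n_diel"] / d["n_tested"])
        .reset_index()
    )
    summary.to_csv(out / "diel_summary.tsv", sep="\t", index=False)
    total = int(rres["is_diel"].sum())
    print(f"{total}/{len(rres)} series called diel at BH {cfg.alpha} "
          f"(n_perm={cfg.n_perm}, seed={seed})")
    print(summary.to_string(index=False))


if __name__ == "__main__":
    main()
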