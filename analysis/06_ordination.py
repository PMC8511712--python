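#!/usr/bin/env python
"""Stage 6: Bray-Curtis NMDS ordination of (bin, timepoint) compositions.

Writes results/observations.tsv (replicate-averaged, prevalence-filtered,
row-normalized composition matrix), results/braycurtis.tsv and
results/ordination.tsv (NMDS coordinates with Kruskal stress in the log).
"""

from pathlib import Path

import pandas as pd

from common import load_config, load_inputs

from dieltx import bray_curtis, build_observation_matrix, nmds, quantify, substream_seed


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

    obs = build_observation_matrix(abund, design, retained, cfg.prevalence)
    obs.values.reset_index().to_csv(out / "observations.tsv", sep="\t", index=False)

    d = bray_curtis(obs)
    d.to_csv(out / "braycurtis.tsv", sep="\t")

    seed = substream_seed(cfg.seed, "ordination")
    res = nmds(d, k=cfg.k, trymax=cfg.trymax, seed=seed)
    coords = pd.DataFrame(
        res.coordinates,
        columns=[f"dim{i + 1}" for i in range(cfg.k)],
        index=pd.MultiIndex.from_tuples(res.row_labels, names=["taxon_id", "day", "hour"]),
    )
    coords.reset_index().to_csv(out / "ordination.tsv", sep="\t", index=False)
    print(f"{obs.n_rows} rows x {obs.values.shape[1]} features; "
          f"NMDS k={cfg.k} stress={res.stress:.4f} converged={res.converged}")


if __name__ == "__main__":
    main()
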