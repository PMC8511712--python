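# dieltx — diel rhythmicity analysis of binned metatranscriptomes

Marine microbial eukaryotes synchronize much of their transcription to the
24-hour light/dark cycle. Detecting that synchronization in a *mixed
community* metatranscriptome is harder than in a culture: reads must first
be assigned to "environmental taxon bins" (all contigs of a taxonomic
lineage, treated as one organism proxy), abundances must be normalized
within each bin rather than against the whole library, and rhythmicity must
be tested without assuming a waveform, on as few as six time-of-day groups.

`dieltx` implements that workflow end to end:

1. **Synthetic community generator** — negative-binomial fragment counts
   with planted 24-h cosine families and a complete truth ledger, so every
   downstream claim can be audited against known ground truth.
2. **Bin quantification** — bin-denominated FPKM: fragments per kilobase per
   million fragments *mapped to the same taxon bin*.
3. **Completeness filter** — BUSCO-style scoring against a core gene-family
   set; bins detecting >900 families are retained.
4. **Rhythmicity** — a rank-based cyclic umbrella permutation test
   (Jonckheere–Terpstra-type statistics over all 30 peak/trough patterns on
   a 6-point circle, combined by permutation max-T), with
   Benjamini–Hochberg FDR control and peak-hour assignment.
5. **Pathway enrichment** — one-sided Fisher exact tests of pathway
   membership among diel families per (bin, peak hour).
6. **Ordination** — Bray–Curtis + NMDS of (bin, timepoint) compositions;
   rhythmic bins order their timepoints like a clock face.

Statistical details, exact formulas and caveats (including why
bin-denominated FPKM is compositional) are in
[docs/methods.md](docs/methods.md).

## Worked example

The numbered drivers in `analysis/` run the whole study from one
configuration (`analysis/config.yaml`: 6 genus bins × 1000 gene families,
20% planted diel at amplitude 1.0, one planted pathway enrichment, 6×4×2
sampling design, 2000 permutations):

```sh
cd analysis
python 01_simulate_inputs.py     # writes results/inputs/*.tsv + truth.json
python 02_quantify_bins.py
python 03_filter_completeness.py
python 04_test_rhythmicity.py
python 05_pathway_enrichment.py
python 06_ordination.py
```

Actual output from this repository's committed configuration (seed 1):

```text
$ python 02_quantify_bins.py
6 genus bins, 6000 (bin, family) series, 0 zero-denominator cells

$ python 04_test_rhythmicity.py
1276/6000 series called diel at BH 0.05 (n_perm=2000, seed=1596810411)
taxon_id  n_tested  n_diel  pct_diel
    g001      1000     228      22.8
...

$ python 05_pathway_enrichment.py
{"enumerated": 720, "retained": 720, "enriched": 1, "alpha": 0.05, ...}
taxon_id pathway_id  hour  odds_ratio   p_adjusted
    g001      pw003   6.0  147.557143 4.633845e-23

$ python 06_ordination.py
144 rows x 1000 features; NMDS k=3 stress=0.1424 converged=True
```

The single enrichment recovered is exactly the triple planted by
`01_simulate_inputs.py` (genus g001, pathway pw003, 06:00). The per-genus
diel percentages sit a little above the planted 20% because FPKM
normalization is compositional: when a fifth of a bin's families oscillate,
the bin denominator oscillates too, inducing genuine anti-phase rhythms in
otherwise flat families (see docs/methods.md, "Compositional caveat").

The same pipeline is available as a single command:

```sh
dieltx run-all --config analysis/config.yaml   # or --input-dir for real data
dieltx simulate --out sim_inputs --seed 3
dieltx validate sim_inputs
```

## Library use

```python
from dieltx import (make_design, GenusSpec, simulate_study,
                    quantify, run_rhythmicity)
from dieltx.taxonomy import TaxonomyTree

design = make_design([6, 10, 14, 18, 22, 2], n_days=4, n_replicates=2)
study = simulate_study(design, [GenusSpec("g001", 1000, diel_fraction=0.2)], seed=1)
tax = TaxonomyTree.from_frame(study.taxonomy)
abund = quantify(study.contigs, tax, "genus")
results = run_rhythmicity(abund, design, n_perm=2000, seed=2)
print(results[results.is_diel].head())
```

## Reproduction

Everything is seeded and deterministic given a seed; re-running a
configuration reproduces every output byte-identically.

- `python -m pytest -q tests/` runs the full suite, including acceptance
  tests for BH arithmetic, design bookkeeping, realized FDR control on 20
  seeded communities, oracle equivalence of the permutation and Fisher
  tests against exhaustive enumeration, planted-signal recovery and the
  completeness metric.
- `python scripts/acceptance.py --seed 1 --out results/acceptance.json`
  recomputes the headline false-discovery check: 20 seeded communities
  (40 bins × 200 families, 20% planted diel, amplitude 1.0, NB dispersion
  0.3), umbrella test with 2000 permutations and global BH at 0.05, pooled
  realized false-discovery proportion against the truth ledger. It writes
  `{"t5": {"value": <FDP>, "n": <discoveries>}}`; the committed run gives
  FDP ≈ 0.040 over 33,348 discoveries (≤ 0.05). Runtime ≈ 7 minutes on one
  CPU.
- `analysis/` regenerates every table in `results/` from
  `analysis/config.yaml` as shown above.
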