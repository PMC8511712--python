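# Methods

`dieltx` detects 24-hour ("diel") transcriptional rhythms in taxonomically
binned metatranscriptome count data and characterizes them downstream
(peak-phase assignment, pathway enrichment, ordination). This document
specifies every statistical method precisely enough to reimplement it.

## Sampling design

The reference design samples six times of day (06:00, 10:00, 14:00, 18:00,
22:00, 02:00) over four consecutive days with two biological replicates per
sampling event: 6 × 4 × 2 = 48 samples, eight observations per time-of-day
group. `dieltx.design.make_design` accepts any evenly spaced grid of two or
more times of day; the rhythmicity test additionally requires at least three
groups.

## Synthetic community generator

Because real diel metatranscriptomes require billions of environmental reads,
the package ships a generator whose parameters are study conditions fixed in
advance, not quantities fit to data.

Each genus bin carries `n_gene_families` families, each split across
`n_contigs_per_family` contigs with lengths drawn uniformly from
`contig_length_range`. A fraction `diel_fraction` of families is planted
diel, each with a peak hour drawn from the sampling grid. The expected
fragment count of family *i* in a sample taken at hour *h* is

    mu_i(h) = base_mean * (1 + a_i * cos(2*pi*(h - peak_i) / 24))

with amplitude `a_i ∈ [0, 1]` (so the trough mean stays non-negative), split
across the family's contigs proportionally to contig length. Counts are
negative binomial with `size = 1/nb_dispersion`, i.e.

    Var(X) = mu + nb_dispersion * mu^2

so `nb_dispersion = 0.3` gives realistic RNA-seq overdispersion. Every
planted quantity (diel status, peak hour, amplitude, planted pathway
enrichments, core families) is recorded in a truth ledger written alongside
the simulated tables.

Pathway enrichments are planted by re-assigning a pathway's member families
in one taxon to a common peak hour with probability `planting_rate` (default
0.8), which must exceed the background diel rate for the enrichment to be
detectable.

## Bin quantification: bin-denominated FPKM

Contigs are assigned to an "environmental taxon bin": the set of contigs
annotated to a taxonomic node or any of its descendants at the chosen rank.
Within bin *b*, the abundance of a contig of length `L` bp with `f` mapped
fragments in a sample is

    FPKM = ( f / (L / 1000) ) / ( M_b / 1e6 )

where `M_b` is the total number of fragments mapped to *all* contigs of bin
*b* in that sample — annotated or not — rather than the whole library. This
makes abundances comparable across bins of very different sequencing depth.
If `M_b = 0` in a sample, the FPKM is set to 0 and the (bin, sample) cell is
flagged. Contig FPKM values are summed to (bin, gene family) series;
unannotated contigs contribute to `M_b` but not to any family. Bins can be
rolled up to a coarser rank by summing fragments and denominators over the
subtree before renormalizing.

### Compositional caveat

The bin denominator makes family-level FPKM series *compositional*: if a
fifth of a bin's families genuinely oscillate, `M_b` itself oscillates, so a
family with a perfectly flat count series acquires a real anti-phase rhythm
after division by `M_b`. A rhythmicity test applied to such FPKM series will
correctly report those families as rhythmic — that is a property of the
normalization, not an error of the test. Consequences:

- interpret diel calls on FPKM series as "rhythmic relative abundance";
- to audit the *test's* false-discovery control against planted truth, run
  it on the raw per-family count series, whose null/diel status is exactly
  the planted truth (`scripts/acceptance.py` does this).

## Completeness filter

A core gene-family set is derived from a reference presence/absence matrix:
families present in at least 95% of reference taxa (inclusive boundary).
Each bin is scored as the percentage of core families it detects, and bins
detecting more than 900 total families (strictly greater) are retained for
downstream analysis. Example: a bin detecting 170 of 316 core families
scores 100·170/316 = 53.8%.

## Rhythmicity: cyclic umbrella permutation test

The test is a rank-based test against *umbrella alternatives* on the circle,
in the spirit of RAIN (Thaben & Westermark 2014) built from
Jonckheere–Terpstra-type statistics.

**Patterns.** For `G` time-of-day groups, a pattern is a (peak, trough) pair
of group indices; the profile rises monotonically from trough to peak going
one way around the circle and falls the other way. With `G = 6` there are
6 × 5 = 30 patterns.

**Statistic.** For a pattern, every ordered group pair (i, j) where the
pattern says group j exceeds group i contributes a two-sample Mann–Whitney
count: the number of observation pairs (x in group i, y in group j) with
x < y, counting ties as 1/2. The pattern statistic `S` is the sum over the
pattern's implied pairs; its maximum `S_max` is the total number of
contributing observation pairs. Internally both are doubled so that all
arithmetic is exact integer arithmetic. Reversing a pattern (swapping peak
and trough) gives the complement statistic `S_max − S`, so only half the
patterns need to be computed.

**Null.** Group labels are exchangeable under the null, so the null
distribution is generated by permuting the pooled observations across
groups. Two engines:

- *exhaustive*: enumerate every distinct arrangement of the pooled value
  multiset (feasible up to ~10^6 arrangements; used automatically for small
  series);
- *monte_carlo*: `n_perm` random permutations using a xorshift64* generator
  in a numba kernel, with the add-one estimator `p = (r + 1)/(n_perm + 1)`.

**Combining 30 patterns.** The default is max-T: each pattern's statistic is
standardized by its permutation standard deviation,
`Z = (S − S_max/2) / sd_perm`, and the permutation distribution of the
maximum Z across patterns gives a single familywise-exact p-value. A
Bonferroni option (30 × min per-pattern p, capped at 1) is also available.
Both are valid; max-T is less conservative when pattern statistics are
highly correlated, which they are on a circle.

### Monte-Carlo granularity at very small n

With only ~6 observations the null distribution is extremely discrete, and
the max-T statistic depends on *estimated* permutation standard deviations.
Estimation noise can flip which heavily populated tie atoms fall inside the
rejection region, so the Monte-Carlo max-T p-value is a *valid, calibrated*
p-value that does not converge to the exhaustive max-T p-value as
`n_perm → ∞` at such sizes. Per-pattern tail probabilities and the
Bonferroni combination do converge to their exhaustive counterparts; the
test suite's oracle comparisons therefore target those, while calibration of
the max-T p-value is verified on null simulations directly.

**Peak assignment.** A discovery's peak hour is scored by pooling evidence
across trough choices: each candidate hour's score is the sum of the signed
standardized statistics Z of every pattern peaking there, and the hour with
the largest total support wins (exact ties broken by the larger group mean,
then hour order). Pooling over troughs is markedly more stable than taking
the single best (peak, trough) pattern, whose trough choice is
noise-sensitive. Separately, the single-series test also reports its
best-supported pattern — smallest permutation tail count, ties broken by
the largest Z, remaining ties by enumeration order (smaller peak index,
then smaller trough index) — for inspection of the fitted shape.

## Multiple testing

Benjamini–Hochberg step-up across all (bin, family) series pooled
(`scope="global"`, the default) or within each bin (`scope="per_bin"`).
With `m` tests and `k` discoveries at level `alpha`, the step-up critical
value is `(k/m)·alpha`: e.g. m = 103,904 and k = 9,153 at alpha = 0.05
gives 0.0044. Adjusted p-values are the standard monotone minimum; a series
is called diel when its adjusted p is below `alpha`.

## Pathway enrichment

For each retained bin, each sampling hour and each pathway, a 2×2 table is
built over the bin's detected-family universe:

|                       | in pathway | not in pathway |
|-----------------------|-----------|----------------|
| diel, peak at hour    | a         | c              |
| all other families    | b         | d              |

and tested with a one-sided Fisher exact test (alternative: enrichment,
computed as the hypergeometric survival function). All tables in a run are
BH-corrected together. `mode="any"` replaces "peak at hour" with "diel at
any hour".

## Ordination

Per-bin gene-family FPKM profiles are compared across timepoints: replicate
values are averaged first, giving one row per (bin, day, hour); features
present in fewer than 5% of rows (strictly) are dropped *before* each row is
normalized to sum to one; all-zero rows are kept and flagged. Pairwise
Bray–Curtis dissimilarities feed non-metric multidimensional scaling
(Kruskal stress-1, multiple random restarts, monotone regression); a clear
diel signal places a bin's timepoints in clock-like circular order.

## Temporal profiles

For presentation, a family's profile is summarized per time-of-day group
(n = 8 in the reference design) as mean ± standard error, min–max scaled to
[0, 1]; constant profiles are flagged and plotted at 0.5.

## Reproducibility

Every stochastic stage takes an explicit seed. The pipeline derives
independent substreams from the run seed with
`numpy.random.SeedSequence([seed, offset])`, masked to 31 bits; re-running a
configuration byte-identically reproduces every output table.

## Limitations

- The umbrella test assumes exchangeability across days; it does not model
  day-to-day trends or autocorrelation.
- FPKM-based diel calls are relative-abundance statements (see the
  compositional caveat above).
- Peak assignment resolves only to the sampling grid (4-hour resolution in
  the reference design).
- The generator plants pure cosine waveforms; the umbrella test is
  deliberately waveform-agnostic, so power measured on cosines is an upper
  bound for asymmetric waveforms of equal amplitude.
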