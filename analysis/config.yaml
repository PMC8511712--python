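# Study configuration for the numbered analysis drivers.
# Each genus bin carries 1000 gene families so that bins clear the
# >900-detected-families completeness filter; 20% of families are planted
# 24-h diel at amplitude 1.0 (see docs/methods.md for the generator).
out_dir: results
seed: 1
times_of_day: [6.0, 10.0, 14.0, 18.0, 22.0, 2.0]
n_days: 4
n_replicates: 2
n_genera: 6
n_gene_families: 1000
diel_fraction: 0.2
amplitude: 1.0
nb_dispersion: 0.3
n_contigs_per_family: 2
n_pathways: 20
pathway_size_min: 10
pathway_size_max: 30
n_reference_taxa: 366
core_fraction: 0.1
rank: genus
min_families: 900
alpha: 0.05
n_perm: 2000
prevalence: 0.05
k: 3
trymax: 50
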