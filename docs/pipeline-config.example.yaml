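# Example pipeline configuration for `hybridtriad run --config <file>`.
# Every key is optional; omitted keys keep the defaults shown here.
# Unknown keys are rejected.

# master seed: every stage derives its RNG stream from it
seed: 1

# ---- simulation scale -------------------------------------------------------
n_chromosomes: 2          # ancestral karyotype
chrom_length: 150000      # bp per chromosome
divergence: 0.02          # per-bp divergence between the two parent lineages
novel_mutation_rate: 0.00001   # post-hybridization mutations, per bp
read_depth: 60            # total shotgun coverage for the k-mer spectrum
read_length: 150          # bp
variant_depth: 50         # per-site depth in the genotype table
n_genes: 1000             # triad expression genes
n_replicates: 3           # RNA libraries per role (parent1/parent2/hybrid)

# ---- analysis thresholds (study defaults) -----------------------------------
kmer_k: 17                # spectrum k-mer length (odd)
het_window_bp: 100000     # heterozygosity window
identity_window_bp: 500   # pairwise identity window
alpha: 0.05               # significance level (BH-adjusted)
min_abs_log2fc: 1.0       # 2-fold gate for differential calls
min_snps_per_read: 2      # distinguishing SNPs for an informative ASE read
min_ase_reads: 20         # assigned reads per gene
max_conflict_fraction: 0.10   # conflicting-read ceiling per gene
heatmap_min_fpkm: 5.0     # NDE-TUR display gate
heatmap_min_log2fc: 2.0

# ---- stage selection --------------------------------------------------------
# any subset of: simulate, ploidy, popgen, parentage, triad, enrich
# (dependencies are added automatically)
stages: [simulate, ploidy, popgen, parentage, triad, enrich]
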