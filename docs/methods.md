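# Methods

## The problem and the model

Haploid fungal populations occasionally contain diploid individuals formed by
parasexual fusion of two diverged haploid nuclei.  Such an intraspecific
hybrid is a single nucleus carrying two complete haplotypes (subgenomes A and
B), one per parent, plus whatever mutations arose after hybridization
("novel" alleles).  The package implements the inference chain that (i)
recognises the diploid state, (ii) identifies the parents and the subgenome
structure, and (iii) classifies how the hybrid transcriptome relates to its
parents — the signal relevant to heterosis.

## Synthetic data generator

The generator is the package's substrate for testing; it emulates the
*statistical structure* the diagnostics rely on, not the full biology.

**Lineages.**  An ancestral genome is drawn uniformly over {A,C,G,T}
(`n_chromosomes` × `chrom_length`).  For one or two lineages, each radiates
independently from the ancestor ("star"): per-lineage mutation probabilities
m_i are solved from the requested pairwise divergence in log space,
log(1−m_i) + log(1−m_j) = log(1−d_ij), and sites hit in both lineages are
forced to distinct derived bases, so P(mismatch) = d_ij holds *exactly* in
expectation.  For three or more lineages a star cannot realise
clade-structured divergence matrices (within-clade pairs need shared
history), so the generator fits a neighbor-joining tree to −log(1−d) — the
scale on which independent substitutions are additive — and mutates along
branches with per-bp probability 1−exp(−length); mutations on internal
branches are inherited by all descendants.  Back-mutations make realized
divergence very slightly sub-additive (order d², ~1e−4 at 2% divergence),
well inside the 3-SD Monte-Carlo bands the tests use.  Substitutions only:
the diagnostics in scope are SNP-based; indels appear only as alignment
features in the identity-window stage.

**Dysploidy.**  Optional fusion (concatenation) and fission (split at a
breakpoint) events rearrange chromosomes after mutation; ancestral-coordinate
segment maps keep all truth records valid across rearrangements.

**Hybrid.**  Haplotype A copies parent-a's genome, haplotype B parent-b's,
each with fresh mutations at `novel_mutation_rate` (default well below the
parental divergence, so novel alleles stay a minority class).  Truth labels
every differing site parent_a / parent_b / novel.  Parents with unequal
chromosome counts are accepted as a dysploid hybrid with a warning record.

**Reads.**  Uniform positions, fixed read length, equal depth per haplotype
(total coverage `depth` over the organism), substitution errors at
`error_rate`, half the reads reverse-complemented, constant high quality (no
downstream stage consumes base qualities).

**Genotype tables.**  Sites are the union of variant positions versus the
ancestral reference.  Heterozygous diploid sites split a fixed per-site depth
Binomial(depth, ½) between the two alleles; haploid and homozygous sites put
all reads on one allele, so AD always sums to DP.  QUAL is drawn high by
default, with an optional low-quality fraction to exercise the QUAL filter.

**Triad counts.**  Parental gene means are log-normal around `baseline_mean`
(σ = 0.5 across genes — a realistic expression spread); the hybrid mean is
set by the planted category: Additive = mid-parent, ELD_Pi = parent i,
TUR = max-parent × 2^effect, TDR = min-parent / 2^effect.  ELD parents
differ by the effect (dominance requires differing parents).  UC genes sit
between parents but off mid-parent; to be *resolvable* from Additive and ELD
under the 2-fold gate the parents are spread 2.5× the effect (log2) with the
hybrid 1.2× the effect above the low parent.  Replicate counts are negative
binomial (var = μ + αμ²; α = 0 gives Poisson).  The hybrid total is split
into homoeologs Binomial(total, θ) with θ = ½ except for a planted biased
fraction (default 4-fold).  Allele-informative reads carry 2–4 diagnostic
sites (10% carry one, hence uninformative) and are internally inconsistent
with probability `ase_conflict_rate`.

**GO annotations.**  Terms sample members uniformly except spiked terms,
which weight a designated gene subset by the stated odds.

All operations take one integer seed; identical configs and seeds give
byte-identical serialized outputs.

## Analysis stages and numerical choices

**SNP filtering** follows the two-stage convention: per-sample genotypes are
masked where site QUAL < 20 or sample DP ∉ [10, 400]; sites are then dropped
when not biallelic, when the missing fraction exceeds 0.5, or when the
minor-allele frequency over the remaining called alleles is below 0.02.
Filtering is idempotent.

**Heterozygosity windows** are 0-based half-open, non-overlapping, 100 kb by
default.  "Proportion of heterozygous SNPs" is read as per-SNP
(n_het/n_snps, NaN for empty windows); a per-bp mode (n_het/window_bp) is
retained since the choice of denominator is genuinely open.

**Allele-frequency profiles** use AD[alt]/ΣAD at heterozygous sites
(diploids) or non-reference sites (haploids).  Histogram bins are *centered*
on multiples of 0.02 (51 bins, centers 0.00 … 1.00) so the haploid mode is
reported as exactly 1.0 and the diploid as 0.5; edge-anchored bins would
report 0.99.  With fixed depth D the fractions live on the lattice k/D, so
the reported mode can land on a neighbouring bin center (±0.02) by sampling
noise — inherent to a modal estimator on lattice data.

**IUPAC / p-distance / NJ.**  Heterozygotes encode as degenerate bases
(K = G/T etc.), missing as N.  p-distance compares symbols literally (K vs G
mismatches), excluding N-containing columns; this matches what downstream
distance tools do with IUPAC matrices.  Neighbor joining is the classic
Q-criterion agglomeration with the standard two-point branch lengths;
negative lengths clamp to 0 (count logged) and ties break toward the
lexicographically smallest taxon-index pair so output is deterministic.
scikit-bio's independent implementation is a test oracle only.

**k-mer spectra.**  Exact hash counting over 2-bit integer codes, canonical
form = min(k-mer, reverse complement); k must be odd (no self-complementary
k-mers) and ≤ 31.  Windows containing non-ACGT bases are skipped and
counted, so Σ occurrences + skipped = Σ (len − k + 1).  Peak detection
smooths multiplicities ≥ 1 with an edge-padded centered moving average
(width 3), excludes the error region up to the first local minimum (or a
configured cutoff), and keeps local maxima with prominence ≥ 0.1 × the
retained maximum; positions are read on the smoothed curve, heights on the
raw one.  Diploid-like = exactly two peaks with position ratio within 20% of
2.  Note the multiplicity axis is *k-mer coverage*; sequencing fold-coverage
is larger by L/(L−k+1) (~1.12 at L=150, k=17), the standard spectrum axis
calibration.

**Parentage.**  Within single-copy-gene intervals, each heterozygous hybrid
site is evaluated against every candidate pair; site classes (pair-explained
/ shared / novel-allele / conflicting) partition the evaluated sites — one
consistent reading of a taxonomy whose fine binning is otherwise open.
Pairs rank by explained fraction; a best fraction below 0.9 raises the
missing-parent flag.

**Subgenome assignment** scores each hybrid chromosome by the fraction of its
distinct canonical 31-mers contained anywhere in each parent (optionally
restricted to parent-unique k-mers as a repeat mask); labels need a margin
(default 0.05), otherwise ambiguous.  A per-chromosome coverage table can
replace the k-mer path to stay faithful to read-mapping-coverage workflows.

**Identity windows** are query-anchored, 500 bp, non-overlapping: aligned
columns = matches + mismatches + gap columns (a gap in the query is anchored
at the preceding query base); identity = matches/aligned; windows with
aligned query coverage below half the window are reported missing.  Whether
gap columns belong in the denominator is an open convention; counting them
(as here) makes identity penalise indels.  Alignments must carry extended
(=/X) CIGARs; plain M is rejected.

**Expression engine.**  TMM follows the standard trimmed-mean-of-M-values
estimator (30% M-trim, 5% A-trim, binomial delta-method precision weights,
reference = sample with upper-quartile closest to the mean, factors rescaled
to geometric mean 1); it matches edgeR's `calcNormFactors` to ~1e−6 on test
fixtures.  CPM = count/(lib × factor) × 1e6; FPKM = CPM × 1000/CDS-length.
Differential testing is a pooled-variance two-sided t-test on log2(CPM+1)
with light empirical-Bayes moderation: per-gene pooled variances shrink
toward their across-gene mean with a prior worth 4 residual df (added to the
test df) — the standard remedy at n = 2–3 replicates, where unmoderated
per-gene variances are too unstable and Welch–Satterthwaite df collapse
toward n−1.  BH adjustment is applied per contrast family across genes, and
significance additionally requires |log2FC| ≥ 1 (the 2-fold gate).  Zero
variance with equal means gives p = 1; with unequal means p = 0, flagged
degenerate.

**Triad decision table** (precedence resolves overlapping outcomes
deterministically): TUR if the hybrid is significantly above both parents;
TDR if below both; Additive if the hybrid vs the per-replicate mid-parent
value is non-significant; ELD_P1 if the hybrid matches parent 1 and differs
from parent 2 (ELD_P2 symmetric); else UC.  Replicate pairing for the MPV is
positional and fixed.  NDE-TUR vs DE-TUR splits on the parent-1-vs-parent-2
contrast.  Heatmap candidates are NDE-TUR genes with mean hybrid FPKM > 5
and log2FC > 2 over the *higher* parent.

**ASE and cis/trans.**  A read is informative with ≥ 2 distinguishing SNPs
(flag exposed, since a 1-SNP rule is also defensible), assigned only when
all its sites match one parent; genes need ≥ 20 assigned reads and < 10%
conflicting.  cis = log2 allelic odds (+0.5 haldane correction), tested by
exact binomial against ½; trans = parental log2 ratio − cis, tested by
binomial against the parental proportion; parental significance by the
expression engine; binomial p-values BH-adjusted across genes.  The decision
table: conserved (neither cis nor trans significant), cis-only, trans-only,
compensatory (cis and trans significant, parents not), cis+trans (same
sign), cis×trans (opposite sign, |cis| < |trans|), ambiguous (remainder).
cis + trans ≡ P holds to machine precision by construction.

**Enrichment.**  p = P(X ≥ k) under Hypergeometric(N, K, n) via the scipy
survival function (the rational-arithmetic exact tail is a test oracle);
BH step-up implemented in-package.  The universe defaults to annotated genes
intersected with the tested gene set; terms with no annotated genes are
skipped.

## Pipeline

`run_pipeline` executes simulate → ploidy → popgen → parentage → triad →
enrich (plain files in a run directory, no workflow engine); requesting a
stage subset pulls dependencies by DAG closure.  The manifest records the
full config (every threshold), package version and SHA-256 of each output;
reruns with the same config are byte-identical.  Default simulation sizes
(2 × 150 kb chromosomes, 2% divergence, depth 60 reads, 1000 genes × 3
replicates) keep a full run under a minute on one core while leaving every
signature detectable; the acceptance script uses a 1-Mb genome for the
spectrum so the heterozygous peak is sharply resolved.

## What passing tests do and do not show

The generator draws uniform-composition genomes without repeats, uniform
coverage, substitution-only divergence, and independent negative-binomial
counts with planted clean effects.  Passing recovery tests therefore
demonstrates the *algorithms* are correct and calibrated under their stated
assumptions — not that real data meet those assumptions: repeats blur k-mer
containment, mapping bias distorts allele depths, library composition and
batch effects stress TMM, and real effect sizes are not bimodally planted.
The coverage-table ingestion path, the repeat mask option and the exposed
thresholds are the hooks for such data.

## Known limitations

* No spectrum model fitting (genome size / heterozygosity-rate estimation)
  and no k-mer-pair (smudge-style) analysis; the ploidy call is 1-D.
* The expression engine is a moderated t on log2(CPM+1), not a count-model
  GLM; at very low counts or n = 2 its calibration is conservative.
* Identity windows require extended CIGARs; alignments with plain M are
  rejected rather than re-aligned.
* NJ is the only tree method (no bootstrap, no networks).
* GO annotation maps are taken as given (no ancestor-term propagation).
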