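# Methods

`jointgt` estimates diploid genotypes jointly from two noisy, complementary
measurements of the same samples — SNP-array probe intensities and
low-coverage sequencing reads — plus the linkage disequilibrium (LD) shared
across samples. This note records the model, the tunable parameters and
their defaults, what the synthetic-data generator does and does not emulate,
and the numerical choices made where the design was open.

## Model

For sample *j* and SNP *i*, let *g<sub>ij</sub>* ∈ {0, 1, 2} be the
non-reference allele count, *y<sub>ij</sub>* the 2-vector of probe
intensities, and *x<sub>ij</sub>* the sequence reads. The model is naive
Bayes: *x* and *y* are conditionally independent given *g*, so the joint
likelihood factors as P(x|g)·P(y|g) and all dependence across samples and
SNPs flows through the unknown genotypes.

**Intensity model.** P(y<sub>ij</sub> | g) = N(y<sub>ij</sub>; μ<sub>ig</sub>,
Σ<sub>ig</sub>), a three-component bivariate-Gaussian mixture per SNP with
mixing weights π<sub>ig</sub>. Class index equals the non-reference allele
count; means are kept ordered along the allele-contrast (a−b) axis so array
and sequence genotype indices are interchangeable. Missing intensities
contribute flat likelihoods.

**Sequence model.** Reads are summarised per (SNP, sample) as a pileup of
fragments; each fragment carries 1 or 2 base observations (2 when paired
mates overlap the site). Two likelihoods are implemented:

* *read mode* (the conventional baseline): every base observation is
  independent; P(b|allele) = 1−e on match, e/3 on mismatch, e = 10^(−q/10).
* *fragment mode* (the default): library-preparation (PCR) errors occur on
  the fragment *template*, at rate p (default 1e-4), and are therefore
  shared by overlapping mates. The fragment likelihood marginalises the
  template base f:

      P(frag | {A,B}) = ½ Σ_{h∈{A,B}} Σ_{f∈ACGT} P(f|h;p) Π_k P(b_k|q_k,f)

  with P(f|h;p) = 1−p if f=h else p/3. Errors introduced before sequencing
  are thus counted once per fragment; sequencing errors once per read. For
  p = 0 and no overlapping mates the two modes coincide exactly.

  Third-allele observations are kept as mismatch evidence against both
  alleles rather than filtered; this keeps the likelihood proper without an
  allele-selection heuristic.

**Posteriors via LD.** Per-site joint likelihoods alone ignore LD. The
phasing/imputation engine consumes a genotype-likelihood matrix and returns
P(g<sub>ij</sub> | all data): a likelihood-in / posterior-out contract, so
any imputation engine can be plugged in. The default is an iterative
haploid-copying (Li–Stephens-style) HMM:

1. initialise each sample's haplotype pair by sampling from the per-site
   posterior (likelihood × a moment estimate of genotype frequencies);
2. per iteration, run forward–backward for each of a sample's two
   chromosomes against the pooled haplotypes (samples + optional reference
   panel), with emissions weighted by the input genotype likelihoods given
   the partner chromosome (pseudo-diploid conditioning), then re-sample all
   haplotype pairs from the smoothed posteriors;
3. average the per-iteration genotype posteriors after a burn-in of the
   first half of the iterations.

Numerical details that matter:

* The copying *prior* at site *s* uses state posteriors with the site's own
  emission excluded (one-step-predict × backward), so the data at *s* enter
  the genotype posterior exactly once.
* Heterozygote phase at re-sampling is drawn from the per-chromosome
  alternate-allele probabilities (q₁, q₂), not a fair coin. This is what
  keeps the sampled pool phase-coherent along the chromosome; with random
  phase the pool carries no multi-site LD and imputation stalls (we measured
  masked-site recovery of 0.64 vs 0.90 mean true-genotype posterior).
* Early iterations are systematically noisy (the pool starts from
  non-LD-informed samples), hence the burn-in before averaging.
* A sample's own two haplotypes are masked out of its state pool.
* The diploid process is approximated by two conditioned haploid passes
  (pseudo-diploid) rather than the exact K²-state diploid HMM — chosen for
  desk-scale tractability.

**Outer EM.** Cluster parameters are initialised per SNP by an internal EM
anchored at a prior template (a simplified stand-in for vendor cluster
initialisation). Each outer iteration then: computes intensity likelihoods
under the current clusters, multiplies them with the (fixed) sequence
likelihoods, runs the LD engine, and re-estimates each SNP's cluster
parameters from the intensity points weighted by the posterior
responsibilities. The loop runs a fixed 3 iterations with no convergence
test; the per-iteration expected data log-likelihood is logged. Calls are
made where the top posterior exceeds 1 − 10^(−T/10) for GQ threshold T
(T = 10 ⇔ 90%, T = 20 ⇔ 99%); exact top-two ties are no-calls; GQ =
−10·log₁₀(1 − top), capped at 99.

Ablation flags (`use_array`, `use_sequence`, `use_imputation`, `recluster`)
expose every single-technology / no-phasing / no-reclustering variant, and
entries lacking one data type simply contribute flat likelihoods from that
source — partial-sequencing cohorts need no special casing.

## Parameters and defaults

| parameter | default | units / meaning |
|---|---|---|
| `outer_iterations` | 3 | outer E/M rounds (fixed, no convergence test) |
| `gq_threshold` | 10 | Phred; call iff top posterior > 90% |
| `gq_cap` | 99 | Phred cap (posterior 1.0 would be infinite) |
| `fragment_error` p | 1e-4 | per-fragment template error rate |
| `ld_iterations` | 20 | copying-HMM Gibbs rounds (first half = burn-in) |
| `ld_states` | 100 | state-pool cap (random subset of haplotypes) |
| `ld_recomb` | 0.05 | per-adjacent-SNP switch probability |
| `ld_mismatch` | 0.01 | copy-error emission rate |
| covariance floor | 1e-4 × (mean total intensity)² | eigenvalue floor, prevents degenerate clusters |
| prior pseudo-count | 0.1 | mixing-weight regulariser |
| empty-component inflation | 25× | see below |
| dispute threshold | 0.10 | discordance fraction (alternate analysis: 0.25) |
| "closely match" concordance | 0.90 | dispute-resolution cutoff (not quantified upstream; a config key) |
| LOD threshold | 2 | log₁₀ likelihood ratio for characterization |

**Empty-component covariance inflation.** When the M-step finds a genotype
class with negligible responsibility mass, the class reverts to the template
mean — but with its covariance inflated 25×. A class no sample is believed
to occupy should express *location uncertainty*, not the tight covariance of
an observed cluster. Without the inflation, a failed probe (all samples in
one blob) is fit as one tight component plus two distant confident ones, and
the resulting intensity log-likelihood ratios (hundreds of nats) can never
be overruled by sequence data; with it, the ratio is bounded at a few logs,
4× sequence evidence wins, and one re-clustering round then moves all three
means into the blob, flattening the array evidence at that SNP. This is the
mechanism by which joint calling repairs erroneous cluster locations.

## Synthetic data: what it emulates, what it does not

The generator produces the statistical structure the framework assumes, not
realistic human data:

* **Haplotypes** come from mosaic copying: founders with Bernoulli(½)
  alleles, recombinant copies (switch probability per adjacent SNP), and
  per-site mutation. This creates block-like LD sufficient for imputation —
  but no coalescent genealogy, no realistic allele-frequency spectrum, no
  recombination hotspots, one population. Defaults (`recomb_prob` 0.05,
  `mutation_prob` 0.002) give moderate LD; tests that need strong LD say so
  explicitly (recomb 0.02, mutation 0.001).
* **Reads**: per-site fragment counts are Poisson with rate
  coverage/(1 + overlap_fraction), so expected *base observations* equal the
  nominal coverage. Each fragment draws one of the sample's alleles
  uniformly; fragment errors (rate p) mutate the template uniformly to one
  of the 3 other bases (mirroring the e/3 read-error convention — the
  upstream literature does not specify the spread); read errors re-mutate
  each mate independently. Overlap is all-or-none per fragment at a site.
  No alignment coordinates, mapping quality, indels, or quality-score
  miscalibration.
* **Intensities**: bivariate normal per class around a canonical template
  (hom-ref loads on channel a, hom-alt on b), with per-SNP mean jitter and
  three planted artifact modes: `cluster_shift` (one mean displaced toward a
  neighbouring class — the confusable failure; a shift into empty space is
  harmless and recoverable by intensity-only EM), `merged_clusters`, and
  `null_probe` (all means collapse: array-monomorphic). No batch effects,
  no vendor normalisation artefacts, no intensity-depth correlation.
* **Error-mode covariates** are drawn directly from class-conditional
  Bernoulli/normal distributions; they are *names* (strand bias,
  low-complexity flank, …) with planted effect sizes, not quantities
  computed from sequence context.

A green test therefore establishes that the algorithms behave as specified
on data satisfying their assumptions — it does not certify performance on
real arrays or real sequencing, where the headline numbers depend on cohort
size, marker density and human LD structure far beyond desk scale.

## Statistical procedures

* **Metrics**: sensitivity = fraction of non-reference gold genotypes called
  identically (no-calls count against it); specificity = fraction of
  non-reference calls matching gold (no-calls excluded from the
  denominator). Exact 0/1/2 identity (het ≠ hom-alt). A/T and C/G sites are
  excluded by default (strand ambiguity). MAF strata use frequencies from
  the non-test samples; frequency-0 variants are "private". Undefined
  ratios are reported as undefined, never as 0. Multi-sample evaluation
  counts genotype *entries* (site-level and entry-level counting coincide
  for a single test sample). The normalised off-array metric is
  (joint/seq at off-array sites) × (seq at all sites).
* **Disputes**: discordance per SNP is computed over samples called by both
  technologies (no-calls excluded from the denominator — the upstream
  definition does not say; this is the conservative reading). Disputed iff
  rate ≥ 0.10 (inclusive). Resolution compares joint-vs-sequence and
  joint-vs-array concordance: apparent array error iff the sequence
  concordance is strictly larger *and* ≥ 0.90; mirror case for sequence;
  anything else (including all-no-call joint columns) is unresolved.
* **Enrichment**: binary modes by two-sided Fisher exact; continuous modes
  by tie-corrected Kruskal–Wallis, with an *exact permutation* p-value for
  two-group comparisons of ≤ 6 values per group (the χ² reference is
  unreliable there).
* **Characterization**: binary mode flags value 1. Continuous modes fit 1-D
  Gaussian KDEs to the non-disputed SNPs (Silverman bandwidth) and to each
  apparent-error class (same absolute bandwidth, keeping the ratio stable —
  per-group bandwidths would let a tight error class manufacture LOD), and
  flag a SNP when log₁₀(f_E/f_N) > 2 at its value; numerically zero f_N
  counts as infinite LOD (flagged).

## Known limitations

* The LD engine is a functional stand-in, not a re-implementation of any
  production imputation program; its accuracy at very low coverage with few
  samples is below what dense reference panels achieve.
* The pseudo-diploid approximation mildly miscalibrates heterozygote
  posteriors when both chromosomes are uncertain.
* Absolute sensitivity values on the bundled synthetic worlds are not
  comparable to published human-cohort numbers (different LD, cohort size,
  and marker density); only the qualitative orderings (joint ≥ single
  technology, monotone in coverage, imputation > no imputation) transfer.
* Only biallelic autosomal SNPs; no indels, no sex chromosomes, no
  multi-population panels.
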