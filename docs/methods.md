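# Methods

`mixstock` implements a complete mixed-stock analysis workflow for small
diploid SNP panels: quality control, differentiation statistics with
resampled significance, diagnostic-panel design, and two independent
individual-assignment engines.  This note records the statistical models,
the numerical choices behind them, and what the synthetic-data tests do and
do not demonstrate.

## Data model

Genotypes are biallelic diploid calls stored as alternate-allele counts
(0/1/2) with a reserved missing sentinel (-1), never 0, so frequency
arithmetic and matrix normalizations are unambiguous.  Locus identity is
encoded in names of the form `LG{nn}_{position}_{suffix}`: two-digit
linkage group, 1-based physical position, and a suffix giving the marker's
panel class (`SEL` diagnostic, `CAN` candidate gene, `I{nn}` chromosomal
inversion, `SEX` sex-linked).  Interval inputs (inversion/exclusion
regions) use 0-based half-open BED coordinates, converted at the comparison
boundary; each format keeps its native convention.

## Quality control

Loci are removed with a fixed reason precedence — explicitly listed >
sex-linked > monomorphic > missingness strictly above 50% — so filter
reports are deterministic.  The "listed" mechanism exists because
instrument-side call-quality failures (e.g. poor fluorescence clustering on
a genotyping chip) cannot be recomputed from the genotype matrix; the user
supplies those locus ids.  Individuals with a non-missing call fraction
strictly below 50% are removed after locus filtering.  Both thresholds are
arguments; the boundary cases (exactly 50%) are retained, matching the
strict inequalities in the rules.

## Differentiation statistics

The fixation index is the Weir & Cockerham (1984) theta, computed from the
three variance components a (among populations), b (among individuals
within populations) and c (within individuals), with per-locus sample sizes
taken from non-missing calls.  Multi-locus estimates are the ratio of
components summed over loci, not the mean of per-locus ratios; both are
exposed.  Negative estimates are reported unclipped.

Confidence intervals:

* **Per-locus global theta** — percentile bootstrap resampling individuals
  with replacement within each group (stratified bootstrap).
* **Pairwise multi-locus theta** — a studentized bootstrap over loci:
  resampled theta values are standardized by their own linearization
  standard error `se = sqrt(m * var_j(a_j - theta * s_j)) / T` (m loci,
  s_j the per-locus component sum, T their total), and the t-quantiles are
  inverted around the point estimate.  Plain percentile intervals
  undercover noticeably at panel sizes near 20 loci because the per-locus
  components are few and skewed; the studentized form restores close to
  nominal coverage (measured 92–95% at nominal 95% across divergence levels
  0.1–0.4 in the calibration suite).

Differentiation significance is one-sided: a pair (or locus) is flagged
significant only when the lower CI bound exceeds zero.  Intervals entirely
below zero arise from the estimator's negative bias under panmixia and are
treated as absence of evidence, not as significant structure.

Hardy-Weinberg equilibrium is tested per (group, locus) with the classical
three-class chi-square against expectations n(p², 2pq, q²), and its
significance by permutation: the group's 2n allele copies are randomly
re-paired into diploids, and p = (1 + #{chi²_perm ≥ chi²_obs}) / (n_perm + 1),
which cannot return zero.  The test is exact but conservative in small
samples because the heterozygote-count null is discrete; at n = 50 the
achieved level at nominal 5% is about 3%, converging to nominal by
n ≈ 1000.  Calibration checks therefore run in the large-sample regime;
users testing small samples should expect conservatism, not
anti-conservatism.  A pooled-over-groups test is available: pooling
differentiated populations produces the Wahlund heterozygote deficit, and
an elevated pooled rejection rate at diagnostic loci is the expected
signature of a mechanical mixing zone.

Multiple testing uses the Holm (1979) step-down procedure ("sequential
Bonferroni"): sorted p-values are compared against alpha/(m−i+1) and the
adjusted value is the running maximum of (m−i+1)·p, capped at 1.

For inversion-linked loci, over/underrepresentation of the presumed
collinear (non-inverted) arrangement is tested by bootstrapping individuals
within groups and asking whether the 95% percentile interval excludes the
null frequency, together with a Holm-adjusted two-sided bootstrap p-value.
The null defaults to 0.5 (equal representation of arrangements) and is
configurable; no pooled-sample expectation is imposed.

## Panel design

Candidates are scored by pairwise Weir-Cockerham theta between the two
reference populations and selected greedily from the top of the ranking,
skipping candidates within `min_spacing_bp` (default 1 Mb) of an already
selected locus on the same linkage group and candidates inside supplied
exclusion intervals (typically the inversions).  Physical spacing is the
only linkage proxy — no genotype-correlation pruning — which matches the
design philosophy of spacing diagnostic markers across the genome a priori.
Every constraint (panel size, spacing, intervals) is explicit
configuration; a panel that cannot be filled returns the maximum feasible
set with a warning, and the constraint log records one decision per
candidate.

Panel power is quantified by likelihood reassignment: an individual is
assigned to the reference population maximizing the product over loci of
Hardy-Weinberg genotype probabilities at pseudocount-smoothed frequencies
p' = (x + 0.5)/(2n + 1); reference members are scored leave-one-out, and
exact likelihood ties (e.g. F1 hybrids at fixed differences) are reported
as `ambiguous` rather than broken arbitrarily.

## Admixture engine

The Bayesian clustering model is the classic admixture model: individual i
has proportions q_i ~ Dirichlet(alpha·1_k); cluster frequencies have a
Beta(lambda, lambda) prior (lambda = 1); each of the two allele copies of
each genotype originates from a latent cluster drawn from q_i.  A Gibbs
sweep updates latent origins (categorical), cluster frequencies (Beta) and
q (Dirichlet).  Defaults follow the standard protocol for this analysis:
burn-in 10,000 followed by 100,000 sweeps, 10 replicate runs, thinning
every 10th recorded state (memory control; the posterior mean is unaffected
in expectation).  Missing genotypes contribute nothing.  Non-convergence is
not detected automatically; replicate agreement is the practical check.

alpha is fixed during sampling (no alpha update) and defaults to 0.1.  A
fixed alpha = 1 bounds the posterior-mean q of even a perfectly unambiguous
individual at (1 + 2L)/(k + 2L) — 0.976 for a 20-locus panel — whereas
likelihood-based tuning of alpha in the standard implementations shrinks it
toward zero for well-separated stocks, letting q approach 1.  The small
fixed default reproduces that behaviour while keeping the sampler simple;
both hyperparameters are arguments.

Model evidence for choosing k uses the mean-minus-half-variance estimate
ln P(D) ≈ mean(ln L) − var(ln L)/2 over the recorded trace, and the Evanno
second-order statistic Δk = mean(|L(k+1) − 2L(k) + L(k−1)|)/sd(L(k)) over
replicate runs; Δk is undefined where the replicate sd is zero, and a run
of flat likelihoods is flagged unreliable (all Δk below a threshold of 5).
Replicates are aligned by exhaustive search over the k! cluster
permutations against the first run (minimum Frobenius distance between q
matrices), exact for the small k this tool targets and identical to the
full-search criterion at k = 2; aligned matrices are averaged.  Discrete
stock calls label an individual with its maximum-q cluster when that
maximum reaches `q_threshold` (default 0.8, always reported in output
headers) and `unassigned` otherwise; QC-removed individuals are reported
separately from ambiguous ones, since the two causes of non-assignment are
different.

## PCA engine

Genotypes are normalized per locus with the posterior allele frequency
p̂ = (1 + Σcalls)/(2 + 2n) computed from reference individuals only, each
entry becoming (call − 2p̂)/sqrt(p̂(1−p̂)) with missing entries zero after
centering.  Eigenvectors come from the reference individuals' covariance
(via SVD); all other individuals are placed by least-squares projection of
their observed genotypes onto the locus-space axes, so missing data do not
pull projected points toward the origin.  Reference individuals with
complete data project exactly onto their own coordinates.

Eigenvalue significance uses the Patterson moment-matching construction:
for each axis the leading axes are removed, the remaining spectrum
estimates an effective marker count n', and the leading remaining
eigenvalue is standardized and referred to the Tracy-Widom (beta = 1)
distribution.  The TW CDF is interpolated from a bundled knot table
generated from the Chiani (2014) shifted-gamma approximation (accuracy
about 1e-3); p-values are floored at 1e-6 and reported as exactly 1.0 below
the table range, matching how non-significant axes are conventionally
printed.  Two practical caveats, both encoded in the defaults: (i) deep in
the spectrum of a low-rank panel matrix the sequential p-values become
anticonservative, so assignment uses only the leading consecutive run of
significant axes (falling back to axis 1); (ii) when a single axis carries
a very large variance share (≈80%, as with a 38-locus panel at an allele
frequency difference of 0.8), the moment estimate of n' degenerates toward
1 and the axis-1 test turns conservative — the test is designed for the
moderate-structure regime (axis-1 share of order 30–40%), and the
significance-pattern checks run there.

PCA-based stock assignment is nearest reference-centroid distance on the
significant axes, with an `unassigned` outcome when the relative margin
(d2 − d1)/d2 between the two nearest centroids falls below 0.2 (default,
configurable).

## Synthetic data generator

The generator emulates the survey design this pipeline targets: two source
populations ("west"/"east"), reference sampling units drawn purely from
each, and mixed units populated by mechanical mixing — each individual's
origin is Bernoulli(mixing proportion), then pure sampling; no
interbreeding — plus optional F1 hybrids that draw one allele per locus
from each population.  Per-locus frequencies are either explicit pairs
(diagnostic loci default to 0.9 vs 0.1, i.e. an allele-frequency difference
of 0.8, the regime in which a 20-SNP panel distinguishes stocks nearly
unambiguously) or Balding-Nichols draws
p_pop ~ Beta(p̄(1−F)/F, (1−p̄)(1−F)/F) around an ancestral frequency
p̄ ~ Uniform(0.1, 0.9) at divergence F (candidate loci default to F = 0.25).
Missingness is completely at random.  Inversion-block loci are derived from
a latent diploid inversion genotype shared within the block, with
configurable per-population collinear-arrangement frequencies and
per-allele reporting concordance.  Loci are otherwise independent — blocks
exist to exercise the collinear-allele test and the spacing filter, and the
analysis itself assumes unlinked diagnostic markers.  True origins are
recorded in metadata so any assignment engine can be scored exactly.

A study-shaped fixture reproduces the survey scale: 603 individuals in six
sampling units (67 + 59 + 180 + 205 + 62 + 30, the mixed unit split across
two year strata) genotyped at a 38-locus panel (20 diagnostic, 11
candidate, 7 inversion loci in three blocks on linkage groups 2, 7 and 12),
with a default 40% western share in the mixed unit.  All randomness flows
from one seed through `numpy.random.SeedSequence` stream-splitting, so
datasets are bit-reproducible.

What the generator does not emulate: linkage disequilibrium outside
declared inversion blocks, genotyping error and allele dropout, null
alleles, departures from HWE within sources, selection or drift dynamics,
and family structure.  Passing tests therefore demonstrate correctness of
the estimators and engines under the stated sampling model, not robustness
to those real-data artefacts.

## Problem sizes in the test and acceptance runs

API defaults keep the full-scale settings (10,000 resampling replicates;
10 admixture replicates of 10,000 + 100,000 sweeps).  The test suite and
the acceptance script run the same algorithms at reduced sizes chosen to
exercise every code path at meaningful statistical resolution: 100 random
fixtures for oracle equivalence; 50 calibration replicates per divergence
level with 1,000 bootstrap draws; 1,000 loci at n = 1000 for HWE
calibration (the near-continuous regime of the permutation null); 3
admixture replicates of 1,000 + 10,000 sweeps for assignment recovery;
20 Evanno trials over k = 1..4 at 300 + 1,500 sweeps (ln P(D) gaps across k
are large at diagnostic divergence, so short chains suffice); 10 structured
and 50 null runs for the Tracy-Widom pattern.

## Known limitations

* Biallelic loci only; no exact (Guo-Thompson) HWE test; no LD estimation
  beyond physical spacing.
* The admixture sampler implements the uncorrelated-frequencies model only
  (no F-model, no linkage model, no use of prior population labels).
* Label switching within a single chain is not corrected; with the
  separated stocks this tool targets it has not been observed, but weakly
  structured data may mix labels within a run.
* The Tracy-Widom test inherits the moment-matching degeneracies described
  above; statistic values are not expected to reproduce any particular
  external implementation exactly, only the significance pattern.
* Bootstrap-t intervals can be erratic when fewer than ~10 usable loci
  enter a pairwise estimate; with a degenerate spread (all loci fixed) the
  interval collapses to a point at the estimate.
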