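# Methods

This note documents the models, estimators and design choices behind
germcore, what the synthetic-genotype generator does and does not
emulate, and the numerical conventions used throughout.

## The synthetic population model

The generator (`germcore.synthetic_data`) emulates a germplasm panel of
`n_accessions` diploid accessions drawn from `n_subpops` diverged
subgroups. Divergence follows the Balding–Nichols model: for each locus
an ancestral allele frequency p is drawn uniformly on
[`maf_floor`, 1 − `maf_floor`], and each subgroup receives a frequency
from Beta(p(1−F)/F, (1−p)(1−F)/F), which has mean p and variance
F·p(1−p). F is therefore, to first order, the expected FST between
subgroups; the unit test checks this with an independent Hudson
ratio-of-averages estimator. Defaults — 100 accessions, 2 subgroups,
F = 0.1, 5,000 SNPs plus 500 InDels, MAF floor 0.05, 5 % missing calls,
8 chromosomes of 2 Mb — describe the emulated study panel. F = 0.1 is a
plausible between-subgroup divergence for a regionally structured crop
collection; no published within/between-group FST was available to
calibrate it, so it is a modeling choice, fixed once.

Genotype dosages are Binomial(2, f) draws from the accession's subgroup
frequency; the species this design emulates is autotetraploid but was
genotyped under a diploid model, and the generator mirrors that
simplification — it never emits tetraploid dosages. Missingness is
injected independently per call, the simplest mechanism consistent with
a site-level missingness filter. Duplicate genotype rows are re-drawn
(bounded retries) because the fingerprinting stage is only meaningful
when accessions are pairwise distinguishable; an unachievable
distinctness signals a degenerate configuration and fails loudly.

**Admixture.** A fraction (default 10 %) of accessions receives
locus-wise mixed ancestry. Each admixed accession keeps a *majority*
ancestry from its assigned subgroup and draws a minority weight
uniformly from [0, 0.3); at each locus, with that probability, the
allele frequency of a uniformly chosen other subgroup is used instead.
The cap at 0.3 is deliberate: it emulates backcross-like introgression
while keeping every accession assignable to its majority subgroup, so
the generated two-group structure remains recoverable by PCA and NJ —
a stated invariant of the generator. A 50/50 mixture model would make
subgroup labels of admixed accessions undefined and the recoverability
property false by construction.

**Filter-annotation truth.** `write_vcf` draws QUAL/INFO annotations
(QD, SOR, FS, MQ, MQRankSum, ReadPosRankSum) from uniform *pass* ranges
chosen to satisfy both hard-filter expressions; a configurable fraction
of records instead receives one *fail* value drawn from a uniform range
beyond the corresponding threshold of that record's kind. The returned
truth table (expected pass/fail and the failing clause per record) makes
filter tests exact rather than statistical. Output is byte-deterministic
for a given config; the file-date header line is opt-in.

**What the generator does not emulate:** linkage disequilibrium along
chromosomes (loci are exchangeable), sample- or locus-biased
missingness, sequencing error in genotype calls, tetraploid allele
dosage, and multiallelic sites (all simulated loci are biallelic;
multiallelic handling is still exercised by hand-built records in
tests). Passing tests therefore demonstrate correctness of the
estimators and selectors under idealized panel structure, not
robustness to real-data artifacts such as batch effects or allele-dosage
miscalls.

## Variant filtering and summaries

The hard-filter expressions are evaluated clause by clause with strict
inequalities exactly as printed above; a record fails when any clause of
its kind-specific expression holds. Clauses whose annotation is absent
are skipped — absent evidence never fails a record, matching common
VariantFiltration behavior for missing rank-sum annotations. Records
mixing SNP and InDel alternate alleles are classified `mixed`, counted
separately, and excluded from SNP and InDel summaries. Ti/Tv and the
six-class substitution spectrum are defined on biallelic SNPs only;
a zero transversion count reports the ratio as undefined rather than
infinite. InDel lengths |len(alt) − len(ref)| are binned 1–10 and
">10", one entry per record (first alternate allele), so histogram
totals equal class counts even for multiallelic records.

The population site filter follows the printed wording literally on
both boundaries: MAF *below* 0.05 drops (exactly 0.05 passes), missing
rate *exceeding* 20 % drops (exactly 20 % passes). MAF uses non-missing
calls only (denominator 2 × called samples, VCFtools convention); MAF
and missingness are measured on the same input matrix in one pass.
Multiallelic sites are dropped, not split. The filter emits a per-locus
audit naming the first failing rule in the order MAF → missingness →
biallelic, and is idempotent.

## Distances, neighbor joining, PCA

The pairwise distance is the mean squared half-dosage difference over
loci non-missing in both samples, bounded in [0, 1] (0 = identical
calls, 1 = opposite homozygotes everywhere). The bound and the
missing-awareness are the reasons this normalization was chosen over an
unnormalized squared distance. A pair sharing no locus is an error, not
a silent zero.

Neighbor joining implements the Saitou–Nei agglomeration with the
Studier–Keppler criterion Q(i,j) = (m−2)d(i,j) − r(i) − r(j). Two
conventions make it deterministic and well-behaved: ties in Q are broken
by the lexicographically smallest pair of node indices (leaves in input
order, internal nodes in creation order), and negative branch lengths
are clamped to zero with the deficit logged at debug level. On additive
distances the algorithm is exact; tests verify topology recovery
(Robinson–Foulds 0) and patristic-distance reconstruction to 1e−9 on
random additive trees, plus agreement with scikit-bio's independent NJ.
Bootstrap resamples loci (columns) with replacement — the standard
phylogenetic bootstrap — and scores each internal edge of the main tree
by the percentage of replicates containing the same bipartition
(dendropy's normalized split encoding).

The genomic relationship matrix is the GCTA-style standardized
cross-product; missing dosages are mean-imputed to 2p (GCTA's default
behavior), and monomorphic loci are rejected rather than silently
skipped. PCA is a dense symmetric eigen-decomposition of the GRM;
coordinates are eigenvectors scaled by √λ (λ clamped at 0), variance
fractions are λ/trace.

## Diversity indices

With allele frequencies p over non-missing calls in the evaluated
group: Na counts observed alleles, Ne = 1/Σp², Ho is the heterozygote
fraction, He = 1 − Σp² (Nei's gene diversity), I = −Σ p ln p, and
H = (2n/(2n−1))·He is the unbiased small-sample correction of He, so
H ≥ He with equality only when He = 0. The two names are kept separate
deliberately: reference implementations disagree on what "Nei's index"
means, and published tables sometimes report H values that cannot be
recovered from He by the correction alone; this package defines both
unambiguously instead of guessing another pooling. PLN is the
percentage of loci with Na ≥ 2 in the group.

Group comparisons use two-sided Welch (unequal-variance) t-tests on the
per-locus index vectors. When both vectors are constant and equal
(e.g. Na at fully polymorphic loci) the statistic is reported as
t = 0, p = 1 rather than NaN. The sampling evaluation draws
floor(q % × group size) accessions per group per proportion without
replacement — truncation reproduces the classical printed group-size
ladder (2/7, 5/19, 11/39, 16/58, 22/78 for a 22 + 78 split) which
round-half-up does not — and q = 100 uses the whole groups
deterministically.

## Core selection

Genotype coverage of a subset is the percentage of (locus,
genotype-class) pairs observed anywhere in the full collection that the
subset also exhibits; missing calls neither define nor satisfy targets.
As a coverage function it is monotone submodular, so greedy selection
(ties broken by smallest sample index) enjoys the (1 − 1/e) guarantee —
verified against exhaustive optima on small instances — and yields
non-increasing marginal gains, asserted on every run. Stopping rules:
target coverage, target size, or a marginal-gain floor; the default is
99 % coverage with a 0.01-point gain floor as a secondary stop. The
22-accession / 90.17 % benchmark is a dataset outcome, not a stopping
rule, so the benchmark drives the selector with `target_size=22` and
measures the coverage it attains.

## Fingerprint panel selection

Candidates are biallelic SNPs with MAF ≥ 0.05 and *zero* missing calls;
with zero missingness no missing-data rule is needed for pair
resolution. Heterozygotes count as their own genotype class (three-state
coding A/H/B). A pair of accessions is resolved by a locus subset iff
their dosage vectors differ somewhere on it; pair resolution is
evaluated on bit-packed pair-difference masks (one bitmask per candidate
locus over all n(n−1)/2 pairs), so a panel evaluation is an OR-reduce
plus popcount.

The GA uses bitmask individuals over the candidates, fitness
resolved_fraction − λ·|panel| with λ defaulting to 1/n_candidates (small
enough that any discriminating panel dominates any non-discriminating
one), tournament selection (k = 3), uniform crossover (rate 0.9),
per-bit mutation (rate 1/n_candidates), elitism of 2, and an initial
inclusion probability of max(4, 0.03·n)/n capped at 0.5. The run stops
early after 80 generations without best-fitness improvement; the
`ga_generations` field records the generations actually used. After the
GA, a repair step greedily completes a non-discriminating best
individual, and a pruning pass removes every locus whose removal keeps
all pairs resolved — the returned panel is minimal with respect to
single-locus removal, though not guaranteed globally minimum. Greedy
set cover (with the classical ln-bound) and increasing-size exhaustive
enumeration (guarded to 20 candidates; lexicographically smallest
optimum) provide the deterministic baseline and the ground-truth oracle;
on random 12-candidate instances the GA matches the exhaustive optimum
size in ≥ 95/100 cases. All three selectors raise the same explicit
error, carrying the closest pairs, when identical accessions make the
problem unsolvable.

## Pipeline and reproducibility

Every stochastic component takes an explicit seed; the pipeline derives
per-stage seeds as global seed + stage index so stages can be rerun in
isolation, and writes a manifest with parameters, seeds and SHA-256
checksums of all outputs. Identical config + seed gives identical
checksums. Exit codes separate configuration errors (2) from stage
failures (3).

## Problem sizes used in the benchmarks

The benchmark suite and `scripts/acceptance.py` run the generator at its
default scale (100 accessions, 5,500 loci) over 20 seeds for the core
and fingerprint benchmarks, 100 random additive trees (n ≤ 12) for NJ,
100 random 12-candidate instances for GA-vs-exhaustive, 200 bootstrap
replicates for the structure-recovery check, and small random matrices
for the brute-force kernel oracles. These sizes were chosen so the
whole suite completes in well under an hour on a single CPU while
keeping every statistical check comfortably powered.

## Known limitations

* Strictly diploid, biallelic dosage model downstream of the VCF; no
  phasing, imputation or tetraploid dosage calling.
* NJ is O(n³) dense; fine for hundreds of accessions, not for tens of
  thousands.
* The GA offers no optimality certificate beyond the pruning guarantee;
  use the exhaustive route when the candidate set is small enough.
* Admixture-model ancestry inference (ADMIXTURE-style K selection) is
  out of scope; PCA and the NJ tree are the structure views provided.
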