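# Methods

This note documents the models, the numerical choices, and what the
synthetic-data experiments do and do not demonstrate.

## Genotype representation and QC

Genotypes are stored as counts of the A1 allele of each marker's recorded
pair, with −1 as the missing sentinel; coordinates are 1-based inclusive bp
and interval lengths are (end − start)/1e6 Mb.  The text writer appends the
two allele columns to the `.map` file (read back alongside the standard
4-column dialect) so that the counting allele — and therefore the call
coding — survives a round trip bit-exactly.  When a 4-column map forces
allele inference, the minor allele (alphabetical tie-break) becomes A1.

QC applies, in a fixed order chosen for idempotence: autosome/position
filter and per-SNP filters (missingness > 0.10; GenCall ≤ 0.7 or
GenTrain ≤ 0.4 when a score table is present — both boundaries inclusive),
then per-sample missingness > 0.05 (boundary exclusive: exactly 5% is
kept), then one SNP-missingness re-check.  Merging two panels intersects
marker ids, harmonizes allele codings onto the first panel's pair with
strand-flip resolution by base complementation, and drops A/T and C/G
markers whose codings disagree, since their strand cannot be decided from
the allele pair alone.

## IBS and MDS

IBS for a pair is the mean over mutually genotyped loci of
1 − |g_i − g_j|/2.  The distance fed to classical scaling is the simple
complement 1 − IBS; it is monotone in IBS, so cluster geometry is
preserved whatever the affine choice.  Torgerson scaling double-centers
−D²/2; coordinates are the top-d eigenvectors scaled by √eigenvalue, with
each axis's sign fixed by making its largest-magnitude loading positive.
Negative eigenvalues (non-Euclidean inputs) are reported, never used.

## Admixture model

The sampler implements the admixture model with correlated allele
frequencies: Q_i ~ Dirichlet(α,…,α) with a single shared α; each allele
copy draws its cluster z from Q_i and its allele from p_{k,l};
p_{k,l} ~ Beta(p̄_l(1−F_k)/F_k, (1−p̄_l)(1−F_k)/F_k) with p̄_l ~ Beta(λ,λ),
λ fixed at 1.  Conjugate Gibbs updates are used for z, Q and p; p̄_l, F_k
and α move by random-walk Metropolis (step sd 0.03 per locus, 0.01, and
0.025 respectively; α has a uniform prior on (0, 10], F_k uniform on
(0, 1)).  Missing genotype copies contribute no likelihood term; their z
is drawn from Q alone.  Default chain lengths are 10,000 burn-in +
100,000 sweeps with 20 independent runs; all tests use short chains
(order 100 + 200) because at a few thousand SNPs the posterior for
well-separated populations is sharp and mixing is fast — posterior-mean
ancestry recovers simulated truth with MAE ≈ 0.01–0.02 at F = 0.3.

Evidence for K is the usual ln Pr(X|K) ≈ mean(lnL) − var(lnL)/2 over
post-burn-in sweeps, with the sample (n−1) variance.  Raw argmax of this
estimator plateaus with small noisy gains beyond the true K (measured on
simulated two-population data: a ~18,000-unit jump from K=1 to 2 followed
by ±50–200-unit differences between K=2, 3, 4), so `select_k` chooses K by
the rate of change instead — argmax of the Evanno ΔK second difference,
which cannot select endpoint K values (the standard caveat).  Label
switching across runs is resolved by permuting each run's columns to
minimize the total absolute difference against the incrementally built
reference; the permutation is found by optimal assignment (Hungarian
algorithm) rather than greedy matching, since K is small and the optimum
is exact.

## ROH calling and F_ROH

A run is a maximal stretch of consecutive homozygous-or-missing SNPs with
≥15 SNPs, inter-marker gaps ≤1 Mb, run-average density length/n ≤ 0.1 Mb
per SNP, length at least the class minimum, and missing calls within the
class allowance ((>4 Mb, 1), (>8 Mb, 2), (>16 Mb, 4)).  Interpretations
fixed here: the density rule is a run-average constraint (which makes the
15-SNP floor binding only for runs under 1.5 Mb, never for the ≥4 Mb
classes); the missing-call allowance applies per called run; heterozygote
allowance is zero; a missing call inside a run counts against the
allowance but its position still contributes to length.  Maximality means
no single-SNP extension keeps every constraint — the caller enumerates
candidate stretches split at heterozygotes and oversized gaps, then scans
start positions with O(m) vectorized validity rows; tests verify exact
agreement with a brute-force all-subintervals oracle.

Class calls merge per individual by bp-interval union (overlaps
coalesced); F_ROH>X sums union segments of length ≥X Mb over the
2,444.5 Mb chip-covered autosomal length, and F_ROH 4–8 = F_ROH>4 −
F_ROH>8.  The union rule is monotone and reproduces the decomposition
identity exactly.  The >4/>8 Mb thresholds proxy inbreeding age (~13 vs
~7 generations); these labels are reported as metadata, not estimated.

## Differentiation

Weir–Cockerham components are computed from sample sizes, allele
frequencies and observed heterozygosities per population; loci need ≥2
genotyped individuals per population and at least one polymorphic
population to contribute.  The multilocus estimator is ratio-of-sums;
negative per-locus components stay in the sums (unbiasedness) and are only
clamped at the Reynolds stage, where D = −ln(1−θ) with negatives set to 0
and θ ≥ 1 capped.  Neighbor joining follows Saitou–Nei with the standard
Q criterion; ties break to the lexicographically smallest pair of leaf
label sets, making output deterministic.  Branch lengths are clamped at
zero in Newick output with raw values retained.

## Selection scans

EHH around a core SNP is the probability that two random distinct carrier
haplotypes are identical over all SNPs between the core and the query
marker, computed marker-by-marker outward and truncated below 0.05 or at
the chromosome end; iHH integrates EHH against physical distance
(trapezoid, both directions summed).  Site-specific EHHS uses all
haplotypes, initialized by the core allele grouping and normalized by the
core homozygosity — it is defined for monomorphic cores, and only
monomorphic flanks (zero integral) skip a SNP.  iHS = ln(iHH_A/iHH_D)
standardized within 20 equal-width derived-frequency bins (bins under 20
SNPs merge with a neighbor); ancestral states being unknown on a chip, the
minor allele is taken as derived — |iHS| is polarity-invariant and
p-values are two-sided, so significance calls do not depend on it.
Rsb = ln(iES_A/iES_B), median-centered and sd-scaled genome-wide.  Both
report −log₁₀ of the two-sided normal p-value with the conservative
threshold 4.0.  eROHi outliers use the Tukey upper fence Q3 + 1.5·IQR of
the genome-wide ROH-incidence distribution (≈99% coverage under
normality); a 99th-percentile rule is available via configuration.  The
F_ST outlier scan takes the top 30 per-locus θ between the local breed and
all commercial populations pooled as one group, ties broken by genomic
position.  Overlap reports intersect the named outlier sets and list the
markers inside ±0.05 Mb windows around each outlier.

## Synthetic data: what it shows and what it does not

The generator is Balding–Nichols: ancestral frequencies uniform on
[0.05, 0.95], population frequencies Beta-concentrated with drift F_k,
haplotype alleles drawn independently per locus with per-copy ancestry
from Q.  Markers are evenly spaced (45,000 SNPs over 2,444.5 Mb ≈
0.054 Mb spacing, matching chip density), chromosome lengths proportioned
like the pig autosomes.  There is deliberately **no background linkage
disequilibrium**: the only haplotype structure is what the injectors
create.  Autozygosity injection copies one phase onto the other over
non-overlapping random intervals (mixture of Uniform(4,8) and
Uniform(8,30) Mb segments) until a target fraction is reached, truncating
the last segment to hit the target; the mixture weight is a draw
probability, and the study-scale preset converts a desired length share of
long segments into that probability via the component means.  Sweep
injection gives a chosen fraction of one population's haplotypes an
identical core (±5 Mb by default) around a focal SNP picked near the
chromosome midpoint where the derived allele is rarest — sweeps start from
low-frequency variants, which also keeps the post-sweep minor allele above
the MAF filter.

Consequences: ROH recall/precision and F_ROH recovery results transfer
well to real chips (the caller sees exactly the homozygosity signal it
would see in data); iHS/Rsb power numbers are against an LD-free
background, which is cleaner than real genomes, so they demonstrate the
machinery and its calibration rather than field sensitivity.  Scan
experiments run at chip density on a 2×160 Mb genome so the swept region
stays a small fraction of scanned SNPs, as it would in a full genome —
within-bin standardization is otherwise distorted by the sweep's own SNPs.
The conservation preset fixes six populations (16–20 individuals each,
drift 0.07–0.45) with breed-level autozygosity targets of 0.400/0.098 for
the two local-breed analogs, matching the contrast between an unmanaged
and a pedigree-managed population.

## Problem sizes and degenerate inputs

Validation experiments use 2,000–6,000 SNPs for sampling-based stages and
the full 45,000-SNP map where the ROH density rule matters; these sizes
give sampling noise well inside the asserted tolerances while keeping the
suite fast.  Degenerate inputs have defined behavior throughout: empty
panels and all-removed QC raise explicit errors, monomorphic loci are
excluded from F_ST sums and counted, pairs with no shared genotyped loci
are flagged missing in the IBS matrix and rejected by MDS, fewer than two
allele carriers make EHH undefined (the SNP is skipped in scans), and a
constant ROH-incidence vector yields no eROHi outliers.
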