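# Methods

This note documents the models and procedures implemented in `cllstrat`,
the defaults that matter, and what the synthetic-cohort tests do and do not
demonstrate about real data.

## Somatic call processing

**SNV/indel filtering.** The filter engine applies hard rules in a fixed
order and records, per removed record, the first rule that failed: tumor
depth strictly greater than 10 reads; variant allele fraction (VAF) at or
above 0.05; caller filter field `PASS` with quality strictly above 30;
population (catalog) allele frequency below 0.05; cohort germline frequency
at or below 0.01 (skipped when the record carries no germline annotation);
somatic cohort recurrence at or below 0.05; no repeat overlap; no
indel-proximity flag; VQSR score at or above 2.75 when present (callers
that do not emit a VQSR score skip the rule); panel-of-normals Phred at or
above 80. Depth and quality are strict inequalities; the VAF rule is
inclusive, matching the convention that calls with AF *below* 0.05 are
removed. Filtering is idempotent and monotone in every threshold; both
properties are exercised in the test suite.

**Cancer cell fraction.** CCF = VAF·(ρ·CN_t + 2(1−ρ)) / (ρ·m), with tumor
purity ρ ∈ (0,1], local total copy number CN_t and mutation multiplicity m.
When m is not supplied it is estimated as round(VAF·(ρ·CN_t + 2(1−ρ))/ρ),
floored at 1. Raw values above 1.05 are truncated to 1 and flagged — values
slightly above 1 are expected from binomial read sampling of clonal
variants. This is the standard purity/copy-number rescaling; it assumes the
variant is absent from normal cells and that multiplicity is constant
across tumor cells carrying it.

**CNA filtering.** Segments with quality < 10 are removed, segments
overlapping a user-supplied centromere/telomere exclusion track are
removed (a missing track is a warning, not an error), adjacent segments
with identical state and copy number are merged, and only merged segments
strictly longer than 100 kb are kept.

**SV consensus.** Break-ends are canonically ordered within each call;
calls of the same type whose two break-ends both lie within a tolerance
(default 100 bp, the common multi-caller merge convention) are
single-linkage clustered across callers, and clusters supported by at least
two distinct callers are reported with per-end median coordinates. Calls
with alternative allele fraction below 0.05 are dropped before merging.

## Driver discovery

Per-gene p-values from four external recurrence algorithms enter as a
pluggable table; the algorithms themselves are not part of this package. A
baseline binomial recurrence test (upper-tail P(X ≥ k) with per-sample hit
probability 1 − exp(−rate·length)) is included so the pipeline runs
end-to-end and so the selection rule's power and false-selection rate can
be measured by simulation.

Route 1 selects a gene when at least two of four per-algorithm
Benjamini–Hochberg FDRs fall below α, or when the BH-FDR of a combined
statistic does. Two combinations are provided: weighted Stouffer
(Z = Σwᵢ Φ⁻¹(1−pᵢ) / √Σwᵢ², upper-tail p) and the normalized weighted
harmonic mean (Σwᵢ)/(Σwᵢ/pᵢ). Weights default to 1. The harmonic mean is
used as a ranking statistic without asymptotic (Landau) calibration, which
is anti-conservative for small numbers of tests; since it feeds a BH step
over genes rather than an absolute significance claim, ranking is what
matters here. p-values at exactly 0 or 1 are clamped to (ε, 1−ε), ε=1e−15,
with a warning.

Route 2 computes minimally affected regions per CNA direction by a sweep
line over segment endpoints: maximal intervals where the number of distinct
affected samples reaches 4, reporting the max-coverage core of each run
(1-based inclusive coordinates). Gene-level focality and recurrence scores
follow the MutComFocal construction: per altered sample, recurrence
contributes 1/(lesions in that sample) and focality 1/(genes spanned by the
most focal lesion covering the gene); sums are normalized by cohort size.
Candidates need at least five coding SNV/indels, both scores above a
threshold (default: the cohort's 95th percentile, configurable) and a
mechanism concordant with the CNA direction (loss for tumor suppressors,
gain for oncogenes); genes failing only the SNV count form a separate
permissive list.

## Regulatory elements

The catalog is the merged intersection of ATAC open-chromatin and H3K27ac
peaks (via `pyranges`). Chromatin state is assigned from per-sample
segmentations only when the same state covers the region in at least two
samples; regions overlapping only one IGHV stratum's activity track are
flagged stratum-specific. Internal coordinates are 0-based half-open;
VCF-derived mutation positions (1-based) are converted at the boundary.

Enhancer–gene links are tested only within a shared TAD: Pearson r between
per-sample RE signal and gene expression, two-sided t-test p, BH-FDR over
all tested pairs, kept at r ≥ 0.3 and FDR ≤ 0.05. Constant vectors are
skipped with a warning.

Mutation recurrence per element uses a length-adjusted binomial model:
P(X ≥ n_mutated_samples) with X ~ Binom(N, 1 − exp(−rate·length)). This is
this package's background model — deliberately simple, uniform within the
element, with the background rate supplied by the caller (optionally
stratified externally). Hotspots are single positions mutated in ≥ 3
samples and kataegis is ≥ 6 mutations within 1 kb in one sample; both
cut-offs are package defaults and configurable. BH-FDR across the catalog
at threshold 0.1. Under a matched null the (uniform-smoothed) p-values are
uniform; the test suite checks this by KS test over 1000 simulated
elements.

Allelic skew between an assay (ATAC/RNA) VAF and the WGS VAF requires assay
depth ≥ 10; |difference| > 0.1 calls the direction, otherwise no skew.
Expression contrasts report the mutated/wild-type mean ratio with a
two-sided Welch t-test (Satterthwaite df); single-observation groups return
the ratio with an undefined p.

## Feature matrix

Continuous measures (signature exposures, telomere metrics, counts) are
binarized at the cohort median with ties going to 1. Gene-level coding
drivers are the union (OR) of SNV/indel and CNA presence. Recurrent CNA
features on the same chromosome whose phi coefficient
(ad−bc)/√((a+b)(c+d)(a+c)(b+d)) exceeds 0.3 are union-merged; merging is
transitively closed within a chromosome and never crosses chromosomes.
Features with fewer than five positives are dropped; noncoding drivers
additionally require presence in more than 5% of samples. The shipped
reference schema (58 coding drivers + 36 recurrent CNAs + 44 noncoding
drivers + 12 pathways + 28 global features + 8 complexity groups = 186) is
a synthetic reconstruction — real names where publicly printed, placeholder
identifiers elsewhere — and every category-count invariant is driven by the
schema object, so user schemas are first-class.

Driver counts implement three definitions: total functional burden (a
twelve-term exonic consequence list), SNV/indel-mutated coding drivers, and
all drivers (coding by SNV/indel or CNA, plus noncoding). Pathway burden
counts patients with qualifying lesions per pathway under four gene-set
modes (driver panel; exome high-impact; driver plus noncoding; all), with a
gene in several pathways counted in each. Merging the two pathway catalogs
keeps the primary catalog's entry for shared names (14 + 23 sharing 6 → 31).

## Genomic complexity (MCA)

The 17 genome-wide binary measures are expanded to a complete disjunctive
indicator table (two categories per measure, J = 34) and decomposed by
correspondence analysis: SVD of the standardized residual matrix
D_r^{−1/2}(P − rcᵀ)D_c^{−1/2}. Eigenvalues are squared singular values and
total inertia is (J − Q)/Q = 1; no Benzécri correction is applied (the
default behavior of the R package the analysis mirrors). Dimensions with
eigenvalue above the mean (1/Q) are retained, and variables are ranked by
their eigenvalue-weighted contribution over retained dimensions — i.e.
their share of retained explained inertia — with ties broken by schema
order. Constant columns are dropped before analysis.

Patients map to the eight complexity groups by the presence/absence bits of
the three selected variables (canonically CN loss, CN gain, trisomy), read
as a binary number: (0,0,0) → GC1 … (1,1,1) → GC8. The published label-to-
pattern order is only partially printed, so this fixed documented order is
a package convention. Conventional complexity is ≥ 4 CNAs.

## Genomic subgroups (offset NMF)

Each IGHV stratum's binary matrix (features × patients; the alteration
matrix plus binarized percent germline identity, age and sex) is factorized
as V ≈ WH + b·1ᵀ with all factors nonnegative. The offset b absorbs
features common to the whole stratum so the basis columns capture
subgroup-specific structure. Fitting minimizes generalized KL divergence by
multiplicative updates for W, H and b (the offset update is the row mean of
V/Λ); the objective is non-increasing at every iteration, a property the
test suite asserts numerically. Iteration stops at relative objective
change < 1e−6 (default) or 2000 iterations; initialization is uniform
random from the seed. All-zero feature rows are excluded from the updates
and reported with zero weight.

Rank selection: per candidate k, 30 restarts (10 minimum); patients are
co-assigned by argmax of H (ties to the lowest index); the consensus matrix
is the run-average co-assignment indicator; the cophenetic coefficient
correlates consensus distances (1 − consensus) with their average-linkage
hierarchical representation. k = 1 is reported as NA (zero-variance
distances). The selected rank maximizes the cophenetic coefficient, ties to
the smallest k. The same statistic on data with each feature's values
permuted across patients provides the overfitting control: on planted data
it sits well below the structured value.

Signatures are max-normalized basis columns labelled per stratum in order
of decreasing patient load; defining features have normalized weight ≥ 0.5.
Assignment deconvolves each patient vector onto unit-sum signature
profiles by greedy forward selection with nonnegative least squares
refitting, stopping when the sum-of-squares error improves by less than
1e−3; weights below 6% are discarded and the rest renormalized to
proportions (both thresholds are the published defaults of the mutation-
signature deconvolution tool this scheme follows). The label is the argmax
proportion. Proportions can be refined by a full-covariance Gaussian
mixture over a component grid, selecting the fewest components within 2 BIC
units of the optimum (maximal parsimony).

Validation utilities: split-half signature stability (Hungarian cosine
matching of independently fitted signature matrices) and hold-out
validation — fit on a training fraction (best of 5 restarts), match
training signatures to full-data signatures by cosine, assign every patient
under both models, and report the held-out confusion matrix and agreement
count.

## Outcome statistics

Fisher enrichment uses the two-sided exact test with the conditional-MLE
odds ratio (infinite for separated tables); constant vectors return NA with
a reason. Kaplan–Meier estimates carry Greenwood variance and the median is
the first time S(t) ≤ 0.5 (NA when never reached). The log-rank test
returns the joint (k−1 df) statistic, or, in extreme-pair mode for more
than two groups, compares the best and worst median-survival groups — the
convention used for multi-curve figures. Univariate Cox models use Efron
tie handling with Wald inference (via `lifelines`); monotone-likelihood and
non-convergent fits return NA with a reason instead of raising. BH-FDR is
applied per analysis table (one family per endpoint). With two groups and
no ties the log-rank statistic equals the Cox score test at β = 0, checked
numerically in the suite.

## Synthetic cohorts: what they do and do not show

The generator draws each patient's features Bernoulli(profile prevalence)
followed by symmetric bit-flip noise, which keeps planted-structure
recovery analyzable; real alteration matrices have correlated features,
prevalence gradients and missingness that this does not emulate. Event
times are exponential per subgroup with independent exponential censoring
calibrated so the censoring fraction equals the target (0.3 by default) —
adequate for log-rank/Cox power checks, not a model of trial follow-up.
Variant tables use Poisson depth (mean 100) and binomial allele counts at
the VAF implied by purity, copy number and clonality; 80% of variants are
clonal, the rest uniform CCF 0.2–0.8. RE/expression pairs achieve their
target correlation through a shared latent factor and TAD co-membership is
enforced by construction. Covariates: age ~ round N(65, 10), sex
Bernoulli(0.7 male), percent germline identity uniform within stratum
bounds (≥ 98% for u-IGHV).

The default study conditions are 411 patients (243 u / 168 m by
largest-remainder apportionment), three u and two m subgroups with disjoint
12-feature defining blocks at prevalence 0.85 over a 0.05 background, flip
noise 0.05, and subgroup hazard scales of 18/36/60 (u) and 48/96 (m)
months. Under these conditions rank selection recovers 3 and 2, hold-out
assignment agrees with the full-data assignment for ≥ 48 of 51 held-out
u-stratum patients, and signature defining sets equal the planted blocks.
Passing these tests demonstrates correctness of the machinery on data
satisfying its assumptions; it does not certify performance on real
cohorts, where subgroup separation is weaker and feature noise structured.

## Numerical choices and problem sizes

Random state everywhere is NumPy `default_rng` seeded explicitly;
fixed seeds give bit-identical outputs. Test simulations use deliberately
modest sizes — e.g. 30 NMF restarts per rank over k = 2…5, 500 Cox null
simulations at n = 60, 1000 simulated regulatory elements, 120 driver-
discovery cohorts of 200 samples — chosen as the smallest sizes at which
the checked statistical properties are stable. Degenerate inputs
(constant columns, zero vectors, all-zero rows, singular covariances,
single-observation groups) are handled explicitly and documented in the
docstrings of the functions involved.

## Known limitations

- The noncoding background model is uniform within an element; covariate-
  aware backgrounds (replication timing, expression) must be supplied as
  externally stratified rates.
- The harmonic-mean combination is uncalibrated (see above).
- The deconvolution forward selection is greedy; for highly collinear
  signature sets the proportion split between correlated signatures is not
  identifiable, though the argmax label is stable in practice.
- The GC-group label order and the reference schema's placeholder feature
  identifiers are package conventions, not published assignments.
- Cox models are unstratified; trial-level stratification and penalized
  multivariate selection are out of scope.
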