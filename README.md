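# cllstrat

Whole-genome stratification of chronic lymphocytic leukemia (CLL) as a
tested, reusable Python pipeline.

CLL risk stratification has historically rested on a handful of markers
(IGHV mutational status, del17p/*TP53*). Whole-genome sequencing of trial
cohorts makes a far richer description possible: coding and noncoding driver
mutations, recurrent copy-number alterations (CNAs), structural variants,
mutational signatures, telomere metrics and genome-wide complexity. This
package implements the statistical machinery needed to turn per-patient
somatic call tables into genomic subgroups with survival associations:

- **Somatic call processing** (`cllstrat.variants`) — SNV/indel hard-filter
  rules (depth > 10, VAF ≥ 0.05, PASS and quality > 30, population /
  germline allele-frequency, cohort recurrence, repeat and panel-of-normals
  criteria) with per-record removal reasons; cancer cell fractions
  CCF = VAF·(ρ·CN + 2(1−ρ))/(ρ·m) for purity ρ and multiplicity m; CNA
  quality/length filtering (segments > 100 kb after same-state merging);
  multi-caller SV consensus (reported when ≥ 2 callers agree within a
  break-end tolerance, median coordinates).
- **Driver discovery** (`cllstrat.drivers`) — per-gene p-value integration
  across four recurrence algorithms: a 2-of-4 BH-FDR vote, weighted Stouffer
  Z = Σwᵢzᵢ/√Σwᵢ², and the weighted harmonic mean of p-values
  (Σwᵢ)/(Σwᵢ/pᵢ); minimally affected CNA regions by sweep line (recurrent in
  ≥ 4 samples, max-coverage core); MutComFocal-style focality × recurrence
  scoring integrating SNVs with CNAs and mechanism-of-action concordance.
- **Regulatory elements** (`cllstrat.regulatory`) — an RE catalog from
  ATAC ∩ H3K27ac peaks with chromatin-state consensus (≥ 2 samples);
  enhancer–target links by Pearson correlation of signal and expression
  within TADs (r ≥ 0.3, FDR ≤ 0.05); length-adjusted binomial mutation
  recurrence with hotspot and kataegis annotation (BH-FDR < 0.1); allelic
  skew between assay and WGS VAFs (|Δ| > 0.1 at depth ≥ 10).
- **Feature matrix** (`cllstrat.features`, `cllstrat.schema`) — the binary
  patients × 186 alteration matrix: median binarization, SNV∪CNA gene
  features, phi (> 0.3) same-chromosome CNA merging, ≥ 5-occurrence
  prevalence filter (> 5% for noncoding drivers), driver counts and pathway
  burdens.
- **Genomic complexity** (`cllstrat.complexity`) — multiple correspondence
  analysis of 17 genome-wide binary measures (indicator-matrix SVD), top-3
  variable selection, and the eight GC groups from the presence/absence of
  CN loss, CN gain and trisomy.
- **Genomic subgroups** (`cllstrat.nmf`) — offset non-negative matrix
  factorization V ≈ WH + b·1ᵀ under KL divergence per IGHV stratum,
  cophenetic consensus rank selection with a randomized-data control,
  signatures at normalized weight ≥ 0.5, deconvolution (forward-selection
  NNLS) sample assignment, Gaussian-mixture refinement, and split / hold-out
  validation.
- **Outcome statistics** (`cllstrat.survival`) — Fisher exact enrichment
  (conditional-MLE odds ratio), Kaplan–Meier with Greenwood variance,
  log-rank (including the extreme-pair convention for > 2 groups), and
  univariate Cox with Efron ties, all with per-table BH-FDR.
- **Synthetic cohorts** (`cllstrat.synthetic`) — the generator that plants
  the structure every stage assumes: subgroup prevalence profiles, IGHV
  strata, bit-flip feature noise, purity/copy-number-consistent variant
  tables, TAD-constrained correlated RE/expression pairs, and
  subgroup-dependent exponential survival with censoring.

## Worked example

Recover planted genomic subgroups on a synthetic cohort (243 u-IGHV
patients, three subgroups, 5% feature noise):

```python
import pandas as pd
from cllstrat import nmf
from cllstrat.synthetic import default_cohort_spec, generate_cohort

cohort = generate_cohort(default_cohort_spec(seed=1))
u = cohort.stratum_patients("u")
V = cohort.feature_matrix.values.loc[u].T   # features x patients

est = nmf.estimate_rank(V, k_min=2, k_max=4, n_runs=10, seed=3, randomized=False)
print("cophenetic:", {k: round(v, 3) for k, v in est.cophenetic.items()})
print("selected rank:", nmf.select_rank(est))

model = nmf.fit_nmf_offset(V, k=3, seed=2)
sigs = nmf.extract_signatures(model, stratum="u")
labels = pd.Series({a.patient: a.label for a in nmf.assign_cohort(V, sigs)})
print(pd.crosstab(cohort.true_labels.loc[u], labels))
```

prints

```
cophenetic: {2: 0.922, 3: 1.0, 4: 0.994}
selected rank: 3
col_0     u-GS1  u-GS2  u-GS3
subgroup
u-GS1         0     81      0
u-GS2        81      0      0
u-GS3         0      0     81
```

The cophenetic coefficient peaks at rank 3 (the planted subgroup count), and
deconvolution assigns every patient to the cluster of their generating
profile — NMF signature numbering is arbitrary, so the confusion matrix is a
permutation of a diagonal. Each signature's defining features (normalized
weight ≥ 0.5) are exactly the 12 planted high-prevalence alterations of one
subgroup.

A thin CLI covers the batch steps: `cllstrat simulate`, `cllstrat
filter-snv`, `cllstrat complexity`, `cllstrat stratify`,
`cllstrat survival-cox`, `cllstrat schema-info`.

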