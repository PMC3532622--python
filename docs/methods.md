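# Methods

## Model and procedure

The classifier is a two-class nearest-centroid model on log-ratio expression
profiles restricted to a signature gene set. For a sample profile `x` aligned
to the signature genes, the MSI index is

    index(x) = cos(x, c_MSI) − cos(x, c_MSS)

where `c_MSI` and `c_MSS` are the per-gene mean log-ratios of the
hospital-MSI and hospital-MSS training samples and `cos` is cosine
similarity. "Cosine correlation" is read here as uncentered cosine
similarity; Pearson correlation (mean-centered) is available via the
`centered` flag, since on log-ratio data the two are close but not
identical. The index is scale-invariant in `x` and antisymmetric under
centroid swap, and lies in [−2, 2].

Two thresholds partition the index range. The primary threshold separates
MSS from signature-positive samples; the secondary threshold (≥ primary)
separates MSI-like from MSI among the positives. Both boundaries are
inclusive upward: a sample exactly at a threshold belongs to the upper
class. This convention is frozen into the signature file so downstream users
cannot drift from it.

### Gene selection

Genes are ranked by two-sided two-sample Student *t*-test (pooled variance;
Welch available by flag). A gene with zero pooled variance gets p = 1 and a
flag rather than an error — a constant gene carries no evidence. Ranking
ties are broken by descending |t|, then lexicographic gene id, so rankings
are total and reproducible.

Selection runs a class-stratified 10-fold cross-validation, repeated
(default 1000 times in the full design; the synthetic studies in this
repository use 50, which already saturates recovery at the default effect
size) with reshuffled folds. Every fold-complement is a training set; the
top-`k` genes by p-value (default `k` = signature size = 64) have an
appearance counter incremented. One "loop" is one repeat × fold, so counts
are conserved: they sum to repeats × folds × k. The signature is the 64
genes with the highest counts, ties broken by mean p across loops, then
lexicographically. Stratification is necessary at ~11% MSI prevalence;
unstratified folds would regularly lose the minority class. Counting per
fold (rather than once per repeat) was chosen because it uses every trained
ranking; with top-`k` equal to the signature size the two readings select
nearly identical sets.

### Threshold optimization and evaluation

Candidate thresholds are the midpoints between adjacent sorted unique index
values, plus one candidate below the minimum and one above the maximum, so
every achievable confusion table is visited exactly once and boundary
behaviour is unambiguous. The optimization criterion is the Youden-style sum
sensitivity + specificity; plain accuracy is reported separately in the
performance report rather than optimized. Ties go to the lowest threshold,
favoring sensitivity — appropriate for a screening read-out. A variant rule
constrains the search to sensitivity ≥ 0.90 (used for validation-cohort
read-outs); if the floor is unattainable the error reports the best
achievable sensitivity.

The secondary threshold is optimized by the same criterion among
signature-positive samples only, discriminating hospital-MSI from
hospital-MSS positives; it is undefined (an error) when the positives are a
single hospital class.

AUC is the empirical Mann–Whitney statistic (ties ½), computed via
scikit-learn. The 95% CI is a class-stratified bootstrap percentile interval
(2000 resamples, seeded) by default; an asymptotic DeLong interval is
available. Platform-reduced models (gene intersection below the development
set, floor 50 genes) keep their numeric thresholds but are flagged stale and
refuse to classify until re-optimized, because the index distribution shifts
with signature dimension.

### Normalization

Two-channel arrays against a common reference are normalized per array:
M = log2(sample/reference) minus a Lowess fit of M on
A = ½·log2(sample·reference). Defaults are span 0.3 with 3 robustness
iterations — common two-colour-array practice; both are configurable, and at
least 50 genes are required for a stable fit. Imputation (gene-mean) is a
separate step with a 20% per-gene missingness cap; imputed cells are
recorded in matrix metadata. The data model records the log scale; log2 is
used internally, and any log10 presentation (e.g. TYMS display) is a
plotting-layer conversion.

### Mutation frequency

Variant inclusion: coverage ≥ 10, variant reads ≥ 5, detection on both
strands (implemented as ≥ 1 read per strand, since no per-strand minimum is
part of the rule), protein-coding consequence, and absence from the normal
panel. Germline removal is modelled as the precomputed `in_normal_panel`
boolean — matched-normal sequencing is upstream of this package. Mutation
frequency is the fraction of distinct panel genes (615 by default) with at
least one surviving variant; multiple variants in a gene count once. Group
comparisons use the two-sided Student *t*-test on per-sample frequencies.

### Survival

The endpoint is 10-year distant-metastasis-free survival with administrative
censoring at the horizon. Kaplan–Meier, log-rank and Cox PH come from
lifelines; ties use the Efron approximation. The primary prognostic contrast
is binary — signature-positive (MSI ∪ MSI-like) vs MSS — because a
concordant-MSI stratum can have zero events, which makes per-stratum hazard
ratios degenerate; the three-way split is tested by log-rank. When one group
has no events the Cox estimate is still reported with a warning (the Wald CI
is unbounded). Stage filtering (e.g. stage II only) is a pipeline option,
not hard-coded.

## Synthetic-data generator

The generator emulates the study conditions the analysis assumes:

| parameter | default | meaning |
|---|---|---|
| `n_samples` | 276 | development-cohort size |
| `prevalence_msi` | 0.11 | latent MSI fraction |
| `prevalence_msi_like_among_mss` | 0.10 | MSI-like fraction within latent MSS |
| `n_genes` / `n_informative` | 1000 / 64 | measured genes / MSI-program genes |
| `effect_size_msi` | 2.0 σ | program shift in MSI (gene SD units) |
| `effect_attenuation_msi_like` | 0.6 | program strength in MSI-like |
| `hospital_error_rate` | 0.02 | label-flip rate of the hospital assay |
| `mut_rate_msi/msi_like/mss` | 0.082 / 0.064 / 0.016 | per-gene panel mutation rates |
| `hazard_ratio_positive` | 0.25 | DMFS hazard of signature-positive vs MSS |
| `event_rate_mss` | 0.20 | 10-year event fraction in MSS |
| `tech_noise_sd` | 0.05 | per-cell replicate noise (log2 units) |
| `tyms_shift_msi/msi_like` | 0.4 / 0.3 | TYMS up-regulation by class |

Latent classes are drawn per sample; informative genes are shifted by the
class effect with a fixed alternating up/down direction per gene (directions
are a property of the program, shared by every cohort from the same
configuration — otherwise a signature frozen on one cohort could not
transfer to another). The hospital label is the MSI indicator flipped at the
error rate. BRAF mutation status is drawn at class-dependent rates
(0.64 / 0.17 / 0.02). Variant records for mutated genes are built to pass
every inclusion filter (negative-binomial coverage around 80×, beta variant
fraction, binomial strand split clamped to both strands); an additional
`decoy_fraction` of records each violate exactly one filter so that
filtering is exercised and checkable. Survival times are exponential with
the baseline rate set from the MSS 10-year event fraction, scaled by the
hazard ratio for positive classes; "administrative censoring" is a common
cutoff at the horizon (zero event rate yields an all-censored cohort).
Replicates add Gaussian cell noise plus small day and operator offsets.

What the generator does **not** model: gene–gene correlation (genes are
independent given class, which makes selection easier than on real arrays),
intensity-dependent dye bias in the simulated log-ratios (the Lowess module
is validated on separately simulated two-channel intensities), microsatellite
biology itself, cohort heterogeneity in stage/grade, and informative
censoring. Passing tests therefore demonstrate correctness of the machinery
and recoverability under the stated conditions — not clinical performance on
real tumours.

## Numerical and design choices

- All stochastic routines take a seed or generator; sub-seeds are drawn
  below 2³¹. Identical configuration + seed reproduces outputs byte for byte
  (TSV writers emit 17 significant digits, so round trips are exact).
- The CV selector recomputes the vectorized t-test per training fold; it is
  cross-checked against `scipy.stats.ttest_ind` in the tests.
- Synthetic-study metrics that are statements about the study conditions
  (gene recovery, AUC against latent class, replicate concordance) are
  reported as averages over a handful of independent study seeds, since a
  single 276-sample cohort draw carries visible sampling noise.
- The development-scale studies shipped here run CV selection at 50 repeats
  and n = 276 × 1001 genes; at the default 2σ effect, recovery of the
  informative set is already complete at this depth.
- Degenerate inputs fail loudly: empty confusion tables, single-class
  inputs to AUC/log-rank/secondary threshold, zero-norm profiles for the
  cosine, unset or stale thresholds at classification time.

## Known limitations

- The equal-variance t-test is the default by design; strongly heteroskedastic
  genes are better served by the Welch flag.
- The bootstrap AUC CI is percentile-based and can undercover slightly below
  n ≈ 50 per class.
- `compare_groups` returns ±∞/0 for two zero-variance groups with unequal
  means — a flag value, not an inferential statement.
- The CLI covers the standard study flow; unusual designs (custom fold
  structures, alternative selection statistics) are library-level work.
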