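# Methods

This note documents the statistical procedures, the defaults and the
design decisions behind `gutbalance`, and what the synthetic-data tests
do and do not establish.

## Data model

All analyses operate on closed compositions: a samples × features matrix
of non-negative relative abundances renormalized to unit row sums
(percent tables are converted on read). Species-level rows are selected
from merged taxonomic tables by requiring a species rank and no strain
rank in the pipe-separated lineage; pathway tables keep community totals
and drop taxon-stratified rows. Zeros are handled by one table-wide
pseudo-fraction — half the smallest nonzero value of the table — applied
before any logarithm, so balances and fold-changes computed from the
same table are mutually comparable. Feature matching against annotation
maps is exact on the terminal species token after stripping rank
prefixes; unmatched features are `unknown` (no fuzzy matching).

Clinical tables carry one row per sample (patient id × timepoint
pre/post), binary covariates coded strictly 0/1, and CPET/lung-function
parameters that may be missing; missing values are excluded
pairwise per analysis and never imputed. The paired design keeps only
patients with both timepoints present; incomplete patients are dropped
with a logged warning.

## Diversity

Shannon (−Σ p ln p), Gini–Simpson (1 − Σ p²; the bounded form matching
[0,1]-scaled plots) and Chao1. Chao1 is a richness estimator defined on
counts; on relative data it is computed from pseudo-counts (abundance ×
library size, default 10 000, rounded), which makes it approximate —
the caveat is logged. Bray–Curtis distances come from
`scipy.spatial.distance`; PCoA is classical (Torgerson) scaling of the
double-centred squared distances with all eigenvalues reported, the
negative ones included rather than silently dropped (Bray–Curtis is not
Euclidean). PERMANOVA partitions squared distances
(SS_total = Σ_{i<j} d²/n; SS_within summed per group) and permutes
labels with a seeded generator; `strata=` restricts permutations within
a blocking factor such as patient, the appropriate choice for paired
designs, while the default is free permutation (the convention of
`vegan::adonis`). With non-Euclidean distances an anti-clustered
grouping can give SS_between < 0, so R² may be slightly negative under
the null; it is reported as computed. The permutation count defaults to
999.

## Paired differential abundance

Features are first filtered at 10 % prevalence across all samples (pre
and post pooled, boundary inclusive). Per feature, the paired Wilcoxon
signed-rank test on post − pre differences uses the exact distribution
for ≤ 25 untied pairs and the normal approximation with continuity and
tie correction otherwise; zero differences are dropped, and a feature
whose differences are all zero is flagged untestable (p = 1, excluded
from the FDR family). Benjamini–Hochberg q-values are computed across
all testable features of a table. Significance for downstream stages
defaults to q < 0.05; the raw-p reading (P < 0.05) is exposed
(`use_fdr=False` / `--no-fdr`) and is the convention used by the
pipeline's network-restriction and correlation-screen stages, matching
how such figure panels are conventionally gated. Log₂ fold-changes are
ratios of mean relative abundances with the shared pseudo-fraction. The
oxygen-class comparison sums the relative abundances of all features of
one class per sample, tests the sums with the paired Wilcoxon, and
reports the matched-pairs effect size r = |Z|/√n_pairs, the standard
definition compatible with percent-scale reporting; subgroup variants
(e.g. recurrent patients only) are obtained by subsetting the pairs
first.

## SparCC co-abundance networks

The variation matrix t_ij = Var(log(x_i/x_j)) is computed from the log
covariance. Under the sparsity assumption, basis variances solve
M ω² = (A∘t)·1 with M = A + diag(A·1), where A is the adjacency of
non-excluded pairs (initially all off-diagonal); correlations follow as
ρ_ij = (ω_i² + ω_j² − t_ij)/(2 ω_i ω_j), clipped to [−1, 1]. The
strongest still-active pair with |ρ| above the exclusion threshold
(default 0.1) is excluded and the system re-solved, up to 10 rounds; a
component left with fewer than two active partners is removed from the
system. Negative solved variances are clipped to a small floor with a
warning. Zero handling follows the method's own resampling design: each
of the (default 20) inference iterations draws sample-wise fractions
from a Dirichlet posterior over pseudo-counts (relative abundance ×
depth 10 000, +1 prior), and the final ρ is the element-wise mean.
Significance is a permutation pseudo p-value: each of the (default 100)
permutations shuffles every feature's values across samples
independently — breaking all between-feature dependence — re-runs the
full estimate, and p = (1 + exceedances)/(1 + permutations), two-sided
on |ρ|; it can never be exactly zero. Requiring at least 19 permutations
guarantees the 0.05 level is reachable. Pre and post networks are fitted
on their own sample subsets, independently; a sign-flip edge is a
feature pair significant in both networks with opposite correlation
signs, optionally restricted to the differentially abundant features,
and edge significance is per-condition (no joint test of the
difference).

Known limitation: at finite resampling depth the Dirichlet noise for
rare taxa inflates the variation matrix and attenuates |ρ| toward zero —
a planted ρ = 0.8 between two rare taxa may be estimated around 0.55–
0.7. The recovery tests therefore plant correlations between equally
abundant taxa to measure the correlation-recovery property itself;
estimates for rare taxa in real tables should be read as conservative.

## Partial Spearman screens

The feature, the parameter and each continuous covariate column are
average-ranked (binary and one-hot dummy columns pass through; ranking a
binary column is an affine map, so this is without loss); the partial
correlation is read off the precision matrix of the rank-correlation
matrix, ρ_xy·Z = −P_xy/√(P_xx P_yy), with significance from
t = ρ√((n−2−q)/(1−ρ²)) on n−2−q degrees of freedom. Cancer type enters
as one-hot dummies with the first level dropped — the only encoding
compatible with a correlation matrix. Cells are computed on their own
pairwise-complete cases (n reported per cell), collinear covariates
raise an error naming the offending columns, and exact monotone
agreement of x and y returns ±1. **No multiple-testing correction is
applied in this screen** — reported rows are filtered on raw p < 0.05
(and optionally a minimum |ρ|, 0.65 for the fungal profile), unlike the
differential module; results are for reporting and visualization, not
confirmatory inference. The change-table variant correlates per-patient
log₂((post+ε)/(pre+ε)) feature changes against the parameters.

## Balance selection

`compute_balance` implements the log-contrast exactly (proportional
form) or with the isometric-log-ratio scaling √(k₊k₋/(k₊+k₋))
(normalized form); swapping the two sets negates B, and the closure
constant cancels between the two means. Forward selection starts from
the ordered pair maximizing the fit criterion — squared Pearson
correlation with a continuous response, AUC of B as a ranking score for
a dichotomous one — then repeatedly adds the single feature, to either
side, that most improves the fit, giving a balance sequence
C = 2 … C_max (default 20). Ties break on the lexicographically
smallest feature id, plus side first, so selection is deterministic.
Cross-validation is 5 folds × 10 repeats by default (the referenced
method's convention; configurable): each training fold yields its own
forward path, held-out balance values are pooled within a repeat, and
the held-out criterion per C is averaged across repeats with its
standard error. C_opt is the smallest C within one standard error of
the best mean (parsimony; the reported balances in this study family
have 2–7 components). The global balance is refit on all samples at
C_opt and oriented so its association with the response is positive;
component and whole-balance frequencies are tallied across all CV fits
at C_opt. Both the in-sample fit of the global balance and the
cross-validated fit at C_opt are reported side by side, since either
may be the quantity of interest. For dichotomous responses the
accuracy is computed at the Youden-optimal threshold
(max sensitivity + specificity − 1). Overall survival is treated as a
continuous response (optionally log-transformed); censoring indicators,
if supplied, are ignored with a warning — the model correlates, it does
not model censoring. Phylum-level log-ratios (e.g.
Firmicutes/Bacteroidetes, or Proteobacteria against
Euryarchaeota + Actinobacteria) parse phyla from the lineage labels and
use the same pseudo-fraction.

## Synthetic data

The generator draws per-timepoint basis log abundances from a
multivariate normal with configurable mean spectrum (default N(0, 2²)
per taxon — a broad, realistic abundance range), unit log-sd, and
per-timepoint correlation matrices; differential effects add δ·ln2 to
the post log-means; closure yields the observed compositions. The
log-normal basis (rather than Dirichlet) matches SparCC's own generative
model, keeping network recovery tests fair. Sign flips are planted by
setting an entry to +ρ pre and −ρ post and projecting both matrices to
the nearest positive-semidefinite correlation matrix (eigenvalue
clipping at 1e-8, rescale to unit diagonal). Outcomes derive from a
planted balance B on the post compositions: VO₂ = intercept + β·(B − B̄)
+ γ·covariates + N(0, σ²); recurrence ~ Bernoulli(logistic(·));
OS = scale · exp(0.1·linear predictor + noise). A single integer seed
drives one generator for all draws, making outputs byte-reproducible.

The demo study (`default_study_spec`) mirrors the motivating study's
conditions: 15 paired patients, 60 species across five phyla, 10 taxa
shifted by 2–3 log₂ units (4–8-fold — the magnitude detectable in 15
pairs), the down-shifted taxa forming a collectively decreasing
anaerobe class with most other species unannotated (as in real
oxygen-tolerance maps), one planted ±0.8 sign-flip edge between
differential taxa, and a 2-vs-2-taxon balance (β = 3, σ = 1) driving
VO₂, recurrence and OS, with COPD and cancer type as confounders.

What the generator does **not** emulate: sequencing count noise
(negative-binomial/zero-inflation — generated compositions have no
structural zeros), taxonomic misassignment, fungal ITS-specific noise
(fungal tables come from the same compositional mechanism), or
censoring in survival. Passing recovery tests therefore establish
correctness of the algorithms under their own generative assumptions,
not robustness to those real-data artefacts.

## Test and acceptance problem sizes

Property tests use the smallest sizes at which each property is
informative: exhaustive PERMANOVA enumeration at n = 6; null PERMANOVA
calibration over 500 replicates of 20 samples with 99 permutations;
SparCC recovery with 50 taxa × 200 samples over 50 seeds (20 inference
iterations) and pseudo-p calibration with 25 taxa × 100 samples × 100
permutations; sign-flip detection with 25 taxa × 200 paired samples
over 50 seeds; partial-correlation oracle agreement on 200 random
instances; balance recovery with 15 taxa × 50 samples over 50 seeds
(5 × 10 CV) and null calibration over 50 seeds per response kind. The
acceptance script runs the full pipeline at the demo-study scale
(15 patients × 60 species) with the canonical settings (999 PERMANOVA
permutations, 20 SparCC iterations, 100 permutations, C_max = 20,
5 × 10 CV).

## Known limitations

- At n = 15 pairs the per-feature FDR-controlled Wilcoxon has limited
  power; single-seed demo runs legitimately vary in how many planted
  taxa reach q < 0.05.
- SparCC networks on 15 samples per condition are noisy; sign-flip
  counts at that scale are indicative, not stable.
- Chao1 from relative abundances depends on the assumed library size.
- The correlation screen is unadjusted for multiplicity by design.
- OS modelling ignores censoring by design.
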