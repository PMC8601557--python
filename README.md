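# gutbalance

Analysis toolkit for paired (before/after intervention) gut-microbiome
studies, built around the question of how the gut community of lung-cancer
patients changes after lung resection surgery and how those changes relate
to exercise capacity (CPET), tumour recurrence and overall survival.

It is written for researchers who have species-level relative-abundance
tables (MetaPhlAn-merged style) and/or pathway-abundance tables
(HUMAnN-pathabundance style) plus per-sample clinical metadata, and want
the complete downstream statistical workflow:

- **Diversity** — Shannon, Gini–Simpson and Chao1 alpha diversity;
  Bray–Curtis beta diversity with PCoA; one-way PERMANOVA with seeded,
  optionally stratified (within-patient) permutations.
- **Paired differential abundance** — 10 % prevalence filter, paired
  Wilcoxon signed-rank tests (exact for ≤ 25 untied pairs) with
  Benjamini–Hochberg FDR, log₂ fold-change ranking, and an
  aerobe/anaerobe aggregate comparison with the matched-pairs effect size
  r = |Z|/√n.
- **Co-abundance networks** — SparCC basis-correlation inference
  (averaged over Dirichlet-resampling iterations), permutation pseudo
  p-values, and extraction of edges whose significant correlation flips
  sign between conditions.
- **Covariate-adjusted screens** — partial Spearman correlations of
  features (or their post/pre changes) against lung-function and CPET
  parameters, adjusted for COPD and cancer type via the precision-matrix
  formula.
- **Microbial balances** — log-contrast balance computation and
  selbal-style cross-validated forward selection predicting continuous
  (VO₂, OS) or dichotomous (recurrence) responses, with C_opt chosen by
  the 1-SE rule and robustness frequencies across CV fits.
- **Synthetic paired studies** — a generator planting differential taxa,
  basis correlations (including sign flips) and balance-driven outcomes,
  so every stage has a ground-truth recovery test.

## The core quantities

A sample is a composition `X = (X1, …, Xk)`, carrying only relative
information. For two disjoint taxon sets `I+` (size k₊) and `I−` (size
k₋), the **balance** is the log-contrast

    B(X+, X−) = (1/k₊) Σ_{i∈I+} log Xi − (1/k₋) Σ_{j∈I−} log Xj,

invariant to the closure constant; the `normalized` form multiplies by
√(k₊k₋/(k₊+k₋)). Forward selection grows `I+`/`I−` one taxon at a time to
maximize the squared Pearson correlation of B with a continuous response
(or the AUC of B as a score for a binary one), and repeated k-fold
cross-validation picks the number of components C_opt.

**SparCC** estimates correlations of the unobserved absolute abundances
from the variation matrix `t_ij = Var(log(xi/xj))`: under sparsity the
basis variances ω² solve a linear system in the row sums of t, and
`ρ_ij = (ωi² + ωj² − t_ij)/(2ωiωj)`; strongly correlated pairs are
iteratively excluded and re-solved.

**PERMANOVA** partitions the squared Bray–Curtis distances into between-
and within-group sums of squares; `R² = SS_between/SS_total` and the
pseudo-F is referred to seeded label permutations,
`p = (1 + #{F_perm ≥ F_obs}) / (1 + n_perm)`.

## Worked example

```python
from gutbalance import (bray_curtis, permanova, prevalence_filter,
                        paired_wilcoxon, significant_features)
from gutbalance.balance_selection import BalanceSelector
from gutbalance.synthetic import default_study_spec, generate

ds = generate(default_study_spec(seed=1))          # 15 patients, 60 species
tp = ds.clinical.column("timepoint").reindex(ds.abundance.sample_ids)
print(permanova(bray_curtis(ds.abundance), tp, n_permutations=999, seed=1).summary())

da = paired_wilcoxon(prevalence_filter(ds.abundance, 0.10), ds.pairs)
sig = significant_features(da, alpha=0.05)
print(f"{len(sig)} species differential at q < 0.05")

post = ds.abundance.subset_features(sig).subset_samples(ds.pairs.post_samples)
model = BalanceSelector.from_clinical(post, ds.clinical, "VO2")
print(model.fit(C_max=8, seed=1).summary())
```

prints

```
PERMANOVA: pseudo-F = 1.6818, R2 = 5.7%, P = 0.052 (999 permutations, n = 30, 2 groups)
5 species differential at q < 0.05
Balance selection results
============================================================
response kind: continuous   CV: 5 folds x 10 repeats
C_opt = 2 (1-SE rule)
held-out fit at C_opt: 0.565
global balance: in-sample Pearson r = 0.771 (P = 0.00077)
I+ : k__Bacteria|p__Euryarchaeota|g__Genus009|s__Species_009
I- : k__Bacteria|p__Proteobacteria|g__Genus002|s__Species_002
```

Reading: community composition shifts modestly after surgery (R² = 5.7 %
of distance variance, P ≈ 0.05); five species pass the FDR-controlled
paired test; and a two-taxon balance of those species correlates with
VO₂ at r = 0.77 in-sample, holding up at a held-out R² of 0.57 — with
both members selected in 98 % of the cross-validation fits.

A command-line interface mirrors the library
(`gutbalance simulate | validate | convert | diversity | permanova |
diff | network | correlate | balance | run | report`); `gutbalance run
--config run.yaml --out results/` executes every stage from one seeded
YAML config and writes per-stage TSVs plus a run manifest.

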