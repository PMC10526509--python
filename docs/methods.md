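# Methods

## The procedure

Given a samples-by-features table with a binary grade label (aggressive
grade coded 1), the pipeline runs in five stages, all driven by one master
seed:

1. **Normalization.** Continuous features (Age) are z-scored with the
   population convention (divide by n) over the full table, once, before
   selection and classification. This mirrors the usual protocol for
   these cohorts; it leaks fold-level means/SDs of a single covariate into
   training, which is mild but real. A strict mode
   (`--per-fold-normalize` / `RunConfig.normalize_per_fold`) instead
   standardizes with training-split statistics inside every fold; it is
   off by default so that default runs match the conventional protocol.
2. **Fold partition.** One stratified 5-fold partition is generated from
   the seed and reused by both the selection and evaluation phases. The
   alternative — separate partitions per phase — is equally defensible
   but strictly less reproducible, and selection-on-training-split
   already keeps each fold's test data out of the selectors.
3. **Per-fold dual selection.** On each fold's *training split*:
   - **mRMR filter.** Continuous features are quantile-discretized
     (default 4 bins; ties on a bin edge go to the lower bin, making the
     binning order-invariant). Mutual information is the plug-in estimate
     in bits. Greedy forward selection picks exactly `⌈log₂ p⌉` features
     under the difference criterion (MID), `I(f;y) − mean_S I(f;s)`; the
     quotient criterion (MIQ) is available via config. Score ties within
     1e-9 resolve to the lower feature index — exact ties are common on
     small binary tables, and an explicit rule keeps the greedy path
     identical to its brute-force re-evaluation.
   - **LASSO embedded.** L1-penalized *logistic* regression (binary
     outcome), parameterized by the mean-loss penalty α with
     `C = 1/(n·α)`. The grid is 50 geometric points on
     `[1e-4·α_max, α_max]`, where `α_max = max|Xᵀ(y − ȳ)|/n` is the
     smallest penalty nulling all coefficients at the intercept-only
     solution. The best α maximizes mean accuracy over 10 inner
     stratified folds; ties go to the larger (sparser) α. The model is
     refit at that α on the whole training split, and features with
     |coefficient| > 1e-8 (numerical dust threshold) are selected. An
     all-zero fit yields a legal empty selection. Non-convergence is
     recorded as a warning, never an error.
4. **Weighting.** LASSO carries rank 2 and mRMR rank 1 by default
   (`fixed` mode), reflecting their relative standalone accuracies on the
   glioma cohorts; `empirical` mode re-derives the ranks on the data at
   hand by scoring each method standalone (per-fold selection + per-fold
   fits, best mean accuracy over the model list) and giving rank 2 to the
   winner, with exact ties keeping the canonical order. A feature's
   weight is the sum of ranks over every (fold, method) event that
   selected it: the cap is `folds × Σranks = 15`, a never-selected
   feature stays at 0.
5. **Sweep and selection.** For every threshold k from 15 down to 1 the
   candidate set `{f : weight(f) ≥ k}` is evaluated with all five
   classifiers on the shared partition. Adjacent thresholds frequently
   share a candidate set; each still gets its own sweep row (the
   deterministic evaluation is memoized on the feature tuple, so
   duplicate rows are byte-identical). Thresholds above the maximum
   observed weight have empty candidate sets and are skipped with a
   logged notice. The final configuration maximizes mean accuracy, with
   ties broken by (1) fewer features, (2) larger k, (3) the fixed model
   order SVM, LR, KNN, RF, AdaBoost. The runner-up rule excludes every
   cell tied with the winning accuracy and re-applies the same
   selection, i.e. it reports the second-best *distinct* accuracy.

## Classifiers and metrics

The five classifiers use fixed, deliberately plain settings (none of them
are tuned): KNN with k = 5 and Euclidean distance; L2 logistic regression
with C = 1; RBF SVM with C = 1 and `gamma = 1/(p·var)`; random forest
with 100 trees; AdaBoost with 50 depth-1 stumps. The master seed is
threaded into every stochastic model.

Six metrics are computed per fold from the confusion matrix at the
model's default decision threshold and averaged over folds (not pooled):
accuracy (reported as a percent), precision, recall/sensitivity,
specificity and F1 with the aggressive grade as the positive class, plus
ROC AUC from continuous scores — decision values for margin models,
predicted probabilities otherwise; the rank-based AUC only needs the
ordering. Degenerate ratios (zero denominators, or AUC on a single-class
test fold) are recorded as 0 with a warning rather than propagating NaN
into the means.

## The synthetic cohort generator

`SyntheticSpec`/`generate` emulate the structure of the public glioma
tables: a Bernoulli grade label (default P(positive) = 0.4, roughly the
TCGA class balance), class-conditional Bernoulli mutation indicators, an
Age column drawn from class-conditional normals (default 45 ± 13 vs.
58 ± 13 — a one-SD upward shift for the aggressive grade), and
label-independent Bernoulli(0.05) noise genes padding the table to 23
features. The default informative contrasts are loosely inspired by
reported class-conditional mutation frequencies in gliomas — an IDH1-like
marker mutated in 77% of low-grade but 3% of high-grade tumors, a
PTEN-like marker with the opposite direction (2% vs. 34%), and a weaker
NF1-like marker (1% vs. 11%) — as *inspiration*, not a claim of
distributional fidelity. An optional redundancy knob appends (noisy)
copies of the first informative feature to exercise the mRMR redundancy
penalty and L1's duplicate-splitting behavior.

What the generator does **not** emulate: linkage and co-mutation
structure between genes, missing data, label noise, site effects, or the
real cohorts' exact sizes. Passing the planted-recovery and null-behavior
tests therefore demonstrates that the pipeline recovers strong
conditionally-independent signal and does not hallucinate signal from
noise — not that it reproduces real-cohort accuracies.

## Numerical and design choices

- **Mutual information in bits** (log base 2). Any base gives the same
  greedy ranking; one base is fixed for reproducibility.
- **Subset-size heuristic**: the ceiling convention `⌈log₂ p⌉` (5 at
  p = 23, also 5 at p = 22); an explicit `m` override is exposed since
  rounding conventions differ at non-powers of two.
- **Categorical clinical features** (gender, race) are integer-coded by
  sorted level order — deterministic and row-order independent. One-hot
  encoding is deliberately not used so the feature count stays aligned
  with the published 22/23-feature tables.
- **Missing values are rejected**, not imputed; the intended inputs are
  preprocessed complete tables, and silent imputation would change what
  the selected features mean.
- **Seed policy**: per-stage seeds derive from the master seed by fixed
  offsets (per-fold LASSO seeds at +101+fold, evaluation at +7), so each
  stage is independently reproducible and a report re-run is
  byte-identical.
- **Empty LASSO folds** in the standalone baseline grid fall back to
  majority-class prediction for that fold.

## Problem sizes used in the shipped experiments

The planted-recovery experiment uses 3 strong informative markers (every
|Δp| ≥ 0.4), 17 noise genes, n = 600 and 10 seeds; the null-behavior
check uses a label-independent 21-feature table at n = 1000; the greedy
oracle check uses 100 random tables with p ≤ 10 at n = 50. These sizes
are large enough for the binomial contrasts to concentrate and small
enough that the full suite runs in minutes on one core.

## Known limitations

- Published real-cohort accuracies depend on unstated classifier
  settings and fold seeds, so they are reproducible only qualitatively;
  the shipped worked examples of the *selection rule* on the published
  sweep grids are exact regardless. `scripts/fetch_tcga_uci.py` exists
  for the qualitative comparison and needs network access.
- The weighting core supports exactly two selection methods; the types
  generalize to more, but nothing beyond two is tested.
- No wrapper selectors, no elastic net, no classifier tuning, no nested
  CV beyond the LASSO alpha search — all deliberate scope cuts.
- The full-table z-score default is a (documented, conventional) mild
  leak; use the per-fold flag for a strictly leak-free protocol.
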