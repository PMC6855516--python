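# Methods

## Model

Signal is organized as a tensor of cell types × marks × genomic bins
(200 bp by default), on the `log2(x + 0.1)` scale, with a per-(cell,
mark) availability mask. Missingness is *block* missingness: a mark is
observed for all bins of a cell type or for none. A sporadic NaN inside
an observed track is treated as an input error and reported with its
location, not silently handled.

Chromatin states are components of a multivariate-Gaussian mixture over
the `p` marks. For a cell type observing the mark subset `O`, the
emission of state `k` is the marginal `N(mu_k[O], Sigma_k[O, O])` — the
exact marginal of the full Gaussian, so cell types with different mark
sets are scored in a single consistent model.

Positional structure enters through a locus prior: each bin carries a
state-propensity vector shared by all cell types, updated from the
cell-weighted posterior state counts at that bin plus a pseudocount
(`prior_strength`, default 1 per bin, split across states). This is the
mechanism by which the states observed at a locus in data-rich cell
types inform data-poor ones. Cell weights `w_i = (#observed marks)/p`
enter only these assignment counts (locus prior and state frequencies),
never the Gaussian parameter estimation within states, and are not
renormalized across cell types.

## EM on sufficient statistics

Per state, parameters are read off the augmented moment matrix `V`
((1+p)×(1+p): count, sums, cross-products, in a fixed global mark
order). Blocks of `V` involving missing marks are filled with their
expectations under the current Gaussian via the regression
`X_mis ~ alpha + beta X_obs` with `beta = Sigma_mo Sigma_oo^-1`,
`alpha = mu_m - beta mu_o`; per-pattern contributions are re-embedded
into the global mark order and summed over cell types. Iteration starts
from `V_0 = I` and stops when the relative Frobenius change of `V` drops
below `1e-6` (at most 200 iterations; non-convergence returns the
current estimate with a warning). Soft state responsibilities enter as
fractional row weights.

Two variants of the missing×missing block are provided. The
`regression_only` variant plugs the regression predictions directly into
the cross-products, `(alpha + beta X_obs)'(alpha + beta X_obs)`, which
omits the conditional covariance of the missing marks and therefore
systematically shrinks missing-mark variances (this shrinkage is itself
asserted in the tests). The default `corrected` variant adds
`n * Sigma_cond` with `Sigma_cond = Sigma_mm - Sigma_mo Sigma_oo^-1
Sigma_om`, the textbook EM E-step, under which the observed-data
log-likelihood is non-decreasing across iterations (verified on random
fixtures).

Numerical choices: every covariance is floored with
`ridge * trace(Sigma)/p * I`, `ridge = 1e-6`, before inversion; a
singular observed block after the floor is an error naming the pattern.
Fitting a state requires an effective (weighted) count above `p`,
otherwise the covariance would be rank-deficient.

## Segmentation

The full fit is a generalized EM sweep: the E-step computes per (cell,
bin) state posteriors from the locus prior and the marginal emissions;
the M-step performs one sufficient-statistics V-update per state from
the current responsibilities (full inner convergence per sweep is
available via `nested_em` but is not the default); then the locus prior
and state frequencies are refreshed. Sweeps stop when the largest
posterior change falls below `1e-4` (default cap 60 sweeps). Hard labels
are the posterior argmax, ties broken toward the lowest state index.
States whose total responsibility falls below `1e-8` are dropped with a
log notice. Initialization is k-means (deterministic given the seed) on
the cell types with the most observed marks, restricted to their common
marks; remaining dimensions start at the global per-mark mean/variance.

Strategies. `direct` fits everything jointly as above. `two_step` fits
the complete-mark cell types first, then segments the remainder with the
first-step Gaussians as priors — posterior parameters are the
pseudo-count shrinkage `(s*prior + n*estimate)/(s + n)` in both mean and
covariance, so strength 0 re-estimates freely and strength → ∞ freezes
the first-step states; the first-step locus prior is also transferred by
default (`transfer_locus_prior`). `concatenated` replaces the locus
prior with a single global state-frequency vector, removing all
positional sharing. `common_marks` restricts to the marks present in
every cell type. `impute_first` segments a fully imputed tensor (from
the internal imputer or an external tool). With complete data, `direct`,
`common_marks` and `impute_first` coincide bit-wise given the same seed;
`concatenated` differs by construction (no locus prior).

## State-count selection

The number of states is chosen by inter-run reproducibility at a 50%
threshold, descending from `K_init`: at each K, four independent runs
are fitted, each on its own random half of the bins (random genomic
regions) with randomized k-means++ seeding and no locus prior; each run
then labels every bin from its emission posteriors. States are matched
across each pair of runs greedily by correlation of emission means, and
a state is reproducible in a pair when the Jaccard overlap of its
hard-label bin sets reaches the threshold. The selected K is the largest
at which at least three of the four runs mutually keep all K states and
reproduce all of them (a majority consensus, so one bad local optimum
cannot veto the correct K); if no K >= 2 qualifies, 1 is returned with a
warning.

Design rationale: reproducibility must be measured between runs that are
genuinely independent. With deterministic initialization two runs are
nearly identical, so even arbitrary carvings of structureless data
reproduce; conversely, with fully random initialization at an inflated
K, real states are split differently across runs and nothing reproduces
at K_init. Fitting on disjoint random bin subsets with randomized
seeding, excluding the locus prior (whose per-bin lock-in would make any
carve reproducible), and demanding a majority consensus over four runs
makes the criterion sharp in both directions: planted 3-state genomes
select 3 from `K_init = 8`, and single-Gaussian noise selects 1 from
`K_init = 5`, stably across seeds. A model-complexity penalty is
deliberately not part of the selection.

## Imputation

A missing (cell, mark, bin) value is predicted from the emission means
of the chromatin state at that bin: the hard-assigned state's mean, or
(default) the posterior-weighted average of state means. Observed values
pass through bit-exactly. Output stays on the log2 scale; the CLI can
invert the transform for bedGraph export. Accuracy against held-out
truth is reported per (cell, mark) as Pearson and Spearman correlation
and mean absolute error; correlations of zero-variance vectors are NaN
with a warning. Imputation beyond state means (local signal variation)
is out of scope.

## Evaluation metrics

ARI is the chance-corrected pair-counting Rand index (computed via
scikit-learn, verified against a pair-enumeration oracle); segmentation
similarity is exposed per cell and pooled. Cell-type distances are
`1 − ARI` between label sequences; concordance of a partial-data
distance matrix with the full-data one is the per-cell Spearman
correlation of distance vectors (diagonal excluded). Peaks are called
per (cell, mark) track by a z-test on the log-scale signal with the null
mean/sd estimated from all bins of the track — deliberately the
whole-genome, peak-contaminated null; a median/MAD variant is available
as `call_peaks_robust` — with one-sided upper-tail p-values and
Benjamini–Hochberg selection at FDR 0.05. Peak recovery by a
segmentation is the AUC of the precision–recall curve over state
prefixes: states ranked by decreasing emission mean of the mark (ties by
state index), one (recall, precision) point per prefix, the recall-0
limit (precision 1) prepended, trapezoid integration over recall.

## Expression and enhancer prediction

A region's categorical state profile is summarized as its occupancy
vector (fraction of bins per state; rows sum to 1). Regressing log2
RPKM on TSS-window (±2 kb) occupancy across all genes and cell types
gives one coefficient per state; because occupancy rows sum to 1 the
design with intercept is rank-deficient by one, so the fit uses the
minimum-norm least-squares solution and the intercept is folded into the
per-state coefficients (which are then identified). A region's numeric
predictor is the dot product of its occupancy with these coefficients.
Distal predictors use bins within 500 kb but outside the 2 kb core,
weighted uniformly per bin. Prediction power is R² (and adjusted R² for
model comparisons) of per-cell-type fits across genes or per-gene fits
across cell types; fits with fewer than 3 observations are NaN. Genes
are split into four categories at mean log2 RPKM = −1 and sd = 2
(boundaries assigned to the high side): off, low-variable,
high-variable, on. Enhancer references average Fantom5-style libraries:
mean log2(TPM + 0.1) per region (the pseudocount matches the signal
transform), and logit of mean peak presence clamped to
[1e-3, 1 − 1e-3]. Category-balanced Wilcoxon sign tests and regressions
of per-cell ARIs on missingness covariates depend on real data and are
provided as report scripts (`scripts/report_sign_test.py`,
`scripts/report_ari_regression.py`), not as tested operations.

## Synthetic genomes

The generator emulates the data the model assumes: per-bin state
propensities drawn from a symmetric Dirichlet with concentration
`1/locus_strength` (0 gives exactly uniform propensities, i.e. no
positional structure); per (cell, bin) states drawn from the shared
propensities; signals from state Gaussians whose means are
`separation`-scaled standard normal vectors and whose covariances are
random positive definite with unit-scale variances, on the log scale.
Defaults mirror the benchmark design on real epigenomes: 17 cell types ×
12 marks, 200 bp bins, `locus_strength = 2`, `separation = 3` (clearly
separated states), and the ablation protocol removes one sampled mark
set from each sampled cell type, with the grid {1, 5, 10} cells ×
{8, 10, 11} marks spanning ≈4%–54% missing (cell, mark) slices; removed
data are returned as held-out truth.

What the generator does not emulate: read-level noise and the Poisson
p-value computation, genomic autocorrelation along the chromosome
(bins are exchangeable given the propensities; the model itself has no
transition structure, so this is consistent), mark-specific signal
distributions, replicate structure, and mappability artifacts. Passing
tests therefore demonstrate correctness of the estimation and the
relative behavior of the strategies under the model's own assumptions,
not performance on real epigenomes.

## Problem sizes

The shipped experiments are sized for a single CPU: parameter recovery
and imputation use 8 cell types × 6 marks × 20 000 bins with K = 4 and
3 cells missing 3 marks; strategy comparisons use 5 replicates of 6 cell
types × 6 marks × 3 000 bins with strong locus structure
(`locus_strength = 4`, `separation = 1.5`) and 4 cells missing 4 marks;
state-count selection uses 2 000 bins (planted K = 3, `K_init = 8`) and
1 500 bins (single Gaussian, `K_init = 5`).

## Known limitations

- The host model is a locus-prior mixture, not the full Bayesian
  nonparametric machinery of the original segmentation platform (no
  local cell-type clustering, no Dirichlet-process state priors, no
  model-complexity penalty); positional borrowing across cell types is
  captured by the shared locus prior alone.
- No HMM transitions along the genome; states are position-class based.
- Per-bin (sporadic) missingness is rejected rather than modeled.
- The `regression_only` EM variant is provided for fidelity and
  comparison; it is biased (shrinks missing-mark variances) and is not
  the default.
- Peak calling with the whole-genome null is conservative when a mark is
  broadly enriched; use the robust variant for such tracks.
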