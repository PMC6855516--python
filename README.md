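# segem

Multi-cell-type chromatin-state genome segmentation when different cell
types have different chromatin marks profiled — without imputing the
missing tracks first.

## The problem

Genome segmentation assigns a chromatin-state label to every genomic bin
of every cell type from the combinatorial pattern of chromatin-mark
signals (histone-modification ChIP-seq, DNase hypersensitivity, ...).
Standard multi-cell segmentation requires the *same* marks in every cell
type, so analyses are usually restricted to the small common set, or the
missing tracks are machine-imputed beforehand — which is costly and
propagates imputation error into the annotation. In practice most large
collections (ENCODE, Roadmap Epigenomics, IHEC) are highly incomplete.

`segem` segments incomplete collections directly. Each chromatin state
`k` is a mixture component with a multivariate Gaussian emission
`N(mu_k, Sigma_k)` over all `p` marks. A cell type that observes only a
subset `O` of marks is scored through the *marginal* emission
`N(mu_k[O], Sigma_k[O, O])` — no per-bin imputation is ever needed. The
per-state parameters are estimated from block-missing data by EM on the
augmented sufficient-statistics matrix

    V = [[n,        1'X      ],        mean  = V[0, 1:] / n
         [X'1,      X'X      ]]        Sigma = V[1:, 1:] / n - mean mean'

whose blocks involving missing marks are filled with their expected
values via the regression `X_mis ~ alpha + beta X_obs` implied by the
current Gaussian (`beta = Sigma_mo Sigma_oo^-1`,
`alpha = mu_m - beta mu_o`), iterated to convergence. Positional
information is shared across cell types through a locus-specific prior:
a per-bin state-propensity vector that lets data-rich cell types inform
the annotation of data-poor ones. Cell types are weighted by the
fraction of observed marks (`w_i = #observed / p`) in the
state-assignment counts.

Five strategies for incomplete collections are implemented and
comparable on equal footing: direct joint segmentation, two-step
(fit states on complete cell types, then use them as Gaussian priors),
impute-first, concatenated pseudo-genome (no positional sharing), and
common-marks-only. After segmentation, missing tracks can be imputed
from the state emission means (hard or posterior-weighted), and the
package ships the full evaluation battery: adjusted Rand index (ARI),
1−ARI cell-type distances with Spearman concordance, z-test peak calling
with Benjamini–Hochberg FDR control, state-ranked precision–recall AUC
for peak recovery, and state-occupancy regression predictors of
expression and enhancer (eRNA) signals.

## Worked example

```python
import numpy as np
from segem import generate_genome, ablate_marks, segment, SegConfig, impute_marks
from segem.imputation import imputation_accuracy
from segem.evaluation import adjusted_rand_index

# synthetic genome: 4 states, 6 marks, 8 cell types, 5000 x 200 bp bins,
# then remove 3 marks from 3 cell types (the held-out truth is returned)
tensor, truth, _ = generate_genome(K=4, p=6, n_bins=5000, n_cells=8, seed=11)
partial, held = ablate_marks(tensor, n_cells_ablated=3, n_marks_ablated=3, seed=12)
print(f"missing slices: {(~partial.mask).sum()} of {partial.mask.size}")

model, prior, seg = segment(partial, SegConfig(K_init=4, seed=1))
ari = adjusted_rand_index(seg.labels.ravel(), truth.labels.ravel())
print(f"segmentation ARI vs planted states: {ari:.3f}")

imputed = impute_marks(partial, model, seg, mode="posterior")
acc = imputation_accuracy(imputed, held, held.mask)
print(acc.round(3).to_string(index=False))
```

prints

```
missing slices: 9 of 48
segmentation ARI vs planted states: 0.989
 cell  mark  pearson  spearman   mae
cell2 mark1    0.654     0.620 0.955
cell2 mark2    0.848     0.784 0.863
cell2 mark5    0.875     0.848 0.865
cell4 mark1    0.650     0.623 0.943
cell4 mark2    0.850     0.792 0.881
cell4 mark5    0.869     0.838 0.888
cell8 mark1    0.654     0.629 0.941
cell8 mark2    0.848     0.784 0.881
cell8 mark5    0.865     0.837 0.879
```

Despite 19% of the (cell, mark) tracks being absent, the direct
segmentation recovers the planted states almost exactly (ARI 0.989), and
the post-segmentation imputation reconstructs the removed tracks with
Pearson correlations of 0.65–0.88 on the log2 signal scale.

The occupancy→predictor transform used for expression prediction is one
dot product: with state coefficients 3 and −2 and a region that is 20%
state A and 80% state B,

```python
from segem.expression import region_predictor
region_predictor((0.2, 0.8), (3.0, -2.0))   # -> -1.0
```

A thin CLI mirrors the library for shell pipelines
(`segem simulate | segment | impute | eval`); tracks are read as
bedGraph / fixed-step wig, binned to 200 bp with blacklist removal and
the `log2(x + 0.1)` transform, and segmentations are written as merged
BED9 with one color per state.

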