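"""Mixture-model genome segmentation across cell types with block-missing marks.

Chromatin states are the components of a multivariate-Gaussian mixture
over the p marks.  Cell types with missing marks are scored through the
marginal density of their observed marks, and state parameters are
re-estimated by the sufficient-statistics EM of :mod:`segem.em`.  The
positional structure of the genome enters through a locus-specific prior:
a per-bin state-propensity vector shared across cell types, so that the
states seen at a locus in data-rich cell types inform the assignment in
data-poor ones.

Five strategies for handling incomplete mark collections are exposed:

1. ``segment`` — direct joint segmentation of all cell types on whatever
   marks each has (the method of interest);
2. ``segment_two_step`` — fit states on the complete-mark cell types,
   then segment the remaining cell types with those states as Gaussian
   priors;
3. ``segment_impute_first`` — segment a fully imputed tensor;
4. ``segment_concatenated`` — treat cell types as disjoint stretches of a
   single pseudo-genome, so no positional information is shared;
5. ``segment_common_marks`` — restrict to the marks observed in every
   cell type.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass, field, replace

import numpy as np
from scipy.special import logsumexp
from sklearn.cluster import KMeans

from . import em as _em
from .core import (
    LocusPrior,
    Segmentation,
    SignalTensor,
    StateModel,
    cell_weights,
    enumerate_patterns,
)

logger = logging.getLogger(__name__)

__all__ = [
    "SegConfig",
    "GaussianPrior",
    "SegmentResult",
    "segment",
    "segment_two_step",
    "segment_concatenated",
    "segment_common_marks",
    "segment_impute_first",
    "select_state_count",
]

_EMPTY_STATE_TOL = 1e-8


@dataclass
class SegConfig:
    """Segmentation settings.

    ``prior_strength`` is the pseudocount added to every bin's locus-prior
    update (and, in the two-step strategy, the strength of the Gaussian
    prior carried over from the first step).  ``max_sweeps`` bounds the
    outer E/M alternation; convergence is declared when the largest
    posterior change falls below ``posterior_tol``.
    """

    K_init: int = 20
    reproducibility_threshold: float = 0.5
    strategy: str = "direct"
    seed: int = 0
    prior_strength: float = 1.0
    em: _em.EMConfig = field(default_factory=_em.EMConfig)
    max_sweeps: int = 60
    posterior_tol: float = 1e-4
    nested_em: bool = False
    transfer_locus_prior: bool = True

    def __post_init__(self) -> None:
        if not (0 < self.reproducibility_threshold <= 1) and self.reproducibility_threshold != 0:
            raise ValueError("reproducibility_threshold must be in (0, 1] (or 0 to disable)")


@dataclass
class GaussianPrior:
    """Per-state Gaussian prior (mean, covariance, pseudo-count strength).

    State parameters fitted under this prior are shrunk toward it:
    ``mean = (s * m0 + n * mean_hat) / (s + n)`` and likewise for the
    covariance, with ``s`` the strength and ``n`` the effective count.
    """

    mean: np.ndarray  # (K, p)
    cov: np.ndarray  # (K, p, p)
    strength: float = 1.0

    def __post_init__(self) -> None:
        if self.strength < 0:
            raise ValueError("prior strength must be >= 0")


@dataclass
class SegmentResult:
    model: StateModel
    locus_prior: LocusPrior
    segmentation: Segmentation
    n_sweeps: int = 0
    active: np.ndarray | None = None  # surviving original state indices


# ---------------------------------------------------------------------------
# initialization


def _kmeans_init(
    tensor: SignalTensor, K: int, seed: int
) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    """Seed state means/covs by k-means on the most completely observed cells.

    Distances ignore missing dimensions by clustering only the marks
    common to the cells with the largest observed-mark count; remaining
    dimensions are filled with the global per-mark mean/variance over the
    cells that observe them.
    """
    p = tensor.n_marks
    obs_counts = tensor.mask.sum(axis=1)
    best = np.flatnonzero(obs_counts == obs_counts.max())
    common = np.flatnonzero(tensor.mask[best].all(axis=0))
    rows = np.concatenate(
        [tensor.values[i][common].T for i in best], axis=0
    )  # (n_rows, |common|)
    n_clusters = min(K, rows.shape[0])
    km = KMeans(n_clusters=n_clusters, n_init=4, random_state=int(seed) % (2**31))
    labels = km.fit_predict(rows)

    # global per-mark moments over observing cells
    gmean = np.zeros(p)
    gvar = np.ones(p)
    for j in range(p):
        cells = np.flatnonzero(tensor.mask[:, j])
        if len(cells):
            vals = tensor.values[cells, j, :].ravel()
            gmean[j] = vals.mean()
            gvar[j] = max(vals.var(), 1e-3)

    mean = np.tile(gmean, (K, 1))
    cov = np.tile(np.diag(gvar), (K, 1, 1))
    freq = np.full(K, 1.0 / K)
    for k in range(n_clusters):
        mean[k, common] = km.cluster_centers_[k]
        freq[k] = max((labels == k).mean(), 1e-3)
    freq /= freq.sum()
    return mean, cov, freq


# ---------------------------------------------------------------------------
# core fitter


def _fit(
    tensor: SignalTensor,
    K: int,
    config: SegConfig,
    use_locus_prior: bool = True,
    gaussian_prior: GaussianPrior | None = None,
    locus_prior_init: LocusPrior | None = None,
) -> SegmentResult:
    tensor.validate()
    p = tensor.n_marks
    n_cells, n_bins = tensor.n_cells, tensor.n_bins
    patterns = enumerate_patterns(tensor)
    weights = cell_weights(tensor)
    emc = config.em

    # per-pattern stacked observed rows: (len(cells) * n_bins, |obs|)
    pat_rows = {}
    for pt in patterns:
        vals = tensor.values[np.ix_(pt.cells, pt.observed)]  # (c, o, b)
        pat_rows[pt] = np.moveaxis(vals, 1, 2).reshape(-1, len(pt.observed))

    if gaussian_prior is not None:
        mean = gaussian_prior.mean.copy()
        cov = gaussian_prior.cov.copy()
        freq = np.full(K, 1.0 / K)
    else:
        mean, cov, freq = _kmeans_init(tensor, K, config.seed)

    if locus_prior_init is not None:
        prior = locus_prior_init.propensity.copy()
    else:
        prior = np.full((n_bins, K), 1.0 / K)
    prior_anchor = prior.copy()  # pseudocount target for the locus-prior update

    active = np.arange(K)  # surviving original state indices
    resp_prev = None
    n_sweeps = 0
    for n_sweeps in range(1, config.max_sweeps + 1):
        Kc = mean.shape[0]
        # ---- E-step: per (cell, bin) state posteriors ------------------
        logpost = np.empty((n_cells, n_bins, Kc))
        logprior = (
            np.log(np.clip(prior, 1e-300, None))
            if use_locus_prior
            else np.log(np.clip(freq, 1e-300, None))[None, :]
        )
        for pt in patterns:
            dens = np.empty((len(pt.cells) * n_bins, Kc))
            for k in range(Kc):
                dens[:, k] = _em.marginal_log_density(
                    pat_rows[pt], pt.observed, mean[k], cov[k], ridge=emc.ridge
                )
            dens = dens.reshape(len(pt.cells), n_bins, Kc)
            for ci, cell in enumerate(pt.cells):
                logpost[cell] = logprior + dens[ci]
        logpost -= logsumexp(logpost, axis=2, keepdims=True)
        resp = np.exp(logpost)

        # ---- drop empty states ----------------------------------------
        totals = resp.sum(axis=(0, 1))
        keep = np.flatnonzero(totals > _EMPTY_STATE_TOL)
        if len(keep) < Kc:
            dropped = [int(active[k]) for k in range(Kc) if k not in set(keep)]
            logger.info("dropping empty states %s", dropped)
            resp = resp[:, :, keep]
            resp /= resp.sum(axis=2, keepdims=True)
            mean, cov, freq = mean[keep], cov[keep], freq[keep]
            prior = prior[:, keep]
            prior /= prior.sum(axis=1, keepdims=True)
            prior_anchor = prior_anchor[:, keep]
            prior_anchor /= prior_anchor.sum(axis=1, keepdims=True)
            active = active[keep]
            resp_prev = None
            Kc = len(keep)

        # ---- M-step: Gaussian update per state via sufficient stats ----
        for k in range(Kc):
            blocks = []
            for pt in patterns:
                w = resp[list(pt.cells), :, k].reshape(-1)
                blocks.append(_em.DataBlock(pt.observed, pat_rows[pt], w))
            n_k = sum(_em.block_suffstats(b)[0] for b in blocks)
            if n_k <= _EMPTY_STATE_TOL:
                continue
            if config.nested_em and n_k > p:
                res = _em.em_fit_state(blocks, p, emc)
                m_hat, c_hat = res.mean, res.cov
            else:
                # one generalized-EM V update from the current parameters
                V = np.zeros((p + 1, p + 1))
                for b in blocks:
                    mis = tuple(j for j in range(p) if j not in set(b.observed))
                    if mis:
                        reg = _em.regression_from_params(
                            mean[k], cov[k], b.observed, mis, ridge=emc.ridge
                        )
                    else:
                        reg = _em.RegressionMap(np.zeros(0), np.zeros((0, p)))
                    V += _em.expected_moments_for_cell(b, reg, p, variant=emc.variant)
                _, m_hat, c_hat = _em.moments_from_V(V)
            if gaussian_prior is not None and gaussian_prior.strength > 0:
                s = gaussian_prior.strength
                k0 = int(active[k])
                m_hat = (s * gaussian_prior.mean[k0] + n_k * m_hat) / (s + n_k)
                c_hat = (s * gaussian_prior.cov[k0] + n_k * c_hat) / (s + n_k)
            mean[k] = m_hat
            cov[k] = _em.ridge_floor(c_hat, emc.ridge)

        # ---- locus prior / state frequency update ----------------------
        wresp = np.einsum("i,ibk->bk", weights, resp)
        freq = wresp.sum(axis=0)
        freq = freq / freq.sum()
        if use_locus_prior:
            counts = wresp + config.prior_strength * prior_anchor
            prior = counts / counts.sum(axis=1, keepdims=True)

        # ---- convergence ----------------------------------------------
        if resp_prev is not None and resp.shape == resp_prev.shape:
            if np.max(np.abs(resp - resp_prev)) < config.posterior_tol:
                resp_prev = resp
                break
        resp_prev = resp

    labels = np.argmax(resp_prev, axis=2)
    model = StateModel(mean=mean, cov=cov, state_freq=freq, mark_names=list(tensor.mark_names))
    locus = LocusPrior(propensity=prior if use_locus_prior else np.tile(freq, (n_bins, 1)),
                       concentration=config.prior_strength)
    seg = Segmentation(labels=labels, posterior=resp_prev, cell_names=list(tensor.cell_names))
    return SegmentResult(model, locus, seg, n_sweeps, active=active)


# ---------------------------------------------------------------------------
# public strategies


def segment(
    tensor: SignalTensor, config: SegConfig
) -> tuple[StateModel, LocusPrior, Segmentation]:
    """Direct joint segmentation on the (possibly incomplete) tensor."""
    res = _fit(tensor, config.K_init, config, use_locus_prior=True)
    return res.model, res.locus_prior, res.segmentation


def segment_two_step(
    tensor: SignalTensor, config: SegConfig
) -> tuple[StateModel, LocusPrior, Segmentation]:
    """Fit states on complete-mark cell types, then segment the rest under those priors."""
    complete = [int(i) for i in np.flatnonzero(tensor.mask.all(axis=1))]
    if not complete:
        raise ValueError(
            "no cell type with the complete mark set; use strategy='direct' instead"
        )
    rest = [i for i in range(tensor.n_cells) if i not in set(complete)]
    res1 = _fit(tensor.subset_cells(complete), config.K_init, config, use_locus_prior=True)
    if not rest:
        return res1.model, res1.locus_prior, res1.segmentation

    K1 = res1.model.K
    gp = GaussianPrior(
        mean=res1.model.mean, cov=res1.model.cov, strength=config.prior_strength
    )
    lp_init = res1.locus_prior if config.transfer_locus_prior else None
    res2 = _fit(
        tensor.subset_cells(rest),
        K1,
        config,
        use_locus_prior=True,
        gaussian_prior=gp,
        locus_prior_init=lp_init,
    )
    # Re-embed second-step states into the first-step state indexing (some
    # may have been dropped as empty in the second run).
    active2 = res2.active if res2.active is not None else np.arange(res2.model.K)
    mean = res1.model.mean.copy()
    cov = res1.model.cov.copy()
    freq = np.full(K1, 1e-12)
    for k2, k0 in enumerate(active2):
        mean[k0] = res2.model.mean[k2]
        cov[k0] = res2.model.cov[k2]
        freq[k0] = res2.model.state_freq[k2]
    freq /= freq.sum()
    model = StateModel(mean=mean, cov=cov, state_freq=freq, mark_names=list(tensor.mark_names))

    labels = np.empty((tensor.n_cells, tensor.n_bins), dtype=int)
    post = np.zeros((tensor.n_cells, tensor.n_bins, K1))
    for ci, cell in enumerate(complete):
        labels[cell] = res1.segmentation.labels[ci]
        post[cell] = res1.segmentation.posterior[ci]
    for ci, cell in enumerate(rest):
        labels[cell] = active2[res2.segmentation.labels[ci]]
        post[cell][:, active2] = res2.segmentation.posterior[ci]
    lp = np.zeros((tensor.n_bins, K1))
    lp[:, active2] = res2.locus_prior.propensity
    lp /= np.clip(lp.sum(axis=1, keepdims=True), 1e-300, None)
    seg = Segmentation(labels=labels, posterior=post, cell_names=list(tensor.cell_names))
    return model, LocusPrior(lp, config.prior_strength), seg


def segment_concatenated(tensor: SignalTensor, config: SegConfig) -> Segmentation:
    """Segment with cell types as one pseudo-genome: no positional sharing.

    The locus prior is replaced by a single global state-frequency vector,
    so bins of different cell types no longer share positional information.
    """
    res = _fit(tensor, config.K_init, config, use_locus_prior=False)
    return res.segmentation


def segment_common_marks(tensor: SignalTensor, config: SegConfig) -> Segmentation:
    """Segment using only the marks observed in every cell type."""
    common = np.flatnonzero(tensor.mask.all(axis=0))
    if len(common) == 0:
        raise ValueError("no mark is observed in every cell type")
    res = _fit(tensor.subset_marks(common), config.K_init, config, use_locus_prior=True)
    return res.segmentation


def segment_impute_first(
    tensor: SignalTensor, imputed: SignalTensor, config: SegConfig
) -> Segmentation:
    """Segment a fully imputed tensor (internally or externally imputed)."""
    if not imputed.mask.all():
        raise ValueError("imputed tensor must have a full observation mask")
    res = _fit(imputed, config.K_init, config, use_locus_prior=True)
    return res.segmentation


# ---------------------------------------------------------------------------
# state-count selection


def _greedy_match(meanA: np.ndarray, meanB: np.ndarray) -> list[tuple[int, int]]:
    """Greedy pairing of states by correlation of emission-mean vectors."""
    KA, KB = meanA.shape[0], meanB.shape[0]
    corr = np.empty((KA, KB))
    for a in range(KA):
        for b in range(KB):
            va, vb = meanA[a], meanB[b]
            sa, sb = va.std(), vb.std()
            if sa < 1e-12 or sb < 1e-12:
                corr[a, b] = -np.inf if not (sa < 1e-12 and sb < 1e-12) else 1.0
            else:
                corr[a, b] = np.corrcoef(va, vb)[0, 1]
    pairs = []
    usedA: set[int] = set()
    usedB: set[int] = set()
    flat = sorted(
        ((corr[a, b], a, b) for a in range(KA) for b in range(KB)), reverse=True
    )
    for _, a, b in flat:
        if a in usedA or b in usedB:
            continue
        pairs.append((a, b))
        usedA.add(a)
        usedB.add(b)
    return pairs


def _seeded_init(
    tensor: SignalTensor, K: int, seed: int
) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    """Randomized k-means++ seeding (centers only, no Lloyd iterations).

    Used for the independent reproducibility runs: the seeds are spread
    over the data but genuinely random, so two runs explore different
    local optima when the state structure is not real.
    """
    from sklearn.cluster import kmeans_plusplus

    p = tensor.n_marks
    obs_counts = tensor.mask.sum(axis=1)
    best = np.flatnonzero(obs_counts == obs_counts.max())
    common = np.flatnonzero(tensor.mask[best].all(axis=0))
    rows = np.concatenate([tensor.values[i][common].T for i in best], axis=0)
    centers, _ = kmeans_plusplus(
        rows, n_clusters=min(K, rows.shape[0]), random_state=int(seed) % (2**31)
    )
    gmean = np.zeros(p)
    gvar = np.ones(p)
    for j in range(p):
        cells = np.flatnonzero(tensor.mask[:, j])
        if len(cells):
            vals = tensor.values[cells, j, :].ravel()
            gmean[j] = vals.mean()
            gvar[j] = max(vals.var(), 1e-3)
    mean = np.tile(gmean, (K, 1))
    mean[: len(centers), common] = centers
    return mean, np.tile(np.diag(gvar), (K, 1, 1)), np.full(K, 1.0 / K)


def _reproducibility_run(
    tensor: SignalTensor, K: int, seed: int, config: SegConfig
) -> tuple[StateModel, np.ndarray]:
    """One independent run for reproducibility scoring.

    Fits a K-state model on a random half of the bins (random genomic
    regions) with randomized seeding and no locus prior, then labels
    every bin of the full tensor from the emission posteriors under the
    fitted state frequencies.
    """
    rng = np.random.default_rng(seed)
    sub = np.sort(rng.choice(tensor.n_bins, size=max(tensor.n_bins // 2, 1), replace=False))
    tsub = SignalTensor(
        tensor.values[:, :, sub],
        tensor.mask,
        tensor.bins.iloc[sub].reset_index(drop=True),
        list(tensor.mark_names),
        list(tensor.cell_names),
    )
    global _kmeans_init
    orig = _kmeans_init
    _kmeans_init = _seeded_init
    try:
        res = _fit(tsub, K, replace(config, seed=seed), use_locus_prior=False)
    finally:
        _kmeans_init = orig
    model = res.model
    labels = np.empty((tensor.n_cells, tensor.n_bins), dtype=int)
    logfreq = np.log(np.clip(model.state_freq, 1e-300, None))
    for pt in enumerate_patterns(tensor):
        rows = np.moveaxis(
            tensor.values[np.ix_(pt.cells, pt.observed)], 1, 2
        ).reshape(-1, len(pt.observed))
        lp = np.empty((rows.shape[0], model.K))
        for k in range(model.K):
            lp[:, k] = _em.marginal_log_density(
                rows, pt.observed, model.mean[k], model.cov[k], ridge=config.em.ridge
            )
        lab = (lp + logfreq).argmax(axis=1).reshape(len(pt.cells), tensor.n_bins)
        for ci, cell in enumerate(pt.cells):
            labels[cell] = lab[ci]
    return model, labels


def select_state_count(tensor: SignalTensor, config: SegConfig) -> int:
    """Choose the number of states by inter-run reproducibility.

    Starting from ``K_init`` and descending, the model is fitted twice
    with independent seeds, each run on its own random half of the bins
    with randomized seeding; states are matched greedily by correlation
    of their emission means, and a state counts as reproducible when the
    Jaccard overlap of its hard-label bin sets (pooled over cell types)
    reaches the reproducibility threshold (default 50%).  The selected K
    is the largest at which both runs keep all K states and every state
    is reproducible; if no K >= 2 qualifies, 1 is returned with a
    warning (a degenerate single-state fit).
    """
    if config.reproducibility_threshold == 0:
        return config.K_init
    if config.K_init < 2:
        raise ValueError("K_init must be >= 2")
    thr = config.reproducibility_threshold

    def pair_reproducible(runA, runB, K: int) -> bool:
        (modelA, labA), (modelB, labB) = runA, runB
        if modelA.K != K or modelB.K != K:
            return False
        labA, labB = labA.ravel(), labB.ravel()
        count = 0
        for a, b in _greedy_match(modelA.mean, modelB.mean):
            setA = labA == a
            setB = labB == b
            union = np.logical_or(setA, setB).sum()
            if union and np.logical_and(setA, setB).sum() / union >= thr:
                count += 1
        return count == K

    # Accept K when a majority consensus exists: at least 3 of 4 independent
    # runs mutually reproduce all K states (a single bad local optimum must
    # not veto the correct K).
    from itertools import combinations

    n_runs = 4
    for K in range(config.K_init, 1, -1):
        seed = config.seed + 37 * K
        runs = [
            _reproducibility_run(tensor, K, seed + i, config) for i in range(n_runs)
        ]
        ok = {
            (i, j): pair_reproducible(runs[i], runs[j], K)
            for i, j in combinations(range(n_runs), 2)
        }
        if any(
            ok[(i, j)] and ok[(i, k)] and ok[(j, k)]
            for i, j, k in combinations(range(n_runs), 3)
        ):
            return K
    warnings.warn(
        "no reproducible multi-state model; returning 1",
        RuntimeWarning,
        stacklevel=2,
    )
    return 1
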