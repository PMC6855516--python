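"""Gaussian parameter estimation from block-missing data via EM on sufficient statistics.

For each chromatin state, the data assigned to it form an (effective)
``n x p`` matrix whose columns split, per cell type, into observed and
missing marks.  Rather than imputing individual values, the algorithm
keeps the augmented moment matrix

    V = [[n,        1'X_obs,        1'X_mis       ],
         [X_obs'1,  X_obs'X_obs,    X_obs'X_mis   ],
         [X_mis'1,  X_mis'X_obs,    X_mis'X_mis   ]]

(in canonical mark order) and fills in the blocks that involve missing
marks with their expected values under the current Gaussian.  The
expectation uses the regression of missing on observed marks,
``X_mis ~ alpha + beta X_obs``, whose coefficients are closed-form
functions of the moments of V.  Iterating expectation and re-accumulation
to convergence yields the maximum-likelihood mean and covariance.

Two variants of the missing x missing block are provided:

``regression_only``
    plugs the regression predictions straight into the cross-products,
    i.e. ``X_mis'X_mis ~ (alpha + beta X_obs)'(alpha + beta X_obs)``.
    This omits the conditional covariance of the missing marks given the
    observed ones and therefore shrinks missing-mark variances.
``corrected`` (default)
    adds ``n * Sigma_cond`` with
    ``Sigma_cond = Sigma_mm - Sigma_mo Sigma_oo^-1 Sigma_om`` to the
    missing x missing block, which is the textbook EM E-step for a
    multivariate Gaussian and makes the observed-data likelihood
    non-decreasing across iterations.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
from scipy.stats import multivariate_normal

from .core import MissingnessPattern, MomentMatrix, RegressionMap

__all__ = [
    "EMConfig",
    "EMResult",
    "DataBlock",
    "init_moment_matrix",
    "moments_from_V",
    "ridge_floor",
    "regression_from_moments",
    "regression_from_params",
    "block_suffstats",
    "expected_moments_for_cell",
    "em_fit_state",
    "marginal_log_density",
    "observed_loglik",
]


@dataclass
class EMConfig:
    """Settings for the per-state sufficient-statistics EM.

    ``tol`` is the relative Frobenius-norm change of V at which the
    iteration stops; ``ridge`` scales the covariance floor
    ``ridge * trace(Sigma)/p * I`` added before every inversion.
    """

    max_iter: int = 200
    tol: float = 1e-6
    variant: str = "corrected"  # or "regression_only"
    ridge: float = 1e-6
    track_loglik: bool = False

    def __post_init__(self) -> None:
        if self.tol <= 0:
            raise ValueError("tol must be > 0")
        if self.max_iter < 1:
            raise ValueError("max_iter must be >= 1")
        if self.variant not in ("corrected", "regression_only"):
            raise ValueError(f"unknown variant {self.variant!r}")


@dataclass
class EMResult:
    mean: np.ndarray
    cov: np.ndarray
    n_iter: int
    converged: bool
    V: np.ndarray
    loglik_trace: list[float] = field(default_factory=list)


@dataclass
class DataBlock:
    """Observed rows of one missingness pattern, with optional row weights.

    ``X`` has one column per *observed* mark (indices ``observed`` in the
    canonical global order); ``weights`` are soft state responsibilities
    (fractional row multiplicities), defaulting to 1.
    """

    observed: tuple[int, ...]
    X: np.ndarray  # (n_rows, n_observed)
    weights: np.ndarray | None = None

    def __post_init__(self) -> None:
        self.X = np.atleast_2d(np.asarray(self.X, dtype=float))
        self.observed = tuple(int(j) for j in self.observed)
        if self.X.shape[1] != len(self.observed):
            raise ValueError("X column count does not match observed mark set")
        if self.weights is not None:
            self.weights = np.asarray(self.weights, dtype=float)
            if self.weights.shape != (self.X.shape[0],):
                raise ValueError("weights length does not match rows")


def init_moment_matrix(p: int) -> np.ndarray:
    """Initial guess V_0: the (1+p) x (1+p) identity.

    Implies count 1, zero means and identity covariance, so the first
    regression map is alpha = 0, beta = 0.
    """
    if p < 1:
        raise ValueError("p must be >= 1")
    return np.eye(p + 1)


def moments_from_V(V: np.ndarray) -> tuple[float, np.ndarray, np.ndarray]:
    """Read (n, mean, cov) off an augmented moment matrix."""
    n = float(V[0, 0])
    mean = V[0, 1:] / n
    cov = V[1:, 1:] / n - np.outer(mean, mean)
    return n, mean, 0.5 * (cov + cov.T)


def ridge_floor(cov: np.ndarray, ridge: float) -> np.ndarray:
    """Add ``ridge * trace(Sigma)/p`` to the diagonal (at least ``ridge``)."""
    p = cov.shape[0]
    scale = max(float(np.trace(cov)) / p, 1.0) * ridge
    return cov + scale * np.eye(p)


def regression_from_params(
    mean: np.ndarray,
    cov: np.ndarray,
    observed: tuple[int, ...],
    missing: tuple[int, ...],
    ridge: float = 1e-6,
    pattern_name: str = "",
) -> RegressionMap:
    """Regression of missing on observed marks under a Gaussian (mean, cov)."""
    obs = list(observed)
    mis = list(missing)
    covr = ridge_floor(cov, ridge)
    Soo = covr[np.ix_(obs, obs)]
    Smo = cov[np.ix_(mis, obs)]
    try:
        beta = np.linalg.solve(Soo, Smo.T).T
    except np.linalg.LinAlgError as err:
        raise np.linalg.LinAlgError(
            f"singular observed-mark covariance block for pattern "
            f"{pattern_name or observed!r}"
        ) from err
    alpha = mean[mis] - beta @ mean[obs]
    cond = cov[np.ix_(mis, mis)] - beta @ cov[np.ix_(obs, mis)]
    return RegressionMap(alpha=alpha, beta=beta, cond_cov=0.5 * (cond + cond.T))


def regression_from_moments(
    V: np.ndarray | MomentMatrix,
    pattern: MissingnessPattern,
    ridge: float = 1e-6,
) -> RegressionMap:
    """Closed-form (alpha, beta) from the sufficient statistics in V."""
    arr = V.V if isinstance(V, MomentMatrix) else np.asarray(V, dtype=float)
    _, mean, cov = moments_from_V(arr)
    return regression_from_params(
        mean, cov, pattern.observed, pattern.missing, ridge=ridge,
        pattern_name=str(pattern.observed),
    )


def block_suffstats(block: DataBlock) -> tuple[float, np.ndarray, np.ndarray]:
    """Weighted (n, sums, cross-products) of one observed block."""
    X = block.X
    if block.weights is None:
        n = float(X.shape[0])
        s = X.sum(axis=0)
        G = X.T @ X
    else:
        w = block.weights
        n = float(w.sum())
        s = w @ X
        G = X.T @ (X * w[:, None])
    return n, s, G


def expected_moments_for_cell(
    block: DataBlock,
    reg: RegressionMap,
    p: int,
    variant: str = "corrected",
) -> np.ndarray:
    """Expected sufficient-statistic contribution V^k of one cell group.

    The observed blocks are exact weighted sums/cross-products; blocks
    involving missing marks are filled from the regression predictions
    ``alpha + beta x_obs`` without touching individual bins:

        sum x_mis        -> n alpha + beta s_o
        X_mis' X_obs     -> alpha s_o' + beta G_oo
        X_mis' X_mis     -> n alpha alpha' + alpha (beta s_o)' +
                            (beta s_o) alpha' + beta G_oo beta'
                            [+ n Sigma_cond under variant="corrected"]

    The result is embedded in canonical global mark order.
    """
    obs = list(block.observed)
    mis = [j for j in range(p) if j not in set(obs)]
    n, s, G = block_suffstats(block)
    V = np.zeros((p + 1, p + 1))
    V[0, 0] = n
    io = np.array(obs, dtype=int) + 1
    V[0, io] = s
    V[np.ix_(io, io)] = G
    if mis:
        if reg.beta.shape != (len(mis), len(obs)):
            raise ValueError(
                f"regression map shape {reg.beta.shape} does not match pattern "
                f"({len(mis)} missing x {len(obs)} observed)"
            )
        im = np.array(mis, dtype=int) + 1
        bs = reg.beta @ s
        s_m = n * reg.alpha + bs
        V[0, im] = s_m
        C_mo = np.outer(reg.alpha, s) + reg.beta @ G
        V[np.ix_(im, io)] = C_mo
        V[np.ix_(io, im)] = C_mo.T
        M_mm = (
            n * np.outer(reg.alpha, reg.alpha)
            + np.outer(reg.alpha, bs)
            + np.outer(bs, reg.alpha)
            + reg.beta @ G @ reg.beta.T
        )
        if variant == "corrected":
            if reg.cond_cov is None:
                raise ValueError("corrected variant needs cond_cov in the regression map")
            M_mm = M_mm + n * reg.cond_cov
        elif variant != "regression_only":
            raise ValueError(f"unknown variant {variant!r}")
        V[np.ix_(im, im)] = 0.5 * (M_mm + M_mm.T)
    V[1:, 1:] = 0.5 * (V[1:, 1:] + V[1:, 1:].T)
    V[1:, 0] = V[0, 1:]
    return V


def observed_loglik(
    blocks: list[DataBlock], mean: np.ndarray, cov: np.ndarray, ridge: float = 1e-6
) -> float:
    """Weighted log-likelihood of the observed marks under (mean, cov)."""
    covr = ridge_floor(cov, ridge)
    total = 0.0
    for block in blocks:
        obs = list(block.observed)
        lp = multivariate_normal(
            mean[obs], covr[np.ix_(obs, obs)], allow_singular=True
        ).logpdf(block.X)
        lp = np.atleast_1d(lp)
        total += float(lp.sum() if block.weights is None else block.weights @ lp)
    return total


def em_fit_state(
    blocks: list[DataBlock], p: int, config: EMConfig | None = None
) -> EMResult:
    """Fit one state's Gaussian mean/covariance by EM on sufficient statistics.

    ``blocks`` hold the (responsibility-weighted) data of each missingness
    pattern assigned to the state.  Starting from V_0 = identity, each
    iteration computes the regression maps from the current V, accumulates
    the expected V^k over all blocks, and sums them; the loop stops when
    the relative Frobenius change of V drops below ``config.tol``.
    """
    config = config or EMConfig()
    n_total = sum(block_suffstats(b)[0] for b in blocks)
    if n_total <= p:
        raise ValueError(
            f"effective count {n_total:.3g} <= p={p}: covariance would be rank-deficient"
        )
    # Fully observed blocks contribute their exact Gram matrix, constant
    # across iterations.
    exact = np.zeros((p + 1, p + 1))
    partial: list[DataBlock] = []
    for b in blocks:
        if len(b.observed) == p:
            exact += expected_moments_for_cell(b, RegressionMap(np.zeros(0), np.zeros((0, p))), p)
        else:
            partial.append(b)

    V = init_moment_matrix(p)
    converged = False
    trace: list[float] = []
    n_iter = 0
    for n_iter in range(1, config.max_iter + 1):
        _, mean, cov = moments_from_V(V)
        V_new = exact.copy()
        for b in partial:
            mis = tuple(j for j in range(p) if j not in set(b.observed))
            reg = regression_from_params(
                mean, cov, b.observed, mis, ridge=config.ridge
            )
            V_new += expected_moments_for_cell(b, reg, p, variant=config.variant)
        delta = np.linalg.norm(V_new - V) / max(np.linalg.norm(V), 1e-300)
        V = V_new
        if config.track_loglik:
            _, m1, c1 = moments_from_V(V)
            trace.append(observed_loglik(blocks, m1, c1, ridge=config.ridge))
        if delta < config.tol:
            converged = True
            break
    if not converged:
        warnings.warn(
            f"state EM did not converge in {config.max_iter} iterations",
            RuntimeWarning,
            stacklevel=2,
        )
    _, mean, cov = moments_from_V(V)
    return EMResult(
        mean=mean,
        cov=ridge_floor(cov, config.ridge),
        n_iter=n_iter,
        converged=converged,
        V=V,
        loglik_trace=trace,
    )


def marginal_log_density(
    x_obs: np.ndarray,
    observed: tuple[int, ...],
    mean: np.ndarray,
    cov: np.ndarray,
    ridge: float = 1e-6,
) -> np.ndarray:
    """Log-density of observed marks under the state's marginal Gaussian.

    The marginal of a multivariate normal over a subset of coordinates is
    the normal with the corresponding sub-vector mean and sub-matrix
    covariance; no integration over the missing marks is needed.
    ``x_obs`` may be a single vector or a matrix of rows.
    """
    obs = list(observed)
    sub = cov[np.ix_(obs, obs)]
    try:
        dist = multivariate_normal(mean[obs], sub)
    except (np.linalg.LinAlgError, ValueError):
        dist = multivariate_normal(mean[obs], ridge_floor(sub, ridge))
    return np.asarray(dist.logpdf(np.asarray(x_obs, dtype=float)))
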