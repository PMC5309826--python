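"""Weighted Poisson non-negative matrix factorization (wp-NMF).

The log-TPM matrix X (genes x cells) is approximated by U @ V with
non-negative metagene basis U (genes x K) and coefficients V (K x cells)
whose columns live on the probability simplex.  Each observation is a
two-component mixture: with probability pi_nm the value follows a Poisson
distribution with mean mu_nm = (U @ V)_nm (the gene is expressed), and
otherwise a low-magnitude Poisson with mean lambda0 (a dropout event).
The weights pi are re-estimated from the current fit and enter a weighted
Poisson log-likelihood

    L(U, V) = sum_nm pi_nm * [ X log mu - mu - log Gamma(X+1) ]

maximized by majorization-minimization sweeps that are exact under the
simplex constraint on V, so L ascends monotonically at fixed pi.

Because the objective is non-convex, the fit is repeated over an ensemble
of random basis initializations; runs are aligned by Hungarian matching,
averaged into V_bar, and summarized by a consensus matrix whose cophenetic
correlation guides the choice of the rank K.

The per-cell metagene entropy H_m = -sum_k V_km log V_km measures how many
latent programmes are simultaneously active in a cell; high entropy marks
progenitor-like plasticity, low entropy lineage commitment.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
from scipy.cluster.hierarchy import cophenet, linkage
from scipy.optimize import linear_sum_assignment
from scipy.spatial.distance import squareform
from scipy.special import gammaln, xlogy

from .expression import ExpressionMatrix

__all__ = [
    "FactorizationConfig",
    "FactorizationResult",
    "ConsensusResult",
    "RankSelection",
    "nndsvd_init",
    "estimate_dropout_weights",
    "burnin_weighted_nmf",
    "wpnmf_fit",
    "run_ensemble",
    "best_run",
    "select_rank",
    "metagene_entropy",
]

_MU_FLOOR = 1e-10
_DEN_FLOOR = 1e-12


@dataclass
class FactorizationConfig:
    """Tuning knobs of the wp-NMF fit.

    ``lambda0`` is the Poisson mean of the dropout component and ``w0`` the
    fixed weight given to zero entries during the burn-in phase.  ``r_mf``
    is the ensemble size used for consensus/rank selection.
    """

    K: int = 4
    lambda0: float = 0.1
    w0: float = 0.1
    r_mf: int = 20
    max_iter_burnin: int = 100
    max_iter_main: int = 500
    tol: float = 1e-5
    tol_window: int = 10
    pi_every: int = 10
    seed: int = 0

    def __post_init__(self) -> None:
        if self.K < 2:
            raise ValueError("K must be at least 2")
        if self.lambda0 <= 0:
            raise ValueError("lambda0 must be positive")
        if not 0 < self.w0 <= 1:
            raise ValueError("w0 must lie in (0, 1]")
        if self.r_mf < 1:
            raise ValueError("r_mf must be at least 1")


@dataclass
class FactorizationResult:
    U: np.ndarray                 # genes x K
    V: np.ndarray                 # K x cells, columns on the simplex
    pi: np.ndarray                # genes x cells dropout weights in [0, 1]
    loglik_trace: np.ndarray
    entropy: np.ndarray           # per-cell metagene entropy
    converged: bool
    config: FactorizationConfig | None = None


@dataclass
class ConsensusResult:
    consensus: np.ndarray         # cells x cells in [0, 1]
    cophenetic: float
    V_bar: np.ndarray             # mean aligned coefficients, K x cells
    K: int = 0


@dataclass
class RankSelection:
    selected_K: int
    K_grid: list[int] = field(default_factory=list)
    cophenetics: list[float] = field(default_factory=list)
    monotone_warning: bool = False


# ---------------------------------------------------------------------------
# initialization


def nndsvd_init(x: ExpressionMatrix | np.ndarray, K: int) -> tuple[np.ndarray, np.ndarray]:
    """Non-negative double SVD initialization (Boutsidis & Gallopoulos).

    Deterministic.  Zeros in the output are replaced by a small epsilon
    (1e-6 times the matrix mean) so multiplicative updates cannot lock
    them at zero; V columns are renormalized onto the simplex.
    """
    X = x.values if isinstance(x, ExpressionMatrix) else np.asarray(x, float)
    n, m = X.shape
    if K > min(n, m):
        raise ValueError(f"K={K} exceeds min(genes, cells)={min(n, m)}")
    Usvd, S, Vt = np.linalg.svd(X, full_matrices=False)
    U0 = np.zeros((n, K))
    V0 = np.zeros((K, m))
    U0[:, 0] = np.sqrt(S[0]) * np.abs(Usvd[:, 0])
    V0[0, :] = np.sqrt(S[0]) * np.abs(Vt[0, :])
    for j in range(1, K):
        u, v = Usvd[:, j], Vt[j, :]
        up, un = np.maximum(u, 0), np.maximum(-u, 0)
        vp, vn = np.maximum(v, 0), np.maximum(-v, 0)
        n_up, n_vp = np.linalg.norm(up), np.linalg.norm(vp)
        n_un, n_vn = np.linalg.norm(un), np.linalg.norm(vn)
        if n_up * n_vp >= n_un * n_vn:
            scale, uu, vv = n_up * n_vp, up / max(n_up, _DEN_FLOOR), vp / max(n_vp, _DEN_FLOOR)
        else:
            scale, uu, vv = n_un * n_vn, un / max(n_un, _DEN_FLOOR), vn / max(n_vn, _DEN_FLOOR)
        U0[:, j] = np.sqrt(S[j] * scale) * uu
        V0[j, :] = np.sqrt(S[j] * scale) * vv
    eps = 1e-6 * max(X.mean(), _DEN_FLOOR)
    U0[U0 <= 0] = eps
    V0[V0 <= 0] = eps
    V0 = V0 / V0.sum(axis=0, keepdims=True)
    return U0, V0


# ---------------------------------------------------------------------------
# dropout weights


def _poisson_logpdf(x: np.ndarray, mu) -> np.ndarray:
    # continuous extension exp(-mu) mu^x / Gamma(x+1); valid for real x >= 0
    mu = np.maximum(mu, _MU_FLOOR)
    return xlogy(x, mu) - mu - gammaln(x + 1.0)


def estimate_dropout_weights(x, U: np.ndarray, V: np.ndarray, lambda0: float = 0.1) -> np.ndarray:
    """Posterior probability that each entry is expressed rather than dropout.

    pi_nm = Pois(X; mu_nm) / (Pois(X; mu_nm) + Pois(X; lambda0)) with
    mu = U @ V, using the continuous Poisson density for real-valued
    log-TPM observations.
    """
    X = x.values if isinstance(x, ExpressionMatrix) else np.asarray(x, float)
    mu = U @ V
    log_expr = _poisson_logpdf(X, mu)
    log_drop = _poisson_logpdf(X, lambda0)
    with np.errstate(over="ignore"):
        pi = 1.0 / (1.0 + np.exp(log_drop - log_expr))
    return pi


# ---------------------------------------------------------------------------
# core weighted-Poisson MM machinery


def _simplex_columns(A: np.ndarray, B: np.ndarray) -> np.ndarray:
    """Maximize sum_k (A_k log v_k - B_k v_k) per column subject to
    sum_k v_k = 1, v >= 0.  Solution v_k = A_k / (B_k + lam) with the
    column multiplier lam found by bisection on the monotone function
    g(lam) = sum_k A_k / (B_k + lam)."""
    K, m = A.shape
    pos = A > 0
    S = A.sum(axis=0)
    degenerate = S <= 0
    Ssafe = np.where(degenerate, 1.0, S)
    Bmax = np.where(pos, B, -np.inf).max(axis=0)
    Bmin = np.where(pos, B, np.inf).min(axis=0)
    Bmax = np.where(degenerate, 1.0, Bmax)
    Bmin = np.where(degenerate, 0.0, Bmin)
    lo = np.maximum(Ssafe - Bmax, -Bmin + 1e-15)
    hi = np.maximum(Ssafe - Bmin, lo)
    for _ in range(80):
        mid = 0.5 * (lo + hi)
        with np.errstate(divide="ignore", invalid="ignore"):
            g = np.where(pos, A / (B + mid), 0.0).sum(axis=0)
        too_big = g > 1.0
        lo = np.where(too_big, mid, lo)
        hi = np.where(too_big, hi, mid)
    lam = 0.5 * (lo + hi)
    # near the one-hot limit lam -> -min(B) and a denominator can underflow;
    # clip and rescale by the column max so the normalization stays finite
    denom = B + lam
    denom = np.where(denom <= 0, 1e-300, denom)
    V = np.minimum(np.where(pos, A / denom, 0.0), 1e300)
    V[:, degenerate] = 1.0 / K
    V = V / np.maximum(V.max(axis=0, keepdims=True), 1e-300)
    return V / V.sum(axis=0, keepdims=True)


def _weighted_loglik(X: np.ndarray, W: np.ndarray, U: np.ndarray, V: np.ndarray) -> float:
    mu = np.maximum(U @ V, _MU_FLOOR)
    return float((W * (xlogy(X, mu) - mu - gammaln(X + 1.0))).sum())


def _mm_sweep(X: np.ndarray, W: np.ndarray, U: np.ndarray, V: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    """One exact majorization sweep of the weighted Poisson objective:
    closed-form multiplicative update of U, then the simplex-constrained
    update of V.  Each half-step cannot decrease the objective."""
    mu = np.maximum(U @ V, _MU_FLOOR)
    R = W * X / mu
    U = U * (R @ V.T) / np.maximum(W @ V.T, _DEN_FLOOR)
    mu = np.maximum(U @ V, _MU_FLOOR)
    A = V * (U.T @ (W * X / mu))
    B = U.T @ W
    V = _simplex_columns(A, B)
    return U, V


def _run_mm(X, W, U, V, max_iter, tol, tol_window, trace=None):
    """Iterate MM sweeps at fixed weights until the relative likelihood
    change over ``tol_window`` sweeps drops below ``tol``."""
    trace = [] if trace is None else trace
    converged = False
    WG = (W * gammaln(X + 1.0)).sum()  # constant at fixed weights
    for it in range(max_iter):
        U, V = _mm_sweep(X, W, U, V)
        if not (np.isfinite(U).all() and np.isfinite(V).all()):
            raise FloatingPointError(f"non-finite factor update at iteration {it}")
        mu = np.maximum(U @ V, _MU_FLOOR)
        ll = float((W * (xlogy(X, mu) - mu)).sum() - WG)
        trace.append(ll)
        if len(trace) > tol_window:
            prev = trace[-1 - tol_window]
            if abs(ll - prev) <= tol * (abs(prev) + 1e-12):
                converged = True
                break
    return U, V, trace, converged


def burnin_weighted_nmf(
    x: ExpressionMatrix | np.ndarray,
    K: int,
    w0: float = 0.1,
    max_iter_burnin: int = 100,
    seed: int = 0,
    U0: np.ndarray | None = None,
    V0: np.ndarray | None = None,
    tol: float = 1e-5,
) -> tuple[np.ndarray, np.ndarray]:
    """Weighted-NMF burn-in: zero entries get fixed weight ``w0`` (one
    elsewhere), V starts from NNDSVD and U at random unless supplied."""
    X = x.values if isinstance(x, ExpressionMatrix) else np.asarray(x, float)
    if V0 is None:
        _, V0 = nndsvd_init(X, K)
    V = V0
    if U0 is None:
        # exponential draws give enough dispersion for ensemble runs to
        # explore distinct optima of the non-convex objective
        rng = np.random.default_rng(seed)
        U0 = rng.exponential(max(X.mean(), _DEN_FLOOR), size=(X.shape[0], K)) + _DEN_FLOOR
    W = np.where(X == 0, w0, 1.0)
    U, V, _, _ = _run_mm(X, W, U0, V, max_iter_burnin, tol, 10)
    return U, V


def wpnmf_fit(
    x: ExpressionMatrix | np.ndarray,
    config: FactorizationConfig,
    V0: np.ndarray | None = None,
) -> FactorizationResult:
    """Full wp-NMF fit: burn-in, then alternate dropout-weight re-estimation
    with blocks of weighted MM sweeps until the likelihood stabilizes."""
    X = x.values if isinstance(x, ExpressionMatrix) else np.asarray(x, float)
    if isinstance(x, ExpressionMatrix) and not x.transformed:
        raise ValueError("wp-NMF expects a log-transformed matrix")
    if config.K > min(X.shape):
        raise ValueError(f"K={config.K} exceeds min(genes, cells)={min(X.shape)}")

    U, V = burnin_weighted_nmf(
        X, config.K, w0=config.w0, max_iter_burnin=config.max_iter_burnin,
        seed=config.seed, V0=V0, tol=config.tol,
    )

    trace: list[float] = []
    pi = estimate_dropout_weights(X, U, V, config.lambda0)
    converged = False
    it = 0
    while it < config.max_iter_main and not converged:
        block = min(config.pi_every, config.max_iter_main - it)
        U, V, trace, converged = _run_mm(
            X, pi, U, V, block, config.tol, config.tol_window, trace=trace,
        )
        it = len(trace)
        if not converged:
            pi = estimate_dropout_weights(X, U, V, config.lambda0)

    return FactorizationResult(
        U=U, V=V, pi=pi,
        loglik_trace=np.asarray(trace),
        entropy=metagene_entropy(V),
        converged=converged,
        config=config,
    )


def metagene_entropy(V: np.ndarray) -> np.ndarray:
    """Shannon entropy of each coefficient column (natural log)."""
    return -xlogy(V, V).sum(axis=0)


# ---------------------------------------------------------------------------
# ensemble, consensus, rank selection


def _align_components(V_ref: np.ndarray, V: np.ndarray, U: np.ndarray):
    """Permute metagenes of (U, V) to best match V_ref by correlation of
    coefficient rows (Hungarian matching); NMF component order is arbitrary."""
    K = V_ref.shape[0]
    C = np.corrcoef(V_ref, V)[:K, K:]
    C = np.nan_to_num(C, nan=0.0)
    _, perm = linear_sum_assignment(-C)
    return U[:, perm], V[perm, :]


def best_run(results: list[FactorizationResult]) -> FactorizationResult:
    """The ensemble member with the highest final weighted log-likelihood
    (maximum-likelihood selection across random restarts)."""
    return max(results, key=lambda r: r.loglik_trace[-1])


def run_ensemble(
    x: ExpressionMatrix | np.ndarray, config: FactorizationConfig
) -> tuple[list[FactorizationResult], ConsensusResult]:
    """Repeat wp-NMF ``r_mf`` times from diversified random starts.

    Runs use seeds ``seed+1 .. seed+r_mf``; the first run starts V at the
    deterministic NNDSVD solution, later runs at random simplex draws, and
    every run draws a fresh random basis U.  The consensus matrix holds the
    fraction of runs in which two cells share a dominant metagene; its
    cophenetic correlation (average-linkage, Brunet-style) measures how
    reproducible the decomposition at this rank is.
    """
    from dataclasses import replace as _replace

    X = x.values if isinstance(x, ExpressionMatrix) else np.asarray(x, float)
    results: list[FactorizationResult] = []
    for r in range(config.r_mf):
        cfg = _replace(config, seed=config.seed + 1 + r)
        if r == 0:
            V0 = None  # NNDSVD start for the reference run
        else:
            rng = np.random.default_rng(cfg.seed)
            V0 = rng.dirichlet(np.ones(config.K), size=X.shape[1]).T
        results.append(wpnmf_fit(x, cfg, V0=V0))

    for res in results[1:]:
        res.U, res.V = _align_components(results[0].V, res.V, res.U)

    m = results[0].V.shape[1]
    consensus = np.zeros((m, m))
    for res in results:
        labels = np.argmax(res.V, axis=0)
        consensus += (labels[:, None] == labels[None, :]).astype(float)
    consensus /= len(results)

    V_bar = np.mean([res.V for res in results], axis=0)
    V_bar = V_bar / V_bar.sum(axis=0, keepdims=True)

    coph = consensus_cophenetic(consensus)
    return results, ConsensusResult(consensus=consensus, cophenetic=coph, V_bar=V_bar, K=config.K)


def consensus_cophenetic(consensus: np.ndarray) -> float:
    """Cophenetic correlation between 1-consensus distances and the
    dendrogram distances of their average-linkage clustering."""
    d = squareform(1.0 - consensus, checks=False)
    if np.allclose(d, d[0] if d.size else 0.0):
        return 1.0  # constant distances: dendrogram is exact by convention
    Z = linkage(d, method="average")
    c, _ = cophenet(Z, d)
    return float(c)


def select_rank(
    x: ExpressionMatrix | np.ndarray,
    K_grid: list[int],
    config: FactorizationConfig,
    delta: float = 0.01,
) -> RankSelection:
    """Scan candidate ranks and return the largest K before the cophenetic
    correlation first falls by more than ``delta``."""
    from dataclasses import replace as _replace

    K_grid = sorted(K_grid)
    if len(K_grid) < 2:
        raise ValueError("K_grid must contain at least two ranks")
    cophs = []
    for K in K_grid:
        _, cons = run_ensemble(x, _replace(config, K=K))
        cophs.append(cons.cophenetic)
    return first_fall(K_grid, cophs, delta)


def first_fall(K_grid: list[int], cophenetics: list[float], delta: float = 0.01) -> RankSelection:
    """The largest rank before the cophenetic profile first drops by more
    than ``delta``; a profile that never falls returns the largest rank
    with a warning flag."""
    for i in range(len(K_grid) - 1):
        if cophenetics[i] - cophenetics[i + 1] > delta:
            return RankSelection(K_grid[i], list(K_grid), list(cophenetics),
                                 monotone_warning=False)
    warnings.warn("cophenetic correlation never fell; returning the largest rank")
    return RankSelection(K_grid[-1], list(K_grid), list(cophenetics), monotone_warning=True)
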