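"""Heterogeneous metagene-metacell graph, random walk with restart, gene scores.

The graph has K metagene vertices (indices 0..K-1) followed by P metacell
vertices.  Transition structure:

* metacell -> metacell: only between hexagonal grid neighbours, and only
  in the direction of decreasing metagene entropy in ``committed`` mode
  (increasing in ``progenitor`` mode).  A fraction ``beta`` of the row
  mass goes to these admissible neighbours, proportional to a Gaussian
  similarity s_pq = exp(-d_pq^2 / sigma^2) of their metagene profiles,
  with d_pq the Euclidean distance between codebook columns and sigma the
  median neighbour distance.
* metacell -> metagene: the remaining (1 - beta) mass, proportional to
  the scaled codebook intensity W_kp.  A metacell with no admissible
  neighbour sends its whole mass to the metagene block.
* metagene -> metacell: proportional to W_kp.

Every row is normalized; a row with no outgoing mass gets a self-loop.
A random walk restarting at one metagene on the committed-mode graph
concentrates on metacells committed to that programme; restarting at
several metagenes on the progenitor-mode graph concentrates on the
multipotent metacells that can still reach all of them.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np

from .som import MetacellExpression, MetacellMap

__all__ = [
    "StateGraph",
    "PrioritizationResult",
    "GeneScoreTable",
    "build_graph",
    "random_walk_with_restart",
    "gene_enrichment_score",
]


@dataclass
class StateGraph:
    G: np.ndarray                 # (K+P) x (K+P) row-stochastic
    K: int
    P: int
    beta: float
    mode: str                     # "committed" or "progenitor"
    sigma: float
    no_neighbour_metacells: list[int] = field(default_factory=list)

    @property
    def n_vertices(self) -> int:
        return self.K + self.P


@dataclass
class PrioritizationResult:
    u: np.ndarray                 # steady-state probability per metacell, sums to 1
    ranking: np.ndarray           # metacells ordered by decreasing u
    restart_set: list[int]
    restart_prob: float
    mode: str
    n_iter: int = 0


@dataclass
class GeneScoreTable:
    scores: np.ndarray
    ranking: np.ndarray           # gene indices ordered by decreasing score
    gene_ids: list[str] | None = None
    mode: str | None = None
    restart_set: list[int] | None = None


def build_graph(mp: MetacellMap, beta: float = 0.85, mode: str = "committed",
                sigma: float | None = None) -> StateGraph:
    if mode not in ("committed", "progenitor"):
        raise ValueError("mode must be 'committed' or 'progenitor'")
    if not 0 < beta <= 1:
        raise ValueError("beta must lie in (0, 1]")
    if mp.W is None or mp.H_p is None:
        raise ValueError("map must carry the scaled codebook W and entropies H_p")
    K, P = mp.K, mp.n_metacells
    W, H = mp.W, mp.H_p
    adj = mp.neighbours()
    cb = mp.codebook  # K x P

    pair_d = [np.linalg.norm(cb[:, p] - cb[:, q]) for p in range(P) for q in adj[p] if q > p]
    if sigma is None:
        sigma = float(np.median(pair_d)) if pair_d else 1.0
    if sigma <= 0:
        sigma = 1.0

    G = np.zeros((K + P, K + P))
    # metagene rows: to metacells in proportion to scaled intensity
    for k in range(K):
        row = W[k]
        tot = row.sum()
        if tot > 0:
            G[k, K:] = row / tot
        else:
            G[k, k] = 1.0
    # metacell rows
    no_nb = []
    for p in range(P):
        i = K + p
        if mode == "committed":
            admissible = [q for q in adj[p] if H[q] < H[p]]
        else:
            admissible = [q for q in adj[p] if H[q] > H[p]]
        wk = W[:, p]
        wk_tot = wk.sum()
        if admissible:
            s = np.array([np.exp(-np.linalg.norm(cb[:, p] - cb[:, q]) ** 2 / sigma**2)
                          for q in admissible])
            G[i, [K + q for q in admissible]] = beta * s / s.sum()
            if wk_tot > 0:
                G[i, :K] = (1.0 - beta) * wk / wk_tot
            else:
                G[i, [K + q for q in admissible]] = s / s.sum()
        else:
            no_nb.append(p)
            if wk_tot > 0:
                G[i, :K] = wk / wk_tot
        tot = G[i].sum()
        if tot <= 0:
            G[i, i] = 1.0
        else:
            G[i] /= tot

    return StateGraph(G=G, K=K, P=P, beta=beta, mode=mode, sigma=sigma,
                      no_neighbour_metacells=no_nb)


def random_walk_with_restart(
    graph: StateGraph,
    restart_set: list[int],
    restart_prob: float = 0.85,
    tol: float = 1e-12,
    max_iter: int = 100_000,
) -> PrioritizationResult:
    """Iterate ``u <- (1-r) G^T u + r e`` to the fixed point, with ``e``
    uniform over the restart metagene vertices, then restrict to the
    metacell sub-vector and renormalize it to a probability vector."""
    if not restart_set:
        raise ValueError("restart_set must not be empty")
    if not all(0 <= k < graph.K for k in restart_set):
        raise ValueError("restart_set must contain metagene indices in [0, K)")
    n = graph.n_vertices
    e = np.zeros(n)
    e[list(restart_set)] = 1.0 / len(restart_set)
    u = e.copy()
    GT = graph.G.T
    for it in range(max_iter):
        u_new = (1.0 - restart_prob) * (GT @ u) + restart_prob * e
        if np.abs(u_new - u).sum() < tol:
            u = u_new
            break
        u = u_new
    else:
        raise RuntimeError(f"RWR did not converge in {max_iter} iterations")
    u_mc = u[graph.K:]
    tot = u_mc.sum()
    if tot <= 0:
        warnings.warn("no steady-state mass on metacells; returning uniform")
        u_mc = np.full(graph.P, 1.0 / graph.P)
    else:
        u_mc = u_mc / tot
    ranking = np.argsort(-u_mc, kind="stable")
    return PrioritizationResult(u=u_mc, ranking=ranking, restart_set=list(restart_set),
                                restart_prob=restart_prob, mode=graph.mode, n_iter=it + 1)


def gene_enrichment_score(Y: MetacellExpression | np.ndarray, u: np.ndarray,
                          gene_ids: list[str] | None = None,
                          mode: str | None = None,
                          restart_set: list[int] | None = None) -> GeneScoreTable:
    """Score genes against a prioritization: E_n = sum_p (u_p - mean(u)) Y_np.

    Centering the steady state makes the score of a constant gene exactly
    zero; genes whose expression tracks the prioritized metacells score
    high, genes depleted there score negative.
    """
    if isinstance(Y, MetacellExpression):
        gene_ids = gene_ids or Y.gene_ids
        Y = Y.Y
    Y = np.asarray(Y, float)
    u = np.asarray(u, float)
    if Y.shape[1] != u.shape[0]:
        raise ValueError(f"Y has {Y.shape[1]} metacells but u has {u.shape[0]}")
    scores = Y @ (u - u.mean())
    ranking = np.argsort(-scores, kind="stable")
    return GeneScoreTable(scores=scores, ranking=ranking, gene_ids=gene_ids,
                          mode=mode, restart_set=restart_set)
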