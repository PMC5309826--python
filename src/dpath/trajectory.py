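"""Developmental trajectories and pseudotime on the metacell landscape.

A trajectory for a lineage runs from the progenitor terminus (the metacell
maximizing the progenitor-mode steady state) to the committed terminus of
its metagene (maximizing the committed-mode steady state), following the
shortest path on the hexagonal grid where each step is weighted by the
Euclidean distance between the metagene profiles of adjacent metacells.
Cells assigned to path metacells are ordered by the normalized cumulative
path distance of their metacell (arc-length pseudotime in [0, 1]), with
within-metacell order refined by each cell's coefficient-space distance to
the committed terminus.  Agreement with ordinal stage labels is measured
by Kendall's tau-b, which corrects for the heavy ties of staged designs.
"""

from __future__ import annotations

import heapq
import warnings
from dataclasses import dataclass, field

import numpy as np
from scipy.stats import kendalltau

from .graph import PrioritizationResult
from .som import MetacellMap

__all__ = [
    "Trajectory",
    "terminal_states",
    "shortest_path_trajectory",
    "order_cells_pseudotime",
    "kendall_concordance",
    "entropy_pseudotime",
]


@dataclass
class Trajectory:
    metagene_id: int
    path: list[int]                      # metacell indices, progenitor -> committed
    edge_weights: list[float] = field(default_factory=list)
    cell_indices: np.ndarray | None = None
    pseudotime: np.ndarray | None = None
    cell_order: np.ndarray | None = None  # cell indices sorted by pseudotime


def terminal_states(
    progenitor: PrioritizationResult,
    committed: dict[int, PrioritizationResult],
    H_p: np.ndarray,
) -> tuple[int, dict[int, int]]:
    """Pick the argmax metacell of each steady state.

    Ties break by higher entropy for the progenitor query and lower
    entropy for committed queries, then by index.  A perfectly flat
    steady state is rejected as a degenerate landscape.
    """

    def _argmax(u: np.ndarray, prefer_high_entropy: bool) -> int:
        if np.allclose(u, u[0]):
            raise ValueError("flat steady state: degenerate landscape")
        best = np.flatnonzero(u == u.max())
        if len(best) > 1:
            h = H_p[best]
            target = h.max() if prefer_high_entropy else h.min()
            best = best[h == target]
        return int(best[0])

    prog = _argmax(progenitor.u, prefer_high_entropy=True)
    comm = {k: _argmax(res.u, prefer_high_entropy=False) for k, res in committed.items()}
    return prog, comm


def _codebook_edge_weight(mp: MetacellMap, p: int, q: int) -> float:
    return float(np.linalg.norm(mp.codebook[:, p] - mp.codebook[:, q]))


def shortest_path_trajectory(mp: MetacellMap, source: int, target: int,
                             metagene_id: int = -1) -> Trajectory:
    """Dijkstra on the hex grid with metagene-profile edge weights.

    Ties between equal-length paths break lexicographically on the
    metacell index sequence, so the result is deterministic.
    """
    P = mp.n_metacells
    if not (0 <= source < P and 0 <= target < P):
        raise ValueError("source/target must be metacell indices on the grid")
    adj = mp.neighbours()
    # heap entries (distance, hops, path-tuple): the heap order itself
    # implements the fewest-hops-then-lexicographic tie-break, which
    # networkx's Dijkstra leaves unspecified
    heap = [(0.0, 0, (source,))]
    best: dict[int, tuple[float, int, tuple[int, ...]]] = {}
    while heap:
        entry = heapq.heappop(heap)
        node = entry[2][-1]
        if node in best and best[node] <= entry:
            continue
        best[node] = entry
        if node == target:
            break
        d, hops, path = entry
        for q in adj[node]:
            nd = d + _codebook_edge_weight(mp, node, q)
            cand = (nd, hops + 1, path + (q,))
            if q not in best or cand < best[q]:
                heapq.heappush(heap, cand)
    d, _, path = best[target]
    weights = [_codebook_edge_weight(mp, path[i], path[i + 1]) for i in range(len(path) - 1)]
    return Trajectory(metagene_id=metagene_id, path=list(path), edge_weights=weights)


def order_cells_pseudotime(
    traj: Trajectory,
    mp: MetacellMap,
    V_bar: np.ndarray,
    include_neighbours: bool = False,
    arc_length: bool = True,
) -> Trajectory:
    """Assign pseudotime to the cells lying on the trajectory.

    Each path metacell gets the normalized cumulative path distance to it
    (or its rank / path length with ``arc_length=False``); a cell inherits
    the value of its metacell.  With ``include_neighbours``, cells in grid
    neighbours of path metacells join at the value of the nearest path
    node.  The returned ``cell_order`` sorts by pseudotime, breaking
    within-metacell ties by decreasing coefficient-space distance to the
    committed terminus (cells closest to commitment come last).
    """
    path = traj.path
    cum = np.concatenate([[0.0], np.cumsum(traj.edge_weights)])
    if arc_length and cum[-1] > 0:
        node_t = cum / cum[-1]
    elif len(path) > 1:
        node_t = np.arange(len(path)) / (len(path) - 1)
    else:
        node_t = np.zeros(1)
    node_of = {p: i for i, p in enumerate(path)}
    if include_neighbours:
        adj = mp.neighbours()
        for i, p in enumerate(path):
            for q in adj[p]:
                node_of.setdefault(q, i)

    members = [c for c, p in enumerate(mp.assignment) if int(p) in node_of]
    if not members:
        warnings.warn("no cells assigned to the trajectory path")
        traj.cell_indices = np.array([], dtype=int)
        traj.pseudotime = np.array([])
        traj.cell_order = np.array([], dtype=int)
        return traj
    members = np.asarray(members)
    t = np.array([node_t[node_of[int(mp.assignment[c])]] for c in members])
    terminus = mp.codebook[:, path[-1]]
    d_comm = np.linalg.norm(V_bar[:, members] - terminus[:, None], axis=0)
    order = np.lexsort((-d_comm, t))
    traj.cell_indices = members
    traj.pseudotime = t
    traj.cell_order = members[order]
    return traj


def entropy_pseudotime(entropy: np.ndarray) -> np.ndarray:
    """Order cells purely by decreasing metagene entropy (the simple
    comparator: most plastic cells first), normalized to [0, 1]."""
    e = np.asarray(entropy, float)
    rank = np.argsort(np.argsort(-e, kind="stable"), kind="stable")
    return rank / max(len(e) - 1, 1)


def kendall_concordance(pseudotime: np.ndarray, stage_labels: np.ndarray) -> float:
    """Kendall tau-b between pseudotime and ordinal stage labels."""
    pseudotime = np.asarray(pseudotime, float)
    stage = np.asarray(stage_labels)
    if stage.dtype.kind in "OUS":
        _, stage = np.unique(stage, return_inverse=True)
    if len(pseudotime) < 2 or len(np.unique(stage)) < 2:
        raise ValueError("need at least two cells and two distinct stages")
    tau, _ = kendalltau(pseudotime, stage)
    return float(tau)
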