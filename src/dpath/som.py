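"""Metacell landscape: hexagonal self-organizing map, entropy, partitioning.

Cells, represented by their metagene coefficient vectors (points on the
K-simplex), are mapped onto a fixed hexagonal grid of *metacells* by a
batch self-organizing map.  Neighbouring metacells end up with similar
metagene profiles, so the grid is a 2-D landscape of cellular states:
high-entropy (progenitor-like) metacells sit between the low-entropy
committed territories they can feed.

Grid convention: odd-row offset layout.  Metacell (row, col) sits at
planar position (col + 0.5*(row % 2), row * sqrt(3)/2); the six hexagonal
neighbours are the units at planar distance 1.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
from scipy.special import xlogy

__all__ = [
    "MetacellMap",
    "MetacellPartition",
    "MetacellExpression",
    "hex_positions",
    "hex_adjacency",
    "fit_som",
    "scale_codebook",
    "metacell_entropy",
    "pam",
    "partition_metacells",
    "aggregate_metacell_expression",
]


# ---------------------------------------------------------------------------
# hexagonal grid geometry


def hex_positions(rows: int, cols: int) -> np.ndarray:
    """Planar coordinates of each grid unit (row-major order), odd rows
    shifted right by half a unit, unit spacing 1."""
    r, c = np.divmod(np.arange(rows * cols), cols)
    x = c + 0.5 * (r % 2)
    y = r * (np.sqrt(3) / 2.0)
    return np.column_stack([x, y])


def hex_adjacency(rows: int, cols: int) -> list[list[int]]:
    """Neighbour lists: units at planar distance 1 (six for interior units)."""
    pos = hex_positions(rows, cols)
    d2 = ((pos[:, None, :] - pos[None, :, :]) ** 2).sum(-1)
    adj = []
    for p in range(rows * cols):
        nb = np.flatnonzero(np.abs(d2[p] - 1.0) < 1e-9)
        adj.append([int(q) for q in nb])
    return adj


# ---------------------------------------------------------------------------
# containers


@dataclass
class MetacellMap:
    grid_rows: int
    grid_cols: int
    codebook: np.ndarray          # K x P prototype coefficient vectors
    assignment: np.ndarray        # cell -> metacell index
    W: np.ndarray | None = None   # K x P min-max scaled codebook
    H_p: np.ndarray | None = None  # per-metacell metagene entropy
    coords: np.ndarray | None = None
    cell_ids: list[str] | None = None

    def __post_init__(self) -> None:
        if self.coords is None:
            self.coords = hex_positions(self.grid_rows, self.grid_cols)

    @property
    def n_metacells(self) -> int:
        return self.grid_rows * self.grid_cols

    @property
    def K(self) -> int:
        return self.codebook.shape[0]

    def neighbours(self) -> list[list[int]]:
        return hex_adjacency(self.grid_rows, self.grid_cols)

    def occupied(self) -> np.ndarray:
        counts = np.bincount(self.assignment, minlength=self.n_metacells)
        return counts > 0


@dataclass
class MetacellPartition:
    labels: np.ndarray            # metacell -> cluster id (0-based)
    C: int
    min_size: int
    connected: list[bool] = field(default_factory=list)
    feasible: bool = True


@dataclass
class MetacellExpression:
    Y: np.ndarray                 # genes x P aggregated expression
    imputed: np.ndarray           # boolean flag per metacell (was empty)
    gene_ids: list[str] | None = None


# ---------------------------------------------------------------------------
# SOM fit


def fit_som(V_bar: np.ndarray, grid_rows: int = 15, grid_cols: int = 15,
            seed: int = 0, epochs: int = 100) -> MetacellMap:
    """Train a batch SOM of ``grid_rows x grid_cols`` metacells on the
    cell coefficient vectors (columns of ``V_bar``).

    The codebook starts on the plane of the two leading principal
    components of the data and is refined with a Gaussian neighbourhood
    whose radius decays linearly from half the grid span to 1.  The batch
    rule is deterministic given the seed (used only to perturb degenerate
    starts), so refits reproduce identical assignments.
    """
    V_bar = np.asarray(V_bar, float)
    K, m = V_bar.shape
    if m < 2:
        raise ValueError("need at least two cells to fit a SOM")
    P = grid_rows * grid_cols
    pos = hex_positions(grid_rows, grid_cols)
    grid_d2 = ((pos[:, None, :] - pos[None, :, :]) ** 2).sum(-1)

    data = V_bar.T  # cells x K
    centre = data.mean(axis=0)
    Xc = data - centre
    # PCA-plane initialization: spread the grid along the two leading PCs
    _, s, Vt = np.linalg.svd(Xc, full_matrices=False)
    rng = np.random.default_rng(seed)
    axes = np.zeros((2, K))
    scale = np.ones(2)
    for j in range(min(2, Vt.shape[0])):
        axes[j] = Vt[j]
        scale[j] = s[j] / max(np.sqrt(m), 1.0)
    if s.size < 2 or s[1] <= 1e-12 * max(s[0], 1e-12):
        axes[1] = rng.standard_normal(K) * 1e-3  # degenerate second axis
        scale[1] = max(scale[0] * 1e-3, 1e-6)
    u = (pos - pos.mean(axis=0)) / np.maximum(pos.max(axis=0) - pos.min(axis=0), 1e-12) * 2
    codebook = centre[None, :] + u @ (axes * scale[:, None])  # P x K

    radius0 = max(grid_rows, grid_cols) / 2.0
    for epoch in range(epochs):
        radius = radius0 + (1.0 - radius0) * epoch / max(epochs - 1, 1)
        d = ((data[:, None, :] - codebook[None, :, :]) ** 2).sum(-1)
        bmu = np.argmin(d, axis=1)
        h = np.exp(-grid_d2[bmu] / (2.0 * radius**2))  # cells x P
        denom = h.sum(axis=0)
        num = h.T @ data
        nonempty = denom > 1e-12
        codebook[nonempty] = num[nonempty] / denom[nonempty, None]

    d = ((data[:, None, :] - codebook[None, :, :]) ** 2).sum(-1)
    assignment = np.argmin(d, axis=1)

    mp = MetacellMap(
        grid_rows=grid_rows, grid_cols=grid_cols,
        codebook=codebook.T, assignment=assignment, coords=pos,
    )
    mp.W = scale_codebook(mp)
    mp.H_p = metacell_entropy(mp.W)
    return mp


def scale_codebook(mp: MetacellMap) -> np.ndarray:
    """Min-max scale each metagene row of the codebook across metacells to
    [0, 1], making metagene intensities comparable on the landscape.
    Constant rows scale to 0 with a warning."""
    cb = mp.codebook
    lo = cb.min(axis=1, keepdims=True)
    rng_ = cb.max(axis=1, keepdims=True) - lo
    flat = rng_[:, 0] <= 0
    if flat.any():
        warnings.warn(f"{int(flat.sum())} constant metagene row(s) scaled to zero")
    W = np.where(rng_ > 0, (cb - lo) / np.where(rng_ > 0, rng_, 1.0), 0.0)
    return W


def metacell_entropy(W: np.ndarray) -> np.ndarray:
    """Entropy of each metacell's metagene profile.  Columns are first
    renormalized to the simplex; an all-zero column gets the uniform
    profile (entropy log K)."""
    W = np.asarray(W, float)
    colsum = W.sum(axis=0, keepdims=True)
    Wn = np.where(colsum > 0, W / np.where(colsum > 0, colsum, 1.0), 1.0 / W.shape[0])
    return -xlogy(Wn, Wn).sum(axis=0)


# ---------------------------------------------------------------------------
# PAM partitioning


def pam(D: np.ndarray, C: int, seed: int = 0, max_swaps: int = 200) -> np.ndarray:
    """Partitioning Around Medoids on a precomputed distance matrix.

    Classic BUILD then SWAP: greedily seed medoids to minimize total
    distance-to-nearest-medoid, then apply best improving medoid swaps
    until none remains.  Deterministic (ties break by lowest index)."""
    D = np.asarray(D, float)
    P = D.shape[0]
    if not 1 <= C <= P:
        raise ValueError(f"cannot form {C} clusters from {P} items")
    medoids = [int(np.argmin(D.sum(axis=1)))]
    while len(medoids) < C:
        cur = D[:, medoids].min(axis=1)
        gains = np.maximum(cur[None, :] - D, 0).sum(axis=1)
        gains[medoids] = -np.inf
        medoids.append(int(np.argmax(gains)))
    medoids = sorted(medoids)
    for _ in range(max_swaps):
        cur_cost = D[:, medoids].min(axis=1).sum()
        best = (0.0, None)
        med_set = set(medoids)
        for i, mi in enumerate(medoids):
            others = [mj for j, mj in enumerate(medoids) if j != i]
            base = D[:, others].min(axis=1) if others else np.full(P, np.inf)
            for h in range(P):
                if h in med_set:
                    continue
                cost = np.minimum(base, D[:, h]).sum()
                improve = cur_cost - cost
                if improve > best[0] + 1e-12:
                    best = (improve, (i, h))
        if best[1] is None:
            break
        i, h = best[1]
        medoids[i] = h
        medoids = sorted(medoids)
    return np.argmin(D[:, medoids], axis=1)


def _clusters_connected(labels: np.ndarray, adj: list[list[int]]) -> list[bool]:
    out = []
    for c in range(labels.max() + 1):
        members = set(np.flatnonzero(labels == c).tolist())
        if not members:
            out.append(False)
            continue
        stack, seen = [next(iter(sorted(members)))], set()
        while stack:
            p = stack.pop()
            if p in seen:
                continue
            seen.add(p)
            stack.extend(q for q in adj[p] if q in members and q not in seen)
        out.append(seen == members)
    return out


def partition_metacells(mp: MetacellMap, C: int | None = None,
                        min_size: int = 15, seed: int = 0) -> MetacellPartition:
    """PAM-partition the metacell codebook (Euclidean distances).

    With ``C`` given, cluster directly into C groups.  Otherwise scan C
    downward from ``floor(P / min_size)`` and return the largest C whose
    clusters all have at least ``min_size`` metacells and are connected
    regions of the hex grid; if no C >= 2 is feasible, fall back to a
    single cluster with a warning.
    """
    X = mp.codebook.T  # P x K
    D = np.sqrt(((X[:, None, :] - X[None, :, :]) ** 2).sum(-1))
    adj = mp.neighbours()
    P = mp.n_metacells

    def check(labels):
        sizes = np.bincount(labels, minlength=labels.max() + 1)
        conn = _clusters_connected(labels, adj)
        return (sizes >= min_size).all() and all(conn), conn

    if C is not None:
        labels = pam(D, C, seed=seed)
        ok, conn = check(labels)
        return MetacellPartition(labels, C, min_size, conn, feasible=ok)

    for c in range(max(P // min_size, 2), 1, -1):
        labels = pam(D, c, seed=seed)
        ok, conn = check(labels)
        if ok:
            return MetacellPartition(labels, c, min_size, conn, feasible=True)
    warnings.warn("no feasible partition with C >= 2; returning a single cluster")
    return MetacellPartition(np.zeros(P, dtype=int), 1, min_size, [True], feasible=True)


# ---------------------------------------------------------------------------
# metacell-level expression


def aggregate_metacell_expression(x, mp: MetacellMap) -> MetacellExpression:
    """Mean expression of each gene over the cells assigned to each
    metacell.  Empty metacells are imputed from the mean of their grid
    neighbours (iterating outward if the whole neighbourhood is empty) and
    flagged."""
    from .expression import ExpressionMatrix

    if isinstance(x, ExpressionMatrix):
        values, gene_ids = x.values, x.gene_ids
    else:
        values, gene_ids = np.asarray(x, float), None
    if values.shape[1] != mp.assignment.shape[0]:
        raise ValueError(
            f"matrix has {values.shape[1]} cells but the map assigns {mp.assignment.shape[0]}"
        )
    P = mp.n_metacells
    counts = np.bincount(mp.assignment, minlength=P).astype(float)
    Y = np.zeros((values.shape[0], P))
    np.add.at(Y.T, mp.assignment, values.T)
    filled = counts > 0
    Y[:, filled] /= counts[filled]
    imputed = ~filled
    adj = mp.neighbours()
    todo = set(np.flatnonzero(~filled).tolist())
    while todo:
        progress = []
        for p in sorted(todo):
            nb = [q for q in adj[p] if filled[q]]
            if nb:
                Y[:, p] = Y[:, nb].mean(axis=1)
                progress.append(p)
        if not progress:  # isolated empty region: fall back to global mean
            for p in sorted(todo):
                Y[:, p] = Y[:, filled].mean(axis=1)
            break
        for p in progress:
            filled[p] = True
            todo.discard(p)
    return MetacellExpression(Y=Y, imputed=imputed, gene_ids=gene_ids)


def plot_landscape(mp: MetacellMap, values: np.ndarray | None = None,
                   ax=None, cmap: str = "viridis", size: float = 160.0,
                   title: str | None = None):
    """Draw the hexagonal landscape coloured by a per-metacell quantity
    (the metacell entropy by default).  Returns the matplotlib axes."""
    import matplotlib.pyplot as plt

    if values is None:
        if mp.H_p is None:
            raise ValueError("no values given and the map carries no entropy")
        values = mp.H_p
        title = title or "metagene entropy"
    if ax is None:
        _, ax = plt.subplots(figsize=(6, 5.5))
    sc = ax.scatter(mp.coords[:, 0], mp.coords[:, 1], c=values, s=size,
                    marker="h", cmap=cmap, edgecolors="none")
    ax.set_aspect("equal")
    ax.invert_yaxis()
    ax.set_xticks([])
    ax.set_yticks([])
    if title:
        ax.set_title(title)
    plt.colorbar(sc, ax=ax, shrink=0.8)
    return ax
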