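"""Synthetic single-cell expression data and the factorization benchmark.

Generative model: metagene membership V is filled with 0/1 Bernoulli draws
(an entry is active with probability ``p_one``), columns rescaled onto the
simplex; the basis U is i.i.d. Gamma; the expected expression is
mu = U @ V.  Dropout acts as an i.i.d. Bernoulli mask D: the observed
count X_nm is Poisson(mu_nm) when D_nm = 0 and exactly zero otherwise.
Defaults: 200 genes, 50 cells, 4 metagenes, 50% dropout, Gamma(shape 2,
rate 0.05) basis: mean expression 40 with standard deviation ~28, the
overdispersed tens-of-TPM magnitude typical of detected, variable genes
after filtering.

The staged variant emulates a differentiation time course: early-stage
cells are uniform metagene mixtures (progenitors), intermediate cells are
partly committed, late cells are one-hot (committed), which gives ground
truth for entropy, prioritization and pseudotime checks.

Factorizations are compared exactly as in the benchmark design: the
leave-one-out cross-validated error of a linear SVM predicting the cell
class from the factors, and the within-cluster to total sum of squares
ratio of the factors under the true classes.  Lower is better for both.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
from sklearn.decomposition import PCA
from sklearn.svm import SVC

from .expression import ExpressionMatrix

__all__ = [
    "SimConfig",
    "SimResult",
    "EvalReport",
    "simulate_expression",
    "simulate_staged",
    "to_expression_matrix",
    "loocv_classification_error",
    "wss_tss_ratio",
    "pca_baseline",
    "active_pattern_labels",
]


@dataclass
class SimConfig:
    n_genes: int = 200
    n_cells: int = 50
    K_true: int = 4
    p_one: float = 0.7            # probability a V entry is active (p_zero = 1 - p_one)
    dropout_rate: float = 0.5
    gamma_shape: float = 2.0
    gamma_rate: float = 0.05
    seed: int = 0
    staged: bool = False
    n_stages: int = 3
    stage_commitment: tuple = (0.0, 0.6, 1.0)  # mixing toward one-hot per stage

    def __post_init__(self) -> None:
        if not 0 < self.p_one <= 1:
            raise ValueError("p_one must lie in (0, 1]")
        if not 0 <= self.dropout_rate <= 1:
            raise ValueError("dropout_rate must lie in [0, 1]")
        if self.n_cells < self.K_true:
            raise ValueError("need at least as many cells as metagenes")

    @property
    def p_zero(self) -> float:
        return 1.0 - self.p_one


@dataclass
class SimResult:
    X: np.ndarray                 # observed counts, genes x cells
    U_true: np.ndarray
    V_true: np.ndarray
    D: np.ndarray                 # binary dropout mask
    labels: np.ndarray            # per-cell dominant metagene (argmax, ties -> lowest index)
    stage: np.ndarray | None = None
    is_progenitor: np.ndarray | None = None
    config: SimConfig | None = None


@dataclass
class EvalReport:
    method: str
    K: int
    loocv_error: float
    wss_tss: float
    seeds: list[int] = field(default_factory=list)
    predictions: np.ndarray | None = None


def simulate_expression(config: SimConfig) -> SimResult:
    """Draw one synthetic data set from the generative model above."""
    rng = np.random.default_rng(config.seed)
    K, n, m = config.K_true, config.n_genes, config.n_cells
    V = (rng.random((K, m)) < config.p_one).astype(float)
    empty = V.sum(axis=0) == 0
    while empty.any():  # a cell must belong to at least one metagene
        V[:, empty] = (rng.random((K, int(empty.sum()))) < config.p_one).astype(float)
        empty = V.sum(axis=0) == 0
    V = V / V.sum(axis=0, keepdims=True)
    U = rng.gamma(shape=config.gamma_shape, scale=1.0 / config.gamma_rate, size=(n, K))
    mu = U @ V
    D = (rng.random((n, m)) < config.dropout_rate).astype(int)
    X = rng.poisson(mu).astype(float)
    X[D == 1] = 0.0
    labels = np.argmax(V, axis=0)
    return SimResult(X=X, U_true=U, V_true=V, D=D, labels=labels, config=config)


def simulate_staged(config: SimConfig) -> SimResult:
    """Staged differentiation variant with ordinal stage labels.

    Cells are split evenly across stages; a cell of stage s committed to
    lineage k has coefficients (1-a_s) * uniform + a_s * onehot(k) with
    a_s the stage's commitment level.  Stage 0 cells (a = 0) are uniform
    mixtures and flagged as progenitors.
    """
    rng = np.random.default_rng(config.seed)
    K, n, m = config.K_true, config.n_genes, config.n_cells
    n_stages = config.n_stages
    commitment = np.asarray(config.stage_commitment, float)
    if len(commitment) != n_stages:
        raise ValueError("stage_commitment length must equal n_stages")
    stage = np.arange(m) % n_stages
    lineage = rng.integers(0, K, size=m)
    V = np.zeros((K, m))
    for c in range(m):
        a = commitment[stage[c]]
        V[:, c] = (1.0 - a) / K
        V[lineage[c], c] += a
    U = rng.gamma(shape=config.gamma_shape, scale=1.0 / config.gamma_rate, size=(n, K))
    mu = U @ V
    D = (rng.random((n, m)) < config.dropout_rate).astype(int)
    X = rng.poisson(mu).astype(float)
    X[D == 1] = 0.0
    return SimResult(
        X=X, U_true=U, V_true=V, D=D,
        labels=np.argmax(V, axis=0),
        stage=stage,
        is_progenitor=commitment[stage] < 0.5,
        config=config,
    )


def to_expression_matrix(sim: SimResult, log: bool = True) -> ExpressionMatrix:
    """Wrap a simulation as an ExpressionMatrix (log(X+1) by default,
    matching the real-data path into the factorization)."""
    n, m = sim.X.shape
    values = np.log1p(sim.X) if log else sim.X
    stage = sim.stage if sim.stage is not None else None
    return ExpressionMatrix(
        values=values,
        gene_ids=[f"gene{i}" for i in range(n)],
        cell_ids=[f"cell{j}" for j in range(m)],
        transformed=log,
        cell_stage=stage,
    )


def active_pattern_labels(V: np.ndarray, threshold: float | None = None) -> np.ndarray:
    """Class label per cell from the set of active metagenes.

    A metagene is active in a cell when its coefficient exceeds
    ``threshold`` (default 1/(2K), half the smallest active level of the
    0/1-mixture model).  Cells sharing an active set share a label; label
    ids are arbitrary, suitable for partition-agreement metrics.
    """
    K = V.shape[0]
    thr = 1.0 / (2 * K) if threshold is None else threshold
    pattern = (V > thr).astype(int)
    _, labels = np.unique(pattern.T, axis=0, return_inverse=True)
    return labels


def loocv_classification_error(factors: np.ndarray, labels: np.ndarray,
                               C: float = 1.0) -> EvalReport:
    """Leave-one-out error of a linear SVM predicting the cell class from
    the per-cell factors (columns).  Classes with a single member are
    skipped with a warning (they cannot appear in their training fold)."""
    factors = np.asarray(factors, float)
    labels = np.asarray(labels)
    m = factors.shape[1]
    if m != len(labels):
        raise ValueError("factors and labels disagree on the number of cells")
    counts = {c: int((labels == c).sum()) for c in np.unique(labels)}
    if len(counts) < 2:
        raise ValueError("need at least two classes")
    singletons = {c for c, k in counts.items() if k < 2}
    if singletons:
        warnings.warn(f"skipping singleton classes {sorted(map(str, singletons))}")
    preds = np.full(m, -1, dtype=object)
    evaluated = 0
    wrong = 0
    X = factors.T
    for i in range(m):
        if labels[i] in singletons:
            continue
        mask = np.ones(m, bool)
        mask[i] = False
        clf = SVC(kernel="linear", C=C)
        clf.fit(X[mask], labels[mask])
        pred = clf.predict(X[i:i + 1])[0]
        preds[i] = pred
        evaluated += 1
        wrong += int(pred != labels[i])
    err = wrong / evaluated if evaluated else float("nan")
    return EvalReport(method="", K=factors.shape[0], loocv_error=err,
                      wss_tss=float("nan"), predictions=preds)


def wss_tss_ratio(factors: np.ndarray, labels: np.ndarray) -> float:
    """Within-cluster over total sum of squares of the per-cell factors
    under the given classes; 0 means classes collapse to points, values
    near 1 mean the classes explain nothing."""
    X = np.asarray(factors, float).T  # cells x K
    labels = np.asarray(labels)
    classes = np.unique(labels)
    if len(classes) < 2:
        warnings.warn("single class: WSS/TSS is 1 by convention")
        return 1.0
    grand = X.mean(axis=0)
    tss = ((X - grand) ** 2).sum()
    if tss <= 0:
        return 0.0
    wss = 0.0
    for c in classes:
        sub = X[labels == c]
        wss += ((sub - sub.mean(axis=0)) ** 2).sum()
    return float(wss / tss)


def pca_baseline(x: ExpressionMatrix | np.ndarray, K: int) -> np.ndarray:
    """Top-K principal-component scores of the centered matrix, returned
    as K x cells to mirror the metagene coefficient layout.  Sign follows
    scikit-learn's deterministic convention."""
    X = x.values if isinstance(x, ExpressionMatrix) else np.asarray(x, float)
    n, m = X.shape
    if K > min(n, m):
        raise ValueError(f"K={K} exceeds the rank bound min(genes, cells)={min(n, m)}")
    pca = PCA(n_components=K, svd_solver="full")
    scores = pca.fit_transform(X.T)  # cells x K
    return scores.T
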