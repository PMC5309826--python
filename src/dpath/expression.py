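"""Expression-matrix containers, I/O, log transform and gene filtering.

The pipeline starts from a genes x cells matrix of TPM values.  Genes are
screened in three steps before factorization:

1. *Detection*: a gene must reach TPM >= 1 in at least two cells.
2. *Technical noise*: a line is fitted to (log2 mean, log2 CV) over the
   detected genes and the genes furthest from the line (largest residual)
   are discarded as technically noisy.
3. *Ubiquitous expression*: genes whose CV falls below a quantile of the
   CV distribution (the median by default) carry little cluster signal and
   are discarded as well.

The two removal sets may overlap; the kept set is the detected set minus
their union.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd
from scipy.io import mmread, mmwrite
from scipy.sparse import coo_matrix

__all__ = [
    "ExpressionMatrix",
    "GeneFilterReport",
    "load_matrix",
    "load_metadata",
    "save_matrix",
    "log_transform",
    "fit_noise_model",
    "filter_genes",
]

DETECTION_TPM = 1.0
DETECTION_MIN_CELLS = 2


@dataclass
class ExpressionMatrix:
    """A genes x cells matrix of TPM (or log-TPM) values with identifiers.

    Parameters
    ----------
    values
        Non-negative dense array, genes in rows and cells in columns.
    gene_ids, cell_ids
        Unique row/column identifiers.
    transformed
        True once :func:`log_transform` has been applied; guards against
        double transformation.
    cell_stage
        Optional ordinal stage label per cell (e.g. ``E7.25 < E7.75``).
    """

    values: np.ndarray
    gene_ids: list[str]
    cell_ids: list[str]
    transformed: bool = False
    cell_stage: np.ndarray | None = None

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=float)
        self.gene_ids = [str(g) for g in self.gene_ids]
        self.cell_ids = [str(c) for c in self.cell_ids]
        if self.values.ndim != 2:
            raise ValueError("expression values must be a 2-D array")
        n, m = self.values.shape
        if len(self.gene_ids) != n:
            raise ValueError(f"{len(self.gene_ids)} gene ids for {n} rows")
        if len(self.cell_ids) != m:
            raise ValueError(f"{len(self.cell_ids)} cell ids for {m} columns")
        _check_unique(self.gene_ids, "gene")
        _check_unique(self.cell_ids, "cell")
        if not np.isfinite(self.values).all():
            raise ValueError("expression values contain non-finite entries")
        if (self.values < 0).any():
            raise ValueError("expression values must be non-negative")
        if self.cell_stage is not None:
            self.cell_stage = np.asarray(self.cell_stage)
            if self.cell_stage.shape != (m,):
                raise ValueError("cell_stage length must match number of cells")

    @property
    def n_genes(self) -> int:
        return self.values.shape[0]

    @property
    def n_cells(self) -> int:
        return self.values.shape[1]

    def subset_genes(self, gene_ids: list[str]) -> "ExpressionMatrix":
        index = {g: i for i, g in enumerate(self.gene_ids)}
        rows = [index[g] for g in gene_ids]
        return replace(self, values=self.values[rows, :], gene_ids=list(gene_ids))

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(self.values, index=self.gene_ids, columns=self.cell_ids)


@dataclass
class GeneFilterReport:
    """Per-gene statistics of the mean--CV noise fit and the filter outcome."""

    n_detected: int
    per_gene: pd.DataFrame  # index = detected gene ids; mean, cv, residual
    fit_params: dict = field(default_factory=dict)  # slope, intercept
    n_noise_removed: int = 0
    n_ubiquitous_removed: int = 0
    kept_gene_ids: list[str] = field(default_factory=list)
    noise_gene_ids: list[str] = field(default_factory=list)
    ubiquitous_gene_ids: list[str] = field(default_factory=list)

    def to_dict(self) -> dict:
        return {
            "n_detected": self.n_detected,
            "n_noise_removed": self.n_noise_removed,
            "n_ubiquitous_removed": self.n_ubiquitous_removed,
            "n_kept": len(self.kept_gene_ids),
            "fit_params": self.fit_params,
            "kept_gene_ids": self.kept_gene_ids,
        }


def _check_unique(ids: list[str], what: str) -> None:
    if len(set(ids)) != len(ids):
        seen, dups = set(), []
        for i in ids:
            if i in seen:
                dups.append(i)
            seen.add(i)
        raise ValueError(f"duplicated {what} ids: {sorted(set(dups))[:5]}")


def load_matrix(path, format: str | None = None, genes_file=None, cells_file=None) -> ExpressionMatrix:
    """Read an expression matrix from TSV/CSV (genes x cells, header row of
    cell ids, first column gene ids) or MatrixMarket MTX with sidecar
    ``genes.txt`` / ``cells.txt`` name files (one id per line)."""
    path = str(path)
    if format is None:
        format = "mtx" if path.endswith(".mtx") else ("csv" if path.endswith(".csv") else "tsv")
    if format in ("tsv", "csv"):
        sep = "\t" if format == "tsv" else ","
        try:
            df = pd.read_csv(path, sep=sep, index_col=0)
        except (pd.errors.ParserError, ValueError) as exc:
            raise ValueError(f"malformed {format} file {path}: {exc}") from exc
        if not all(np.issubdtype(dt, np.number) for dt in df.dtypes):
            bad = [c for c, dt in df.dtypes.items() if not np.issubdtype(dt, np.number)]
            raise ValueError(f"non-numeric columns in {path}: {bad[:5]}")
        return ExpressionMatrix(df.to_numpy(float), list(df.index), list(df.columns))
    if format == "mtx":
        import os

        base = os.path.dirname(path)
        genes_file = genes_file or os.path.join(base, "genes.txt")
        cells_file = cells_file or os.path.join(base, "cells.txt")
        values = np.asarray(mmread(path).todense() if hasattr(mmread(path), "todense") else mmread(path), dtype=float)
        genes = _read_names(genes_file)
        cells = _read_names(cells_file)
        return ExpressionMatrix(values, genes, cells)
    raise ValueError(f"unknown format {format!r}")


def _read_names(path) -> list[str]:
    with open(path) as fh:
        return [line.strip() for line in fh if line.strip()]


def load_metadata(path) -> pd.DataFrame:
    """Read a cell metadata TSV with at least ``cell_id`` and ``stage`` columns."""
    df = pd.read_csv(path, sep="\t")
    missing = {"cell_id", "stage"} - set(df.columns)
    if missing:
        raise ValueError(f"metadata file {path} lacks columns {sorted(missing)}")
    return df


def save_matrix(x: ExpressionMatrix, path, format: str = "tsv",
                genes_file=None, cells_file=None) -> None:
    path = str(path)
    if format in ("tsv", "csv"):
        x.to_frame().to_csv(path, sep="\t" if format == "tsv" else ",")
        return
    if format == "mtx":
        import os

        base = os.path.dirname(path)
        mmwrite(path, coo_matrix(x.values))
        with open(genes_file or os.path.join(base, "genes.txt"), "w") as fh:
            fh.write("\n".join(x.gene_ids) + "\n")
        with open(cells_file or os.path.join(base, "cells.txt"), "w") as fh:
            fh.write("\n".join(x.cell_ids) + "\n")
        return
    raise ValueError(f"unknown format {format!r}")


def log_transform(x: ExpressionMatrix, pseudocount: float = 1.0,
                  base: float | None = None) -> ExpressionMatrix:
    """Return ``log(TPM + pseudocount)`` (natural log by default).

    Raises if ``x`` is already transformed — the flag makes the transform
    idempotence-safe.
    """
    if x.transformed:
        raise ValueError("matrix is already log-transformed")
    values = np.log(x.values + pseudocount)
    if base is not None:
        values = values / math.log(base)
    return replace(x, values=values, transformed=True)


def detected_genes(x: ExpressionMatrix) -> np.ndarray:
    """Boolean mask of genes detected (TPM >= 1) in at least two cells."""
    return (x.values >= DETECTION_TPM).sum(axis=1) >= DETECTION_MIN_CELLS


def fit_noise_model(x: ExpressionMatrix) -> GeneFilterReport:
    """Fit the technical-noise line in (log2 mean, log2 CV) space.

    Only detected genes enter; genes with zero variance get CV = 0 and a
    ``-inf`` residual sentinel and are excluded from the least-squares fit.
    The signed residual is ``log2 CV - (intercept + slope * log2 mean)``.
    """
    if x.transformed:
        raise ValueError("noise model must be fitted on raw TPM values")
    mask = detected_genes(x)
    ids = [g for g, keep in zip(x.gene_ids, mask) if keep]
    if len(ids) < 3:
        raise ValueError(f"only {len(ids)} genes detected; need at least 3")
    sub = x.values[mask, :]
    mean = sub.mean(axis=1)
    sd = sub.std(axis=1, ddof=1)
    cv = np.divide(sd, mean, out=np.zeros_like(sd), where=mean > 0)

    fit_mask = cv > 0
    if fit_mask.sum() < 2:
        raise ValueError("fewer than 2 detected genes with positive CV; cannot fit noise model")
    lx = np.log2(mean[fit_mask])
    ly = np.log2(cv[fit_mask])
    slope, intercept = np.polyfit(lx, ly, 1)

    residual = np.full(mean.shape, -np.inf)
    residual[fit_mask] = np.log2(cv[fit_mask]) - (intercept + slope * np.log2(mean[fit_mask]))

    per_gene = pd.DataFrame({"mean": mean, "cv": cv, "residual": residual}, index=ids)
    return GeneFilterReport(
        n_detected=len(ids),
        per_gene=per_gene,
        fit_params={"slope": float(slope), "intercept": float(intercept)},
    )


def filter_genes(
    x: ExpressionMatrix,
    report: GeneFilterReport,
    noise_fraction: float = 0.10,
    ubiquitous_quantile: float = 0.5,
    one_sided: bool = False,
) -> tuple[ExpressionMatrix, GeneFilterReport]:
    """Apply the noise and ubiquitous-expression filters.

    Removal set (a): the ``ceil(noise_fraction * n_detected)`` detected genes
    with the largest absolute residual from the noise fit (``one_sided=True``
    ranks by the signed residual instead, removing only above-line genes).
    Genes excluded from the fit (CV = 0) never enter set (a); they are
    constant and fall to set (b) instead.

    Removal set (b): detected genes with CV below the ``ubiquitous_quantile``
    of the detected-gene CV distribution.

    Kept genes = detected minus the union of (a) and (b); ties at the
    residual cutoff break by gene id for determinism.
    """
    if not 0 < noise_fraction < 1 or not 0 < ubiquitous_quantile < 1:
        raise ValueError("noise_fraction and ubiquitous_quantile must lie in (0, 1)")
    per = report.per_gene
    ids = list(per.index)
    n_detected = report.n_detected

    ranked = sorted(
        (g for g in ids if np.isfinite(per.at[g, "residual"])),
        key=lambda g: (
            -(per.at[g, "residual"] if one_sided else abs(per.at[g, "residual"])),
            g,
        ),
    )
    n_noise = math.ceil(noise_fraction * n_detected)
    noise_set = ranked[:n_noise]

    cv_cut = float(per["cv"].quantile(ubiquitous_quantile))
    ubiq_set = [g for g in ids if per.at[g, "cv"] < cv_cut]

    removed = set(noise_set) | set(ubiq_set)
    kept = [g for g in ids if g not in removed]
    if not kept:
        raise ValueError("gene filters removed every detected gene")

    out_report = replace(
        report,
        n_noise_removed=len(noise_set),
        n_ubiquitous_removed=len(ubiq_set),
        kept_gene_ids=kept,
        noise_gene_ids=sorted(noise_set),
        ubiquitous_gene_ids=sorted(ubiq_set),
    )
    return x.subset_genes(kept), out_report
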