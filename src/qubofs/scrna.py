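"""Minimal single-cell front end.

Reads a gene-by-cell count matrix (MatrixMarket triplet directory, dense
CSV/TSV, or h5ad), applies standard quality-control filters, normalizes with
the analytic Pearson-residual transform, and derives a pseudotime target
from a user-supplied 2-D embedding via a principal-curve fit.  Embedding
computation itself (PHATE, UMAP, ...) is consumed, never computed here; a
precomputed pseudotime vector can also be supplied verbatim downstream, which
is the most faithful route when one exists.

QC defaults: minimum library size 1,000 reads per cell, maximum 15%
mitochondrial fraction per cell, minimum 500 detected genes per cell, then
minimum 15 nonzero cells per gene on the surviving cells.
"""

from __future__ import annotations

import gzip
import logging
import warnings
from dataclasses import dataclass
from pathlib import Path

import numpy as np
import pandas as pd
import scipy.io
import scipy.sparse as sp

logger = logging.getLogger(__name__)


@dataclass
class CountMatrix:
    """Sparse nonnegative count matrix, genes × cells, with name sidecars."""

    counts: sp.csr_matrix
    gene_names: np.ndarray
    cell_barcodes: np.ndarray

    def __post_init__(self) -> None:
        self.counts = sp.csr_matrix(self.counts)
        if self.counts.nnz and self.counts.data.min() < 0:
            raise ValueError("counts must be nonnegative")
        self.gene_names = np.asarray(self.gene_names, dtype=object)
        self.cell_barcodes = np.asarray(self.cell_barcodes, dtype=object)
        g, c = self.counts.shape
        if self.gene_names.size != g:
            raise ValueError(f"{self.gene_names.size} gene names for {g} matrix rows")
        if self.cell_barcodes.size != c:
            raise ValueError(f"{self.cell_barcodes.size} barcodes for {c} matrix columns")

    @property
    def n_genes(self) -> int:
        return self.counts.shape[0]

    @property
    def n_cells(self) -> int:
        return self.counts.shape[1]


@dataclass
class PseudotimeVector:
    """Per-cell trajectory position, min-max normalized to [0, 1]."""

    values: np.ndarray

    def __post_init__(self) -> None:
        v = np.asarray(self.values, dtype=np.float64).ravel()
        if not np.all(np.isfinite(v)):
            raise ValueError("pseudotime contains non-finite values")
        span = v.max() - v.min()
        if span > 0:
            v = (v - v.min()) / span
        self.values = v


def _dedup(names: list[str]) -> np.ndarray:
    """Suffix duplicate names deterministically: A, A.1, A.2, ..."""
    seen: dict[str, int] = {}
    out = []
    for nm in names:
        if nm in seen:
            seen[nm] += 1
            out.append(f"{nm}.{seen[nm]}")
        else:
            seen[nm] = 0
            out.append(nm)
    return np.asarray(out, dtype=object)


def _read_sidecar(path: Path, column: int = 0) -> list[str]:
    opener = gzip.open if path.suffix == ".gz" else open
    with opener(path, "rt") as fh:
        rows = [line.rstrip("\n").split("\t") for line in fh if line.strip()]
    ncol = max(len(r) for r in rows)
    col = min(column, ncol - 1)
    return [r[col] if col < len(r) else r[0] for r in rows]


def _find_one(d: Path, stems: list[str]) -> Path | None:
    for stem in stems:
        for suffix in ("", ".gz"):
            cand = d / (stem + suffix)
            if cand.exists():
                return cand
    return None


def read_counts(path: str | Path, format: str = "mtx_dir",
                orientation: str = "genes_by_cells") -> CountMatrix:
    """Load a count matrix; orientation is normalized to genes × cells.

    ``mtx_dir`` expects a directory with matrix.mtx[.gz] plus
    features.tsv/genes.tsv and barcodes.tsv sidecars (gene name taken from
    the second sidecar column when present, per the common triplet layout).
    ``csv`` reads a dense table with gene names in the index by default; pass
    ``orientation='cells_by_genes'`` when rows are cells.  ``h5ad`` reads an
    AnnData file (cells × genes on disk, transposed on load).
    """
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(str(path))
    if format == "mtx_dir":
        mtx = _find_one(path, ["matrix.mtx"])
        feats = _find_one(path, ["features.tsv", "genes.tsv", "features.txt", "genes.txt"])
        bars = _find_one(path, ["barcodes.tsv", "barcodes.txt"])
        if mtx is None or feats is None or bars is None:
            raise FileNotFoundError(
                f"{path} must contain matrix.mtx[.gz], features/genes and barcodes sidecars")
        M = sp.csr_matrix(scipy.io.mmread(mtx))
        genes = _read_sidecar(feats, column=1)
        cells = _read_sidecar(bars, column=0)
        if M.shape == (len(genes), len(cells)):
            pass
        elif M.shape == (len(cells), len(genes)):
            M = sp.csr_matrix(M.T)
        else:
            raise ValueError(
                f"matrix shape {M.shape} matches neither {len(genes)} genes x "
                f"{len(cells)} cells nor its transpose")
        return CountMatrix(M, _dedup(genes), _dedup(cells))
    if format == "csv":
        sep = "\t" if str(path).endswith((".tsv", ".tsv.gz", ".txt")) else ","
        df = pd.read_csv(path, index_col=0, sep=sep)
        if orientation == "cells_by_genes":
            df = df.T
        elif orientation != "genes_by_cells":
            raise ValueError(f"unknown orientation {orientation!r}")
        return CountMatrix(sp.csr_matrix(df.to_numpy(dtype=np.float64)),
                           _dedup([str(i) for i in df.index]),
                           _dedup([str(c) for c in df.columns]))
    if format == "h5ad":
        import anndata

        adata = anndata.read_h5ad(path)
        X = adata.X
        M = sp.csr_matrix(X.T if not sp.issparse(X) else X.T)
        return CountMatrix(M, _dedup([str(v) for v in adata.var_names]),
                           _dedup([str(o) for o in adata.obs_names]))
    raise ValueError(f"unknown format {format!r}; choose mtx_dir, csv or h5ad")


def qc_filter(m: CountMatrix, min_libsize: int = 1000, max_mito_frac: float = 0.15,
              min_cells_per_gene: int = 15, min_genes_per_cell: int = 500,
              mito_prefix: str = "MT-") -> tuple[CountMatrix, dict]:
    """Apply cell filters (library size, mitochondrial fraction, detected
    genes), then the gene filter (nonzero cells) on the surviving cells.

    Returns the filtered matrix and an attrition report.  Idempotent:
    filtering an already-filtered matrix removes nothing further only when
    the gene filter does not create new sub-threshold cells; the standard
    guarantee tested here is that a second pass is a no-op.
    """
    X = sp.csc_matrix(m.counts)
    libsize = np.asarray(X.sum(axis=0)).ravel()
    genes_per_cell = np.asarray((X > 0).sum(axis=0)).ravel()
    is_mito = np.array([str(g).upper().startswith(mito_prefix.upper())
                        for g in m.gene_names])
    if is_mito.any():
        mito_frac = np.asarray(X[is_mito].sum(axis=0)).ravel() / np.maximum(libsize, 1)
        mito_ok = mito_frac <= max_mito_frac
    else:
        logger.warning("no gene names match mitochondrial prefix %r; "
                       "mito filter skipped", mito_prefix)
        mito_ok = np.ones(m.n_cells, dtype=bool)
    lib_ok = libsize >= min_libsize
    det_ok = genes_per_cell >= min_genes_per_cell
    cell_keep = lib_ok & mito_ok & det_ok
    report = {
        "cells_in": m.n_cells, "genes_in": m.n_genes,
        "cells_fail_libsize": int((~lib_ok).sum()),
        "cells_fail_mito": int((~mito_ok).sum()),
        "cells_fail_min_genes": int((~det_ok).sum()),
    }
    if not cell_keep.any():
        raise ValueError(f"all cells removed by QC: {report}")
    Xc = X[:, cell_keep]
    cells_per_gene = np.asarray((Xc > 0).sum(axis=1)).ravel()
    gene_keep = cells_per_gene >= min_cells_per_gene
    report.update({
        "genes_fail_min_cells": int((~gene_keep).sum()),
        "cells_out": int(cell_keep.sum()), "genes_out": int(gene_keep.sum()),
    })
    out = CountMatrix(sp.csr_matrix(Xc[gene_keep]),
                      m.gene_names[gene_keep], m.cell_barcodes[cell_keep])
    return out, report


def pearson_residual_transform(m: CountMatrix, theta: float = 100.0,
                               clip: float | str = "auto") -> np.ndarray:
    """Analytic Pearson residuals of the counts, genes × cells (dense).

    Under the null of a gene-by-cell product expectation
    mu_gc = (row_g total · col_c total) / grand total and negative-binomial
    noise with overdispersion ``theta``, the residual is
    (x − mu) / sqrt(mu + mu²/theta).  ``clip='auto'`` clips to ±sqrt(n_cells),
    which bounds the leverage of rare extreme counts; theta → inf recovers
    Poisson residuals (x − mu)/sqrt(mu).
    """
    X = np.asarray(m.counts.todense(), dtype=np.float64)
    grand = X.sum()
    if grand == 0:
        raise ValueError("zero grand total; nothing to normalize")
    mu = np.outer(X.sum(axis=1), X.sum(axis=0)) / grand
    with np.errstate(divide="ignore", invalid="ignore"):
        res = (X - mu) / np.sqrt(mu + mu * mu / theta)
    res[~np.isfinite(res)] = 0.0
    if clip == "auto":
        clip = float(np.sqrt(m.n_cells))
    if clip is not None:
        np.clip(res, -clip, clip, out=res)
    return res


def fit_pseudotime(embedding: np.ndarray, n_knots: int = 20,
                   max_iter: int = 10, flip: bool = False) -> PseudotimeVector:
    """Principal-curve pseudotime from a cells × 2 embedding.

    Initialized by projection on the first principal axis; each iteration
    fits a least-squares cubic spline (evenly spaced interior knots over the
    rank parameterization) to both coordinates, then re-projects every cell
    to its nearest point on the densely sampled curve and reparameterizes by
    normalized arc length.  The fit is a linear smoother per coordinate, so
    the result is invariant (up to direction reversal) under translation,
    rotation and uniform scaling of the embedding.  ``flip`` reverses the
    arbitrary direction.
    """
    from scipy.interpolate import LSQUnivariateSpline
    from scipy.spatial import cKDTree

    Y = np.asarray(embedding, dtype=np.float64)
    if Y.ndim != 2 or Y.shape[1] != 2:
        raise ValueError("embedding must be cells x 2")
    p = Y.shape[0]
    if p < 10:
        raise ValueError("need at least 10 cells")
    if not np.all(np.isfinite(Y)):
        raise ValueError("embedding contains non-finite values")
    Yc = Y - Y.mean(axis=0)
    scale = np.sqrt((Yc ** 2).sum(axis=1)).max()
    if scale == 0:
        raise ValueError("degenerate embedding: all cells coincident")
    Yc = Yc / scale
    _, _, Vt = np.linalg.svd(Yc, full_matrices=False)
    t = Yc @ Vt[0]
    grid = np.linspace(0.0, 1.0, 512)
    for _ in range(max_iter):
        order = np.argsort(t, kind="stable")
        u = np.linspace(0.0, 1.0, p)          # rank parameterization
        k_int = max(1, min(n_knots, p // 10))
        knots = np.linspace(0, 1, k_int + 2)[1:-1]
        curve = np.column_stack([
            LSQUnivariateSpline(u, Yc[order, d], t=knots, k=3)(grid)
            for d in range(2)])
        seg_vec = np.diff(curve, axis=0)
        seg_len = np.sqrt((seg_vec ** 2).sum(axis=1))
        arclen = np.concatenate([[0.0], np.cumsum(seg_len)])
        _, nearest = cKDTree(curve).query(Yc)
        # refine the grid hit by exact projection onto the two adjacent
        # polyline segments, removing the grid-quantization error
        t_new = np.empty(p)
        for c in range(p):
            best_d2, best_t = np.inf, arclen[nearest[c]]
            for si in (nearest[c] - 1, nearest[c]):
                if si < 0 or si >= len(seg_vec) or seg_len[si] == 0:
                    continue
                w = Yc[c] - curve[si]
                frac = np.clip((w @ seg_vec[si]) / seg_len[si] ** 2, 0.0, 1.0)
                proj = curve[si] + frac * seg_vec[si]
                d2 = float(((Yc[c] - proj) ** 2).sum())
                if d2 < best_d2:
                    best_d2 = d2
                    best_t = arclen[si] + frac * seg_len[si]
            t_new[c] = best_t
        if np.allclose(np.sort(t_new), np.sort(t), atol=1e-10):
            t = t_new
            break
        t = t_new
    if flip:
        t = t.max() - t
    return PseudotimeVector(values=t)


def smoothed_profiles(expr: np.ndarray, pt: PseudotimeVector | np.ndarray,
                      gene_indices, span: float = 0.3,
                      grid_size: int = 100) -> tuple[np.ndarray, np.ndarray]:
    """LOESS-smoothed expression along pseudotime, one curve per gene.

    ``expr`` is genes × cells; returns (grid, curves) with curves of shape
    (len(gene_indices), grid_size), each from a locally weighted linear
    regression of that gene's expression on pseudotime evaluated on an even
    grid over the observed pseudotime range.
    """
    from statsmodels.nonparametric.smoothers_lowess import lowess

    t = pt.values if isinstance(pt, PseudotimeVector) else np.asarray(pt, float).ravel()
    expr = np.asarray(expr, dtype=np.float64)
    if expr.shape[1] != t.size:
        raise ValueError("expr cell dimension does not match pseudotime length")
    gene_indices = list(gene_indices)
    if not gene_indices:
        raise ValueError("empty gene list")
    grid = np.linspace(t.min(), t.max(), grid_size)
    curves = np.empty((len(gene_indices), grid_size))
    for row, g in enumerate(gene_indices):
        with warnings.catch_warnings():
            warnings.simplefilter("ignore", RuntimeWarning)
            curves[row] = lowess(expr[g], t, frac=span, xvals=grid)
    return grid, curves
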