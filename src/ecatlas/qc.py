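"""Quality control and normalization of raw UMI matrices.

The filters follow the atlas convention: genes kept when expressed by at
least 10 cells and with a raw row mean of at least 0.003 counts per cell;
cells removed when they express fewer than 300 genes (low quality), more
genes than 2 standard deviations above the mean (potential doublets), or
derive more than 10% of UMIs from the mitochondrial genome. Removal
thresholds are strict inequalities, so a cell at exactly 300 genes or
exactly 10% mitochondrial UMIs survives.
"""

from __future__ import annotations

from dataclasses import dataclass

import anndata as ad
import numpy as np
import pandas as pd
import scanpy as sc
from scipy import sparse


@dataclass
class QCThresholds:
    min_cells_per_gene: int = 10
    min_gene_row_mean: float = 0.003
    min_genes_per_cell: int = 300
    doublet_sd_multiplier: float = 2.0
    max_mito_umi_fraction: float = 0.10

    def __post_init__(self) -> None:
        for f in self.__dataclass_fields__:
            if getattr(self, f) < 0:
                raise ValueError(f"{f} must be >= 0")


def _counts(adata: ad.AnnData) -> sparse.csr_matrix:
    X = adata.X
    return X.tocsr() if sparse.issparse(X) else sparse.csr_matrix(X)


def filter_genes(adata: ad.AnnData, thr: QCThresholds | None = None) -> ad.AnnData:
    """Keep genes expressed in >= ``min_cells_per_gene`` cells AND with raw
    row mean >= ``min_gene_row_mean`` counts per cell. Order preserved."""
    thr = thr or QCThresholds()
    X = _counts(adata)
    n_cells_expr = np.asarray((X > 0).sum(axis=0)).ravel()
    # sum/n rather than sparse .mean (which multiplies by 1/n and can push
    # an exact-boundary row mean just below the threshold)
    row_mean = np.asarray(X.sum(axis=0)).ravel().astype(np.float64) / X.shape[0]
    keep = (n_cells_expr >= thr.min_cells_per_gene) & (
        row_mean >= thr.min_gene_row_mean
    )
    if not keep.any():
        raise ValueError("all genes filtered out by gene QC thresholds")
    return adata[:, keep].copy()


def filter_cells(
    adata: ad.AnnData, thr: QCThresholds | None = None
) -> tuple[ad.AnnData, pd.DataFrame]:
    """Remove low-quality cells, doublet suspects and high-mitochondrial cells.

    The doublet cutoff (mean + ``doublet_sd_multiplier`` x SD of genes per
    cell) is computed over cells that already pass the low-gene rule, so a
    tail of empty droplets cannot drag the cutoff down. Returns the filtered
    matrix and a per-cell report attributing each removed cell to the first
    failing rule (``low_genes``, ``doublet``, ``mito``).
    """
    thr = thr or QCThresholds()
    X = _counts(adata)
    genes_per_cell = np.asarray((X > 0).sum(axis=1)).ravel()
    total_umi = np.asarray(X.sum(axis=1)).ravel().astype(float)
    if "is_mito" in adata.var.columns:
        mito_umi = np.asarray(X[:, adata.var["is_mito"].to_numpy()].sum(axis=1)).ravel()
    else:
        mito_umi = np.zeros(adata.n_obs)
    with np.errstate(invalid="ignore", divide="ignore"):
        mito_frac = np.where(total_umi > 0, mito_umi / total_umi, 0.0)

    low = genes_per_cell < thr.min_genes_per_cell
    base = genes_per_cell[~low]
    cutoff = base.mean() + thr.doublet_sd_multiplier * base.std(ddof=0) if base.size else np.inf
    doublet = genes_per_cell > cutoff
    mito = mito_frac > thr.max_mito_umi_fraction

    rule = np.full(adata.n_obs, "", dtype=object)
    rule[mito] = "mito"
    rule[doublet] = "doublet"
    rule[low] = "low_genes"  # first-failing-rule attribution, QC order
    keep = rule == ""
    report = pd.DataFrame(
        {"kept": keep, "rule": rule}, index=adata.obs_names.copy()
    )
    report.index.name = "barcode"
    if keep.sum() < 2:
        raise ValueError("fewer than 2 cells remain after cell QC")
    return adata[keep].copy(), report


def normalize_scale(
    adata: ad.AnnData, target_sum: float | None = 1e4
) -> ad.AnnData:
    """Depth-normalize to ``target_sum`` counts per cell, log(1+x) transform,
    and store a per-gene z-scored copy in ``layers['scaled']``.

    ``target_sum=None`` normalizes to the median depth, which keeps
    normalized values on the raw-count scale (the scale on which the
    highly-variable-gene mean band of the trajectory module is defined).

    Zero-variance genes scale to 0 rather than NaN. The normalization record
    (method, target sum, log base) is kept in ``.uns['normalization']`` so
    the choice is auditable.
    """
    X = _counts(adata)
    depth = np.asarray(X.sum(axis=1)).ravel()
    if (depth == 0).any():
        raise ValueError("zero-depth cell encountered; run cell QC first")
    nm = adata.copy()
    nm.layers["counts"] = X.copy()
    sc.pp.normalize_total(nm, target_sum=target_sum)
    sc.pp.log1p(nm)
    dense = (nm.X.toarray() if sparse.issparse(nm.X) else np.asarray(nm.X)).astype(
        np.float64
    )
    mean = dense.mean(axis=0)
    sd = dense.std(axis=0, ddof=0)
    sd_safe = np.where(sd == 0, 1.0, sd)
    nm.layers["scaled"] = (dense - mean) / sd_safe
    nm.uns["normalization"] = {
        "method": "depth-normalize + log1p + per-gene z-score",
        "target_sum": "median_depth" if target_sum is None else target_sum,
        "log_base": "e",
        "zero_variance_policy": "scaled to 0",
    }
    return nm
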