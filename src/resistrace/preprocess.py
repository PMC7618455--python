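"""Count-matrix quality control, normalization, and variable-gene selection.

Cells are filtered on total UMI count, detected-gene count, and
mitochondrial fraction; genes expressed in too few cells are removed.
Normalization is depth-scaling followed by log1p; variable genes are
ranked by a variance-stabilized standardized variance (clipped z-scores
of counts around a lowess mean-variance trend).
"""

from __future__ import annotations

from dataclasses import dataclass

import anndata as ad
import numpy as np
from statsmodels.nonparametric.smoothers_lowess import lowess


@dataclass(frozen=True)
class QCThresholds:
    """Inclusive UMI/gene intervals; strict upper bound on mito fraction."""

    umi_range: tuple[float, float]
    gene_range: tuple[float, float]
    max_mito_fraction: float = 0.15
    min_cells_per_gene: int = 3

    def __post_init__(self) -> None:
        for lo, hi in (self.umi_range, self.gene_range):
            if lo > hi:
                raise ValueError("range lower bound exceeds upper bound")


#: default thresholds for pre-treatment samples
PRE_QC = QCThresholds(umi_range=(20000, 200000), gene_range=(2500, 12000))
#: default thresholds for post-treatment samples
POST_QC = QCThresholds(umi_range=(10000, 100000), gene_range=(2000, 10000))


def _counts(adata: ad.AnnData) -> np.ndarray:
    X = adata.layers.get("counts", adata.X)
    return np.asarray(X)


def qc_metrics(adata: ad.AnnData, mito_prefix: str = "MT-") -> ad.AnnData:
    """Annotate obs with total_counts, n_genes, mito_fraction (in place)."""
    X = _counts(adata)
    adata.obs["total_counts"] = X.sum(axis=1)
    adata.obs["n_genes"] = (X > 0).sum(axis=1)
    mito = np.array([g.startswith(mito_prefix) for g in adata.var_names])
    with np.errstate(invalid="ignore"):
        frac = X[:, mito].sum(axis=1) / np.maximum(adata.obs["total_counts"], 1)
    adata.obs["mito_fraction"] = frac
    adata.var["n_cells_expressing"] = (X > 0).sum(axis=0)
    return adata


def filter_genes(adata: ad.AnnData, min_cells: int = 3) -> ad.AnnData:
    """Keep genes expressed (count > 0) in at least ``min_cells`` cells."""
    keep = (_counts(adata) > 0).sum(axis=0) >= min_cells
    if not keep.any():
        raise ValueError("no genes pass the expression filter")
    return adata[:, keep].copy()


def filter_cells(
    adata: ad.AnnData, thresholds: QCThresholds = PRE_QC, mito_prefix: str = "MT-"
) -> tuple[ad.AnnData, dict[str, int]]:
    """Apply the per-cell QC intervals; returns (matrix, removal report).

    UMI and gene intervals are inclusive on both ends; the mitochondrial
    bound is strict (a cell at exactly the threshold is removed).
    """
    if "total_counts" not in adata.obs:
        qc_metrics(adata, mito_prefix=mito_prefix)
    umi = adata.obs["total_counts"].to_numpy()
    ngene = adata.obs["n_genes"].to_numpy()
    mito = adata.obs["mito_fraction"].to_numpy()
    lo_u, hi_u = thresholds.umi_range
    lo_g, hi_g = thresholds.gene_range
    ok_umi = (umi >= lo_u) & (umi <= hi_u)
    ok_gene = (ngene >= lo_g) & (ngene <= hi_g)
    ok_mito = mito < thresholds.max_mito_fraction
    keep = ok_umi & ok_gene & ok_mito
    report = {
        "removed_umi": int((~ok_umi).sum()),
        "removed_genes": int((~ok_gene).sum()),
        "removed_mito": int((~ok_mito).sum()),
        "removed_total": int((~keep).sum()),
        "kept": int(keep.sum()),
    }
    return adata[keep].copy(), report


def normalize_log(adata: ad.AnnData, scale: float = 1e4) -> ad.AnnData:
    """Depth-normalize and log-transform: x -> ln(1 + x * scale / cell_total).

    Raw counts are preserved in ``layers['counts']``.  Zero-total cells
    are an error (they carry no information and break the scaling).
    """
    out = adata.copy()
    X = np.asarray(out.X, dtype=float)
    totals = X.sum(axis=1, keepdims=True)
    if np.any(totals == 0):
        raise ValueError("cell with zero total count; filter cells first")
    if "counts" not in out.layers:
        out.layers["counts"] = np.asarray(adata.X).copy()
    out.X = np.log1p(X * scale / totals)
    return out


def top_variable_genes(
    adata: ad.AnnData, n: int, span: float = 0.3
) -> list[str]:
    """Rank genes by standardized variance after a mean-variance trend fit.

    Per-gene count mean and variance are computed; the variance trend is
    fit by lowess in log10 space on genes with positive variance; counts
    are standardized by the trend-expected standard deviation, clipped at
    sqrt(n_cells), and the variance of the clipped values is the ranking
    statistic.  Returns the top ``n`` gene names in rank order.
    """
    if n > adata.n_vars:
        raise ValueError(f"requested {n} genes but matrix has {adata.n_vars}")
    X = _counts(adata).astype(float)
    n_cells = X.shape[0]
    mean = X.mean(axis=0)
    var = X.var(axis=0, ddof=1)
    std_var = np.zeros(adata.n_vars)
    positive = (var > 0) & (mean > 0)
    if positive.sum() >= 2:
        log_mean = np.log10(mean[positive])
        log_var = np.log10(var[positive])
        fitted = lowess(
            log_var, log_mean, frac=span, return_sorted=False
        )
        exp_sd = np.sqrt(10.0**fitted)
        clip = np.sqrt(n_cells)
        Z = (X[:, positive] - mean[positive]) / exp_sd
        np.clip(Z, -clip, clip, out=Z)
        std_var[positive] = Z.var(axis=0, ddof=1)
    order = np.lexsort((adata.var_names, -std_var))
    return [adata.var_names[i] for i in order[:n]]
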