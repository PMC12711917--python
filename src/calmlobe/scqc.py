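"""Single-cell QC, depth normalization, and expression summaries.

Implements the count-matrix processing recipe used for the fetal
hippocampus expression survey of CALM1-3, on an AnnData (cells x genes):

1. drop cells detecting fewer than 800 or more than 7000 genes (bounds
   inclusive on the kept side),
2. keep genes detected in at least 30 of the surviving cells,
3. drop hemoglobin-expressing cells (any count in the globin gene set),
4. drop cells with more than 15% mitochondrial counts,
then scale every cell to 10^4 total counts.

The filters are order-sensitive and the applied order is recorded in the
returned report.  Cluster labels, when present, are taken as given; no
clustering is performed here.
"""

from __future__ import annotations

import re
from dataclasses import dataclass, field

import anndata as ad
import numpy as np
import pandas as pd
from scipy import sparse

__all__ = ["QCParams", "QCReport", "qc_filter", "depth_normalize",
           "cluster_expression_summary", "read_mtx_triplet"]

#: Globin symbols (HBA1/2, HBB, HBD, HBE1, HBG1/2, HBM, HBQ1, HBZ) while
#: excluding non-globin HB-prefixed genes (HBEGF, HBS1L, HBP1).
HEMOGLOBIN_PATTERN = r"^HB[ABDEGMQZ]\d*$"
MITO_PREFIX = "MT-"


@dataclass(frozen=True)
class QCParams:
    min_genes_per_cell: int = 800
    max_genes_per_cell: int = 7000
    min_cells_per_gene: int = 30
    max_mito_fraction: float = 0.15
    hemoglobin_pattern: str = HEMOGLOBIN_PATTERN
    hemoglobin_min_count: int = 1   # "expressing" = any nonzero count
    mito_prefix: str = MITO_PREFIX


@dataclass
class QCReport:
    steps: list[dict] = field(default_factory=list)
    final_cells: int = 0
    final_genes: int = 0

    def add(self, name: str, axis: str, before: int, after: int) -> None:
        self.steps.append(
            {"filter": name, "axis": axis, "in": before, "out": after,
             "removed": before - after}
        )

    @property
    def order(self) -> list[str]:
        return [s["filter"] for s in self.steps]


def _counts(adata: ad.AnnData) -> sparse.csr_matrix:
    x = adata.X
    return sparse.csr_matrix(x) if not sparse.issparse(x) else x.tocsr()


def qc_filter(adata: ad.AnnData, params: QCParams = QCParams()) -> tuple[ad.AnnData, QCReport]:
    """Apply the four QC filters in order; returns (filtered, report)."""
    report = QCReport()
    out = adata.copy()

    # 1. cell gene-count bounds (inclusive)
    x = _counts(out)
    n_genes = np.asarray((x > 0).sum(axis=1)).ravel()
    keep = (n_genes >= params.min_genes_per_cell) & (n_genes <= params.max_genes_per_cell)
    before = out.n_obs
    out = out[keep].copy()
    report.add("cell_gene_count_bounds", "cells", before, out.n_obs)

    # 2. gene detection threshold, computed on the surviving cells
    x = _counts(out)
    n_cells = np.asarray((x > 0).sum(axis=0)).ravel()
    keep_genes = n_cells >= params.min_cells_per_gene
    before = out.n_vars
    out = out[:, keep_genes].copy()
    report.add("gene_min_cells", "genes", before, out.n_vars)

    # 3. hemoglobin-expressing cells
    hb_re = re.compile(params.hemoglobin_pattern)
    hb_mask = np.array([bool(hb_re.match(g)) for g in out.var_names])
    x = _counts(out)
    hb_counts = np.asarray(x[:, hb_mask].sum(axis=1)).ravel() if hb_mask.any() else np.zeros(out.n_obs)
    keep = hb_counts < params.hemoglobin_min_count
    before = out.n_obs
    out = out[keep].copy()
    report.add("hemoglobin_expressing", "cells", before, out.n_obs)

    # 4. mitochondrial fraction
    mt_mask = np.array([g.startswith(params.mito_prefix) for g in out.var_names])
    x = _counts(out)
    total = np.asarray(x.sum(axis=1)).ravel()
    mito = np.asarray(x[:, mt_mask].sum(axis=1)).ravel() if mt_mask.any() else np.zeros(out.n_obs)
    with np.errstate(invalid="ignore", divide="ignore"):
        frac = np.where(total > 0, mito / np.maximum(total, 1), 0.0)
    keep = frac <= params.max_mito_fraction
    before = out.n_obs
    out = out[keep].copy()
    report.add("mito_fraction", "cells", before, out.n_obs)

    report.final_cells, report.final_genes = out.n_obs, out.n_vars
    if out.n_obs == 0 or out.n_vars == 0:
        raise ValueError(f"QC removed everything; attrition: {report.steps}")
    return out, report


def depth_normalize(
    adata: ad.AnnData, target_sum: float = 1e4, log1p_layer: bool = False
) -> ad.AnnData:
    """Scale each cell to ``target_sum`` total counts (post-QC matrices only)."""
    import scanpy as sc

    x = _counts(adata)
    totals = np.asarray(x.sum(axis=1)).ravel()
    if np.any(totals == 0):
        raise ValueError("zero-total cell; run qc_filter first")
    out = adata.copy()
    sc.pp.normalize_total(out, target_sum=target_sum)
    if log1p_layer:
        out.layers["log1p"] = sc.pp.log1p(out, copy=True).X
    return out


def cluster_expression_summary(
    adata: ad.AnnData, cluster_key: str, genes: list[str]
) -> pd.DataFrame:
    """Per (gene, cluster): mean over all cells, fraction of expressing
    cells, and mean over expressing cells (NaN when no cell expresses).

    Unknown gene symbols produce a warning and are omitted.
    """
    import warnings

    if cluster_key not in adata.obs:
        raise KeyError(f"no cluster labels under obs[{cluster_key!r}]")
    clusters = adata.obs[cluster_key]
    if clusters.isna().any():
        raise ValueError("cluster labels must cover all cells")
    rows = []
    for gene in genes:
        if gene not in adata.var_names:
            warnings.warn(f"unknown gene symbol {gene!r}; omitted")
            continue
        vec = np.asarray(_counts(adata[:, gene]).todense()).ravel()
        for cl in pd.unique(clusters):
            vals = vec[np.asarray(clusters == cl)]
            nz = vals[vals > 0]
            rows.append(
                {
                    "gene": gene,
                    "cluster": cl,
                    "mean_all": float(vals.mean()) if vals.size else np.nan,
                    "fraction_expressing": float((vals > 0).mean()) if vals.size else np.nan,
                    "mean_expressing": float(nz.mean()) if nz.size else np.nan,
                }
            )
    return pd.DataFrame(rows)


def read_mtx_triplet(mtx_path, features_path, barcodes_path) -> ad.AnnData:
    """Read MatrixMarket counts (genes x cells) with feature/barcode lists."""
    from scipy.io import mmread

    m = sparse.csr_matrix(mmread(mtx_path).T)  # cells x genes
    genes = pd.read_csv(features_path, header=None, sep="\t")[0].astype(str).tolist()
    cells = pd.read_csv(barcodes_path, header=None, sep="\t")[0].astype(str).tolist()
    adata = ad.AnnData(X=m)
    adata.var_names = genes
    adata.obs_names = cells
    return adata
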