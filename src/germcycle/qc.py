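"""Cell-level quality filtering and log-normalization.

Cells detecting too few genes (empty droplets, debris) are removed before any
scoring; the default keeps cells expressing more than 200 genes, read as a
strict inequality.  Expression values downstream are library-size normalized
and log-transformed: ``log(1 + scale_factor * count / total)`` with natural
log.  The normalization parameters travel in ``.uns['normalization']`` so
every result declares how it was produced.
"""

from __future__ import annotations

import warnings

import anndata as ad
import numpy as np


def detected_genes_per_cell(adata: ad.AnnData) -> np.ndarray:
    """Number of genes with count > 0 in each cell."""
    X = np.asarray(adata.X)
    return (X > 0).sum(axis=1)


def filter_cells(
    adata: ad.AnnData,
    min_genes: int = 200,
    strict: bool = True,
    keep_cells: list[str] | None = None,
) -> ad.AnnData:
    """Drop low-quality cells by detected-gene count.

    Parameters
    ----------
    min_genes
        Threshold on the number of detected (count > 0) genes.
    strict
        If True (default) a cell is retained when it detects *more than*
        ``min_genes`` genes; if False, at least ``min_genes``.
    keep_cells
        Optional include-list of cell IDs applied before the gene filter
        (e.g. cells already identified as germ cells rather than somatic
        contamination).

    Gene set and cell order are preserved; the operation is idempotent.
    """
    if keep_cells is not None:
        adata = adata[adata.obs_names.isin(set(keep_cells))]
    n_detected = detected_genes_per_cell(adata)
    mask = n_detected > min_genes if strict else n_detected >= min_genes
    if len(mask) and not mask.any():
        warnings.warn(
            f"filter_cells removed all {adata.n_obs} cells "
            f"(min_genes={min_genes}, strict={strict})",
            stacklevel=2,
        )
    out = adata[np.asarray(mask)].copy()
    out.uns["qc"] = {
        "min_genes": min_genes,
        "strict": bool(strict),
        "n_cells_before": int(adata.n_obs),
        "n_cells_after": int(out.n_obs),
    }
    return out


def lognormalize(adata: ad.AnnData, scale_factor: float = 1e4) -> ad.AnnData:
    """Library-size normalize and log-transform counts.

    ``value(c, g) = ln(1 + scale_factor * count(c, g) / total(c))``.

    Raises :class:`ValueError` naming the first offending cell if any cell
    has zero total counts.
    """
    X = np.asarray(adata.X, dtype=float)
    totals = X.sum(axis=1)
    zero = np.flatnonzero(totals == 0)
    if zero.size:
        raise ValueError(
            f"cell {adata.obs_names[zero[0]]!r} has zero total counts; "
            "filter such cells before normalizing"
        )
    out = adata.copy()
    out.X = np.log1p(scale_factor * X / totals[:, None])
    out.layers["counts"] = np.asarray(adata.X).copy()
    out.uns["normalization"] = {
        "method": "library-size log1p",
        "scale_factor": float(scale_factor),
        "log_base": "e",
    }
    return out
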