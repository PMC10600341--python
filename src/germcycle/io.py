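"""Readers and writers for the package's on-disk formats.

Counts travel as Matrix Market triplets in the 10x layout (``matrix.mtx``
with genes as rows and cells as columns, ``barcodes.tsv``, ``features.tsv``)
plus a ``cell_metadata.csv`` carrying group labels and, for synthetic data,
the true phase.  Gene sets use GMT (see :mod:`germcycle.genesets`); images
are multi-page TIFF (page 0 = DAPI, page 1 = signal) with a ``truth.csv``
for synthetic fields.
"""

from __future__ import annotations

from pathlib import Path

import anndata as ad
import numpy as np
import pandas as pd
import tifffile
from scipy import io as spio
from scipy import sparse


def write_counts(adata: ad.AnnData, outdir: str | Path) -> Path:
    """Write a count matrix as MTX + barcodes/features TSV + metadata CSV."""
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    X = sparse.csc_matrix(np.asarray(adata.X).T)  # genes x cells, 10x layout
    spio.mmwrite(outdir / "matrix.mtx", X, field="integer")
    (outdir / "barcodes.tsv").write_text("\n".join(adata.obs_names) + "\n")
    (outdir / "features.tsv").write_text("\n".join(adata.var_names) + "\n")
    meta = adata.obs.reset_index(names="barcode")
    meta.to_csv(outdir / "cell_metadata.csv", index=False)
    return outdir


def read_counts(indir: str | Path) -> ad.AnnData:
    """Read a count directory written by :func:`write_counts` (or dense CSV).

    A directory holding ``counts.csv`` (cells as rows, genes as columns,
    first column = cell ID) is also accepted.
    """
    indir = Path(indir)
    csv = indir / "counts.csv"
    if csv.exists():
        df = pd.read_csv(csv, index_col=0)
        adata = ad.AnnData(X=df.to_numpy(dtype=np.int64),
                           obs=pd.DataFrame(index=df.index.astype(str)),
                           var=pd.DataFrame(index=df.columns.astype(str)))
    else:
        mtx = indir / "matrix.mtx"
        X = sparse.csr_matrix(spio.mmread(mtx).T)  # back to cells x genes
        barcodes = (indir / "barcodes.tsv").read_text().split()
        features = (indir / "features.tsv").read_text().split()
        adata = ad.AnnData(
            X=np.asarray(X.todense(), dtype=np.int64),
            obs=pd.DataFrame(index=barcodes),
            var=pd.DataFrame(index=features),
        )
    meta_path = indir / "cell_metadata.csv"
    if meta_path.exists():
        meta = pd.read_csv(meta_path, index_col="barcode")
        adata.obs = adata.obs.join(meta)
    return adata


def write_image(image: np.ndarray, path: str | Path,
                truth: pd.DataFrame | None = None) -> Path:
    """Write a (channels, H, W) stack as multi-page TIFF (+ truth CSV)."""
    path = Path(path)
    path.parent.mkdir(parents=True, exist_ok=True)
    tifffile.imwrite(path, image)
    if truth is not None:
        truth.to_csv(path.with_suffix(".truth.csv"), index=False)
    return path


def read_image(path: str | Path) -> np.ndarray:
    """Read a multi-page/multi-channel TIFF into a (channels, H, W) array."""
    arr = tifffile.imread(path)
    if arr.ndim == 2:
        arr = arr[None]
    return arr
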