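"""Reading, writing and preprocessing of spatial transcriptomics inputs.

A :class:`SpatialDataset` pairs a spots-by-genes expression matrix with 2-D
spatial coordinates, keeping both row-aligned.  Accepted on-disk forms are
AnnData ``.h5ad`` (coordinates in ``obsm['spatial']``), a 10x-style
MatrixMarket directory, and a CSV pair (expression + coordinates).

Preprocessing follows the standard pipeline preceding graph construction:
total-count normalization to a target sum, log1p, and dispersion-ranked
selection of highly variable genes.
"""

from __future__ import annotations

import os
import warnings
from dataclasses import dataclass, field, replace

import anndata as ad
import numpy as np
import pandas as pd
import scanpy as sc
import scipy.sparse as sp
from scipy.io import mmread, mmwrite

__all__ = [
    "SpatialDataset",
    "read_spatial_dataset",
    "write_spatial_dataset",
    "normalize_expression",
    "select_hvg",
]

DEFAULT_TARGET_SUM = 1e4
DEFAULT_N_HVG = 3000


@dataclass
class SpatialDataset:
    """Expression matrix + spatial coordinates, row-aligned.

    ``expression`` is spots x genes (dense ndarray or CSR); ``coords`` holds
    the platform's physical x/y per spot.  ``is_normalized`` / ``is_log1p``
    record preprocessing state and guard against double normalization.
    """

    expression: np.ndarray | sp.csr_matrix
    coords: np.ndarray
    spot_ids: np.ndarray
    gene_ids: np.ndarray
    is_normalized: bool = False
    is_log1p: bool = False

    def __post_init__(self):
        self.coords = np.asarray(self.coords, dtype=float)
        self.spot_ids = np.asarray(self.spot_ids, dtype=object)
        self.gene_ids = np.asarray(self.gene_ids, dtype=object)
        if sp.issparse(self.expression):
            self.expression = sp.csr_matrix(self.expression)
        else:
            self.expression = np.asarray(self.expression, dtype=float)
        n, g = self.expression.shape
        if self.coords.shape != (n, 2):
            raise ValueError(
                f"coords shape {self.coords.shape} does not match {n} spots"
            )
        if len(self.spot_ids) != n or len(self.gene_ids) != g:
            raise ValueError("id lists do not match matrix shape")
        if len(set(self.spot_ids)) != n:
            raise ValueError("spot_ids not unique")
        if len(set(self.gene_ids)) != g:
            raise ValueError("gene_ids not unique")
        if not self.is_normalized and self._min() < 0:
            raise ValueError("raw expression must be non-negative")

    def _min(self) -> float:
        X = self.expression
        return float(X.data.min()) if sp.issparse(X) and X.nnz else float(np.min(X)) if not sp.issparse(X) else 0.0

    @property
    def n_spots(self) -> int:
        return self.expression.shape[0]

    @property
    def n_genes(self) -> int:
        return self.expression.shape[1]

    def dense(self) -> np.ndarray:
        X = self.expression
        return X.toarray() if sp.issparse(X) else X

    def to_anndata(self) -> ad.AnnData:
        adata = ad.AnnData(
            X=self.expression.copy(),
            obs=pd.DataFrame(index=pd.Index(self.spot_ids.astype(str), name="spot_id")),
            var=pd.DataFrame(index=pd.Index(self.gene_ids.astype(str), name="gene_id")),
        )
        adata.obsm["spatial"] = self.coords.copy()
        return adata


def _from_anndata(adata: ad.AnnData) -> SpatialDataset:
    if "spatial" not in adata.obsm:
        raise ValueError("no spatial information: obsm['spatial'] missing")
    X = adata.X
    X = sp.csr_matrix(X) if sp.issparse(X) else np.asarray(X, dtype=float)
    return SpatialDataset(
        expression=X,
        coords=np.asarray(adata.obsm["spatial"], dtype=float)[:, :2],
        spot_ids=adata.obs_names.to_numpy(),
        gene_ids=adata.var_names.to_numpy(),
    )


def _find(dirpath, candidates):
    for name in candidates:
        p = os.path.join(dirpath, name)
        if os.path.exists(p):
            return p
    return None


def _align_coords(spot_ids, coord_df: pd.DataFrame) -> np.ndarray:
    """Reorder an id-indexed (x, y) table to match ``spot_ids``; strict both ways."""
    ids = [str(s) for s in spot_ids]
    missing = [s for s in ids if s not in coord_df.index]
    if missing:
        raise ValueError(
            f"alignment error: spot id {missing[0]!r} has no coordinates "
            f"({len(missing)} missing in total)"
        )
    extra = coord_df.index.difference(pd.Index(ids))
    if len(extra):
        raise ValueError(
            f"alignment error: coordinate id {extra[0]!r} absent from expression"
        )
    return coord_df.loc[ids, ["x", "y"]].to_numpy(dtype=float)


def read_spatial_dataset(path, fmt: str) -> SpatialDataset:
    """Load expression + coordinates into a :class:`SpatialDataset`.

    Parameters
    ----------
    path
        For ``h5ad``: the file.  For ``mtx_dir``: a 10x-convention directory
        (``matrix.mtx``, ``features.tsv``/``genes.tsv``, ``barcodes.tsv``)
        with a ``coords.csv`` or ``tissue_positions.csv`` (columns id,x,y).
        For ``csv_pair``: a directory containing ``expression.csv`` (spots x
        genes, first column = spot id) and ``coords.csv`` (id,x,y), or an
        (expression_csv, coords_csv) pair of paths.
    fmt
        One of ``h5ad``, ``mtx_dir``, ``csv_pair``.
    """
    if fmt == "h5ad":
        return _from_anndata(ad.read_h5ad(path))

    if fmt == "mtx_dir":
        mtx = _find(path, ["matrix.mtx", "matrix.mtx.gz"])
        feats = _find(path, ["features.tsv", "genes.tsv", "features.tsv.gz", "genes.tsv.gz"])
        bars = _find(path, ["barcodes.tsv", "barcodes.tsv.gz"])
        if mtx is None or feats is None or bars is None:
            raise FileNotFoundError("mtx_dir needs matrix.mtx, features/genes and barcodes files")
        X = sp.csr_matrix(mmread(mtx)).T  # 10x stores genes x cells
        gene_ids = pd.read_csv(feats, sep="\t", header=None).iloc[:, 0].astype(str).to_numpy()
        spot_ids = pd.read_csv(bars, sep="\t", header=None).iloc[:, 0].astype(str).to_numpy()
        cpath = _find(path, ["coords.csv", "tissue_positions.csv"])
        if cpath is None:
            raise ValueError("no spatial information: coords.csv / tissue_positions.csv missing")
        cdf = pd.read_csv(cpath, index_col=0)
        cdf = cdf.iloc[:, :2]
        cdf.columns = ["x", "y"]
        cdf.index = cdf.index.astype(str)
        coords = _align_coords(spot_ids, cdf)
        return SpatialDataset(X, coords, spot_ids, gene_ids)

    if fmt == "csv_pair":
        if isinstance(path, (tuple, list)):
            expr_path, coord_path = path
        else:
            expr_path = os.path.join(path, "expression.csv")
            coord_path = os.path.join(path, "coords.csv")
        if not os.path.exists(expr_path):
            raise FileNotFoundError(expr_path)
        if not os.path.exists(coord_path):
            raise ValueError("no spatial information: coordinates file missing")
        edf = pd.read_csv(expr_path, index_col=0)
        cdf = pd.read_csv(coord_path, index_col=0)
        cdf.columns = ["x", "y"]
        cdf.index = cdf.index.astype(str)
        coords = _align_coords(edf.index.astype(str), cdf)
        return SpatialDataset(
            edf.to_numpy(dtype=float),
            coords,
            edf.index.to_numpy(),
            edf.columns.to_numpy(),
        )

    raise ValueError(f"unknown format {fmt!r}")


def write_spatial_dataset(ds: SpatialDataset, path, fmt: str = "csv_pair") -> None:
    """Write a dataset in a form :func:`read_spatial_dataset` round-trips."""
    if fmt == "h5ad":
        ds.to_anndata().write_h5ad(path)
        return
    if fmt == "csv_pair":
        os.makedirs(path, exist_ok=True)
        pd.DataFrame(ds.dense(), index=ds.spot_ids.astype(str), columns=ds.gene_ids.astype(str)).to_csv(
            os.path.join(path, "expression.csv")
        )
        pd.DataFrame(
            {"x": ds.coords[:, 0], "y": ds.coords[:, 1]},
            index=pd.Index(ds.spot_ids.astype(str), name="id"),
        ).to_csv(os.path.join(path, "coords.csv"))
        return
    if fmt == "mtx_dir":
        os.makedirs(path, exist_ok=True)
        mmwrite(os.path.join(path, "matrix.mtx"), sp.coo_matrix(ds.expression).T)
        pd.Series(ds.gene_ids.astype(str)).to_csv(
            os.path.join(path, "features.tsv"), sep="\t", index=False, header=False
        )
        pd.Series(ds.spot_ids.astype(str)).to_csv(
            os.path.join(path, "barcodes.tsv"), sep="\t", index=False, header=False
        )
        pd.DataFrame(
            {"x": ds.coords[:, 0], "y": ds.coords[:, 1]},
            index=pd.Index(ds.spot_ids.astype(str), name="id"),
        ).to_csv(os.path.join(path, "coords.csv"))
        return
    raise ValueError(f"unknown format {fmt!r}")


def normalize_expression(
    ds: SpatialDataset,
    target_sum: float = DEFAULT_TARGET_SUM,
    apply_log1p: bool = True,
) -> SpatialDataset:
    """Scale each spot's counts to ``target_sum``, then optionally log1p.

    All-zero spots are left as zero rows (warned about, never dropped: removing
    spots would change the spatial graph topology downstream).  Re-normalizing
    an already-normalized dataset raises.
    """
    if ds.is_normalized:
        raise ValueError("dataset already normalized; refusing to rescale twice")
    if target_sum <= 0:
        raise ValueError("target_sum must be positive")
    adata = ds.to_anndata()
    rowsum = np.ravel(adata.X.sum(axis=1))
    n_zero = int((rowsum == 0).sum())
    if n_zero:
        warnings.warn(f"{n_zero} spot(s) have zero total counts; left as zero rows")
    with warnings.catch_warnings():
        warnings.simplefilter("ignore", UserWarning)
        sc.pp.normalize_total(adata, target_sum=target_sum)
        if apply_log1p:
            sc.pp.log1p(adata)
    X = adata.X
    X = sp.csr_matrix(X) if sp.issparse(X) else np.asarray(X, dtype=float)
    return replace(ds, expression=X, is_normalized=True, is_log1p=apply_log1p)


def _dispersion(X) -> np.ndarray:
    """Per-gene dispersion var/mean; degenerate genes (zero mean/var) score 0."""
    if sp.issparse(X):
        mean = np.ravel(X.mean(axis=0))
        sq = np.ravel(X.multiply(X).mean(axis=0))
        var = sq - mean**2
    else:
        mean = X.mean(axis=0)
        var = X.var(axis=0)
    with np.errstate(divide="ignore", invalid="ignore"):
        disp = np.where(mean > 0, var / np.maximum(mean, 1e-300), 0.0)
    disp[var <= 0] = 0.0
    return disp


def select_hvg(ds: SpatialDataset, n_top: int = DEFAULT_N_HVG) -> SpatialDataset:
    """Keep the ``n_top`` most variable genes by dispersion (var/mean) ranking.

    Gene order of the original matrix is preserved; ties break toward the
    earlier gene.  Requires a normalized dataset.
    """
    if not ds.is_normalized:
        raise ValueError("select_hvg expects a normalized dataset")
    if n_top > ds.n_genes:
        raise ValueError(f"n_top={n_top} exceeds n_genes={ds.n_genes}")
    disp = _dispersion(ds.expression)
    order = np.argsort(-disp, kind="stable")[:n_top]
    keep = np.zeros(ds.n_genes, dtype=bool)
    keep[order] = True
    X = ds.expression[:, keep]
    return replace(ds, expression=X, gene_ids=ds.gene_ids[keep])
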