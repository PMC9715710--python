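"""Reading and writing cell-by-gene matrices.

Supported formats, chosen by path shape:

* a directory containing ``matrix.mtx`` + ``barcodes.tsv`` + ``features.tsv``
  (the 10x-style triplet; the matrix is stored features x barcodes and
  transposed on read);
* ``.csv`` / ``.tsv``: dense cells x genes with a header row of gene ids and
  an index column of cell ids;
* ``.h5ad``: the AnnData container.
"""

from __future__ import annotations

from pathlib import Path

import anndata
import numpy as np
import pandas as pd
import scipy.sparse as sp
from anndata import AnnData
from scipy.io import mmread, mmwrite


def read_dataset(path) -> AnnData:
    path = Path(path)
    if path.is_dir():
        mtx = path / "matrix.mtx"
        if not mtx.exists():
            raise FileNotFoundError(f"no matrix.mtx in {path}")
        M = sp.csr_matrix(mmread(mtx).T)
        barcodes = pd.read_csv(path / "barcodes.tsv", header=None, sep="\t")[0]
        features = pd.read_csv(path / "features.tsv", header=None, sep="\t")[0]
        ad = AnnData(X=M, obs=pd.DataFrame(index=barcodes.astype(str)),
                     var=pd.DataFrame(index=features.astype(str)))
        for side in ("obs", "var"):
            meta = path / f"{side}.csv"
            if meta.exists():
                df = pd.read_csv(meta, index_col=0)
                getattr(ad, side)[df.columns] = df.values
        return ad
    if path.suffix == ".h5ad":
        return anndata.read_h5ad(path)
    if path.suffix in (".csv", ".tsv"):
        sep = "," if path.suffix == ".csv" else "\t"
        df = pd.read_csv(path, index_col=0, sep=sep)
        return AnnData(X=df.to_numpy(dtype=np.float64),
                       obs=pd.DataFrame(index=df.index.astype(str)),
                       var=pd.DataFrame(index=df.columns.astype(str)))
    raise ValueError(f"unrecognized dataset path: {path}")


def write_dataset(adata: AnnData, path, fmt: str | None = None) -> None:
    path = Path(path)
    fmt = fmt or ("h5ad" if path.suffix == ".h5ad" else
                  "csv" if path.suffix == ".csv" else
                  "tsv" if path.suffix == ".tsv" else "mtx")
    if fmt == "h5ad":
        adata.write_h5ad(path)
        return
    X = adata.X
    dense = np.asarray(X.todense()) if sp.issparse(X) else np.asarray(X)
    if fmt in ("csv", "tsv"):
        pd.DataFrame(dense, index=adata.obs_names, columns=adata.var_names).to_csv(
            path, sep="," if fmt == "csv" else "\t"
        )
        return
    path.mkdir(parents=True, exist_ok=True)
    mmwrite(str(path / "matrix.mtx"), sp.coo_matrix(dense.T))
    pd.Series(adata.obs_names).to_csv(path / "barcodes.tsv", index=False, header=False)
    pd.Series(adata.var_names).to_csv(path / "features.tsv", index=False, header=False)
    if len(adata.obs.columns):
        adata.obs.to_csv(path / "obs.csv")
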