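"""Preprocessing: from raw count matrices to the model's scaled HVG inputs.

The pipeline mirrors the standard single-cell recipe and is applied per
dataset, in a fixed order:

1. filter cells with fewer than ``min_genes_per_cell`` expressed genes, then
   genes expressed in fewer than ``min_cells_per_gene`` cells;
2. normalize total counts per cell (default target: median of per-cell sums);
3. ``log1p`` transform;
4. select highly variable genes (HVGs) — a *common* set scored jointly across
   both datasets on their gene-id intersection, plus a *specific* set per
   dataset;
5. scale every gene to [0, 1] by its maximum absolute value, per dataset.

Datasets are carried as :class:`anndata.AnnData` (cells x genes). Scanpy does
the standard steps; the HVG dispersion statistic is implemented here so that
its exact binning rules are documented and testable (see docs/methods.md).
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
import scanpy as sc
import scipy.sparse as sp
from anndata import AnnData
from sklearn.decomposition import TruncatedSVD


def _dense(X) -> np.ndarray:
    return np.asarray(X.todense()) if sp.issparse(X) else np.asarray(X)


def validate_dataset(adata: AnnData, name: str = "dataset") -> None:
    """Check the container invariants: finite non-negative matrix, unique ids."""
    X = _dense(adata.X)
    if not np.all(np.isfinite(X)):
        raise ValueError(f"{name}: matrix contains non-finite entries")
    if X.min() < 0:
        raise ValueError(f"{name}: matrix contains negative entries")
    if adata.obs_names.duplicated().any():
        raise ValueError(f"{name}: duplicate cell ids")
    if adata.var_names.duplicated().any():
        raise ValueError(f"{name}: duplicate gene ids")


def filter_cells_genes(
    adata: AnnData,
    min_genes_per_cell: int = 200,
    min_cells_per_gene: int = 3,
) -> AnnData:
    """Drop cells with fewer than ``min_genes_per_cell`` expressed genes, then
    genes expressed in fewer than ``min_cells_per_gene`` surviving cells.

    Strict "fewer than" semantics; the gene filter runs after the cell filter;
    survivor order is preserved.
    """
    if min_genes_per_cell < 0 or min_cells_per_gene < 0:
        raise ValueError("filter thresholds must be >= 0")
    out = adata.copy()
    if min_genes_per_cell > 0:
        sc.pp.filter_cells(out, min_genes=min_genes_per_cell)
    if out.n_obs == 0:
        raise ValueError("all cells filtered out")
    if min_cells_per_gene > 0:
        sc.pp.filter_genes(out, min_cells=min_cells_per_gene)
    if out.n_vars == 0:
        raise ValueError("all genes filtered out")
    return out


def normalize_total(adata: AnnData, target_sum: float | None = None) -> AnnData:
    """Scale each cell so its counts sum to ``target_sum``.

    ``target_sum=None`` uses the median of the pre-normalization per-cell
    totals. All-zero cells are left untouched.
    """
    X = _dense(adata.X)
    if X.min() < 0:
        raise ValueError("normalize_total requires non-negative input")
    out = adata.copy()
    sc.pp.normalize_total(out, target_sum=target_sum)
    return out


def log1p(adata: AnnData) -> AnnData:
    """Elementwise natural log of (value + 1)."""
    out = adata.copy()
    sc.pp.log1p(out)
    out.uns.pop("log1p", None)
    return out


def dispersion_scores(X: np.ndarray | sp.spmatrix, n_bins: int | None = None) -> np.ndarray:
    """Mean-binned normalized dispersion of log-normalized expression.

    Genes are scored on the de-logged values (``expm1``): dispersion is
    variance/mean, log-transformed, then z-scored within quantile bins of the
    log mean so that variability is judged relative to genes of similar
    abundance. Bins with fewer than two genes, or zero spread, contribute a
    normalized dispersion of 0. Genes with zero variance score ``-inf`` and are
    never selected.

    Returns one score per gene (higher = more variable).
    """
    E = np.expm1(_dense(X).astype(np.float64))
    mean = E.mean(axis=0)
    var = E.var(axis=0, ddof=1) if E.shape[0] > 1 else np.zeros(E.shape[1])
    with np.errstate(divide="ignore", invalid="ignore"):
        disp = np.where(mean > 0, var / mean, 0.0)
    log_mean = np.log1p(mean)
    with np.errstate(divide="ignore"):
        log_disp = np.where(disp > 0, np.log(disp), -np.inf)

    n_genes = len(mean)
    if n_bins is None:
        n_bins = min(20, max(1, n_genes // 5))
    bins = pd.qcut(log_mean, q=n_bins, duplicates="drop", labels=False)
    bins = np.asarray(bins)

    scores = np.full(n_genes, -np.inf)
    for b in np.unique(bins):
        idx = np.where(bins == b)[0]
        vals = log_disp[idx]
        ok = np.isfinite(vals)
        if ok.sum() >= 2:
            mu, sd = vals[ok].mean(), vals[ok].std(ddof=1)
        else:
            mu, sd = 0.0, 0.0
        for i, v in zip(idx, vals):
            if not np.isfinite(v):
                scores[i] = -np.inf
            elif sd > 0:
                scores[i] = (v - mu) / sd
            else:
                scores[i] = 0.0
    return scores


def _ranked_genes(scores: np.ndarray, genes: pd.Index) -> list[str]:
    """Genes sorted by decreasing score, ties broken by gene id."""
    order = sorted(range(len(genes)), key=lambda i: (-scores[i], genes[i]))
    return [genes[i] for i in order if np.isfinite(scores[i])]


def select_hvg(
    adata: AnnData,
    n_top: int = 2000,
    shared_with: AnnData | None = None,
) -> list[str]:
    """Select the ``n_top`` most variable genes by normalized dispersion.

    With ``shared_with``, candidates are restricted to the gene-id
    intersection, the dispersion statistic is computed independently in both
    datasets, and genes are ranked by the sum of their per-dataset ranks
    (ties broken lexicographically by gene id). Genes with zero variance in
    either dataset are excluded. Expects log-normalized input.
    """
    if n_top < 1:
        raise ValueError("n_top must be >= 1")
    if shared_with is None:
        candidates = adata.var_names
        if len(candidates) == 0:
            raise ValueError("no candidate genes")
        ranked = _ranked_genes(dispersion_scores(adata.X), candidates)
    else:
        candidates = adata.var_names.intersection(shared_with.var_names)
        if len(candidates) == 0:
            raise ValueError("no candidate genes in the intersection")
        candidates = pd.Index(sorted(candidates))
        rank_sum: dict[str, float] = {g: 0.0 for g in candidates}
        finite: dict[str, bool] = {g: True for g in candidates}
        for ds in (adata, shared_with):
            scores = dispersion_scores(ds[:, candidates].X)
            order = _ranked_genes(scores, candidates)
            for r, g in enumerate(order):
                rank_sum[g] += r
            kept = set(order)
            for g in candidates:
                if g not in kept:
                    finite[g] = False
        ranked = sorted(
            (g for g in candidates if finite[g]), key=lambda g: (rank_sum[g], g)
        )
    if len(ranked) < n_top:
        warnings.warn(
            f"only {len(ranked)} variable genes available (< n_top={n_top}); "
            "returning all of them"
        )
        return ranked
    return ranked[:n_top]


def maxabs_scale(adata: AnnData) -> AnnData:
    """Scale each gene to [0, 1] by its maximum value; zero columns unchanged."""
    X = _dense(adata.X).astype(np.float64)
    if X.min() < 0:
        raise ValueError("maxabs_scale expects non-negative input")
    colmax = X.max(axis=0)
    colmax[colmax == 0] = 1.0
    out = adata.copy()
    out.X = X / colmax
    return out


def tfidf_lsi(adata: AnnData, n_components: int = 50) -> np.ndarray:
    """TF-IDF weighting followed by truncated SVD, for peak-level data.

    Term frequency is per cell (row-normalized); the inverse document
    frequency of peak j with document frequency df_j over n cells is
    ``log(1 + n / (1 + df_j))``. Dialects of this transform differ; this one
    is fixed so results are reproducible. Utility for external
    dimensionality-reduction workflows; not on the default training path.
    """
    X = _dense(adata.X).astype(np.float64)
    n, p = X.shape
    if n_components >= min(n, p):
        raise ValueError(f"n_components={n_components} must be < min(n_cells, n_peaks)={min(n, p)}")
    rowsum = X.sum(axis=1, keepdims=True)
    rowsum[rowsum == 0] = 1.0
    tf = X / rowsum
    df = (X > 0).sum(axis=0)
    idf = np.log(1.0 + n / (1.0 + df))
    tfidf = tf * idf
    svd = TruncatedSVD(n_components=n_components, algorithm="arpack")
    return svd.fit_transform(tfidf)


@dataclass
class GenePartition:
    """Scaled model inputs for a pair of datasets.

    ``common`` maps dataset id -> cells x k matrix over ``common_genes`` (same
    column order for both datasets); ``specific`` maps dataset id -> cells x
    k_id matrix over that dataset's own ``specific_genes``.
    """

    dataset_ids: tuple[str, str]
    common_genes: list[str]
    specific_genes: dict[str, list[str]]
    common: dict[str, np.ndarray]
    specific: dict[str, np.ndarray]
    cell_ids: dict[str, list[str]] = field(default_factory=dict)
    cell_types: dict[str, np.ndarray | None] = field(default_factory=dict)

    @property
    def n_common(self) -> int:
        return len(self.common_genes)

    def n_cells(self, ds: str) -> int:
        return self.common[ds].shape[0]

    def __post_init__(self) -> None:
        a, b = self.dataset_ids
        if self.common[a].shape[1] != self.n_common or self.common[b].shape[1] != self.n_common:
            raise ValueError("common matrix width does not match common gene list")
        for ds in self.dataset_ids:
            if self.specific[ds].shape[1] != len(self.specific_genes[ds]):
                raise ValueError(f"specific matrix width mismatch for {ds!r}")
            for M in (self.common[ds], self.specific[ds]):
                if M.size and (M.min() < 0 or M.max() > 1):
                    raise ValueError("partition matrices must be scaled to [0, 1]")


def preprocess_pair(
    adata_x: AnnData,
    adata_y: AnnData,
    dataset_ids: tuple[str, str] = ("x", "y"),
    min_genes_per_cell: int = 200,
    min_cells_per_gene: int = 3,
    n_common_hvg: int = 2000,
    n_specific_hvg: int = 2000,
    target_sum: float | None = None,
    cell_type_key: str = "cell_type",
) -> GenePartition:
    """Run the full pipeline on a dataset pair and return the model inputs."""
    processed = []
    for ds, name in ((adata_x, dataset_ids[0]), (adata_y, dataset_ids[1])):
        validate_dataset(ds, name)
        out = filter_cells_genes(ds, min_genes_per_cell, min_cells_per_gene)
        out = log1p(normalize_total(out, target_sum))
        processed.append(out)
    px, py = processed

    common_genes = select_hvg(px, n_common_hvg, shared_with=py)
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        specific_genes = {
            dataset_ids[0]: select_hvg(px, n_specific_hvg),
            dataset_ids[1]: select_hvg(py, n_specific_hvg),
        }

    common, specific, cell_ids, cell_types = {}, {}, {}, {}
    for ds, name in ((px, dataset_ids[0]), (py, dataset_ids[1])):
        common[name] = _dense(maxabs_scale(ds[:, common_genes]).X).astype(np.float32)
        specific[name] = _dense(maxabs_scale(ds[:, specific_genes[name]]).X).astype(np.float32)
        cell_ids[name] = list(ds.obs_names)
        cell_types[name] = (
            ds.obs[cell_type_key].to_numpy() if cell_type_key in ds.obs else None
        )
    return GenePartition(
        dataset_ids=dataset_ids,
        common_genes=common_genes,
        specific_genes=specific_genes,
        common=common,
        specific=specific,
        cell_ids=cell_ids,
        cell_types=cell_types,
    )
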