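"""Synthetic two-modality single-cell data with known ground truth.

The generator emulates the situation the integration model is built for: two
modalities measuring overlapping cell populations through a shared set of
*common* genes plus disjoint modality-*specific* genes, with one modality
distorted by a batch effect. The generative model is

* per-cell-type latent centroids in R^latent_dim, cells scattered around
  their centroid with isotropic Gaussian noise;
* non-negative factor loadings mapping the latent state to per-gene log
  rates through an exp link with per-gene baselines;
* modality y additionally distorted: a per-gene additive log-rate shift
  (the batch effect) and a monotone gain compression of the latent
  activation, both controlled by ``batch_effect_scale`` (0 = identical
  measurement processes);
* observed counts ~ Poisson(rate), thinned by Bernoulli dropout.

When ``paired`` the same latent draws generate both modalities in aligned
row order, giving known cell-to-cell correspondence (for FOSCTTM). Removing
cell types from one modality produces the unbalanced scenarios. The returned
ground truth carries latents, labels, loadings and rates, sufficient to score
integration, imputation and deconvolution without any external data.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from anndata import AnnData

#: spread of cell-type centroids in latent space; together with WITHIN_NOISE
#: this sets cluster separation comparable to well-resolved scRNA cell types
CENTROID_SCALE = 1.5
#: within-cell-type latent standard deviation
WITHIN_NOISE = 0.35
#: scale of the factor loadings; sets per-gene log-rate spread (~1.5) so that
#: biological variance dominates Poisson noise, as for real top HVGs
LOADING_SCALE = 1.5
#: per-gene baseline log rates, uniform on [log BASE_LO, log BASE_HI]; deep
#: full-length-protocol coverage (tens of thousands of counts per cell over
#: ~450 genes) so that for typical genes biological variance clearly
#: dominates Poisson sampling noise
BASE_LO, BASE_HI = 10.0, 100.0
#: gain compression applied to modality y's activation per unit of
#: batch_effect_scale (monotone distortion)
GAIN_PER_SCALE = 0.5


@dataclass
class SimConfig:
    n_cells: int = 600
    n_celltypes: int = 3
    latent_dim: int = 10
    n_common_genes: int = 300
    n_specific_genes: int = 150
    batch_effect_scale: float = 0.5
    dropout_rate: float = 0.3
    removed_celltypes_x: tuple = ()
    removed_celltypes_y: tuple = ()
    paired: bool = False
    seed: int = 0

    def __post_init__(self):
        types = {f"type{t}" for t in range(self.n_celltypes)}
        for removed in (self.removed_celltypes_x, self.removed_celltypes_y):
            if not set(removed) <= types:
                raise ValueError(f"removed cell types {removed} not a subset of {sorted(types)}")
        if not 0 <= self.dropout_rate < 1:
            raise ValueError("dropout_rate must be in [0, 1)")
        if self.n_cells < 1 or self.n_celltypes < 1 or self.latent_dim < 1:
            raise ValueError("sizes must be positive")


@dataclass
class GroundTruth:
    config: SimConfig
    centroids: np.ndarray
    latents: dict[str, np.ndarray]
    labels: dict[str, np.ndarray]
    loadings_common: np.ndarray
    loadings_specific: dict[str, np.ndarray]
    baseline_common: np.ndarray
    baseline_specific: dict[str, np.ndarray]
    batch_shift_common: np.ndarray
    batch_shift_specific: np.ndarray
    gain_y: float
    paired: bool
    extras: dict = field(default_factory=dict)


def _loadings(rng: np.random.Generator, latent_dim: int, n_genes: int) -> np.ndarray:
    W = np.abs(rng.normal(0.0, 1.0, size=(latent_dim, n_genes)))
    return LOADING_SCALE * W / np.sqrt(latent_dim)


def _rates(u: np.ndarray, W: np.ndarray, baseline: np.ndarray,
           shift: np.ndarray | None = None, gain: float = 1.0) -> np.ndarray:
    act = gain * (u @ W)
    log_rate = baseline + act if shift is None else baseline + shift + act
    return np.exp(np.clip(log_rate, -30.0, 8.0))


def _observe(rng: np.random.Generator, rate: np.ndarray, dropout: float) -> np.ndarray:
    counts = rng.poisson(rate).astype(np.float64)
    if dropout > 0:
        counts *= rng.random(rate.shape) >= dropout
    return counts


def simulate(config: SimConfig) -> tuple[AnnData, AnnData, GroundTruth]:
    """Generate the two modalities and their ground truth."""
    cfg = config
    rng = np.random.default_rng(cfg.seed)
    K, T = cfg.latent_dim, cfg.n_celltypes
    type_names = np.array([f"type{t}" for t in range(T)])

    centroids = rng.normal(0.0, CENTROID_SCALE, size=(T, K))
    Wc = _loadings(rng, K, cfg.n_common_genes)
    Wsx = _loadings(rng, K, cfg.n_specific_genes)
    Wsy = _loadings(rng, K, cfg.n_specific_genes)
    base_c = rng.uniform(np.log(BASE_LO), np.log(BASE_HI), cfg.n_common_genes)
    base_sx = rng.uniform(np.log(BASE_LO), np.log(BASE_HI), cfg.n_specific_genes)
    base_sy = rng.uniform(np.log(BASE_LO), np.log(BASE_HI), cfg.n_specific_genes)
    shift_c = cfg.batch_effect_scale * rng.normal(0.0, 1.0, cfg.n_common_genes)
    shift_sy = cfg.batch_effect_scale * rng.normal(0.0, 1.0, cfg.n_specific_genes)
    gain_y = 1.0 / (1.0 + GAIN_PER_SCALE * cfg.batch_effect_scale)

    lab_x = rng.integers(0, T, size=cfg.n_cells)
    u_x = centroids[lab_x] + WITHIN_NOISE * rng.normal(size=(cfg.n_cells, K))
    if cfg.paired:
        lab_y, u_y = lab_x.copy(), u_x.copy()
    else:
        lab_y = rng.integers(0, T, size=cfg.n_cells)
        u_y = centroids[lab_y] + WITHIN_NOISE * rng.normal(size=(cfg.n_cells, K))

    keep_x = ~np.isin(type_names[lab_x], cfg.removed_celltypes_x)
    keep_y = ~np.isin(type_names[lab_y], cfg.removed_celltypes_y)
    lab_x, u_x = lab_x[keep_x], u_x[keep_x]
    lab_y, u_y = lab_y[keep_y], u_y[keep_y]

    rate_xc = _rates(u_x, Wc, base_c)
    rate_xs = _rates(u_x, Wsx, base_sx)
    rate_yc = _rates(u_y, Wc, base_c, shift_c, gain_y)
    rate_ys = _rates(u_y, Wsy, base_sy, shift_sy, gain_y)

    Xc = _observe(rng, rate_xc, cfg.dropout_rate)
    Xs = _observe(rng, rate_xs, cfg.dropout_rate)
    Yc = _observe(rng, rate_yc, cfg.dropout_rate)
    Ys = _observe(rng, rate_ys, cfg.dropout_rate)

    common_names = [f"gc{i:04d}" for i in range(cfg.n_common_genes)]
    adata_x = _assemble("x", Xc, Xs, common_names,
                        [f"gx{i:04d}" for i in range(cfg.n_specific_genes)],
                        type_names[lab_x])
    adata_y = _assemble("y", Yc, Ys, common_names,
                        [f"gy{i:04d}" for i in range(cfg.n_specific_genes)],
                        type_names[lab_y])

    gt = GroundTruth(
        config=cfg, centroids=centroids,
        latents={"x": u_x, "y": u_y},
        labels={"x": type_names[lab_x], "y": type_names[lab_y]},
        loadings_common=Wc,
        loadings_specific={"x": Wsx, "y": Wsy},
        baseline_common=base_c,
        baseline_specific={"x": base_sx, "y": base_sy},
        batch_shift_common=shift_c,
        batch_shift_specific=shift_sy,
        gain_y=gain_y, paired=cfg.paired,
        extras={"rates": {"xc": rate_xc, "xs": rate_xs, "yc": rate_yc, "ys": rate_ys}},
    )
    return adata_x, adata_y, gt


def _assemble(ds_id, Mc, Ms, common_names, specific_names, labels) -> AnnData:
    X = np.hstack([Mc, Ms])
    n = X.shape[0]
    ad = AnnData(
        X=X,
        obs=pd.DataFrame(
            {"dataset_id": ds_id, "cell_type": labels},
            index=[f"{ds_id}_cell{i:05d}" for i in range(n)],
        ),
        var=pd.DataFrame(
            {"gene_block": ["common"] * len(common_names) + ["specific"] * len(specific_names)},
            index=list(common_names) + list(specific_names),
        ),
    )
    return ad


def cross_specific_rates(gt: GroundTruth, source: str = "x", target: str = "y",
                         normalize: bool = False) -> np.ndarray:
    """Noiseless expected rates of the *target* modality's specific genes for
    the *source* modality's cells — the ground truth for cross-modality
    imputation (the source never observes these genes).

    With ``normalize=True`` rates are divided by each cell's total expected
    counts over the target's full gene panel (common + specific), matching
    the library-size normalization applied during preprocessing: models
    trained on normalized data predict *relative*, not absolute, expression.
    """
    u = gt.latents[source]
    W = gt.loadings_specific[target]
    base = gt.baseline_specific[target]
    if target == "y":
        rates = _rates(u, W, base, gt.batch_shift_specific, gt.gain_y)
        common = _rates(u, gt.loadings_common, gt.baseline_common,
                        gt.batch_shift_common, gt.gain_y)
    else:
        rates = _rates(u, W, base)
        common = _rates(u, gt.loadings_common, gt.baseline_common)
    if normalize:
        rates = rates / (rates.sum(1) + common.sum(1))[:, None]
    return rates


def simulate_spots(
    config: SimConfig,
    cells_per_spot_range: tuple[int, int] = (1, 10),
    n_spots: int = 150,
) -> tuple[AnnData, pd.DataFrame, AnnData, GroundTruth]:
    """Build synthetic spatial spots as sums of modality-x cell profiles.

    Each spot pools a uniformly drawn number of cells (inclusive range) from
    the modality-x dataset of :func:`simulate`; the true cell-type proportions
    of every spot are recorded. Returns (spots, true proportions, the source
    single-cell dataset, its ground truth).
    """
    adata_x, _, gt = simulate(config)
    rng = np.random.default_rng(config.seed + 1)
    lo, hi = cells_per_spot_range
    if lo < 1 or hi < lo:
        raise ValueError("invalid cells_per_spot_range")
    X = np.asarray(adata_x.X)
    labels = adata_x.obs["cell_type"].to_numpy()
    types = sorted(set(labels))
    spots = np.zeros((n_spots, X.shape[1]))
    props = np.zeros((n_spots, len(types)))
    members = []
    for j in range(n_spots):
        k = int(rng.integers(lo, hi + 1))
        idx = rng.choice(X.shape[0], size=k, replace=False)
        members.append(idx)
        spots[j] = X[idx].sum(axis=0)
        for t_i, t in enumerate(types):
            props[j, t_i] = np.mean(labels[idx] == t)
    spot_ids = [f"spot{j:04d}" for j in range(n_spots)]
    adata_spots = AnnData(
        X=spots,
        obs=pd.DataFrame({"dataset_id": "spots"}, index=spot_ids),
        var=adata_x.var.copy(),
    )
    true_props = pd.DataFrame(props, index=spot_ids, columns=types)
    gt.extras["spot_members"] = members
    return adata_spots, true_props, adata_x, gt
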