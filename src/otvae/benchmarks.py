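"""Canonical synthetic-data evaluation experiments.

These functions string the whole pipeline together on generated data with
known ground truth: simulate -> preprocess -> fit -> evaluate. They are used
by the test suite and the reproduction script, and serve as worked examples
of the API. Problem sizes follow the generator defaults (600 cells per
modality, 3 cell types, 300 common + 150 specific genes); training runs
2,000 iterations with a compact encoder (256-64 hidden units), which on one
CPU core takes well under a minute per fit.
"""

from __future__ import annotations

from dataclasses import replace

import numpy as np
from scipy.stats import pearsonr

from .downstream import deconvolute, impute
from .metrics import foscttm, knn_transfer_scores
from .preprocess import preprocess_pair
from .synthdata import SimConfig, cross_specific_rates, simulate, simulate_spots
from .train import TrainConfig, embed, fit

#: training setup for the synthetic benchmarks: a compact encoder and a fixed
#: 2,000-iteration budget (early stopping disabled via a large patience) keep
#: single-CPU runs fast while leaving every other default untouched
BENCH_TRAIN = dict(
    max_iterations=2000,
    hidden_dims=(256, 64),
    patience=10_000,
)


def _bench_config(seed: int, **overrides) -> TrainConfig:
    kw = dict(BENCH_TRAIN)
    kw.update(overrides)
    return TrainConfig(seed=seed, **kw)


def integration_run(
    seed: int,
    paired: bool = False,
    removed_celltypes_x: tuple = (),
    sim_overrides: dict | None = None,
    **train_overrides,
):
    """Simulate a dataset pair, preprocess it, and train the model.

    Returns a dict with the fitted result, embeddings of both modalities,
    the partition and the ground truth.
    """
    sim = SimConfig(seed=seed, paired=paired,
                    removed_celltypes_x=removed_celltypes_x,
                    **(sim_overrides or {}))
    adata_x, adata_y, gt = simulate(sim)
    part = preprocess_pair(adata_x, adata_y, min_genes_per_cell=1,
                           min_cells_per_gene=1)
    res = fit(part, _bench_config(seed, **train_overrides))
    z_x = embed(res.model, part.common["x"])
    z_y = embed(res.model, part.common["y"])
    return {
        "result": res, "partition": part, "ground_truth": gt,
        "z_x": z_x, "z_y": z_y,
        "labels_x": part.cell_types["x"], "labels_y": part.cell_types["y"],
    }


def label_transfer_ari(run, restrict_to: set | None = None) -> float:
    """kNN label-transfer ARI from modality x (reference) to y (query)."""
    lx, ly = run["labels_x"], run["labels_y"]
    zx, zy = run["z_x"], run["z_y"]
    if restrict_to is not None:
        mask = np.isin(ly, sorted(restrict_to))
        zy, ly = zy[mask], ly[mask]
    ari, _, _ = knn_transfer_scores(zx, lx, zy, ly)
    return ari


def paired_foscttm(run) -> float:
    if not run["ground_truth"].paired:
        raise ValueError("FOSCTTM requires a paired run")
    return foscttm(run["z_x"], run["z_y"])


def imputation_experiment(run, holdout_frac: float = 0.2, seed: int = 0) -> dict:
    """Score cross-modality imputation of y-specific genes for x cells.

    A random ``holdout_frac`` of modality-y specific genes is evaluated:
    genes modality x never observes, imputed by decoding x cells through the
    y branches. Per-gene Pearson correlation against the generative truth
    (log relative expression, matching the normalization the model is
    trained on) is compared with a cell-shuffled baseline of the same
    predictions.
    """
    gt = run["ground_truth"]
    part = run["partition"]
    model = run["result"].model
    rng = np.random.default_rng(seed)

    _, ys_hat = impute(model, part.common["x"], "x", "y")
    truth = np.log(cross_specific_rates(gt, source="x", target="y",
                                        normalize=True))
    gene_names = [f"gy{i:04d}" for i in range(truth.shape[1])]
    col_of = {g: i for i, g in enumerate(gene_names)}
    model_genes = part.specific_genes["y"]

    candidates = [j for j, g in enumerate(model_genes) if g in col_of]
    n_hold = max(1, int(round(holdout_frac * len(candidates))))
    held = rng.choice(candidates, size=n_hold, replace=False)
    perm = rng.permutation(ys_hat.shape[0])

    wins, corrs = [], []
    for j in held:
        t = truth[:, col_of[model_genes[j]]]
        if t.std() == 0 or ys_hat[:, j].std() == 0:
            continue
        r = pearsonr(ys_hat[:, j], t)[0]
        r_shuf = pearsonr(ys_hat[perm, j], t)[0]
        corrs.append(r)
        wins.append(r > r_shuf)
    return {
        "fraction_beating_baseline": float(np.mean(wins)),
        "median_correlation": float(np.median(corrs)),
        "n_held_out": len(wins),
    }


def deconvolution_experiment(seed: int, n_spots: int = 150,
                             cells_per_spot_range: tuple[int, int] = (1, 10)) -> dict:
    """Train cells-vs-spots with the global plan and score proportion recovery."""
    sim = SimConfig(seed=seed)
    adata_spots, true_props, adata_x, _ = simulate_spots(
        sim, cells_per_spot_range=cells_per_spot_range, n_spots=n_spots
    )
    part = preprocess_pair(adata_x, adata_spots, dataset_ids=("cells", "spots"),
                           min_genes_per_cell=1, min_cells_per_gene=1)
    # batch sizes proportional to the population sizes: a spot's transport
    # demand then covers several cells' capacity, as its composition requires
    n_cells = adata_x.n_obs
    by = min(64, n_spots)
    bx = min(n_cells, by * max(1, round(n_cells / n_spots)))
    cfg = _bench_config(seed, global_plan=True, batch_size=(bx, by))
    res = fit(part, cfg)
    dec = deconvolute(res.global_plan, part.cell_types["cells"],
                      spot_ids=part.cell_ids["spots"])
    est = dec.proportions.loc[true_props.index, true_props.columns].to_numpy()
    mae = float(np.abs(est - true_props.to_numpy()).mean())
    return {"mae": mae, "result": res, "deconvolution": dec,
            "true_proportions": true_props}


def unbalanced_comparison(seed: int, removed: str = "type2",
                          balanced_run=None) -> dict:
    """Shared-type ARI with and without one cell type removed from modality x."""
    balanced = balanced_run if balanced_run is not None else integration_run(seed)
    unbalanced = integration_run(seed, removed_celltypes_x=(removed,))
    shared = set(unbalanced["labels_x"])
    return {
        "balanced_ari": label_transfer_ari(balanced, restrict_to=shared),
        "unbalanced_ari": label_transfer_ari(unbalanced, restrict_to=shared),
    }
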