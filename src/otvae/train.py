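"""Training loop: coupled VAE + minibatch-UOT alignment.

Each iteration samples one minibatch per dataset (without replacement within
a shuffled epoch, each side cycling independently), encodes both through the
shared encoder, reparameterizes, reconstructs common and specific blocks,
computes the Gaussian transport cost on (mu, sigma), solves the minibatch
UOT plan, and takes one Adam step on

    total = -ELBO* + gamma * UOT*

with the plan held fixed (gradients flow through the cost only). Early
stopping monitors the epoch mean of the total loss with a relative
improvement threshold, and the best-loss parameter snapshot is restored at
the end. All randomness flows from ``TrainConfig.seed``, so runs are
bit-reproducible.
"""

from __future__ import annotations

from dataclasses import dataclass, field, asdict

import numpy as np
import pandas as pd

from . import uot as uot_mod
from .model import CoupledVAE, LossWeights, make_optimizer
from .nn import bce
from .preprocess import GenePartition


@dataclass
class TrainConfig:
    """Hyperparameters; defaults follow the reference training recipe."""

    batch_size: int | tuple[int, int] = 256
    max_iterations: int = 30_000
    learning_rate: float = 2e-4
    weight_decay: float = 5e-4
    lambda_kl: float = 0.5
    lambda_s: float = 0.5
    gamma: float = 1.0
    epsilon: float = 0.1
    rho: float = 1.0
    ot_outer_iters: int = 20
    ot_inner_iters: int = 1
    ot_tol: float = 1e-6
    patience: int = 30
    improvement: float = 1e-4
    seed: int = 0
    global_plan: bool = False
    warm_start_plan: bool = False
    latent_dim: int = 16
    hidden_dims: tuple[int, int] = (1024, 128)
    dtype: str = "float32"
    #: optional per-cell transport weights (full-length vectors, one per
    #: dataset; sliced per minibatch and renormalized) for non-uniformly
    #: matched populations; None means uniform
    marginal_weights: tuple | None = None

    def __post_init__(self):
        if min(self.batch_sizes) < 2:
            raise ValueError("batch sizes must be >= 2")
        if self.max_iterations < 1 or self.patience < 1:
            raise ValueError("max_iterations and patience must be >= 1")

    @property
    def batch_sizes(self) -> tuple[int, int]:
        """(B_x, B_y); a scalar ``batch_size`` is used for both sides."""
        if isinstance(self.batch_size, (tuple, list)):
            return int(self.batch_size[0]), int(self.batch_size[1])
        return int(self.batch_size), int(self.batch_size)

    def to_dict(self) -> dict:
        return asdict(self)


class MinibatchSampler:
    """Duplicate-free index sets from independently cycled epoch permutations.

    Each side holds a shuffled permutation and a cursor; when fewer than a
    full batch remains the side reshuffles and restarts (partial batches are
    dropped — batch normalization breaks on size-1 batches).
    """

    def __init__(self, n_x: int, n_y: int, B_x: int, B_y: int,
                 rng: np.random.Generator):
        if B_x > n_x or B_y > n_y:
            raise ValueError(
                f"batch size exceeds dataset size: ({B_x},{B_y}) vs ({n_x},{n_y})"
            )
        self._rng = rng
        self._state = {}
        for side, n, B in (("x", n_x, B_x), ("y", n_y, B_y)):
            self._state[side] = {"n": n, "B": B, "perm": rng.permutation(n), "pos": 0}

    def _draw(self, side: str) -> np.ndarray:
        st = self._state[side]
        if st["pos"] + st["B"] > st["n"]:
            st["perm"] = self._rng.permutation(st["n"])
            st["pos"] = 0
        out = st["perm"][st["pos"]: st["pos"] + st["B"]]
        st["pos"] += st["B"]
        return out

    def sample(self) -> tuple[np.ndarray, np.ndarray]:
        return self._draw("x"), self._draw("y")


def sample_minibatch_indices(
    n_x: int, n_y: int, B_x: int, B_y: int, rng: np.random.Generator
) -> tuple[np.ndarray, np.ndarray]:
    """One-shot duplicate-free index draw (fresh permutations)."""
    return MinibatchSampler(n_x, n_y, B_x, B_y, rng).sample()


def _training_step(
    model: CoupledVAE,
    xc: np.ndarray, xs: np.ndarray,
    yc: np.ndarray, ys: np.ndarray,
    ids: tuple[str, str],
    weights: LossWeights,
    cfg: TrainConfig,
    opt,
    rng: np.random.Generator,
    plan_init: np.ndarray | None,
    marginals: tuple = (None, None),
) -> dict:
    """Forward, UOT solve, analytic backward, one optimizer step."""
    dsx, dsy = ids
    Bx, By = xc.shape[0], yc.shape[0]
    dt = model.dtype

    # encoder + reparameterization
    mu_x, lv_x, ce_x = model._encode_fwd(np.asarray(xc, dtype=dt))
    mu_y, lv_y, ce_y = model._encode_fwd(np.asarray(yc, dtype=dt))
    sig_x = np.exp(0.5 * lv_x)
    sig_y = np.exp(0.5 * lv_y)
    nu_x = rng.standard_normal(mu_x.shape).astype(dt)
    nu_y = rng.standard_normal(mu_y.shape).astype(dt)
    z_x = mu_x + sig_x * nu_x
    z_y = mu_y + sig_y * nu_y

    # decoders (training mode: DSBN batch statistics)
    pxc, cxc = model.decode_common(z_x, dsx, training=True)
    pyc, cyc = model.decode_common(z_y, dsy, training=True)
    pxs, cxs = model.decode_specific(z_x, dsx, training=True)
    pys, cys = model.decode_specific(z_y, dsy, training=True)

    # minibatch UOT on (mu, sigma), plan detached
    C = uot_mod._sqdist(mu_x, mu_y) + uot_mod._sqdist(sig_x, sig_y)
    C = np.maximum(C, 0.0)
    a, b = marginals
    T = uot_mod.solve_uot_ipot(
        C, a=a, b=b, epsilon=cfg.epsilon, rho=cfg.rho,
        outer_iters=cfg.ot_outer_iters, inner_iters=cfg.ot_inner_iters,
        tol=cfg.ot_tol, init=plan_init,
    ) if weights.gamma > 0 or cfg.global_plan else np.zeros_like(C)
    loss_uot = float(np.sum(C * T))

    # loss values
    rc = float(bce(xc, pxc).sum(1).mean() + bce(yc, pyc).sum(1).mean())
    rs = float(bce(xs, pxs).sum(1).mean() + bce(ys, pys).sum(1).mean())
    kl_x = 0.5 * np.sum(mu_x.astype(np.float64) ** 2 + sig_x.astype(np.float64) ** 2
                        - 1.0 - lv_x.astype(np.float64), axis=1)
    kl_y = 0.5 * np.sum(mu_y.astype(np.float64) ** 2 + sig_y.astype(np.float64) ** 2
                        - 1.0 - lv_y.astype(np.float64), axis=1)
    kl = float(kl_x.mean() + kl_y.mean())
    neg_elbo = rc + weights.lambda_s * rs + weights.lambda_kl * kl
    total = neg_elbo + weights.gamma * loss_uot

    # ------------------------------------------------------------- backward
    opt.zero_grad()
    # reconstruction gradients (fused sigmoid+BCE): d/dlogits = p - target
    gz_x = model._decode_common_bwd(cxc, ((pxc - xc) / Bx).astype(dt))
    gz_y = model._decode_common_bwd(cyc, ((pyc - yc) / By).astype(dt))
    gz_x += model._decode_specific_bwd(cxs, (weights.lambda_s * (pxs - xs) / Bx).astype(dt))
    gz_y += model._decode_specific_bwd(cys, (weights.lambda_s * (pys - ys) / By).astype(dt))

    # KL gradients (mean over cells)
    gmu_x = (weights.lambda_kl / Bx) * mu_x
    gmu_y = (weights.lambda_kl / By) * mu_y
    glv_x = (0.5 * weights.lambda_kl / Bx) * (sig_x**2 - 1.0)
    glv_y = (0.5 * weights.lambda_kl / By) * (sig_y**2 - 1.0)

    # UOT gradients through the cost only
    if weights.gamma > 0:
        g = weights.gamma
        r = T.sum(1)[:, None]
        c = T.sum(0)[:, None]
        gmu_x += (2 * g) * (mu_x * r - (T @ mu_y.astype(np.float64)).astype(dt))
        gmu_y += (2 * g) * (mu_y * c - (T.T @ mu_x.astype(np.float64)).astype(dt))
        gsig_x = (2 * g) * (sig_x * r - (T @ sig_y.astype(np.float64)).astype(dt))
        gsig_y = (2 * g) * (sig_y * c - (T.T @ sig_x.astype(np.float64)).astype(dt))
    else:
        gsig_x = np.zeros_like(sig_x)
        gsig_y = np.zeros_like(sig_y)

    # through z = mu + sigma * nu, sigma = exp(lv/2)
    gmu_x += gz_x
    gmu_y += gz_y
    gsig_x += gz_x * nu_x
    gsig_y += gz_y * nu_y
    glv_x += 0.5 * gsig_x * sig_x
    glv_y += 0.5 * gsig_y * sig_y

    model._encode_bwd(ce_x, gmu_x.astype(dt), glv_x.astype(dt))
    model._encode_bwd(ce_y, gmu_y.astype(dt), glv_y.astype(dt))
    opt.step()

    return {
        "recon_common": rc, "recon_specific": rs, "kl": kl,
        "neg_elbo": neg_elbo, "uot": loss_uot, "total": total, "plan": T,
    }


@dataclass
class FitResult:
    model: CoupledVAE
    history: pd.DataFrame
    global_plan: np.ndarray | None = None
    best_iteration: int = -1
    config: TrainConfig | None = None
    log: list = field(default_factory=list, repr=False)


def fit(partition: GenePartition, config: TrainConfig | None = None) -> FitResult:
    """Train the coupled VAE with UOT alignment on a preprocessed pair."""
    cfg = config or TrainConfig()
    dsx, dsy = partition.dataset_ids
    xc_all = partition.common[dsx]
    yc_all = partition.common[dsy]
    xs_all = partition.specific[dsx]
    ys_all = partition.specific[dsy]
    n_x, n_y = xc_all.shape[0], yc_all.shape[0]
    bx, by = cfg.batch_sizes
    Bx, By = min(bx, n_x), min(by, n_y)

    model = CoupledVAE(
        n_common=partition.n_common,
        specific_dims={ds: partition.specific[ds].shape[1] for ds in partition.dataset_ids},
        latent_dim=cfg.latent_dim,
        hidden_dims=cfg.hidden_dims,
        seed=cfg.seed,
        dtype=np.dtype(cfg.dtype),
        common_genes=partition.common_genes,
        specific_genes=partition.specific_genes,
    )
    opt = make_optimizer(model, lr=cfg.learning_rate, weight_decay=cfg.weight_decay)
    weights = LossWeights(cfg.lambda_kl, cfg.lambda_s, cfg.gamma)
    rng = np.random.default_rng(cfg.seed)
    sampler = MinibatchSampler(n_x, n_y, Bx, By, rng)
    T_global = uot_mod.init_global_plan(n_x, n_y) if cfg.global_plan else None

    iters_per_epoch = int(np.ceil(max(n_x, n_y) / max(Bx, By)))
    best_loss = np.inf
    best_state = model.state_dict()
    best_iter = 0
    since_improve = 0
    rows = []
    epoch_losses: list[float] = []

    for m in range(1, cfg.max_iterations + 1):
        I, J = sampler.sample()
        plan_init = None
        if cfg.global_plan and cfg.warm_start_plan:
            plan_init = T_global[np.ix_(I, J)]
        marginals = (None, None)
        if cfg.marginal_weights is not None:
            wx, wy = cfg.marginal_weights
            a = None if wx is None else np.asarray(wx, dtype=np.float64)[I]
            b = None if wy is None else np.asarray(wy, dtype=np.float64)[J]
            marginals = (
                None if a is None else a / a.sum(),
                None if b is None else b / b.sum(),
            )
        try:
            out = _training_step(
                model, xc_all[I], xs_all[I], yc_all[J], ys_all[J],
                (dsx, dsy), weights, cfg, opt, rng, plan_init, marginals,
            )
        except FloatingPointError as e:
            raise FloatingPointError(f"at iteration {m}: {e}") from e
        if not np.isfinite(out["total"]):
            raise FloatingPointError(
                f"non-finite loss at iteration {m}: "
                f"recon={out['recon_common']:.4g} kl={out['kl']:.4g} uot={out['uot']:.4g}"
            )
        if cfg.global_plan:
            uot_mod.update_global_plan(T_global, out["plan"], I, J)
        rows.append({k: out[k] for k in
                     ("recon_common", "recon_specific", "kl", "neg_elbo", "uot", "total")})
        rows[-1]["iteration"] = m
        epoch_losses.append(out["total"])

        if m % iters_per_epoch == 0 or m == cfg.max_iterations:
            epoch_mean = float(np.mean(epoch_losses))
            epoch_losses = []
            if not np.isfinite(best_loss) or (
                epoch_mean < best_loss - cfg.improvement * abs(best_loss)
            ):
                best_loss = epoch_mean
                best_state = model.state_dict()
                best_iter = m
                since_improve = 0
            else:
                since_improve += 1
            if since_improve >= cfg.patience:
                break

    model.load_state_dict(best_state)
    history = pd.DataFrame(rows)
    return FitResult(model=model, history=history, global_plan=T_global,
                     best_iteration=best_iter, config=cfg)


def embed(model: CoupledVAE, X: np.ndarray, genes: list[str] | None = None) -> np.ndarray:
    """Posterior means (eval mode, no sampling) for downstream analysis."""
    if genes is not None and model.common_genes is not None:
        if list(genes) != list(model.common_genes):
            missing = sorted(set(model.common_genes) - set(genes))
            raise ValueError(
                f"gene list does not match the model's common genes; "
                f"missing {len(missing)}: {missing[:10]}"
            )
    return model.encode(np.asarray(X)).mu
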