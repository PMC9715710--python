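"""The coupled variational autoencoder.

One dataset-free probabilistic encoder maps the common-gene profile of every
cell (whatever dataset it comes from) to a diagonal Gaussian posterior
N(mu, diag(sigma^2)) over a K-dimensional latent space. Decoding is
dataset-conditioned in two ways:

* a single *common* decoder (linear, no hidden layer) reconstructs the
  common-gene block through a Dataset-Specific Batch Normalization (DSBN)
  branch — one batch-norm layer with its own affine parameters and running
  statistics per registered dataset — followed by a sigmoid;
* one *specific* decoder per dataset (linear + sigmoid) reconstructs that
  dataset's specific-gene block.

Inputs are expected max-abs scaled to [0, 1]; reconstruction likelihood is
Bernoulli (binary cross-entropy), the realization of log phi(x|z) matching
sigmoid outputs. The encoder emits log-variance clamped to [-10, 10] and
sigma = exp(logvar / 2).

Everything runs on numpy with explicit analytic gradients (see
:mod:`otvae.nn`); small architectures make this fast and bit-reproducible.
"""

from __future__ import annotations

import json
from dataclasses import dataclass

import numpy as np

from .nn import Adam, BatchNorm, Linear, bce, relu, relu_backward, sigmoid

LOGVAR_CLAMP = 10.0


@dataclass
class LatentGaussian:
    """Per-cell posterior: mean, standard deviation, and optional sample."""

    mu: np.ndarray
    sigma: np.ndarray
    z: np.ndarray | None = None

    def __post_init__(self):
        if np.any(self.sigma <= 0):
            raise ValueError("sigma must be positive")


@dataclass
class LossWeights:
    """Balance parameters of the total loss: -ELBO* + gamma * UOT*."""

    lambda_kl: float = 0.5
    lambda_s: float = 0.5
    gamma: float = 1.0

    def __post_init__(self):
        for v in (self.lambda_kl, self.lambda_s, self.gamma):
            if not np.isfinite(v) or v < 0:
                raise ValueError("loss weights must be finite and >= 0")


def kl_gaussian(lg: LatentGaussian) -> np.ndarray:
    """Per-cell KL( N(mu, diag(sigma^2)) || N(0, I) ), summed over dimensions:
    0.5 * sum_d (mu_d^2 + sigma_d^2 - 1 - 2 log sigma_d).
    """
    if np.any(lg.sigma <= 0):
        raise ValueError("sigma must be positive")
    mu = lg.mu.astype(np.float64)
    s2 = lg.sigma.astype(np.float64) ** 2
    return 0.5 * np.sum(mu**2 + s2 - 1.0 - np.log(s2), axis=1)


def reparameterize(lg: LatentGaussian, rng: np.random.Generator) -> tuple[np.ndarray, np.ndarray]:
    """z = mu + sigma * nu with nu ~ N(0, I) from the supplied generator."""
    nu = rng.standard_normal(lg.mu.shape).astype(lg.mu.dtype)
    return lg.mu + lg.sigma * nu, nu


class CoupledVAE:
    """Coupled VAE over a common-gene block plus per-dataset specific blocks.

    Parameters
    ----------
    n_common : width of the shared (common-gene) input/output block.
    specific_dims : dataset id -> width of that dataset's specific block.
    latent_dim : K, dimension of the latent Gaussians (default 16).
    hidden_dims : encoder hidden layer widths (default (1024, 128)).
    seed : weight-initialization seed.
    dtype : parameter dtype (float32 default; float64 for gradient checks).
    """

    def __init__(
        self,
        n_common: int,
        specific_dims: dict[str, int],
        latent_dim: int = 16,
        hidden_dims: tuple[int, int] = (1024, 128),
        seed: int = 0,
        dtype=np.float32,
        common_genes: list[str] | None = None,
        specific_genes: dict[str, list[str]] | None = None,
    ):
        rng = np.random.default_rng(seed)
        self.n_common = n_common
        self.specific_dims = dict(specific_dims)
        self.dataset_ids = list(specific_dims)
        self.latent_dim = latent_dim
        self.hidden_dims = tuple(hidden_dims)
        self.dtype = np.dtype(dtype).type
        self.common_genes = common_genes
        self.specific_genes = specific_genes
        self.seed = seed

        h1, h2 = hidden_dims
        self.enc_fc1 = Linear(n_common, h1, rng, dtype, "enc_fc1")
        self.enc_fc2 = Linear(h1, h2, rng, dtype, "enc_fc2")
        self.enc_mu = Linear(h2, latent_dim, rng, dtype, "enc_mu")
        self.enc_logvar = Linear(h2, latent_dim, rng, dtype, "enc_logvar")
        self.dec_common = Linear(latent_dim, n_common, rng, dtype, "dec_common")
        self.dsbn = {
            ds: BatchNorm(n_common, dtype, name=f"dsbn.{ds}") for ds in self.dataset_ids
        }
        self.dec_specific = {
            ds: Linear(latent_dim, dim, rng, dtype, f"dec_specific.{ds}")
            for ds, dim in specific_dims.items()
        }

    # ---------------------------------------------------------------- params
    def parameters(self):
        out = []
        for layer in (self.enc_fc1, self.enc_fc2, self.enc_mu, self.enc_logvar,
                      self.dec_common):
            out += layer.parameters()
        for ds in self.dataset_ids:
            out += self.dsbn[ds].parameters()
            out += self.dec_specific[ds].parameters()
        return out

    def state_dict(self) -> dict[str, np.ndarray]:
        state = {p.name: p.value.copy() for p in self.parameters()}
        for ds in self.dataset_ids:
            state[f"dsbn.{ds}.running_mean"] = self.dsbn[ds].running_mean.copy()
            state[f"dsbn.{ds}.running_var"] = self.dsbn[ds].running_var.copy()
        return state

    def load_state_dict(self, state: dict[str, np.ndarray]) -> None:
        for p in self.parameters():
            p.value[...] = state[p.name]
        for ds in self.dataset_ids:
            self.dsbn[ds].running_mean[...] = state[f"dsbn.{ds}.running_mean"]
            self.dsbn[ds].running_var[...] = state[f"dsbn.{ds}.running_var"]

    # --------------------------------------------------------------- forward
    def _check_input(self, x: np.ndarray, dim: int, what: str) -> np.ndarray:
        x = np.asarray(x, dtype=self.dtype)
        if x.ndim != 2 or x.shape[1] != dim:
            raise ValueError(f"{what}: expected (*, {dim}) input, got {x.shape}")
        return x

    def _encode_fwd(self, x: np.ndarray):
        a1, c1 = self.enc_fc1.forward(x)
        h1, m1 = relu(a1)
        a2, c2 = self.enc_fc2.forward(h1)
        h2, m2 = relu(a2)
        mu, cmu = self.enc_mu.forward(h2)
        lv_raw, clv = self.enc_logvar.forward(h2)
        lv = np.clip(lv_raw, -LOGVAR_CLAMP, LOGVAR_CLAMP)
        clamp_mask = np.abs(lv_raw) < LOGVAR_CLAMP
        cache = (c1, m1, c2, m2, cmu, clv, clamp_mask)
        return mu, lv, cache

    def _encode_bwd(self, cache, gmu: np.ndarray, glv: np.ndarray) -> None:
        c1, m1, c2, m2, cmu, clv, clamp_mask = cache
        gh2 = self.enc_mu.backward(cmu, gmu)
        gh2 += self.enc_logvar.backward(clv, glv * clamp_mask)
        ga2 = relu_backward(m2, gh2)
        gh1 = self.enc_fc2.backward(c2, ga2)
        ga1 = relu_backward(m1, gh1)
        self.enc_fc1.backward(c1, ga1)

    def encode(self, x: np.ndarray) -> LatentGaussian:
        """Posterior (mu, sigma) per cell; eval mode, dataset-free."""
        x = self._check_input(x, self.n_common, "encode")
        mu, lv, _ = self._encode_fwd(x)
        return LatentGaussian(mu=mu, sigma=np.exp(0.5 * lv))

    def _require_dataset(self, dataset_id: str) -> None:
        if dataset_id not in self.dsbn:
            raise KeyError(
                f"unknown dataset id {dataset_id!r}; registered: {self.dataset_ids}"
            )

    def decode_common(self, z: np.ndarray, dataset_id: str, training: bool = False):
        """Linear map + the dataset's DSBN branch + sigmoid; output in (0, 1)."""
        self._require_dataset(dataset_id)
        z = self._check_input(z, self.latent_dim, "decode_common")
        a, clin = self.dec_common.forward(z)
        h, cbn = self.dsbn[dataset_id].forward(a, training)
        p = sigmoid(h)
        if training:
            return p, (clin, cbn, dataset_id)
        return p

    def _decode_common_bwd(self, cache, gpre: np.ndarray) -> np.ndarray:
        clin, cbn, ds = cache
        ga = self.dsbn[ds].backward(cbn, gpre)
        return self.dec_common.backward(clin, ga)

    def decode_specific(self, z: np.ndarray, dataset_id: str, training: bool = False):
        """The dataset's own linear decoder + sigmoid (no DSBN)."""
        self._require_dataset(dataset_id)
        z = self._check_input(z, self.latent_dim, "decode_specific")
        a, clin = self.dec_specific[dataset_id].forward(z)
        p = sigmoid(a)
        if training:
            return p, (clin, dataset_id)
        return p

    def _decode_specific_bwd(self, cache, gpre: np.ndarray) -> np.ndarray:
        clin, ds = cache
        return self.dec_specific[ds].backward(clin, gpre)

    # ------------------------------------------------------------ checkpoint
    SCHEMA_VERSION = 1

    def save(self, path) -> None:
        meta = {
            "schema_version": self.SCHEMA_VERSION,
            "n_common": self.n_common,
            "specific_dims": self.specific_dims,
            "latent_dim": self.latent_dim,
            "hidden_dims": list(self.hidden_dims),
            "dtype": np.dtype(self.dtype).name,
            "common_genes": self.common_genes,
            "specific_genes": self.specific_genes,
            "seed": self.seed,
        }
        arrays = {k.replace(".", "__"): v for k, v in self.state_dict().items()}
        np.savez(path, __meta__=np.frombuffer(json.dumps(meta).encode(), dtype=np.uint8),
                 **arrays)

    @classmethod
    def load(cls, path) -> "CoupledVAE":
        with np.load(path) as data:
            meta = json.loads(bytes(data["__meta__"]).decode())
            if meta["schema_version"] != cls.SCHEMA_VERSION:
                raise ValueError(f"unsupported checkpoint schema {meta['schema_version']}")
            model = cls(
                n_common=meta["n_common"],
                specific_dims=meta["specific_dims"],
                latent_dim=meta["latent_dim"],
                hidden_dims=tuple(meta["hidden_dims"]),
                seed=meta["seed"],
                dtype=np.dtype(meta["dtype"]),
                common_genes=meta["common_genes"],
                specific_genes=meta["specific_genes"],
            )
            state = {k.replace("__", "."): data[k] for k in data.files if k != "__meta__"}
            model.load_state_dict(state)
        return model


def elbo_star_loss(
    x_common: np.ndarray,
    y_common: np.ndarray,
    lg_x: LatentGaussian,
    lg_y: LatentGaussian,
    recon_common: tuple[np.ndarray, np.ndarray],
    recon_specific: tuple[np.ndarray, np.ndarray],
    targets_specific: tuple[np.ndarray, np.ndarray],
    weights: LossWeights,
) -> float:
    """Negative modified ELBO for a joint minibatch (a value, not a graph).

    Reconstruction log-likelihoods are negative binary cross-entropies summed
    over features; KL is summed over latent dimensions; each term is averaged
    over its dataset's cells and the two datasets' terms are added. Returns
    recon_common + lambda_s * recon_specific + lambda_kl * KL (i.e. -ELBO*).
    """
    for t in (x_common, y_common) + tuple(targets_specific):
        if t.size and (t.min() < 0 or t.max() > 1):
            raise ValueError("targets must lie in [0, 1]")
    xs_hat, ys_hat = recon_specific
    xc_hat, yc_hat = recon_common
    xs, ys = targets_specific
    rc = bce(x_common, xc_hat).sum(1).mean() + bce(y_common, yc_hat).sum(1).mean()
    rs = bce(xs, xs_hat).sum(1).mean() + bce(ys, ys_hat).sum(1).mean()
    kl = kl_gaussian(lg_x).mean() + kl_gaussian(lg_y).mean()
    return float(rc + weights.lambda_s * rs + weights.lambda_kl * kl)


def make_optimizer(model: CoupledVAE, lr: float = 2e-4,
                   weight_decay: float = 5e-4) -> Adam:
    return Adam(model.parameters(), lr=lr, weight_decay=weight_decay)
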