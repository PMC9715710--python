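import numpy as np
import pytest
from scipy import integrate
from scipy.stats import norm

from otvae.model import (
    CoupledVAE,
    LatentGaussian,
    LossWeights,
    elbo_star_loss,
    kl_gaussian,
    reparameterize,
)
from otvae.nn import bce
from otvae.train import TrainConfig, _training_step


def small_model(dtype=np.float32, seed=1):
    return CoupledVAE(n_common=7, specific_dims={"x": 4, "y": 5}, latent_dim=3,
                      hidden_dims=(6, 5), seed=seed, dtype=dtype)


class TestEncoder:
    def test_identical_inputs_identical_posteriors(self, rng):
        m = small_model()
        x = rng.random((1, 7)).astype(np.float32)
        lg = m.encode(np.vstack([x, x]))
        np.testing.assert_array_equal(lg.mu[0], lg.mu[1])
        np.testing.assert_array_equal(lg.sigma[0], lg.sigma[1])

    def test_default_architecture(self):
        m = CoupledVAE(n_common=20, specific_dims={"x": 5, "y": 5})
        assert m.enc_fc1.W.value.shape == (20, 1024)
        assert m.enc_fc2.W.value.shape == (1024, 128)
        assert m.latent_dim == 16

    def test_dimension_mismatch_raises(self, rng):
        with pytest.raises(ValueError, match="expected"):
            small_model().encode(rng.random((3, 5)))

    def test_encoder_is_dataset_free(self, rng):
        # nothing in the encode path depends on a dataset tag
        m = small_model()
        x = rng.random((4, 7))
        np.testing.assert_array_equal(m.encode(x).mu, m.encode(x).mu)


class TestReparameterize:
    def test_sigma_zero_limit_gives_mu(self, rng):
        lg = LatentGaussian(mu=np.ones((5, 3)), sigma=np.full((5, 3), 1e-12))
        z, _ = reparameterize(lg, rng)
        np.testing.assert_allclose(z, 1.0, atol=1e-10)

    def test_fixed_seed_reproducible(self):
        lg = LatentGaussian(mu=np.zeros((4, 3)), sigma=np.ones((4, 3)))
        z1, _ = reparameterize(lg, np.random.default_rng(5))
        z2, _ = reparameterize(lg, np.random.default_rng(5))
        np.testing.assert_array_equal(z1, z2)

    def test_sample_mean_close_to_mu(self):
        n = 100_000
        mu, sigma = 0.7, 1.3
        lg = LatentGaussian(mu=np.full((n, 1), mu), sigma=np.full((n, 1), sigma))
        z, _ = reparameterize(lg, np.random.default_rng(0))
        assert abs(z.mean() - mu) < 4 * sigma / np.sqrt(n)


class TestKL:
    def test_standard_normal_is_zero(self):
        lg = LatentGaussian(mu=np.zeros((1, 4)), sigma=np.ones((1, 4)))
        np.testing.assert_allclose(kl_gaussian(lg), 0.0, atol=1e-12)

    def test_unit_mean_shift_is_half(self):
        mu = np.zeros((1, 4))
        mu[0, 0] = 1.0
        lg = LatentGaussian(mu=mu, sigma=np.ones((1, 4)))
        np.testing.assert_allclose(kl_gaussian(lg), 0.5, atol=1e-12)

    def test_matches_quadrature(self, rng):
        mu = rng.normal(size=3)
        sigma = rng.uniform(0.5, 2.0, size=3)
        expected = 0.0
        for m, s in zip(mu, sigma):
            f = lambda x: norm.pdf(x, m, s) * (norm.logpdf(x, m, s) - norm.logpdf(x))
            expected += integrate.quad(f, m - 12 * s, m + 12 * s)[0]
        lg = LatentGaussian(mu=mu[None], sigma=sigma[None])
        np.testing.assert_allclose(kl_gaussian(lg)[0], expected, atol=1e-3)

    def test_nonpositive_sigma_rejected(self):
        with pytest.raises(ValueError):
            LatentGaussian(mu=np.zeros((1, 2)), sigma=np.zeros((1, 2)))

    def test_nonnegative_everywhere(self, rng):
        lg = LatentGaussian(mu=rng.normal(size=(50, 6)),
                            sigma=rng.uniform(0.1, 3, size=(50, 6)))
        assert np.all(kl_gaussian(lg) >= 0)


class TestDecoders:
    def test_unknown_dataset_id(self, rng):
        with pytest.raises(KeyError, match="unknown dataset id"):
            small_model().decode_common(rng.random((2, 3)), "nope")

    def test_output_bounded(self, rng):
        m = small_model()
        z = 5.0 * rng.normal(size=(4, 3))
        p = m.decode_common(z, "x")
        assert np.all(p > 0) and np.all(p < 1)

    def test_freshly_initialized_branches_agree(self, rng):
        # DSBN branches start identical, so both ids decode identically
        m = small_model()
        z = rng.normal(size=(4, 3))
        np.testing.assert_array_equal(m.decode_common(z, "x"), m.decode_common(z, "y"))

    def test_branches_diverge_after_update(self, rng):
        m = small_model()
        m.dsbn["x"].gamma.value[...] = 2.0
        z = rng.normal(size=(4, 3)).astype(np.float32)
        assert not np.allclose(m.decode_common(z, "x"), m.decode_common(z, "y"))

    def test_specific_decoder_shapes_and_zero_weights(self, rng):
        m = small_model()
        z = rng.normal(size=(6, 3))
        assert m.decode_specific(z, "x").shape == (6, 4)
        assert m.decode_specific(z, "y").shape == (6, 5)
        m.dec_specific["x"].W.value[...] = 0
        m.dec_specific["x"].b.value[...] = 0
        np.testing.assert_allclose(m.decode_specific(z, "x"), 0.5, atol=1e-7)


class TestLoss:
    def test_perfect_reconstruction_hits_entropy_floor(self):
        # 2 cells x 2 genes, analytic BCE floor with standard-normal posterior
        t = np.array([[0.25, 0.5], [0.75, 1.0]])
        floor = bce(t, t).sum(1).mean()
        lg = LatentGaussian(mu=np.zeros((2, 2)), sigma=np.ones((2, 2)))
        w = LossWeights(lambda_kl=1.0, lambda_s=0.0, gamma=0.0)
        empty = np.zeros((2, 0))
        val = elbo_star_loss(t, t, lg, lg, (t, t), (empty, empty), (empty, empty), w)
        hand = -(0.25 * np.log(0.25) + 0.75 * np.log(0.75)
                 + 0.5 * np.log(0.5) + 0.5 * np.log(0.5)
                 + 0.75 * np.log(0.75) + 0.25 * np.log(0.25)) / 2
        # one target is exactly 1.0; its clipped entropy contribution is ~0
        np.testing.assert_allclose(val, 2 * floor, rtol=1e-6)
        np.testing.assert_allclose(floor, hand, atol=1e-5)

    def test_lambda_s_zero_reduces_to_plain_vae(self, rng):
        t = rng.random((3, 4))
        s = rng.random((3, 2))
        lg = LatentGaussian(mu=rng.normal(size=(3, 2)),
                            sigma=rng.uniform(0.5, 2, (3, 2)))
        w0 = LossWeights(lambda_kl=1.0, lambda_s=0.0, gamma=0.0)
        val = elbo_star_loss(t, t, lg, lg, (t, t), (s, s), (s, s), w0)
        from otvae.model import kl_gaussian as klg
        expect = 2 * bce(t, t).sum(1).mean() + 2 * klg(lg).mean()
        np.testing.assert_allclose(val, expect, rtol=1e-9)

    def test_target_out_of_range_rejected(self, rng):
        t = np.array([[1.5, 0.5]])
        lg = LatentGaussian(mu=np.zeros((1, 2)), sigma=np.ones((1, 2)))
        w = LossWeights()
        with pytest.raises(ValueError, match=r"\[0, 1\]"):
            elbo_star_loss(t, t, lg, lg, (t, t), (t, t), (t, t), w)


class _FrozenOpt:
    def __init__(self, params):
        self.params = list(params)

    def zero_grad(self):
        for p in self.params:
            p.grad[...] = 0

    def step(self):
        pass


def _joint_loss(model, xc, xs, yc, ys, w, nu_x, nu_y, T):
    """Independent re-evaluation of the total training loss with fixed noise
    and a fixed transport plan."""
    from otvae.uot import _sqdist

    mu_x, lv_x, _ = model._encode_fwd(xc)
    mu_y, lv_y, _ = model._encode_fwd(yc)
    sx, sy = np.exp(0.5 * lv_x), np.exp(0.5 * lv_y)
    z_x, z_y = mu_x + sx * nu_x, mu_y + sy * nu_y
    pxc, _ = model.decode_common(z_x, "x", training=True)
    pyc, _ = model.decode_common(z_y, "y", training=True)
    pxs, _ = model.decode_specific(z_x, "x", training=True)
    pys, _ = model.decode_specific(z_y, "y", training=True)
    C = np.maximum(_sqdist(mu_x, mu_y) + _sqdist(sx, sy), 0)
    rc = bce(xc, pxc).sum(1).mean() + bce(yc, pyc).sum(1).mean()
    rs = bce(xs, pxs).sum(1).mean() + bce(ys, pys).sum(1).mean()
    kl = (0.5 * np.sum(mu_x**2 + sx**2 - 1 - lv_x, 1)).mean() + \
         (0.5 * np.sum(mu_y**2 + sy**2 - 1 - lv_y, 1)).mean()
    return float(rc + w.lambda_s * rs + w.lambda_kl * kl + w.gamma * np.sum(C * T))


def test_analytic_gradients_match_finite_differences(rng):
    """The full training-step gradient agrees with central finite differences
    for every parameter group (float64)."""
    model = small_model(dtype=np.float64)
    xc, xs = rng.random((4, 7)), rng.random((4, 4))
    yc, ys = rng.random((4, 7)), rng.random((4, 5))
    w = LossWeights(0.5, 0.5, 1.0)
    cfg = TrainConfig(batch_size=4)
    opt = _FrozenOpt(model.parameters())
    out = _training_step(model, xc, xs, yc, ys, ("x", "y"), w, cfg, opt,
                         np.random.default_rng(42), None)
    # the step's BN running-stat update perturbs eval mode only, not training
    rr = np.random.default_rng(42)
    nu_x = rr.standard_normal((4, 3))
    nu_y = rr.standard_normal((4, 3))
    T = out["plan"]
    eps = 1e-6
    for p in model.parameters():
        flat_idx = rng.integers(0, p.value.size, size=2)
        for fi in flat_idx:
            idx = np.unravel_index(fi, p.value.shape)
            old = p.value[idx]
            p.value[idx] = old + eps
            lp = _joint_loss(model, xc, xs, yc, ys, w, nu_x, nu_y, T)
            p.value[idx] = old - eps
            lm = _joint_loss(model, xc, xs, yc, ys, w, nu_x, nu_y, T)
            p.value[idx] = old
            fd = (lp - lm) / (2 * eps)
            assert abs(fd - p.grad[idx]) < 1e-5 * max(1.0, abs(fd)), p.name


def test_checkpoint_roundtrip(tmp_path, rng):
    m = small_model()
    m.common_genes = [f"g{i}" for i in range(7)]
    m.specific_genes = {"x": [f"sx{i}" for i in range(4)],
                        "y": [f"sy{i}" for i in range(5)]}
    x = rng.random((5, 7))
    path = tmp_path / "ckpt.npz"
    m.save(path)
    m2 = CoupledVAE.load(path)
    np.testing.assert_array_equal(m.encode(x).mu, m2.encode(x).mu)
    np.testing.assert_array_equal(
        m.decode_common(m.encode(x).mu, "y"), m2.decode_common(m2.encode(x).mu, "y")
    )
    assert m2.common_genes == m.common_genes
    assert m2.dataset_ids == ["x", "y"]
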