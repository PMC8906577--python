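"""VAE variants, loss primitives, training contract, and the PCA baseline."""

import dataclasses

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st
from scipy import integrate, stats

from morphvae import (
    VAEConfig,
    encode_decode,
    kl_gaussian,
    mmd_rbf,
    pca_baseline,
    simulate_profiles,
    train_vae,
    vae_loss,
)
from morphvae.models import VAEModel, _backward, _mmd_value_and_grad

from conftest import make_table


# ----------------------------------------------------------------------
# KL divergence


def kl_by_numerical_integration(mu, var):
    """Oracle: integrate q(x) log(q(x)/p(x)) for 1-D Gaussians."""
    q = stats.norm(mu, np.sqrt(var))
    p = stats.norm(0, 1)

    def integrand(x):
        return q.pdf(x) * (q.logpdf(x) - p.logpdf(x))

    val, _ = integrate.quad(integrand, mu - 12 * np.sqrt(var), mu + 12 * np.sqrt(var))
    return val


@pytest.mark.parametrize(
    "mu,var,expect",
    [
        (0.0, 1.0, 0.0),
        (1.0, 1.0, 0.5),
        (0.0, np.e, 0.5 * (np.e - 2)),
    ],
)
def test_kl_closed_forms(mu, var, expect):
    got = kl_gaussian(np.array([mu]), np.array([np.log(var)]))
    assert got == pytest.approx(expect, abs=1e-12)
    assert got == pytest.approx(kl_by_numerical_integration(mu, var), abs=1e-6)


@settings(deadline=None, max_examples=50)
@given(
    st.lists(st.floats(-3, 3), min_size=1, max_size=5),
    st.lists(st.floats(-2, 2), min_size=1, max_size=5),
)
def test_kl_nonnegative_and_zero_only_at_prior(mus, logvars):
    k = min(len(mus), len(logvars))
    mu = np.array(mus[:k])
    lv = np.array(logvars[:k])
    val = kl_gaussian(mu, lv)
    assert val >= -1e-12
    if np.allclose(mu, 0) and np.allclose(lv, 0):
        assert val == pytest.approx(0, abs=1e-12)
    elif max(np.abs(mu).max(), np.abs(lv).max()) > 1e-3:
        assert val > 0


def test_kl_rejects_nonfinite():
    with pytest.raises(ValueError):
        kl_gaussian(np.array([np.nan]), np.array([0.0]))


# ----------------------------------------------------------------------
# MMD


def mmd_double_sum_oracle(a, b, bandwidths):
    """Explicit O(n m) double sums, no vectorized shortcuts."""
    def k(x, y):
        return sum(np.exp(-np.sum((x - y) ** 2) / (2 * h)) for h in bandwidths)

    saa = np.mean([[k(x, y) for y in a] for x in a])
    sbb = np.mean([[k(x, y) for y in b] for x in b])
    sab = np.mean([[k(x, y) for y in b] for x in a])
    return saa + sbb - 2 * sab


def test_mmd_identical_samples_zero():
    rng = np.random.default_rng(0)
    a = rng.normal(size=(6, 3))
    assert mmd_rbf(a, a.copy(), [1.0, 2.0]) == pytest.approx(0, abs=1e-12)


def test_mmd_two_point_hand_value():
    # a = {0}, b = {1}, kernel exp(-d^2/2): 1 + 1 - 2 e^{-1/2}
    got = mmd_rbf(np.array([[0.0]]), np.array([[1.0]]), [1.0])
    assert got == pytest.approx(2 - 2 * np.exp(-0.5), abs=1e-12)


def test_mmd_matches_double_sum_oracle_and_symmetry():
    rng = np.random.default_rng(1)
    for _ in range(10):
        a = rng.normal(size=(rng.integers(2, 10), 3))
        b = rng.normal(size=(rng.integers(2, 10), 3))
        bw = [0.5, 2.0]
        assert mmd_rbf(a, b, bw) == pytest.approx(mmd_double_sum_oracle(a, b, bw), abs=1e-12)
        assert mmd_rbf(a, b, bw) == pytest.approx(mmd_rbf(b, a, bw), abs=1e-12)


def test_mmd_biased_estimator_nonnegative_and_vanishing():
    rng = np.random.default_rng(2)
    a = rng.normal(size=(2000, 2))
    b = rng.normal(size=(2000, 2))
    val = mmd_rbf(a, b, [2.0])
    assert val >= -1e-12
    assert val < 0.01  # same distribution, large n -> near zero


def test_mmd_rejects_empty_and_mismatched():
    with pytest.raises(ValueError):
        mmd_rbf(np.empty((0, 2)), np.ones((2, 2)))
    with pytest.raises(ValueError):
        mmd_rbf(np.ones((2, 2)), np.ones((2, 3)))


# ----------------------------------------------------------------------
# loss and gradients


def test_vae_loss_beta_zero_is_pure_reconstruction():
    rng = np.random.default_rng(3)
    X = rng.uniform(size=(16, 8))
    cfg = VAEConfig(variant="beta", beta=0.0, latent_dim=3, hidden_dim=6, seed=0)
    model = VAEModel(cfg, 8)
    total, recon, reg = vae_loss(X, model, cfg)
    assert reg == 0
    assert total == pytest.approx(recon)


def test_vanilla_equals_beta_one():
    rng = np.random.default_rng(4)
    X = rng.uniform(size=(16, 8))
    cfg_v = VAEConfig(variant="vanilla", latent_dim=3, hidden_dim=6, seed=5)
    cfg_b = VAEConfig(variant="beta", beta=1.0, latent_dim=3, hidden_dim=6, seed=5)
    lv = vae_loss(X, VAEModel(cfg_v, 8), cfg_v, rng=np.random.default_rng(1))
    lb = vae_loss(X, VAEModel(cfg_b, 8), cfg_b, rng=np.random.default_rng(1))
    assert lv == pytest.approx(lb)
    # and identical training trajectories under identical seeds
    mv = train_vae(X, None, dataclasses.replace(cfg_v, epochs=5, batch_size=8))
    mb = train_vae(X, None, dataclasses.replace(cfg_b, epochs=5, batch_size=8))
    np.testing.assert_allclose(
        mv.history["train_total"], mb.history["train_total"], rtol=0, atol=0
    )


@pytest.mark.parametrize("variant,sigmoid", [("beta", True), ("beta", False), ("mmd", False)])
def test_backward_matches_finite_differences(variant, sigmoid):
    rng = np.random.default_rng(6)
    X = rng.uniform(size=(8, 6))
    cfg = VAEConfig(
        variant=variant, latent_dim=3, hidden_dim=5, encoder_batch_norm=True,
        beta=0.7, lam=2.0, sigmoid_output=sigmoid, seed=1,
    )
    model = VAEModel(cfg, 6)
    eps = rng.standard_normal((8, 3))
    prior = rng.standard_normal((8, 3)) if variant == "mmd" else None
    _, _, _, grads = _backward(model, X, eps, prior)
    for key, P in model.params.items():
        for flat in range(min(P.size, 4)):
            idx = np.unravel_index(flat, P.shape)
            h = 1e-6
            old = P[idx]
            P[idx] = old + h
            tp = _backward(model, X, eps, prior)[0]
            P[idx] = old - h
            tm = _backward(model, X, eps, prior)[0]
            P[idx] = old
            num = (tp - tm) / (2 * h)
            assert grads[key][idx] == pytest.approx(num, rel=1e-4, abs=1e-7), key


def test_mmd_gradient_matches_finite_differences():
    rng = np.random.default_rng(7)
    z = rng.standard_normal((5, 3))
    p = rng.standard_normal((7, 3))
    val, grad = _mmd_value_and_grad(z, p, [1.0, 3.0])
    assert val == pytest.approx(mmd_rbf(z, p, [1.0, 3.0]), abs=1e-12)
    for i in range(5):
        for j in range(3):
            h = 1e-6
            z[i, j] += h
            vp = mmd_rbf(z, p, [1.0, 3.0])
            z[i, j] -= 2 * h
            vm = mmd_rbf(z, p, [1.0, 3.0])
            z[i, j] += h
            assert grad[i, j] == pytest.approx((vp - vm) / (2 * h), rel=1e-4, abs=1e-9)


# ----------------------------------------------------------------------
# training contract


def test_training_deterministic_per_seed():
    rng = np.random.default_rng(8)
    X = rng.uniform(size=(120, 10))
    cfg = VAEConfig(variant="mmd", latent_dim=4, hidden_dim=8, epochs=6,
                    batch_size=32, lam=100.0, seed=13)
    a = train_vae(X, X[:20], cfg)
    b = train_vae(X, X[:20], cfg)
    np.testing.assert_array_equal(
        a.history["train_total"].to_numpy(), b.history["train_total"].to_numpy()
    )
    np.testing.assert_array_equal(
        a.history["val_total"].to_numpy(), b.history["val_total"].to_numpy()
    )
    assert len(a.history) == 6


def test_training_beats_pca_bound_on_linear_data():
    """Noise-free rank-3 linear data, k = 10: reconstruction must land well
    below the data variance (PCA with 3 components reconstructs exactly, so
    a 10-dim VAE has no excuse for >10% of the variance)."""
    rng = np.random.default_rng(9)
    W = rng.normal(size=(3, 20))
    X = 0.5 + rng.standard_normal((400, 3)) @ W * 0.1
    cfg = VAEConfig(variant="beta", beta=0.001, latent_dim=10, hidden_dim=32,
                    epochs=100, batch_size=64, encoder_batch_norm=False,
                    learning_rate=3e-3, seed=3)
    model = train_vae(X, None, cfg)
    _, recon = encode_decode(model, X)
    mse = ((recon - X) ** 2).mean()
    data_var = X.var(axis=0).mean()
    assert mse < 0.1 * data_var


def test_training_loss_decreasing_trend():
    rng = np.random.default_rng(10)
    W = rng.normal(size=(4, 16))
    X = rng.standard_normal((300, 4)) @ W * 0.1
    cfg = VAEConfig(variant="vanilla", latent_dim=6, hidden_dim=16, epochs=20,
                    batch_size=50, seed=1)
    hist = train_vae(X, None, cfg).history["train_total"]
    assert np.median(hist[-5:]) < np.median(hist[:5])


# ----------------------------------------------------------------------
# encode/decode/simulate


def test_encode_decode_shapes_and_modes(trained_mmd, default_screen):
    _, norm, _ = default_screen
    z, recon = encode_decode(trained_mmd, norm, mode="mean")
    assert z.shape == (norm.n_samples, 10)
    assert recon.shape == norm.features.shape
    z2, _ = encode_decode(trained_mmd, norm, mode="mean")
    np.testing.assert_array_equal(z, z2)  # deterministic
    zs, _ = encode_decode(trained_mmd, norm, mode="sample", seed=1)
    assert not np.allclose(z, zs)
    with pytest.raises(ValueError):
        encode_decode(trained_mmd, norm.features[:, :5])


def test_simulate_profiles_contract(trained_mmd):
    sim = simulate_profiles(trained_mmd, 7, seed=2)
    assert sim.shape == (7, trained_mmd.n_features)
    np.testing.assert_array_equal(sim, simulate_profiles(trained_mmd, 7, seed=2))
    with pytest.raises(ValueError):
        simulate_profiles(trained_mmd, 0)


def test_simulated_mean_matches_prior_center():
    """Decoding 10,000 prior draws through a linear (PCA) decoder: the mean
    decoded profile converges to the training mean (z has mean ~0 per dim)."""
    rng = np.random.default_rng(11)
    X = rng.normal(size=(200, 6))
    model = pca_baseline(X, n_components=3)
    sim = simulate_profiles(model, 10_000, seed=3)
    np.testing.assert_allclose(sim.mean(axis=0), X.mean(axis=0), atol=0.05)


# ----------------------------------------------------------------------
# PCA baseline


def test_pca_full_rank_identity_and_centering():
    rng = np.random.default_rng(12)
    X = rng.normal(size=(30, 5))
    model = pca_baseline(X, n_components=5)
    z, _ = model.encode(X)
    np.testing.assert_allclose(model.decode(z), X, atol=1e-8)
    zm, _ = model.encode(X.mean(axis=0))
    np.testing.assert_allclose(zm, 0, atol=1e-8)


def test_pca_truncation_error_equals_trailing_eigenvalues():
    rng = np.random.default_rng(13)
    X = rng.normal(size=(5, 3))
    evals = np.linalg.eigvalsh(np.cov(X.T, ddof=1))[::-1]  # oracle eigendecomposition
    model = pca_baseline(X, n_components=1)
    z, recon = encode_decode(model, X)
    per_sample_sq = ((recon - X) ** 2).sum(axis=1)
    # mean squared residual (ddof 1) = sum of the truncated eigenvalues
    assert per_sample_sq.sum() / (5 - 1) == pytest.approx(evals[1:].sum(), rel=1e-10)


def test_pca_too_many_components_errors():
    with pytest.raises(ValueError):
        pca_baseline(np.random.default_rng(0).normal(size=(4, 3)), n_components=5)


def test_sampling_from_pca_posterior_is_an_error():
    X = np.random.default_rng(1).normal(size=(20, 4))
    model = pca_baseline(X, 2)
    with pytest.raises(ValueError, match="no posterior"):
        encode_decode(model, X, mode="sample")
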