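"""Generative models on tabular profiles: three VAE variants and a PCA baseline.

All models share one encoder/decoder contract (:class:`TrainedGenerativeModel`)
so calibration, latent interpretation and latent-space arithmetic run
unchanged on any of them.

The VAEs are two-layer networks (one hidden layer each in encoder and
decoder, LeakyReLU activations, optional encoder batch-norm) trained with
Adam on

    loss = MSE(x, x_hat)  +  regularizer

where MSE is summed over features and averaged over the batch, and the
regularizer is

* vanilla VAE:  KL(q(z|x) || N(0, I))             (beta = 1)
* beta-VAE:     beta * KL(q(z|x) || N(0, I))
* MMD-VAE:      lambda * MMD(z_batch, prior sample)

KL pushes each sample's posterior toward the unit-Gaussian prior; MMD (an
InfoVAE-style regularizer) only pushes the aggregated latent distribution
toward the prior, which lets individual codes keep more information.  The
networks and their gradients are implemented directly in numpy; gradient
correctness is pinned by finite-difference tests.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from typing import Sequence

import numpy as np
import pandas as pd
from sklearn.decomposition import PCA

from .profiles import ProfileTable

_LEAKY_SLOPE = 0.01
_BN_EPS = 1e-5


class TrainingDivergedError(RuntimeError):
    """Raised when a loss becomes non-finite; carries the partial history."""

    def __init__(self, message: str, history: pd.DataFrame):
        super().__init__(message)
        self.history = history


# ----------------------------------------------------------------------
# Config


@dataclass
class VAEConfig:
    """Hyperparameters for one VAE run.

    Defaults follow the consensus-signature (level 5) setting: latent
    dimension 10, hidden width 250 (about half the morphology feature count;
    use 500 for the 978-gene expression tables), learning rate 1e-3, batch
    size 96, encoder batch-norm on.  ``beta`` applies to vanilla/beta
    variants (vanilla is beta = 1); ``lam`` to the MMD variant.  The MMD
    kernel is a sum of RBF kernels with the listed bandwidths, each scaled
    by the latent dimension.
    """

    variant: str = "beta"  # {vanilla, beta, mmd}
    latent_dim: int = 10
    hidden_dim: int = 250
    learning_rate: float = 1e-3
    batch_size: int = 96
    epochs: int = 50
    encoder_batch_norm: bool = True
    beta: float = 1.0
    lam: float = 1000.0
    mmd_bandwidths: tuple[float, ...] = (1.0, 2.0, 4.0, 8.0, 16.0)
    sigmoid_output: bool = False
    seed: int = 0

    def __post_init__(self) -> None:
        if self.variant not in {"vanilla", "beta", "mmd"}:
            raise ValueError(f"unknown variant {self.variant!r}")
        if self.beta < 0 or self.lam < 0:
            raise ValueError("beta and lambda must be non-negative")
        if self.latent_dim < 1:
            raise ValueError("latent_dim must be >= 1")

    @property
    def effective_beta(self) -> float:
        return 1.0 if self.variant == "vanilla" else self.beta


# ----------------------------------------------------------------------
# Loss primitives


def kl_gaussian(mu: np.ndarray, logvar: np.ndarray) -> float:
    """KL divergence of N(mu, diag(exp(logvar))) from the unit Gaussian.

    Summed over latent dimensions; for a batch (2-D input) the per-sample
    KLs are averaged.  Always >= 0, and 0 iff mu = 0 and logvar = 0.
    """
    mu = np.asarray(mu, dtype=float)
    logvar = np.asarray(logvar, dtype=float)
    if not (np.isfinite(mu).all() and np.isfinite(logvar).all()):
        raise ValueError("non-finite input to kl_gaussian")
    per = 0.5 * (mu**2 + np.exp(logvar) - 1.0 - logvar).sum(axis=-1)
    return float(per if per.ndim == 0 else per.mean())


def _sq_dists(a: np.ndarray, b: np.ndarray) -> np.ndarray:
    d = a[:, None, :] - b[None, :, :]
    return np.einsum("ijk,ijk->ij", d, d)


def _multi_rbf(d2: np.ndarray, bandwidths: Sequence[float]) -> np.ndarray:
    k = np.zeros_like(d2)
    for h in bandwidths:
        k += np.exp(-d2 / (2.0 * h))
    return k


def mmd_rbf(
    sample_a: np.ndarray,
    sample_b: np.ndarray,
    bandwidths: Sequence[float] = (1.0,),
) -> float:
    """Biased (V-statistic) squared maximum mean discrepancy.

    Uses a sum of RBF kernels ``exp(-||x - y||^2 / (2 h))`` over the given
    bandwidths ``h``:

        MMD^2 = mean k(a, a') + mean k(b, b') - 2 mean k(a, b)

    The biased estimator is non-negative and is 0 for identical samples.
    """
    a = np.atleast_2d(np.asarray(sample_a, dtype=float))
    b = np.atleast_2d(np.asarray(sample_b, dtype=float))
    if a.shape[0] == 0 or b.shape[0] == 0:
        raise ValueError("mmd_rbf requires nonempty samples")
    if a.shape[1] != b.shape[1]:
        raise ValueError("dimension mismatch between samples")
    kaa = _multi_rbf(_sq_dists(a, a), bandwidths).mean()
    kbb = _multi_rbf(_sq_dists(b, b), bandwidths).mean()
    kab = _multi_rbf(_sq_dists(a, b), bandwidths).mean()
    return float(kaa + kbb - 2.0 * kab)


def _mmd_value_and_grad(
    z: np.ndarray, prior: np.ndarray, bandwidths: Sequence[float]
) -> tuple[float, np.ndarray]:
    """MMD^2(z, prior) and its gradient with respect to z (analytic)."""
    n, m = z.shape[0], prior.shape[0]
    d2_zz = _sq_dists(z, z)
    d2_zp = _sq_dists(z, prior)
    d2_pp = _sq_dists(prior, prior)
    k_zz = _multi_rbf(d2_zz, bandwidths)
    k_zp = _multi_rbf(d2_zp, bandwidths)
    value = k_zz.mean() + _multi_rbf(d2_pp, bandwidths).mean() - 2.0 * k_zp.mean()
    # dk/dz_i for each kernel carries a factor -1/h; accumulate k/h weights.
    w_zz = np.zeros_like(d2_zz)
    w_zp = np.zeros_like(d2_zp)
    for h in bandwidths:
        w_zz += np.exp(-d2_zz / (2.0 * h)) / h
        w_zp += np.exp(-d2_zp / (2.0 * h)) / h
    # d/dz_i of the z-z term: 2 sum_j w_ij (z_j - z_i), via dk/dz_i = -(z_i - z_j)/h * k.
    grad = (2.0 / n**2) * (w_zz @ z - w_zz.sum(axis=1, keepdims=True) * z)
    grad += (2.0 / (n * m)) * (w_zp.sum(axis=1, keepdims=True) * z - w_zp @ prior)
    return float(value), grad


# ----------------------------------------------------------------------
# Model contract


class TrainedGenerativeModel:
    """Encoder/decoder contract shared by the VAEs and the PCA baseline."""

    config: object
    history: pd.DataFrame
    n_features: int
    latent_dim: int
    tag: str

    def encode(self, x: np.ndarray) -> tuple[np.ndarray, np.ndarray | None]:
        """Return (mu, logvar); logvar is None for deterministic models."""
        raise NotImplementedError

    def decode(self, z: np.ndarray) -> np.ndarray:
        raise NotImplementedError


def _leaky(x: np.ndarray) -> np.ndarray:
    return np.where(x > 0, x, _LEAKY_SLOPE * x)


def _leaky_grad(x: np.ndarray) -> np.ndarray:
    return np.where(x > 0, 1.0, _LEAKY_SLOPE)


class VAEModel(TrainedGenerativeModel):
    """A trained two-layer VAE (numpy parameters)."""

    def __init__(self, config: VAEConfig, n_features: int):
        self.config = config
        self.n_features = n_features
        self.latent_dim = config.latent_dim
        self.tag = config.variant
        self.history = pd.DataFrame()
        rng = np.random.default_rng(np.random.SeedSequence([config.seed, 0]))
        H, k, F = config.hidden_dim, config.latent_dim, n_features

        def glorot(fan_in: int, fan_out: int) -> np.ndarray:
            limit = np.sqrt(6.0 / (fan_in + fan_out))
            return rng.uniform(-limit, limit, size=(fan_in, fan_out))

        self.params: dict[str, np.ndarray] = {
            "W_enc": glorot(F, H),
            "b_enc": np.zeros(H),
            "W_mu": glorot(H, k),
            "b_mu": np.zeros(k),
            "W_lv": glorot(H, k),
            "b_lv": np.zeros(k),
            "W_dec": glorot(k, H),
            "b_dec": np.zeros(H),
            "W_out": glorot(H, F),
            "b_out": np.zeros(F),
        }
        if config.encoder_batch_norm:
            self.params["bn_gamma"] = np.ones(H)
            self.params["bn_beta"] = np.zeros(H)
        self.bn_running_mean = np.zeros(H)
        self.bn_running_var = np.ones(H)

    # -- forward pieces -------------------------------------------------
    def _encode_cache(self, x: np.ndarray, training: bool) -> dict[str, np.ndarray]:
        p = self.params
        u = x @ p["W_enc"] + p["b_enc"]
        cache: dict[str, np.ndarray] = {"x": x, "u": u}
        if self.config.encoder_batch_norm:
            if training:
                mean = u.mean(axis=0)
                var = u.var(axis=0)
                self.bn_running_mean = 0.9 * self.bn_running_mean + 0.1 * mean
                self.bn_running_var = 0.9 * self.bn_running_var + 0.1 * var
            else:
                mean, var = self.bn_running_mean, self.bn_running_var
            std = np.sqrt(var + _BN_EPS)
            u_hat = (u - mean) / std
            a = p["bn_gamma"] * u_hat + p["bn_beta"]
            cache.update(u_hat=u_hat, std=std, a=a)
        else:
            a = u
            cache["a"] = a
        h = _leaky(a)
        cache["h"] = h
        cache["mu"] = h @ p["W_mu"] + p["b_mu"]
        cache["logvar"] = np.clip(h @ p["W_lv"] + p["b_lv"], -15.0, 15.0)
        return cache

    def _decode_cache(self, z: np.ndarray) -> dict[str, np.ndarray]:
        p = self.params
        g_pre = z @ p["W_dec"] + p["b_dec"]
        g = _leaky(g_pre)
        out_pre = g @ p["W_out"] + p["b_out"]
        x_hat = 1.0 / (1.0 + np.exp(-out_pre)) if self.config.sigmoid_output else out_pre
        return {"z": z, "g_pre": g_pre, "g": g, "out_pre": out_pre, "x_hat": x_hat}

    # -- public contract ------------------------------------------------
    def encode(self, x: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
        x = np.atleast_2d(np.asarray(x, dtype=float))
        if x.shape[1] != self.n_features:
            raise ValueError(
                f"expected {self.n_features} features, got {x.shape[1]}"
            )
        c = self._encode_cache(x, training=False)
        return c["mu"], c["logvar"]

    def decode(self, z: np.ndarray) -> np.ndarray:
        z = np.atleast_2d(np.asarray(z, dtype=float))
        if z.shape[1] != self.latent_dim:
            raise ValueError(f"expected latent dim {self.latent_dim}, got {z.shape[1]}")
        return self._decode_cache(z)["x_hat"]


class PCAModel(TrainedGenerativeModel):
    """PCA wearing the generative-model contract.

    encode = centered projection onto the top components (logvar None);
    decode = inverse transform.  With as many components as features this is
    the identity, which several exactness tests rely on.
    """

    def __init__(self, pca: PCA, n_features: int):
        self._pca = pca
        self.config = {"n_components": pca.n_components_}
        self.n_features = n_features
        self.latent_dim = pca.n_components_
        self.tag = "pca"
        self.history = pd.DataFrame()

    def encode(self, x: np.ndarray) -> tuple[np.ndarray, None]:
        x = np.atleast_2d(np.asarray(x, dtype=float))
        if x.shape[1] != self.n_features:
            raise ValueError(f"expected {self.n_features} features, got {x.shape[1]}")
        return self._pca.transform(x), None

    def decode(self, z: np.ndarray) -> np.ndarray:
        z = np.atleast_2d(np.asarray(z, dtype=float))
        return self._pca.inverse_transform(z)


class IdentityModel(TrainedGenerativeModel):
    """The original-feature-space 'model': encode = decode = identity.

    Serves as the no-dimensionality-reduction baseline for latent-space
    arithmetic.
    """

    def __init__(self, n_features: int):
        self.config = {}
        self.n_features = n_features
        self.latent_dim = n_features
        self.tag = "original-space"
        self.history = pd.DataFrame()

    def encode(self, x: np.ndarray) -> tuple[np.ndarray, None]:
        return np.atleast_2d(np.asarray(x, dtype=float)), None

    def decode(self, z: np.ndarray) -> np.ndarray:
        return np.atleast_2d(np.asarray(z, dtype=float))


# ----------------------------------------------------------------------
# Loss


def vae_loss(
    batch: np.ndarray,
    model: VAEModel,
    config: VAEConfig,
    rng: np.random.Generator | None = None,
) -> tuple[float, float, float]:
    """(total, reconstruction, regularization) for one batch, no training.

    Reconstruction is MSE summed over features and averaged over the batch.
    For KL variants the regularizer is beta * KL; for the MMD variant it is
    lambda * MMD between the reparameterized latent batch and an equal-size
    fresh draw from the prior.  ``rng`` seeds the reparameterization noise
    and the prior sample (defaults to a fixed stream, making the call
    deterministic).
    """
    batch = np.atleast_2d(np.asarray(batch, dtype=float))
    if batch.shape[0] == 0:
        raise ValueError("empty batch")
    rng = rng or np.random.default_rng(0)
    enc = model._encode_cache(batch, training=False)
    mu, logvar = enc["mu"], enc["logvar"]
    eps = rng.standard_normal(mu.shape)
    z = mu + np.exp(0.5 * logvar) * eps
    x_hat = model._decode_cache(z)["x_hat"]
    recon = float(((x_hat - batch) ** 2).sum(axis=1).mean())
    if config.variant == "mmd":
        prior = rng.standard_normal(z.shape)
        bandwidths = [h * config.latent_dim for h in config.mmd_bandwidths]
        reg = config.lam * mmd_rbf(z, prior, bandwidths)
    else:
        reg = config.effective_beta * kl_gaussian(mu, logvar)
    total = recon + reg
    if not np.isfinite(total):
        raise TrainingDivergedError("non-finite loss", model.history)
    return total, recon, reg


# ----------------------------------------------------------------------
# Training


class _Adam:
    def __init__(self, params: dict[str, np.ndarray], lr: float):
        self.lr = lr
        self.t = 0
        self.m = {k: np.zeros_like(v) for k, v in params.items()}
        self.v = {k: np.zeros_like(v) for k, v in params.items()}

    def step(self, params: dict[str, np.ndarray], grads: dict[str, np.ndarray]) -> None:
        self.t += 1
        b1, b2, eps = 0.9, 0.999, 1e-8
        for key, g in grads.items():
            self.m[key] = b1 * self.m[key] + (1 - b1) * g
            self.v[key] = b2 * self.v[key] + (1 - b2) * g * g
            m_hat = self.m[key] / (1 - b1**self.t)
            v_hat = self.v[key] / (1 - b2**self.t)
            params[key] -= self.lr * m_hat / (np.sqrt(v_hat) + eps)


def _backward(
    model: VAEModel,
    batch: np.ndarray,
    eps: np.ndarray,
    prior: np.ndarray | None,
) -> tuple[float, float, float, dict[str, np.ndarray]]:
    """One forward/backward pass; returns losses and parameter gradients."""
    cfg = model.config
    p = model.params
    n = batch.shape[0]
    enc = model._encode_cache(batch, training=True)
    mu, logvar, h = enc["mu"], enc["logvar"], enc["h"]
    std = np.exp(0.5 * logvar)
    z = mu + std * eps
    dec = model._decode_cache(z)
    x_hat = dec["x_hat"]

    recon = float(((x_hat - batch) ** 2).sum(axis=1).mean())
    if cfg.variant == "mmd":
        assert prior is not None
        bandwidths = [h_ * cfg.latent_dim for h_ in cfg.mmd_bandwidths]
        mmd_val, mmd_grad_z = _mmd_value_and_grad(z, prior, bandwidths)
        reg = cfg.lam * mmd_val
    else:
        reg = cfg.effective_beta * kl_gaussian(mu, logvar)
    total = recon + reg

    grads: dict[str, np.ndarray] = {}
    # decoder
    d_xhat = 2.0 * (x_hat - batch) / n
    d_outpre = d_xhat * x_hat * (1 - x_hat) if cfg.sigmoid_output else d_xhat
    grads["W_out"] = dec["g"].T @ d_outpre
    grads["b_out"] = d_outpre.sum(axis=0)
    d_g = d_outpre @ p["W_out"].T
    d_gpre = d_g * _leaky_grad(dec["g_pre"])
    grads["W_dec"] = z.T @ d_gpre
    grads["b_dec"] = d_gpre.sum(axis=0)
    d_z = d_gpre @ p["W_dec"].T
    if cfg.variant == "mmd":
        d_z = d_z + cfg.lam * mmd_grad_z
    # reparameterization
    d_mu = d_z.copy()
    d_logvar = d_z * 0.5 * std * eps
    if cfg.variant != "mmd":
        b = cfg.effective_beta
        d_mu += b * mu / n
        d_logvar += b * 0.5 * (np.exp(logvar) - 1.0) / n
    grads["W_mu"] = h.T @ d_mu
    grads["b_mu"] = d_mu.sum(axis=0)
    grads["W_lv"] = h.T @ d_logvar
    grads["b_lv"] = d_logvar.sum(axis=0)
    d_h = d_mu @ p["W_mu"].T + d_logvar @ p["W_lv"].T
    d_a = d_h * _leaky_grad(enc["a"])
    if cfg.encoder_batch_norm:
        u_hat, bn_std = enc["u_hat"], enc["std"]
        grads["bn_gamma"] = (d_a * u_hat).sum(axis=0)
        grads["bn_beta"] = d_a.sum(axis=0)
        d_uhat = d_a * p["bn_gamma"]
        d_u = (
            d_uhat - d_uhat.mean(axis=0) - u_hat * (d_uhat * u_hat).mean(axis=0)
        ) / bn_std
    else:
        d_u = d_a
    grads["W_enc"] = batch.T @ d_u
    grads["b_enc"] = d_u.sum(axis=0)
    return total, recon, reg, grads


def _as_matrix(data: ProfileTable | np.ndarray) -> np.ndarray:
    if isinstance(data, ProfileTable):
        return data.features
    return np.atleast_2d(np.asarray(data, dtype=float))


def train_vae(
    train: ProfileTable | np.ndarray,
    val: ProfileTable | np.ndarray | None,
    config: VAEConfig,
) -> VAEModel:
    """Train a VAE variant; deterministic for a given ``config.seed``.

    Per-epoch train and validation losses (reconstruction, regularization,
    total) are recorded in ``model.history``.  Validation reconstruction
    uses the posterior mean (no sampling noise) and, for the MMD variant, a
    prior sample fixed at the start of training, so validation curves are
    comparable across epochs.  A non-finite loss raises
    :class:`TrainingDivergedError` carrying the history so calibration can
    classify the run as unstable.
    """
    X = _as_matrix(train)
    Xval = _as_matrix(val) if val is not None else None
    model = VAEModel(config, X.shape[1])
    ss = np.random.SeedSequence([config.seed, 1])
    shuffle_rng, eps_rng, prior_rng, val_rng = (
        np.random.default_rng(c) for c in ss.spawn(4)
    )
    opt = _Adam(model.params, config.learning_rate)
    n = X.shape[0]
    bs = min(config.batch_size, n)
    # fixed validation noise/prior draws, so val curves are comparable across epochs
    if Xval is not None:
        val_eps = val_rng.standard_normal((len(Xval), config.latent_dim))
        val_prior = (
            val_rng.standard_normal((min(len(Xval), 2048), config.latent_dim))
            if config.variant == "mmd"
            else None
        )
    records = []
    for epoch in range(config.epochs):
        order = shuffle_rng.permutation(n)
        tots, recs, regs = [], [], []
        for start in range(0, n - bs + 1, bs):
            batch = X[order[start : start + bs]]
            eps = eps_rng.standard_normal((batch.shape[0], config.latent_dim))
            prior = (
                prior_rng.standard_normal((batch.shape[0], config.latent_dim))
                if config.variant == "mmd"
                else None
            )
            total, recon, reg, grads = _backward(model, batch, eps, prior)
            if not np.isfinite(total):
                model.history = pd.DataFrame(records)
                raise TrainingDivergedError(
                    f"non-finite loss at epoch {epoch}, batch {start // bs}",
                    model.history,
                )
            opt.step(model.params, grads)
            tots.append(total)
            recs.append(recon)
            regs.append(reg)
        row = {
            "epoch": epoch,
            "train_total": float(np.mean(tots)),
            "train_recon": float(np.mean(recs)),
            "train_reg": float(np.mean(regs)),
        }
        if Xval is not None:
            mu, logvar = model.encode(Xval)
            z_val = mu + np.exp(0.5 * logvar) * val_eps
            x_hat = model.decode(z_val)
            vrec = float(((x_hat - Xval) ** 2).sum(axis=1).mean())
            if config.variant == "mmd":
                bandwidths = [h * config.latent_dim for h in config.mmd_bandwidths]
                vreg = config.lam * mmd_rbf(
                    z_val[: val_prior.shape[0]], val_prior, bandwidths
                )
            else:
                vreg = config.effective_beta * kl_gaussian(mu, logvar)
            row.update(
                val_total=vrec + vreg, val_recon=vrec, val_reg=float(vreg)
            )
            if not np.isfinite(row["val_total"]):
                model.history = pd.DataFrame(records + [row])
                raise TrainingDivergedError(
                    f"non-finite validation loss at epoch {epoch}", model.history
                )
        records.append(row)
    model.history = pd.DataFrame(records)
    return model


# ----------------------------------------------------------------------
# Inference helpers


def encode_decode(
    model: TrainedGenerativeModel,
    table: ProfileTable | np.ndarray,
    mode: str = "mean",
    seed: int = 0,
) -> tuple[np.ndarray, np.ndarray]:
    """Encode a table and decode it back; returns (latents, reconstructions).

    ``mode='mean'`` (the default, and what every downstream analysis uses)
    encodes with the posterior mean and is deterministic; ``mode='sample'``
    draws z ~ N(mu, sigma^2) and only applies to VAEs.
    """
    X = _as_matrix(table)
    mu, logvar = model.encode(X)
    if mode == "mean":
        z = mu
    elif mode == "sample":
        if logvar is None:
            raise ValueError(f"{model.tag} model has no posterior to sample")
        rng = np.random.default_rng(seed)
        z = mu + np.exp(0.5 * logvar) * rng.standard_normal(mu.shape)
    else:
        raise ValueError(f"unknown mode {mode!r}")
    return z, model.decode(z)


def simulate_profiles(
    model: TrainedGenerativeModel, n: int, seed: int = 0
) -> np.ndarray:
    """Decode n draws from the unit-Gaussian prior; reproducible per seed."""
    if n <= 0:
        raise ValueError("n must be positive")
    rng = np.random.default_rng(seed)
    z = rng.standard_normal((n, model.latent_dim))
    return model.decode(z)


def pca_baseline(
    train: ProfileTable | np.ndarray, n_components: int = 10
) -> PCAModel:
    """Fit the PCA baseline under the shared generative-model contract."""
    X = _as_matrix(train)
    if n_components > min(X.shape):
        raise ValueError(
            f"n_components={n_components} exceeds min(n_samples, n_features)={min(X.shape)}"
        )
    pca = PCA(n_components=n_components, svd_solver="full")
    pca.fit(X)
    return PCAModel(pca, X.shape[1])
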