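"""Shared fixtures: small synthetic screens and trained models."""

import numpy as np
import pandas as pd
import pytest

from morphvae import (
    ProfileTable,
    VAEConfig,
    generate_profiles,
    generate_spec,
    normalize_zero_one,
    train_vae,
)


def make_table(X, names=None, moas=None, compounds=None, level="level4", plates=None):
    """Hand-build a ProfileTable from a matrix and optional annotations."""
    X = np.atleast_2d(np.asarray(X, dtype=float))
    n, f = X.shape
    names = names or [f"Cells_Intensity_DNA_{i:03d}" for i in range(f)]
    moas = moas if moas is not None else [()] * n
    compounds = compounds if compounds is not None else [f"cpd{i}" for i in range(n)]
    meta = pd.DataFrame(
        {
            "compound_id": compounds,
            "dose": 1.0,
            "plate": plates if plates is not None else "plate_0",
            "well": [f"w{i}" for i in range(n)],
            "moa": [tuple(m) for m in moas],
            "is_dmso": [str(c).upper() == "DMSO" for c in compounds],
        }
    )
    return ProfileTable(X, names, meta, level)


@pytest.fixture(scope="session")
def noise_free_spec():
    return generate_spec({"noise_sd": 0.0, "plate_effect_sd": 0.0}, seed=21)


@pytest.fixture(scope="session")
def noise_free_table(noise_free_spec):
    return generate_profiles(noise_free_spec)


@pytest.fixture(scope="session")
def default_screen():
    """One default synthetic screen, 0-1 normalized, with its spec."""
    spec = generate_spec({}, seed=100)
    table = generate_profiles(spec)
    norm, record = normalize_zero_one(table)
    return spec, norm, record


@pytest.fixture(scope="session")
def trained_mmd(default_screen):
    """An MMD-VAE trained on the default screen (shared across tests)."""
    _, norm, _ = default_screen
    cfg = VAEConfig(
        variant="mmd", latent_dim=10, hidden_dim=120, epochs=50,
        batch_size=96, lam=1000.0, seed=0,
    )
    return train_vae(norm, None, cfg)
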