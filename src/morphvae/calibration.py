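"""Regularizer-strength calibration for the beta- and MMD-VAEs.

beta is chosen by simulation fidelity: for each candidate, train a beta-VAE,
decode as many unit-Gaussian prior draws as there are training rows, and
measure the symmetric Hausdorff distance between the real and simulated
point clouds.  Too small a beta entangles the latent space (prior draws
decode off-manifold); too large a beta collapses the posterior (simulations
lose data modes); an intermediate beta minimizes the distance.

lambda (MMD weight) barely moves simulation fidelity, so it is instead
chosen as the largest candidate whose training curve stays stable: the
relative spread (max - min) / median of the total training loss over the
last few epochs must stay below a tolerance.
"""

from __future__ import annotations

from dataclasses import dataclass, replace
from typing import Sequence

import numpy as np
import pandas as pd
from scipy.spatial.distance import directed_hausdorff

from .models import (
    TrainingDivergedError,
    VAEConfig,
    simulate_profiles,
    train_vae,
)
from .profiles import ProfileTable


@dataclass
class CalibrationReport:
    """Grid-search record: candidate values, their metric, and the winner."""

    parameter: str  # "beta" or "lambda"
    grid: list[float]
    metric: list[float]  # Hausdorff distance or stability score (inf = diverged)
    selected: float
    seeds: list[int]

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame({self.parameter: self.grid, "metric": self.metric})

    def to_json_dict(self) -> dict:
        return {
            "parameter": self.parameter,
            "grid": self.grid,
            "metric": self.metric,
            "selected": self.selected,
            "seeds": self.seeds,
        }


def hausdorff_distance(set_a: np.ndarray, set_b: np.ndarray) -> float:
    """Symmetric Hausdorff distance between two point sets (Euclidean).

    max( max_a min_b d(a,b), max_b min_a d(b,a) ), computed exactly.
    """
    a = np.atleast_2d(np.asarray(set_a, dtype=float))
    b = np.atleast_2d(np.asarray(set_b, dtype=float))
    if a.shape[0] == 0 or b.shape[0] == 0:
        raise ValueError("hausdorff_distance requires nonempty sets")
    if a.shape[1] != b.shape[1]:
        raise ValueError("dimension mismatch between point sets")
    return float(max(directed_hausdorff(a, b)[0], directed_hausdorff(b, a)[0]))


def beta_sweep_config(n_features: int, seed: int = 0, bounded_data: bool = True) -> VAEConfig:
    """The fixed settings held constant while sweeping beta.

    For 0-1-normalized (bounded) data the decoder uses a sigmoid output so
    prior draws decode into the data cube; with an unbounded linear output
    the max-based Hausdorff metric is dominated by a few off-scale decodes
    and degenerates toward favoring posterior collapse.
    """
    return VAEConfig(
        variant="beta",
        latent_dim=50,
        hidden_dim=max(50, n_features // 2),
        learning_rate=1e-3,
        encoder_batch_norm=True,
        batch_size=128,
        epochs=50,
        sigmoid_output=bounded_data,
        seed=seed,
    )


def _argmin_smallest(grid: Sequence[float], metric: Sequence[float]) -> float:
    """Argmin over the grid; ties broken toward the smaller candidate."""
    best = None
    for g, m in sorted(zip(grid, metric)):
        if best is None or m < best[1]:
            best = (g, m)
    if best is None or not np.isfinite(best[1]):
        raise RuntimeError(f"all candidate runs diverged: {dict(zip(grid, metric))}")
    return best[0]


def select_beta(
    train: ProfileTable | np.ndarray,
    beta_grid: Sequence[float],
    fixed_config: VAEConfig | None = None,
    seed: int = 0,
) -> CalibrationReport:
    """Pick beta by minimum real-vs-simulated Hausdorff distance.

    For each candidate: train with the fixed settings, simulate as many
    points as there are training rows, and measure the distance between the
    two clouds.  Diverged runs score infinity.
    """
    if len(beta_grid) == 0:
        raise ValueError("beta_grid is empty")
    X = train.features if isinstance(train, ProfileTable) else np.asarray(train, float)
    cfg = fixed_config or beta_sweep_config(X.shape[1], seed)
    metrics: list[float] = []
    for beta in beta_grid:
        run_cfg = replace(cfg, variant="beta", beta=float(beta), seed=seed)
        try:
            model = train_vae(X, None, run_cfg)
            sim = simulate_profiles(model, X.shape[0], seed=seed + 1)
            metrics.append(hausdorff_distance(X, sim))
        except TrainingDivergedError:
            metrics.append(float("inf"))
    selected = _argmin_smallest(list(beta_grid), metrics)
    return CalibrationReport("beta", list(map(float, beta_grid)), metrics, selected, [seed])


def stability_score(history: pd.DataFrame, window: int = 10) -> float:
    """(max - min) / median of the total training loss over the last epochs.

    Infinite if any of those losses is non-finite or the median is not
    positive; small values mean the curve has settled.
    """
    tail = np.asarray(history["train_total"])[-window:]
    if tail.size == 0 or not np.isfinite(tail).all():
        return float("inf")
    med = float(np.median(tail))
    if med <= 0:
        return float("inf")
    return float((tail.max() - tail.min()) / med)


def select_lambda(
    train: ProfileTable | np.ndarray,
    lambda_grid: Sequence[float],
    fixed_config: VAEConfig | None = None,
    stability_window: int = 10,
    stability_tol: float = 0.1,
    seed: int = 0,
    histories: Sequence[pd.DataFrame | None] | None = None,
) -> CalibrationReport:
    """Pick the largest lambda whose training curve is stable.

    ``histories`` lets a caller supply precomputed training histories (one
    per grid entry, None marking a diverged run) instead of retraining;
    otherwise each candidate trains an MMD-VAE here.
    """
    grid = list(map(float, lambda_grid))
    if grid != sorted(grid):
        raise ValueError("lambda_grid must be ascending")
    if not grid:
        raise ValueError("lambda_grid is empty")
    X = train.features if isinstance(train, ProfileTable) else np.asarray(train, float)
    scores: list[float] = []
    for i, lam in enumerate(grid):
        if histories is not None:
            hist = histories[i]
        else:
            cfg = fixed_config or VAEConfig(
                variant="mmd", hidden_dim=max(50, X.shape[1] // 2), seed=seed
            )
            try:
                hist = train_vae(X, None, replace(cfg, variant="mmd", lam=lam, seed=seed)).history
            except TrainingDivergedError:
                hist = None
        scores.append(float("inf") if hist is None else stability_score(hist, stability_window))
    stable = [g for g, s in zip(grid, scores) if np.isfinite(s) and s < stability_tol]
    if not stable:
        raise RuntimeError(
            f"no stable lambda in grid; stability scores: {dict(zip(grid, scores))}"
        )
    return CalibrationReport("lambda", grid, scores, max(stable), [seed])


def default_beta_grid() -> list[float]:
    """Log-spaced candidates from 1e-3 to 1e3 (13 points)."""
    return [float(f"{v:.4g}") for v in np.logspace(-3, 3, 13)]
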