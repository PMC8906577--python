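"""Reconstruction and simulation quality metrics.

Covers: held-out reconstruction MSE and per-sample earth-mover (1-D
Wasserstein) distance with 5/95 percentile range; per-feature reconstruction
error with compartment/channel group comparisons; latent correlation export;
and a 2-D UMAP overlay of original, reconstructed and simulated data.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats

from .interpretation import latent_correlation
from .models import TrainedGenerativeModel, encode_decode, simulate_profiles
from .profiles import FeatureDescriptor, ProfileTable


@dataclass
class ReconstructionReport:
    """Summary reconstruction metrics for one model on one dataset."""

    mse: float
    emd_mean: float
    emd_q05: float
    emd_q95: float
    per_feature_mse: np.ndarray
    model_tag: str
    dataset_tag: str = ""
    shuffled: bool = False

    def to_dict(self) -> dict:
        return {
            "mse": self.mse,
            "emd_mean": self.emd_mean,
            "emd_q05": self.emd_q05,
            "emd_q95": self.emd_q95,
            "model": self.model_tag,
            "dataset": self.dataset_tag,
            "shuffled": self.shuffled,
        }


def sample_emd(x: np.ndarray, x_hat: np.ndarray) -> float:
    """1-D Wasserstein-1 distance between a sample's feature-value
    distribution and its reconstruction's.

    With equal-length vectors this is the mean absolute difference of the
    sorted values.
    """
    return float(stats.wasserstein_distance(np.asarray(x), np.asarray(x_hat)))


def reconstruction_metrics(
    model: TrainedGenerativeModel,
    test: ProfileTable,
    dataset_tag: str = "",
    shuffled: bool = False,
) -> ReconstructionReport:
    """MSE and per-sample earth-mover summary on a held-out table.

    MSE averages the squared error over all samples and features.  The
    earth-mover distance is computed per sample between the original and
    reconstructed feature-value distributions; its mean and (0.05, 0.95)
    quantiles are reported.
    """
    if test.n_samples == 0:
        raise ValueError("empty test table")
    _, recon = encode_decode(model, test, mode="mean")
    err = recon - test.features
    mse = float((err**2).mean())
    per_feature = (err**2).mean(axis=0)
    emds = np.array(
        [sample_emd(test.features[i], recon[i]) for i in range(test.n_samples)]
    )
    q05, q95 = np.quantile(emds, [0.05, 0.95])
    return ReconstructionReport(
        mse, float(emds.mean()), float(q05), float(q95), per_feature,
        model.tag, dataset_tag, shuffled,
    )


def group_comparison_test(
    per_feature_mse: np.ndarray, in_group: np.ndarray
) -> dict[str, float]:
    """One-sided test that a feature group reconstructs better than the rest.

    Sample: per-feature MSE differences from the complement-group mean, for
    the features in the group; one-sample t-test with alternative 'less'.
    Skipped (NaN) for groups with fewer than 2 members, an empty complement,
    or a zero-variance difference sample.
    """
    in_group = np.asarray(in_group, dtype=bool)
    g = per_feature_mse[in_group]
    comp = per_feature_mse[~in_group]
    if g.size < 2 or comp.size == 0:
        return {"t": float("nan"), "p": float("nan"), "n": int(g.size)}
    diffs = g - comp.mean()
    if diffs.std(ddof=1) == 0:
        if np.allclose(diffs, 0):  # no signal at all: t = 0, p = 0.5
            return {"t": 0.0, "p": 0.5, "n": int(g.size)}
        return {"t": float("nan"), "p": float("nan"), "n": int(g.size)}
    res = stats.ttest_1samp(diffs, 0.0, alternative="less")
    return {"t": float(res.statistic), "p": float(res.pvalue), "n": int(g.size)}


def per_feature_reconstruction(
    model: TrainedGenerativeModel,
    test: ProfileTable,
    descriptors: list[FeatureDescriptor] | None = None,
) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Per-feature reconstruction MSE and group-vs-rest comparison tests.

    Returns (feature table, test table).  The feature table lists each
    feature's group, original-data variance and reconstruction MSE; the test
    table holds, for every compartment, channel and combined group, the
    one-sided t-test of "this group reconstructs better than its
    complement".
    """
    descriptors = descriptors or test.descriptors()
    report = reconstruction_metrics(model, test)
    mse = report.per_feature_mse
    variance = test.features.var(axis=0)
    feat = pd.DataFrame(
        {
            "feature": test.feature_names,
            "group": [d.group for d in descriptors],
            "compartment": [d.compartment for d in descriptors],
            "channel": [d.channel for d in descriptors],
            "variance": variance,
            "mse": mse,
        }
    )
    rows = []
    for kind, column in (("compartment", "compartment"), ("channel", "channel"),
                         ("group", "group")):
        for label in sorted(feat[column].unique()):
            res = group_comparison_test(mse, (feat[column] == label).to_numpy())
            rows.append({"kind": kind, "label": label, **res})
    return feat, pd.DataFrame(rows)


def embedding_overlay(
    test: ProfileTable,
    reconstructed: np.ndarray,
    simulated: np.ndarray,
    seed: int = 0,
    n_neighbors: int = 15,
    min_dist: float = 0.1,
) -> dict[str, np.ndarray]:
    """2-D UMAP fit on original test data; others transformed into it.

    Display-oriented: shows whether reconstructed and simulated points land
    on the manifold of the real data.
    """
    import umap  # deferred: numba compilation is slow

    if test.n_samples < 10:
        raise ValueError("need at least 10 samples for a meaningful embedding")
    reducer = umap.UMAP(
        n_components=2,
        n_neighbors=min(n_neighbors, test.n_samples - 1),
        min_dist=min_dist,
        random_state=seed,
    )
    original = reducer.fit_transform(test.features)
    return {
        "original": np.asarray(original),
        "reconstructed": np.asarray(reducer.transform(reconstructed)),
        "simulated": np.asarray(reducer.transform(simulated)),
    }


def export_latent_diagnostics(
    model: TrainedGenerativeModel,
    table: ProfileTable,
    csv_path=None,
    figure_path=None,
) -> np.ndarray:
    """Latent Pearson-correlation matrix, optionally written to CSV/PNG."""
    mu, _ = model.encode(table.features)
    corr = latent_correlation(mu)
    if csv_path is not None:
        labels = [f"z{j}" for j in range(corr.shape[0])]
        pd.DataFrame(corr, index=labels, columns=labels).to_csv(csv_path)
    if figure_path is not None:
        import matplotlib

        matplotlib.use("Agg")
        import matplotlib.pyplot as plt

        fig, ax = plt.subplots(figsize=(5, 4))
        im = ax.imshow(corr, vmin=-1, vmax=1, cmap="RdBu_r")
        fig.colorbar(im, ax=ax, label="Pearson r")
        ax.set_title("Latent feature correlation")
        fig.savefig(figure_path, dpi=150, bbox_inches="tight")
        plt.close(fig)
    return corr
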