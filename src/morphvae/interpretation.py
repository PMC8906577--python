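"""Latent-feature interpretation by traversal of the prior.

Because the latent prior is a unit Gaussian, setting one latent coordinate
to +3 and -3 (three prior standard deviations) while holding the others at
zero spans the realistic range of that coordinate.  The absolute difference
between the two decoded profiles says which output features that latent
coordinate drives.  Averaging those differences within each CellProfiler
feature group (compartment x channel, plus AreaShape) and normalizing each
latent column by its maximum yields a groups-by-latents contribution matrix
in which a column's brightest cell is the group that latent feature most
strongly encodes.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy.cluster.hierarchy import average, leaves_list
from scipy.spatial.distance import pdist

from .models import TrainedGenerativeModel
from .profiles import FeatureDescriptor


@dataclass
class ContributionMatrix:
    """Feature-group by latent-feature contribution scores.

    ``values`` is non-negative; after max normalization every non-degenerate
    column has maximum 1.  ``normalization`` records which scheme was applied
    ("column_max", "column_sum" or "none" when a column was all zero).
    """

    values: np.ndarray  # (n_groups, k)
    group_labels: list[str]
    normalization: str

    def to_frame(self) -> pd.DataFrame:
        cols = [f"z{j}" for j in range(self.values.shape[1])]
        return pd.DataFrame(self.values, index=self.group_labels, columns=cols)

    def clustered_order(self) -> tuple[list[int], list[int]]:
        """Row/column display order from average-linkage hierarchical clustering."""
        def order(mat: np.ndarray) -> list[int]:
            if mat.shape[0] < 3:
                return list(range(mat.shape[0]))
            return list(leaves_list(average(pdist(mat))))

        return order(self.values), order(self.values.T)


def traversal_difference(
    model: TrainedGenerativeModel, latent_index: int, magnitude: float = 3.0
) -> np.ndarray:
    """|decode(+m e_j) - decode(-m e_j)| with all other coordinates at 0."""
    k = model.latent_dim
    if not 0 <= latent_index < k:
        raise IndexError(f"latent index {latent_index} out of range for k={k}")
    z = np.zeros((1, k))
    z[0, latent_index] = magnitude
    plus = model.decode(z)[0]
    z[0, latent_index] = -magnitude
    minus = model.decode(z)[0]
    return np.abs(plus - minus)


def contribution_matrix(
    model: TrainedGenerativeModel,
    descriptors: list[FeatureDescriptor],
    magnitude: float = 3.0,
    normalization: str = "column_max",
) -> ContributionMatrix:
    """Aggregate traversal differences into a group x latent matrix.

    For each latent feature the absolute traversal difference is averaged
    over the features of each group; each latent column is then divided by
    its maximum (or its sum, with ``normalization='column_sum'``).  All-zero
    columns are left unnormalized and flagged via the normalization tag.
    """
    if len(descriptors) != model.n_features:
        raise ValueError(
            f"{len(descriptors)} descriptors for {model.n_features} features"
        )
    groups = sorted({d.group for d in descriptors})
    membership = {g: np.array([d.group == g for d in descriptors]) for g in groups}
    empty = [g for g, m in membership.items() if not m.any()]
    for g in empty:
        warnings.warn(f"feature group {g!r} is empty; dropped")
        groups.remove(g)

    k = model.latent_dim
    raw = np.zeros((len(groups), k))
    for j in range(k):
        diff = traversal_difference(model, j, magnitude)
        for gi, g in enumerate(groups):
            raw[gi, j] = diff[membership[g]].mean()

    tag = normalization
    values = raw.copy()
    col_stat = values.max(axis=0) if normalization == "column_max" else values.sum(axis=0)
    if np.all(col_stat == 0):
        tag = "none"
    else:
        nz = col_stat > 0
        values[:, nz] = values[:, nz] / col_stat[nz]
        if not nz.all():
            warnings.warn("all-zero latent column(s); left unnormalized")
    return ContributionMatrix(values, groups, tag)


def latent_correlation(latents: np.ndarray) -> np.ndarray:
    """Pearson correlation matrix of latent coordinates across samples.

    Low off-diagonal correlation indicates a disentangled latent space.
    Constant coordinates get zeroed rows/columns (with a warning) rather
    than NaNs.
    """
    Z = np.atleast_2d(np.asarray(latents, dtype=float))
    if Z.shape[0] < 2:
        raise ValueError("need at least 2 samples for correlation")
    sd = Z.std(axis=0)
    constant = sd == 0
    with np.errstate(invalid="ignore", divide="ignore"):
        corr = np.corrcoef(Z, rowvar=False)
    corr = np.atleast_2d(corr)
    np.fill_diagonal(corr, 1.0)
    if constant.any():
        warnings.warn(
            f"constant latent coordinate(s) {np.flatnonzero(constant).tolist()}; "
            "their correlations set to 0"
        )
        corr[constant, :] = 0.0
        corr[:, constant] = 0.0
    return corr
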