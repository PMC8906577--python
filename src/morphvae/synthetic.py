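"""Synthetic perturbation profiles with known additive MOA structure.

The generator emulates the structure of Cell Painting / L1000 perturbation
screens: each mechanism of action (MOA) shifts a sparse, feature-group-
confined set of morphology features away from the DMSO baseline, scaled by a
saturating dose response; polypharmacology compounds carry two MOAs whose
effects add (plus an optional interaction term); replicates sit on plates
with small plate-level offsets and Gaussian measurement noise.  Because the
effect vectors are known exactly, every downstream stage — training,
calibration, latent interpretation and latent-space arithmetic — can be
tested against analytic ground truth.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
import yaml

from .profiles import (
    CELL_PAINTING_CHANNELS,
    CELL_PAINTING_COMPARTMENTS,
    ProfileTable,
)

#: The 16 Cell Painting feature groups: 3 compartments x 5 channels + AreaShape.
FEATURE_GROUPS: tuple[str, ...] = tuple(
    f"{comp}-{chan}"
    for comp in CELL_PAINTING_COMPARTMENTS
    for chan in CELL_PAINTING_CHANNELS
) + ("Cells-AreaShape",)


def default_dose_levels() -> tuple[float, ...]:
    # 6-point, ~3.3x dilution series in uM, as used in repurposing screens
    return (0.04, 0.12, 0.37, 1.11, 3.33, 10.0)


def dose_response(dose: float) -> float:
    """Saturating response s(d) = d / (d + 1), in (0, 1] over the dose range."""
    return dose / (dose + 1.0)


@dataclass
class SyntheticSpec:
    """Full ground-truth description of a synthetic screen.

    ``effect_matrix`` has one row per single MOA; each row is nonzero only on
    the features of the 1-4 groups assigned to that MOA.  Pair compounds
    combine both members' rows additively plus ``interactions`` (default 0).
    """

    n_features: int
    feature_names: list[str]
    group_of_feature: list[str]
    baseline: np.ndarray
    single_moas: list[str]
    pairs: list[tuple[str, str]]
    effect_matrix: np.ndarray  # (n_single_moas, F)
    dose_levels: tuple[float, ...]
    n_replicates: int
    n_compounds_per_moa: int
    n_plates: int
    n_dmso_per_plate: int
    plate_effects: np.ndarray  # (n_plates, F)
    noise_sd: float
    interactions: dict[tuple[str, str], np.ndarray] = field(default_factory=dict)
    seed: int = 0

    def __post_init__(self) -> None:
        singles = set(self.single_moas)
        for a, b in self.pairs:
            if a not in singles or b not in singles:
                raise ValueError(f"pair ({a!r}, {b!r}) references an undeclared MOA")
        if self.noise_sd < 0:
            raise ValueError("noise_sd must be >= 0")

    # ------------------------------------------------------------------
    def effect_of(self, moa: str) -> np.ndarray:
        return self.effect_matrix[self.single_moas.index(moa)]

    def interaction_of(self, pair: tuple[str, str]) -> np.ndarray:
        if pair in self.interactions:
            return self.interactions[pair]
        if (pair[1], pair[0]) in self.interactions:
            return self.interactions[(pair[1], pair[0])]
        return np.zeros(self.n_features)

    def group_means(self, moas: Sequence[str], dose: float) -> np.ndarray:
        """Noise-free expected profile b + s(d) * sum of effects (+ interaction)."""
        x = self.baseline.copy()
        s = dose_response(dose)
        for m in moas:
            x = x + s * self.effect_of(m)
        if len(moas) == 2:
            x = x + self.interaction_of((moas[0], moas[1]))
        return x

    def to_yaml(self, path) -> None:
        payload = {
            "n_features": self.n_features,
            "feature_names": self.feature_names,
            "group_of_feature": self.group_of_feature,
            "baseline": self.baseline.tolist(),
            "single_moas": self.single_moas,
            "pairs": [list(p) for p in self.pairs],
            "effect_matrix": self.effect_matrix.tolist(),
            "dose_levels": list(self.dose_levels),
            "n_replicates": self.n_replicates,
            "n_compounds_per_moa": self.n_compounds_per_moa,
            "n_plates": self.n_plates,
            "n_dmso_per_plate": self.n_dmso_per_plate,
            "plate_effects": self.plate_effects.tolist(),
            "noise_sd": self.noise_sd,
            "interactions": {
                " ∩ ".join(k): v.tolist() for k, v in self.interactions.items()
            },
            "seed": self.seed,
        }
        with open(path, "w") as fh:
            yaml.safe_dump(payload, fh)


def generate_spec(config: Mapping[str, object] | None = None, seed: int = 0) -> SyntheticSpec:
    """Draw a ground-truth screen specification.

    Defaults: 120 features over the 16 Cell Painting groups, 15 single MOAs,
    5 pairs, 3 compounds per MOA, 6 doses, 5 replicates over 2 plates, noise
    SD 0.05.  Each MOA is assigned 1-4 feature groups; its effect entries on
    those groups are uniform in magnitude within ``effect_range`` with random
    signs, zero elsewhere.  Deterministic for a given seed.
    """
    cfg = dict(config or {})
    rng = np.random.default_rng(seed)
    F = int(cfg.get("n_features", 120))
    n_single = int(cfg.get("n_single_moas", 15))
    n_pairs = int(cfg.get("n_pairs", 5))
    n_compounds = int(cfg.get("n_compounds_per_moa", 3))
    n_replicates = int(cfg.get("n_replicates", 5))
    n_plates = int(cfg.get("n_plates", 2))
    n_dmso = int(cfg.get("n_dmso_per_plate", 24))
    noise_sd = float(cfg.get("noise_sd", 0.05))
    plate_sd = float(cfg.get("plate_effect_sd", 0.01))
    lo, hi = cfg.get("effect_range", (0.3, 1.0))
    dose_levels = tuple(cfg.get("dose_levels", default_dose_levels()))
    max_groups = int(cfg.get("max_groups_per_moa", 4))
    if min(F, n_single, n_compounds, n_replicates, n_plates) <= 0:
        raise ValueError("all counts must be positive")

    # Partition F features over the 16 groups, round-robin so sizes differ by <=1.
    group_of_feature = [FEATURE_GROUPS[i % len(FEATURE_GROUPS)] for i in range(F)]
    group_of_feature.sort(key=lambda g: FEATURE_GROUPS.index(g))
    feature_names = [
        f"{g.split('-')[0]}_Intensity_{g.split('-')[1]}_{i:03d}"
        if g.split("-")[1] != "AreaShape"
        else f"{g.split('-')[0]}_AreaShape_{i:03d}"
        for i, g in enumerate(group_of_feature)
    ]

    single_moas = [f"moa_{chr(ord('a') + i)}" for i in range(n_single)]
    if n_pairs > n_single // 2:
        raise ValueError("need at least two distinct singles per pair")
    pairs = [(single_moas[2 * i], single_moas[2 * i + 1]) for i in range(n_pairs)]

    baseline = rng.uniform(0.2, 0.8, size=F)
    groups = np.asarray(group_of_feature)

    # MOA effects live in a shared low-rank phenotype space: a small basis of
    # group-confined phenotype vectors, mixed with random weights per MOA.
    # This mirrors the low intrinsic dimensionality of real morphology
    # screens (a handful of latent features suffice) and means no MOA's
    # effect direction is unique to it — the property that makes leave-out
    # prediction possible at all.
    n_phenotypes = int(cfg.get("n_phenotypes", 8))
    basis = np.zeros((n_phenotypes, F))
    for b in range(n_phenotypes):
        n_groups = int(rng.integers(1, max(2, max_groups // 2) + 1))
        chosen = rng.choice(len(FEATURE_GROUPS), size=n_groups, replace=False)
        mask = np.isin(groups, [FEATURE_GROUPS[c] for c in chosen])
        basis[b, mask] = rng.uniform(lo, hi, size=mask.sum()) * rng.choice(
            [-1.0, 1.0], size=mask.sum()
        )
    E = np.zeros((n_single, F))
    for m in range(n_single):
        n_mix = int(rng.integers(1, min(2, n_phenotypes) + 1))
        which = rng.choice(n_phenotypes, size=n_mix, replace=False)
        weights = rng.uniform(0.6, 1.2, size=n_mix) * rng.choice([-1.0, 1.0], size=n_mix)
        E[m] = weights @ basis[which]

    plate_effects = rng.normal(0.0, plate_sd, size=(n_plates, F))

    interactions: dict[tuple[str, str], np.ndarray] = {}
    for key, vec in dict(cfg.get("interactions", {})).items():
        pair = tuple(key) if isinstance(key, tuple) else tuple(str(key).split(" ∩ "))
        interactions[pair] = np.asarray(vec, dtype=float)

    return SyntheticSpec(
        n_features=F,
        feature_names=feature_names,
        group_of_feature=group_of_feature,
        baseline=baseline,
        single_moas=single_moas,
        pairs=pairs,
        effect_matrix=E,
        dose_levels=dose_levels,
        n_replicates=n_replicates,
        n_compounds_per_moa=n_compounds,
        n_plates=n_plates,
        n_dmso_per_plate=n_dmso,
        plate_effects=plate_effects,
        noise_sd=noise_sd,
        interactions=interactions,
        seed=seed,
    )


def generate_profiles(spec: SyntheticSpec) -> ProfileTable:
    """Sample a level-4 replicate table from the spec.

    Each compound (annotated with one MOA or one pair) is measured at every
    dose with ``n_replicates`` replicates spread cyclically over plates;
    every plate additionally carries DMSO wells.  A profile is

        x = baseline + s(d) * sum(effects) + interaction + plate_offset + noise.
    """
    rng = np.random.default_rng(np.random.SeedSequence([spec.seed, 7]))
    treatments: list[tuple[str, tuple[str, ...]]] = []
    for m in spec.single_moas:
        for c in range(spec.n_compounds_per_moa):
            treatments.append((f"cpd_{m}_{c}", (m,)))
    for a, b in spec.pairs:
        for c in range(spec.n_compounds_per_moa):
            treatments.append((f"cpd_{a}+{b}_{c}", (a, b)))

    rows, recs = [], []
    counter = 0
    for compound, moas in treatments:
        for dose in spec.dose_levels:
            mean = spec.group_means(list(moas), dose)
            for r in range(spec.n_replicates):
                plate = counter % spec.n_plates
                counter += 1
                x = mean + spec.plate_effects[plate]
                if spec.noise_sd > 0:
                    x = x + rng.normal(0.0, spec.noise_sd, size=spec.n_features)
                rows.append(x)
                recs.append(
                    {
                        "compound_id": compound,
                        "dose": float(dose),
                        "plate": f"plate_{plate}",
                        "well": f"w{counter:05d}",
                        "moa": tuple(moas),
                        "is_dmso": False,
                    }
                )
    for plate in range(spec.n_plates):
        for w in range(spec.n_dmso_per_plate):
            x = spec.baseline + spec.plate_effects[plate]
            if spec.noise_sd > 0:
                x = x + rng.normal(0.0, spec.noise_sd, size=spec.n_features)
            counter += 1
            rows.append(x)
            recs.append(
                {
                    "compound_id": "DMSO",
                    "dose": 0.0,
                    "plate": f"plate_{plate}",
                    "well": f"w{counter:05d}",
                    "moa": (),
                    "is_dmso": True,
                }
            )
    return ProfileTable(
        np.asarray(rows), spec.feature_names, pd.DataFrame(recs), "level4"
    )


def generate_correlated_profiles(
    n_samples: int = 1500,
    n_features: int = 120,
    rank: int = 8,
    loading_sd: float = 0.12,
    noise_sd: float = 0.03,
    seed: int = 0,
) -> ProfileTable:
    """Unlabeled profiles with low-rank (factor-model) correlation structure.

    x = baseline + f @ W + noise, with f ~ N(0, I_rank).  This is the
    training control for "did the model learn between-feature correlation":
    column-shuffling such a table destroys the factor structure while
    keeping every marginal, so a model that exploits correlation trains to a
    lower loss on the real table than on its shuffled copy.  Rows carry
    placeholder metadata (no MOA annotations).
    """
    rng = np.random.default_rng(seed)
    W = rng.normal(0.0, loading_sd, size=(rank, n_features))
    baseline = rng.uniform(0.3, 0.7, size=n_features)
    X = (
        baseline
        + rng.standard_normal((n_samples, rank)) @ W
        + rng.normal(0.0, noise_sd, size=(n_samples, n_features))
    )
    names = [f"Cells_Intensity_DNA_{i:03d}" for i in range(n_features)]
    meta = pd.DataFrame(
        {
            "compound_id": [f"cpd_{i // 6}" for i in range(n_samples)],
            "dose": 1.0,
            "plate": "plate_0",
            "well": [f"w{i:05d}" for i in range(n_samples)],
            "moa": [()] * n_samples,
            "is_dmso": False,
        }
    )
    return ProfileTable(X, names, meta, "level4")


def analytic_lsa_truth(
    spec: SyntheticSpec,
    pair: tuple[str, str],
    dose_set: Sequence[float] | None = None,
) -> np.ndarray:
    """Exact expected profile of the pair, averaged over the dose set.

    This is what latent-space arithmetic should recover when MOA effects are
    additive: mean over doses of b + s(d)(E_A + E_B) + I_AB.
    """
    if tuple(pair) not in {tuple(p) for p in spec.pairs}:
        raise ValueError(f"unknown pair {pair!r}")
    doses = list(dose_set) if dose_set is not None else list(spec.dose_levels)
    profiles = [spec.group_means(list(pair), d) for d in doses]
    return np.mean(profiles, axis=0)
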