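"""Latent-space arithmetic (LSA) for polypharmacology cell-state prediction.

The hypothesis: if a compound class with mechanism "A" shifts the cell state
away from the DMSO vehicle state "D", and "B" likewise, then in a well-
structured latent space

    mean(A) - mean(D) + mean(B)  ~  mean(A ∩ B)

i.e. decoding the arithmetic combination of group-mean latent vectors
predicts the profile of compounds annotated with both mechanisms.  The
prediction is scored against the mean *raw* profile of the "A ∩ B"
compounds by L2 distance and Pearson correlation, and its significance is
assessed against a null built by shuffling all MOA labels (including DMSO)
and repeating the experiment; z = (observed - null mean) / null SD, with a
one-sided normal p-value (low tail for L2, high tail for Pearson).
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
from scipy import stats

from .models import (
    IdentityModel,
    TrainedGenerativeModel,
    VAEConfig,
    pca_baseline,
    train_vae,
)
from .profiles import ProfileTable

PAIR_SEP = " ∩ "


def pair_label(pair: tuple[str, str]) -> str:
    return PAIR_SEP.join(pair)


@dataclass
class MOAGroups:
    """Sample-index groups per retained MOA label, plus the DMSO control.

    ``singles`` maps a single-MOA label to sample indices (all doses, all
    annotated compounds); ``pairs`` maps an (A, B) tuple likewise; ``dmso``
    indexes the vehicle wells.  ``filter_report`` records every dropped
    label and why.
    """

    singles: dict[str, np.ndarray]
    pairs: dict[tuple[str, str], np.ndarray]
    dmso: np.ndarray
    filter_report: dict[str, str] = field(default_factory=dict)

    def all_pairs(self) -> list[tuple[str, str]]:
        return list(self.pairs)


def build_moa_groups(table: ProfileTable) -> MOAGroups:
    """Group samples by MOA annotation and apply the LSA filtering rules.

    Kept: every two-MOA ("A ∩ B") group; every single-MOA group whose label
    participates in at least one kept pair; the DMSO wells.  Dropped (with a
    report entry): compounds with more than two annotations, and single-MOA
    groups orphaned from every pair.
    """
    meta = table.meta
    singles_raw: dict[str, list[int]] = {}
    pairs_raw: dict[tuple[str, str], list[int]] = {}
    report: dict[str, str] = {}
    for i, (moa, is_dmso) in enumerate(zip(meta["moa"], meta["is_dmso"])):
        if is_dmso:
            continue
        moa = tuple(moa)
        if len(moa) == 0:
            continue  # unannotated, not DMSO: unusable for LSA
        if len(moa) > 2:
            report[PAIR_SEP.join(moa)] = "more than two MOA annotations"
            continue
        if len(moa) == 1:
            singles_raw.setdefault(moa[0], []).append(i)
        else:
            key = tuple(sorted(moa))
            pairs_raw.setdefault(key, []).append(i)

    if not pairs_raw:
        raise ValueError("no two-MOA groups present; LSA is undefined")
    dmso = np.flatnonzero(meta["is_dmso"].to_numpy())
    if dmso.size == 0:
        raise ValueError("no DMSO control wells present")

    in_pairs = {m for pair in pairs_raw for m in pair}
    singles: dict[str, np.ndarray] = {}
    for label, idx in singles_raw.items():
        if label in in_pairs:
            singles[label] = np.asarray(idx)
        else:
            report[label] = "single MOA without a corresponding pair"
    # keep only pairs whose both members have a single-MOA group
    pairs: dict[tuple[str, str], np.ndarray] = {}
    for pair, idx in pairs_raw.items():
        if pair[0] in singles and pair[1] in singles:
            pairs[pair] = np.asarray(idx)
        else:
            report[pair_label(pair)] = "pair lacking a single-MOA group for a member"
    if not pairs:
        raise ValueError("no pair retained after filtering; LSA is undefined")
    return MOAGroups(singles, pairs, dmso, report)


@dataclass
class LSAResult:
    """One pair's LSA prediction and its agreement with the real profile."""

    pair: tuple[str, str]
    predicted: np.ndarray  # decoded F-vector
    real: np.ndarray  # mean raw profile of "A ∩ B" samples
    l2: float
    pearson: float
    model_tag: str


@dataclass
class NullResult:
    """Shuffled-label null distribution and significance for one pair."""

    pair: tuple[str, str]
    observed_l2: float
    observed_pearson: float
    null_l2: list[float]
    null_pearson: list[float]
    z_l2: float
    z_pearson: float
    p_l2: float
    p_pearson: float
    n_shuffles: int


def _mean_latents(
    model: TrainedGenerativeModel, table: ProfileTable
) -> np.ndarray:
    mu, _ = model.encode(table.features)
    return mu


def lsa_predict(
    model: TrainedGenerativeModel,
    groups: MOAGroups,
    latents: np.ndarray,
    pair: tuple[str, str],
) -> np.ndarray:
    """decode( mean_z(A) - mean_z(DMSO) + mean_z(B) ) for the given pair."""
    a, b = pair
    if a not in groups.singles or b not in groups.singles:
        raise KeyError(f"pair {pair} lacks a single-MOA group")
    if groups.dmso.size == 0:
        raise KeyError("empty DMSO group")
    mean_a = latents[groups.singles[a]].mean(axis=0)
    mean_b = latents[groups.singles[b]].mean(axis=0)
    mean_d = latents[groups.dmso].mean(axis=0)
    return model.decode(mean_a - mean_d + mean_b)[0]


def score_prediction(
    predicted: np.ndarray, real: np.ndarray
) -> tuple[float, float]:
    """(L2 distance, Pearson correlation across features)."""
    predicted = np.asarray(predicted, dtype=float)
    real = np.asarray(real, dtype=float)
    if predicted.shape != real.shape:
        raise ValueError("profile length mismatch")
    l2 = float(np.linalg.norm(predicted - real))
    if predicted.std() == 0 or real.std() == 0:
        return l2, float("nan")
    r = float(stats.pearsonr(predicted, real).statistic)
    return l2, r


def run_lsa(
    model: TrainedGenerativeModel,
    table: ProfileTable,
    groups: MOAGroups | None = None,
) -> list[LSAResult]:
    """Predict every retained pair and score against its mean raw profile."""
    groups = groups or build_moa_groups(table)
    latents = _mean_latents(model, table)
    results = []
    for pair, idx in groups.pairs.items():
        real = table.features[idx].mean(axis=0)
        pred = lsa_predict(model, groups, latents, pair)
        l2, r = score_prediction(pred, real)
        results.append(LSAResult(pair, pred, real, l2, r, model.tag))
    return results


def _shuffled_groups(table: ProfileTable, rng: np.random.Generator) -> MOAGroups:
    """Rebuild groups after permuting all (moa, is_dmso) labels across rows."""
    perm = rng.permutation(table.n_samples)
    meta = table.meta.copy()
    meta["moa"] = [table.meta["moa"].iloc[i] for i in perm]
    meta["is_dmso"] = table.meta["is_dmso"].to_numpy()[perm]
    shuffled = ProfileTable(table.features, table.feature_names, meta, table.level)
    return build_moa_groups(shuffled)


def zscores_from_null(
    observed: float, null: Sequence[float], better: str
) -> tuple[float, float]:
    """z = (obs - mean(null)) / sd(null) and a one-sided normal p-value.

    ``better='low'`` (L2: smaller is better) takes the low tail,
    ``better='high'`` (Pearson) the high tail.  A zero or undefined null SD
    yields NaN z and p.
    """
    null = np.asarray([v for v in null if np.isfinite(v)], dtype=float)
    if null.size < 2:
        return float("nan"), float("nan")
    sd = null.std(ddof=1)
    if sd == 0 or not np.isfinite(observed):
        return float("nan"), float("nan")
    z = (observed - null.mean()) / sd
    p = stats.norm.cdf(z) if better == "low" else stats.norm.sf(z)
    return float(z), float(p)


def null_significance(
    model: TrainedGenerativeModel,
    table: ProfileTable,
    groups: MOAGroups | None = None,
    n_shuffles: int = 10,
    seed: int = 0,
) -> dict[tuple[str, str], NullResult]:
    """Shuffled-MOA-label null and z/p per pair.

    All MOA labels (DMSO included) are permuted across samples; groups are
    rebuilt and the LSA prediction re-run, but always scored against the
    *real* pair-mean profile.  Ten shuffles give a null ten times the size
    of the observed set.
    """
    groups = groups or build_moa_groups(table)
    latents = _mean_latents(model, table)
    observed = {r.pair: r for r in run_lsa(model, table, groups)}
    null_l2: dict[tuple[str, str], list[float]] = {p: [] for p in groups.pairs}
    null_pr: dict[tuple[str, str], list[float]] = {p: [] for p in groups.pairs}
    rng = np.random.default_rng(seed)
    for _ in range(n_shuffles):
        shuffled = _shuffled_groups(table, rng)
        s_latents = latents  # same rows, labels moved
        for pair, idx in groups.pairs.items():
            a, b = pair
            if a not in shuffled.singles or b not in shuffled.singles:
                continue
            pred = lsa_predict(model, shuffled, s_latents, pair)
            l2, r = score_prediction(pred, observed[pair].real)
            null_l2[pair].append(l2)
            null_pr[pair].append(r)
    out: dict[tuple[str, str], NullResult] = {}
    for pair in groups.pairs:
        obs = observed[pair]
        z_l2, p_l2 = zscores_from_null(obs.l2, null_l2[pair], "low")
        z_pr, p_pr = zscores_from_null(obs.pearson, null_pr[pair], "high")
        out[pair] = NullResult(
            pair,
            obs.l2,
            obs.pearson,
            null_l2[pair],
            null_pr[pair],
            z_l2,
            z_pr,
            p_l2,
            p_pr,
            n_shuffles,
        )
    return out


def run_baselines(
    table: ProfileTable,
    groups: MOAGroups | None = None,
    k: int = 10,
) -> dict[str, list[LSAResult]]:
    """LSA with the PCA(k) baseline and in the original feature space."""
    groups = groups or build_moa_groups(table)
    pca = pca_baseline(table.features, n_components=k)
    identity = IdentityModel(table.n_features)
    return {
        "pca": run_lsa(pca, table, groups),
        "original-space": run_lsa(identity, table, groups),
    }


def top_pairs_by_z(
    nulls: Mapping[tuple[str, str], NullResult], n: int = 5
) -> list[tuple[str, str]]:
    """Best-predicted pairs: most negative z_l2, ties by larger z_pearson."""
    def sort_key(item):
        pair, res = item
        z_l2 = res.z_l2 if np.isfinite(res.z_l2) else np.inf
        z_pr = res.z_pearson if np.isfinite(res.z_pearson) else -np.inf
        return (z_l2, -z_pr)

    ranked = sorted(nulls.items(), key=sort_key)
    return [pair for pair, _ in ranked[:n]]


def leave_out_mask(
    table: ProfileTable, top_pairs: Sequence[tuple[str, str]]
) -> np.ndarray:
    """True for samples retained when the listed pairs are held out.

    Excluded: every sample annotated with a listed pair, or with either
    member MOA alone (or in any other combination).
    """
    excluded_moas = {m for pair in top_pairs for m in pair}

    def is_excluded(moa: tuple[str, ...]) -> bool:
        return bool(set(moa) & excluded_moas)

    return np.array([not is_excluded(tuple(m)) for m in table.meta["moa"]])


def leave_out_experiment(
    table: ProfileTable,
    top_pairs: Sequence[tuple[str, str]],
    config: VAEConfig,
    n_shuffles: int = 10,
    seed: int = 0,
    baseline_nulls: Mapping[tuple[str, str], NullResult] | None = None,
) -> pd.DataFrame:
    """Retrain without the top pairs' compounds; recheck their z-scores.

    Every compound annotated with a listed pair or with either member MOA is
    excluded from the retraining set.  Group means are then recomputed from
    the *full* table encoded by the retrained model, so the removed pairs
    are predicted by a model that never saw them.  Returns one row per
    removed pair with before/after z-scores.
    """
    groups = build_moa_groups(table)
    if not top_pairs:
        nulls = baseline_nulls or null_significance(
            table=table, model=train_vae(table, None, config), n_shuffles=n_shuffles, seed=seed
        )
        return _zscore_frame(nulls, nulls)
    keep = leave_out_mask(table, top_pairs)
    if not keep.any():
        raise ValueError("removal empties the training set")
    retrained = train_vae(table.subset(keep), None, config)
    nulls_after = null_significance(
        retrained, table, groups, n_shuffles=n_shuffles, seed=seed
    )
    if baseline_nulls is None:
        base_model = train_vae(table, None, config)
        baseline_nulls = null_significance(
            base_model, table, groups, n_shuffles=n_shuffles, seed=seed
        )
    rows = []
    for pair in top_pairs:
        key = tuple(sorted(pair))
        before = baseline_nulls.get(key)
        after = nulls_after.get(key)
        rows.append(
            {
                "pair": pair_label(key),
                "z_l2_before": before.z_l2 if before else float("nan"),
                "z_l2_after": after.z_l2 if after else float("nan"),
                "z_pearson_before": before.z_pearson if before else float("nan"),
                "z_pearson_after": after.z_pearson if after else float("nan"),
            }
        )
    return pd.DataFrame(rows)


def _zscore_frame(before, after) -> pd.DataFrame:
    rows = []
    for pair, res in before.items():
        rows.append(
            {
                "pair": pair_label(pair),
                "z_l2_before": res.z_l2,
                "z_l2_after": after[pair].z_l2,
                "z_pearson_before": res.z_pearson,
                "z_pearson_after": after[pair].z_pearson,
            }
        )
    return pd.DataFrame(rows)


def reproducibility_vs_predictability(
    model: TrainedGenerativeModel,
    table: ProfileTable,
    groups: MOAGroups | None = None,
) -> tuple[dict[tuple[str, str], float], dict[tuple[str, str], float], float]:
    """Does a pair reconstruct well iff it predicts well?

    Reproducibility(pair): median over the pair's samples of the Pearson
    correlation between each original profile and its reconstruction.
    Predictability(pair): Pearson correlation between the real pair-mean
    profile and the LSA prediction.  The returned scalar is the Pearson
    correlation of the two vectors over pairs (NaN when fewer than 3 pairs
    or either vector is constant).
    """
    groups = groups or build_moa_groups(table)
    latents = _mean_latents(model, table)
    recon = model.decode(latents)
    repro: dict[tuple[str, str], float] = {}
    pred: dict[tuple[str, str], float] = {}
    for pair, idx in groups.pairs.items():
        cors = []
        for i in idx:
            x, xh = table.features[i], recon[i]
            if x.std() > 0 and xh.std() > 0:
                cors.append(stats.pearsonr(x, xh).statistic)
        repro[pair] = float(np.median(cors)) if cors else float("nan")
        real = table.features[idx].mean(axis=0)
        _, r = score_prediction(lsa_predict(model, groups, latents, pair), real)
        pred[pair] = r
    pairs = [p for p in groups.pairs if np.isfinite(repro[p]) and np.isfinite(pred[p])]
    if len(pairs) < 3:
        return repro, pred, float("nan")
    x = np.array([repro[p] for p in pairs])
    y = np.array([pred[p] for p in pairs])
    if x.std() == 0 or y.std() == 0:
        return repro, pred, float("nan")
    return repro, pred, float(stats.pearsonr(x, y).statistic)


def results_frame(
    results: Mapping[str, Sequence[LSAResult]],
    nulls: Mapping[str, Mapping[tuple[str, str], NullResult]] | None = None,
) -> pd.DataFrame:
    """One row per (pair, model): l2, pearson and, if available, z/p."""
    rows = []
    for tag, res_list in results.items():
        for res in res_list:
            row = {
                "pair": pair_label(res.pair),
                "model": tag,
                "l2": res.l2,
                "pearson": res.pearson,
            }
            if nulls and tag in nulls and res.pair in nulls[tag]:
                nr = nulls[tag][res.pair]
                row.update(
                    z_l2=nr.z_l2,
                    z_pearson=nr.z_pearson,
                    p_l2=nr.p_l2,
                    p_pearson=nr.p_pearson,
                    n_shuffles=nr.n_shuffles,
                )
            rows.append(row)
    return pd.DataFrame(rows)
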