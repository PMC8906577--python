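"""MOA grouping/filtering, latent-space arithmetic, nulls and robustness."""

import dataclasses

import numpy as np
import pytest
from scipy import stats

from morphvae import (
    IdentityModel,
    analytic_lsa_truth,
    build_moa_groups,
    generate_profiles,
    generate_spec,
    lsa_predict,
    null_significance,
    pca_baseline,
    reproducibility_vs_predictability,
    run_baselines,
    run_lsa,
    score_prediction,
)
from morphvae.lsa import (
    leave_out_mask,
    pair_label,
    top_pairs_by_z,
    zscores_from_null,
)

from conftest import make_table


def toy_moa_table(rng=None, n_per=4):
    """A, B, C singles; one A∩B pair; DMSO wells."""
    rng = rng or np.random.default_rng(0)
    rows, moas, compounds = [], [], []
    for label, moa in [
        ("a", ("A",)), ("b", ("B",)), ("c", ("C",)), ("ab", ("A", "B")),
    ]:
        for i in range(n_per):
            rows.append(rng.normal(size=3))
            moas.append(moa)
            compounds.append(f"cpd_{label}{i}")
    for i in range(n_per):
        rows.append(rng.normal(size=3))
        moas.append(())
        compounds.append("DMSO")
    return make_table(np.asarray(rows), names=["f1", "f2", "f3"], moas=moas,
                      compounds=compounds)


# ----------------------------------------------------------------------
# grouping / filtering


def test_build_groups_filtering_rules():
    table = toy_moa_table()
    groups = build_moa_groups(table)
    assert set(groups.singles) == {"A", "B"}
    assert set(groups.pairs) == {("A", "B")}
    assert groups.dmso.size == 4
    assert groups.filter_report["C"] == "single MOA without a corresponding pair"


def test_build_groups_drops_three_annotations():
    table = toy_moa_table()
    table.meta.at[0, "moa"] = ("A", "B", "C")
    groups = build_moa_groups(table)
    assert "A ∩ B ∩ C" in groups.filter_report
    assert 0 not in groups.singles["A"]


def test_build_groups_requires_dmso_and_pairs():
    table = toy_moa_table()
    no_dmso = table.subset(~table.meta["is_dmso"].to_numpy())
    with pytest.raises(ValueError, match="DMSO"):
        build_moa_groups(no_dmso)
    only_singles = table.subset(
        np.array([len(m) != 2 for m in table.meta["moa"]])
    )
    with pytest.raises(ValueError, match="two-MOA"):
        build_moa_groups(only_singles)


# ----------------------------------------------------------------------
# prediction and scoring


def test_lsa_predict_identity_arithmetic():
    X = np.array(
        [[1.0, 0.0], [1.0, 0.0], [0.0, 1.0], [0.0, 1.0],
         [0.5, 0.5], [0.5, 0.5], [0.0, 0.0], [0.0, 0.0]]
    )
    moas = [("A",)] * 2 + [("B",)] * 2 + [("A", "B")] * 2 + [()] * 2
    compounds = ["a1", "a2", "b1", "b2", "ab1", "ab2", "DMSO", "DMSO"]
    table = make_table(X, names=["f1", "f2"], moas=moas, compounds=compounds)
    groups = build_moa_groups(table)
    model = IdentityModel(2)
    latents, _ = model.encode(X), None
    pred = lsa_predict(model, groups, model.encode(X)[0], ("A", "B"))
    np.testing.assert_allclose(pred, [1.0, 1.0])
    with pytest.raises(KeyError):
        lsa_predict(model, groups, model.encode(X)[0], ("A", "Z"))


def test_lsa_predict_degenerate_a_equals_dmso():
    # if mean(A) == mean(DMSO), the prediction collapses to decode(mean(B))
    X = np.array([[0.0, 0.0], [0.0, 0.0], [0.3, 0.7], [0.3, 0.7],
                  [0.3, 0.7], [0.0, 0.0]])
    moas = [("A",)] * 2 + [("B",)] * 2 + [("A", "B")] + [()]
    compounds = ["a1", "a2", "b1", "b2", "ab", "DMSO"]
    table = make_table(X, names=["f1", "f2"], moas=moas, compounds=compounds)
    groups = build_moa_groups(table)
    model = IdentityModel(2)
    pred = lsa_predict(model, groups, model.encode(X)[0], ("A", "B"))
    np.testing.assert_allclose(pred, [0.3, 0.7])


def test_score_prediction_values():
    assert score_prediction([1.0, 2.0], [1.0, 2.0]) == (0.0, pytest.approx(1.0))
    l2, _ = score_prediction([0.0, 0.0], [3.0, 4.0])
    assert l2 == 5.0
    # perfectly anti-ordered 4-point vectors
    _, r = score_prediction([1.0, 2.0, 3.0, 4.0], [4.0, 3.0, 2.0, 1.0])
    assert r == pytest.approx(-1.0)
    _, r = score_prediction([1.0, 1.0, 1.0], [1.0, 2.0, 3.0])
    assert np.isnan(r)


def test_original_space_lsa_exact_on_additive_data(noise_free_spec, noise_free_table):
    groups = build_moa_groups(noise_free_table)
    results = run_lsa(IdentityModel(noise_free_table.n_features), noise_free_table, groups)
    for res in results:
        assert res.l2 < 1e-10
        truth = analytic_lsa_truth(noise_free_spec, res.pair)
        np.testing.assert_allclose(res.predicted, truth, atol=1e-10)


def test_interaction_term_shifts_identity_error_by_its_norm():
    base = generate_spec({"noise_sd": 0.0, "plate_effect_sd": 0.0}, seed=33)
    pair = base.pairs[0]
    I = np.zeros(base.n_features)
    I[:10] = 0.3
    spec = dataclasses.replace(base, interactions={pair: I})
    table = generate_profiles(spec)
    results = {r.pair: r for r in run_lsa(IdentityModel(table.n_features), table)}
    assert results[pair].l2 == pytest.approx(np.linalg.norm(I), abs=1e-10)
    for other in spec.pairs[1:]:
        assert results[other].l2 < 1e-10


# ----------------------------------------------------------------------
# null / z-scores


def test_zscores_from_injected_null():
    z, p = zscores_from_null(2.0, [5.0, 6.0, 4.0, 5.0, 5.0], "low")
    null = np.array([5.0, 6.0, 4.0, 5.0, 5.0])
    expect_z = (2 - null.mean()) / null.std(ddof=1)
    assert z == pytest.approx(expect_z)
    assert p == pytest.approx(stats.norm.cdf(expect_z))
    # observed at the null mean: z = 0, p = 0.5 (both tails)
    z, p = zscores_from_null(5.0, [4.0, 6.0, 5.0], "low")
    assert (z, p) == (0.0, 0.5)
    z, p = zscores_from_null(5.0, [4.0, 6.0, 5.0], "high")
    assert (z, p) == (0.0, 0.5)
    # textbook value: z = -3 -> one-sided p ~ 0.00135
    z, p = zscores_from_null(2.0, [5.0 + d for d in (-1, 0, 1)], "low")
    assert z == pytest.approx(-3.0)
    assert p == pytest.approx(0.00135, abs=2e-5)
    # degenerate null SD
    z, p = zscores_from_null(2.0, [5.0, 5.0, 5.0], "low")
    assert np.isnan(z) and np.isnan(p)


def test_null_distribution_invariant_to_shuffle_seed():
    """Null L2 distributions from two shuffle streams should agree (KS)."""
    rng = np.random.default_rng(7)
    table = toy_moa_table(rng, n_per=12)
    model = IdentityModel(3)
    a = null_significance(model, table, n_shuffles=200, seed=1)
    b = null_significance(model, table, n_shuffles=200, seed=2)
    pair = ("A", "B")
    ks = stats.ks_2samp(a[pair].null_l2, b[pair].null_l2)
    assert ks.pvalue > 0.01


def test_null_significance_reports_all_pairs(trained_mmd, default_screen):
    _, norm, _ = default_screen
    nulls = null_significance(trained_mmd, norm, n_shuffles=5, seed=3)
    assert len(nulls) == 5
    for res in nulls.values():
        assert len(res.null_l2) == 5
        assert np.isfinite(res.z_l2)


# ----------------------------------------------------------------------
# baselines


def test_pca_full_rank_equals_original_space(noise_free_table):
    groups = build_moa_groups(noise_free_table)
    out = run_baselines(noise_free_table, groups, k=noise_free_table.n_features)
    for res_pca, res_orig in zip(out["pca"], out["original-space"]):
        np.testing.assert_allclose(res_pca.predicted, res_orig.predicted, atol=1e-8)


def test_pca_below_phenotype_rank_loses_information(noise_free_table):
    """On noise-free data the original space is exact, so a PCA too small to
    span the phenotype basis must score strictly worse.  (With noise the
    direction is data-dependent: truncation also denoises.)"""
    groups = build_moa_groups(noise_free_table)
    out = run_baselines(noise_free_table, groups, k=4)
    mean_pca = np.mean([r.l2 for r in out["pca"]])
    mean_orig = np.mean([r.l2 for r in out["original-space"]])
    assert mean_orig < 1e-9
    assert mean_pca > mean_orig


# ----------------------------------------------------------------------
# leave-out and reproducibility


def test_leave_out_mask_rule():
    table = toy_moa_table()
    keep = leave_out_mask(table, [("A", "B")])
    for i, moa in enumerate(table.meta["moa"]):
        if set(moa) & {"A", "B"}:
            assert not keep[i]
        else:
            assert keep[i]
    # C singles and DMSO survive
    assert keep[[i for i, m in enumerate(table.meta["moa"]) if m == ("C",)]].all()
    assert keep[table.meta["is_dmso"].to_numpy()].all()


def test_reproducibility_vs_predictability_graded_noise():
    """Pairs with graded noise levels: noisier pairs both reconstruct and
    predict worse under a truncated-PCA model, so the two scores correlate
    positively."""
    rng = np.random.default_rng(11)
    F, n_pairs = 30, 8
    rows, moas, compounds = [], [], []
    base = rng.uniform(0.4, 0.6, F)
    directions = rng.normal(size=(n_pairs, 2, F)) * 0.5
    for p in range(n_pairs):
        noise = 0.02 + 0.12 * p / (n_pairs - 1)
        ea, eb = directions[p]
        for moa, eff in [((f"A{p}",), ea), ((f"B{p}",), eb),
                         ((f"A{p}", f"B{p}"), ea + eb)]:
            for i in range(6):
                rows.append(base + eff + rng.normal(0, noise, F))
                moas.append(moa)
                compounds.append(f"cpd_{'_'.join(moa)}_{i}")
    for i in range(10):
        rows.append(base + rng.normal(0, 0.02, F))
        moas.append(())
        compounds.append("DMSO")
    table = make_table(np.asarray(rows), names=[f"Cells_Intensity_DNA_{i}" for i in range(F)],
                       moas=moas, compounds=compounds)
    model = pca_baseline(table.features, n_components=6)
    repro, pred, r = reproducibility_vs_predictability(model, table)
    assert len(repro) == n_pairs
    assert r > 0


def test_reproducibility_degenerate_perfect_model(noise_free_table):
    repro, pred, r = reproducibility_vs_predictability(
        IdentityModel(noise_free_table.n_features), noise_free_table
    )
    assert all(v == pytest.approx(1.0) for v in repro.values())
    assert np.isnan(r)  # constant vectors: correlation undefined, flagged


def test_top_pairs_ranking():
    class R:
        def __init__(self, z_l2, z_pr):
            self.z_l2, self.z_pearson = z_l2, z_pr

    nulls = {("a", "b"): R(-3, 5), ("c", "d"): R(-9, 2), ("e", "f"): R(-3, 9)}
    top = top_pairs_by_z(nulls, n=2)
    assert top == [("c", "d"), ("e", "f")]  # ties on z_l2 broken by z_pearson
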