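import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from neurotopo.binning import BinMatrix, build_grid
from neurotopo.topo_stats import (bonferroni, condition_anova, detect_mroi,
                                  fdr_bh, mass_univariate, mda,
                                  pca_topography, planned_contrasts)

from ._oracles import anova_f, bh_stepup_significant, mannwhitney_u


def matrix_from_values(values, conditions, grid=None):
    values = np.asarray(values, dtype=float)
    n, p = values.shape
    side = 10.0
    if grid is None:
        nx = p
        grid = build_grid(0, nx * side, 0, side, side)
    meta = pd.DataFrame({
        "subject_id": [f"s{i}" for i in range(n)],
        "condition": list(conditions),
        "bregma_mm": -3.36, "region": "LAd",
        "n_markers": values.sum(axis=1).astype(int),
        "n_outside": 0,
    })
    return BinMatrix(grid, values, meta)


class TestMassUnivariate:
    def test_planted_offset_dominates(self, rng):
        X = rng.poisson(3.0, size=(10, 8)).astype(float)
        X[:5, 4] += 40.0
        mat = matrix_from_values(X, ["a"] * 5 + ["b"] * 5)
        res = mass_univariate(mat)
        assert np.argmin(res.p) == 4
        assert res.p[4] < res.p[np.arange(8) != 4].min() / 10

    def test_matches_sum_of_squares_oracle(self, rng):
        X = rng.normal(30.0, 3.0, size=(12, 20))
        groups = ["a"] * 4 + ["b"] * 4 + ["c"] * 4
        mat = matrix_from_values(X, groups)
        res = mass_univariate(mat)
        for b in range(20):
            f_o, p_o = anova_f([X[:4, b], X[4:8, b], X[8:, b]])
            assert res.f[b] == pytest.approx(f_o, rel=1e-9)
            assert res.p[b] == pytest.approx(p_o, rel=1e-9)

    def test_zero_variance_bins_flagged(self):
        X = np.ones((6, 3))
        X[:, 1] = [1, 2, 3, 4, 5, 6]
        mat = matrix_from_values(X, ["a"] * 3 + ["b"] * 3)
        res = mass_univariate(mat)
        assert res.zero_variance[0] and res.zero_variance[2]
        assert res.p[0] == 1.0 and res.f[0] == 0.0
        assert not res.zero_variance[1]

    def test_single_row_condition_rejected(self):
        X = np.random.default_rng(0).normal(20.0, 1.0, size=(3, 4))
        mat = matrix_from_values(X, ["a", "a", "b"])
        with pytest.raises(ValueError, match="'b'"):
            mass_univariate(mat)

    def test_sections_averaged_before_testing(self, rng):
        # same subject twice must not inflate degrees of freedom
        X = rng.normal(10, 1, size=(8, 5))
        meta_conditions = ["a", "a", "a", "a", "b", "b", "b", "b"]
        mat = matrix_from_values(X, meta_conditions)
        mat.meta.loc[1, "subject_id"] = "s0"  # duplicate of row 0
        res = mass_univariate(mat)
        averaged = mat.subject_averaged()
        assert len(averaged.values) == 7
        f_o, _ = anova_f([averaged.values[averaged.meta["condition"] == "a", 0],
                          averaged.values[averaged.meta["condition"] == "b", 0]])
        assert res.f[0] == pytest.approx(f_o, rel=1e-12)

    def test_type_one_error_null_simulation(self):
        n_rep, m_bins = 1000, 46
        hits = 0
        total = 0
        rng = np.random.default_rng(77)
        for _ in range(n_rep):
            X = rng.normal(20.0, 1.0, size=(10, m_bins))
            mat = matrix_from_values(X, ["a"] * 5 + ["b"] * 5)
            res = mass_univariate(mat)
            hits += (res.p < 0.05).sum()
            total += m_bins
        rate = hits / total
        # bins within a replicate are independent here, so the binomial MC
        # SD over all n_rep * m_bins tests applies
        mc_sd = np.sqrt(0.05 * 0.95 / total)
        assert abs(rate - 0.05) < 4 * mc_sd

    def test_kruskal_variant(self, rng):
        X = rng.poisson(3.0, size=(10, 4)).astype(float)
        X[:5, 2] += 30.0
        mat = matrix_from_values(X, ["a"] * 5 + ["b"] * 5)
        res = mass_univariate(mat, test="kruskal")
        assert np.argmin(res.p) == 2


class TestFdrBh:
    def test_all_half_not_significant(self):
        res = fdr_bh(np.array([0.5, 0.5, 0.5]), q_threshold=0.1)
        assert not res.significant.any()

    def test_single_test_q_equals_p(self):
        res = fdr_bh(np.array([0.03]), q_threshold=0.1)
        assert res.q[0] == pytest.approx(0.03)
        assert res.significant[0]

    def test_matches_stepup_oracle_many_vectors(self):
        rng = np.random.default_rng(123)
        for _ in range(200):
            p = rng.uniform(size=46) ** rng.uniform(0.3, 3.0)
            res = fdr_bh(p, q_threshold=0.1)
            np.testing.assert_array_equal(
                res.significant, bh_stepup_significant(p, 0.1))

    def test_invalid_p_rejected(self):
        with pytest.raises(ValueError):
            fdr_bh(np.array([0.5, 1.5]))
        with pytest.raises(ValueError):
            fdr_bh(np.array([-0.1]))

    def test_by_variant_more_conservative(self):
        rng = np.random.default_rng(5)
        p = rng.uniform(size=46) * 0.2
        bh = fdr_bh(p, 0.1, method="bh")
        by = fdr_bh(p, 0.1, method="by")
        assert (by.q >= bh.q - 1e-12).all()
        assert by.significant.sum() <= bh.significant.sum()

    @given(st.lists(st.floats(0, 1), min_size=2, max_size=40),
           st.floats(0.01, 0.2), st.floats(0.2, 0.5))
    @settings(max_examples=60, deadline=None)
    def test_threshold_monotonicity(self, p, q_small, q_big):
        p = np.asarray(p)
        small = fdr_bh(p, q_small).significant
        big = fdr_bh(p, q_big).significant
        assert (big | ~small).all()  # small set is a subset of big set

    def test_qvalues_monotone_in_p_order(self):
        rng = np.random.default_rng(9)
        p = rng.uniform(size=46)
        res = fdr_bh(p)
        order = np.argsort(p)
        assert (np.diff(res.q[order]) >= -1e-12).all()


class TestBonferroni:
    def test_single_test(self):
        res = bonferroni(np.array([0.04]), alpha=0.05)
        assert res.significant[0]

    def test_dominated_by_bh(self):
        rng = np.random.default_rng(17)
        for _ in range(50):
            p = rng.uniform(size=30) ** 2
            bon = bonferroni(p, alpha=0.1)
            bh = fdr_bh(p, q_threshold=0.1)
            assert (bh.significant | ~bon.significant).all()

    def test_matches_threshold_oracle(self):
        rng = np.random.default_rng(18)
        p = rng.uniform(size=25)
        res = bonferroni(p, alpha=0.05)
        np.testing.assert_array_equal(res.significant, p <= 0.05 / 25)


class TestDetectMroi:
    def test_family_mask_restricts_tests(self, rng):
        X = rng.poisson(2.0, size=(8, 6)).astype(float)
        X[:4, 5] += 50.0
        mat = matrix_from_values(X, ["a"] * 4 + ["b"] * 4)
        fam = np.array([True, True, True, True, True, False])
        res = detect_mroi(mat, family_mask=fam)
        assert np.isnan(res.q[5])
        assert not res.significant[5]

    def test_monotone_in_q_threshold(self, rng):
        X = rng.poisson(2.0, size=(10, 12)).astype(float)
        X[:5, 3] += 8.0
        X[:5, 7] += 3.0
        mat = matrix_from_values(X, ["a"] * 5 + ["b"] * 5)
        small = detect_mroi(mat, q_threshold=0.02).significant
        big = detect_mroi(mat, q_threshold=0.2).significant
        assert (big | ~small).all()

    def test_table_well_formed(self, rng):
        X = rng.poisson(2.0, size=(8, 4)).astype(float)
        mat = matrix_from_values(X, ["a"] * 4 + ["b"] * 4)
        tab = detect_mroi(mat).table()
        assert len(tab) == 4
        assert {"bin_index", "F", "p", "q", "significant",
                "x_center_um", "y_center_um"} <= set(tab.columns)

    def test_empty_family_rejected(self, rng):
        X = rng.poisson(2.0, size=(8, 4)).astype(float)
        mat = matrix_from_values(X, ["a"] * 4 + ["b"] * 4)
        with pytest.raises(ValueError):
            detect_mroi(mat, family_mask=np.zeros(4, dtype=bool))


class TestPlannedContrasts:
    def test_identical_groups_null(self):
        X = np.tile(np.array([[1.0, 2.0, 3.0]]), (8, 1))
        mat = matrix_from_values(X, ["a"] * 4 + ["b"] * 4)
        out = planned_contrasts(mat, [0, 1, 2], [("a", "b")])
        assert (out["stat"] == 0).all()
        assert (out["p"] == 1.0).all()

    def test_mannwhitney_matches_enumeration_oracle(self, rng):
        a = rng.integers(0, 10, size=6).astype(float)
        b = rng.integers(0, 10, size=7).astype(float)
        X = np.concatenate([a, b])[:, None] * np.ones((1, 1))
        mat = matrix_from_values(X, ["a"] * 6 + ["b"] * 7)
        out = planned_contrasts(mat, [0], [("a", "b")], test="mannwhitney")
        assert out["stat"].iloc[0] == pytest.approx(mannwhitney_u(a, b))

    def test_absent_condition_rejected(self, rng):
        X = rng.normal(20.0, 1.0, size=(6, 3))
        mat = matrix_from_values(X, ["a"] * 3 + ["b"] * 3)
        with pytest.raises(ValueError, match="ghost"):
            planned_contrasts(mat, [0], [("a", "ghost")])

    def test_correction_spans_contrasts_times_bins(self, rng):
        X = rng.normal(20.0, 1.0, size=(9, 4))
        mat = matrix_from_values(X, ["a"] * 3 + ["b"] * 3 + ["c"] * 3)
        out = planned_contrasts(mat, [0, 1], [("a", "b"), ("a", "c")])
        m = len(out)
        assert m == 4
        np.testing.assert_allclose(out["p_corrected"],
                                   np.minimum(out["p"] * m, 1.0))

    def test_planted_shift_survives_correction(self, rng):
        hits = 0
        n_sim = 200
        for s in range(n_sim):
            local = np.random.default_rng(s)
            X = local.normal(10, 1, size=(12, 6))
            X[:6, 2] += 6.0  # large effect in exactly one bin
            mat = matrix_from_values(X, ["a"] * 6 + ["b"] * 6)
            out = planned_contrasts(mat, [0, 1, 2, 3, 4, 5], [("a", "b")])
            sig = out[out["significant"]]
            hits += (len(sig) >= 1 and (sig["bin_index"] == 2).all())
        assert hits >= 0.95 * n_sim


class TestPcaTopography:
    def test_rank_one_data(self):
        rng = np.random.default_rng(3)
        direction = rng.normal(size=10)
        coeffs = rng.normal(size=6)
        X = 5.0 + np.outer(coeffs, direction)
        mat = matrix_from_values(X - X.min() + 1, ["a"] * 3 + ["b"] * 3)
        res = pca_topography(mat)
        assert res.explained_variance_ratio[0] == pytest.approx(1.0, abs=1e-10)

    def test_reconstruction_completeness(self, rng):
        X = rng.poisson(4.0, size=(9, 30)).astype(float)
        mat = matrix_from_values(X, ["a"] * 4 + ["b"] * 5)
        res = pca_topography(mat)
        Xc = X - X.mean(axis=0)
        recon = res.scores @ res.loadings
        np.testing.assert_allclose(recon, Xc, atol=1e-8)

    def test_variance_fractions_invariants(self, rng):
        X = rng.poisson(4.0, size=(10, 25)).astype(float)
        mat = matrix_from_values(X, ["a"] * 5 + ["b"] * 5)
        res = pca_topography(mat)
        evr = res.explained_variance_ratio
        assert evr.sum() <= 1 + 1e-9
        assert (np.diff(evr) <= 1e-12).all()
        # loadings orthogonal after normalisation
        G = res.loadings @ res.loadings.T
        np.testing.assert_allclose(G, np.diag(np.diag(G)), atol=1e-8)

    def test_separating_component_recovers_planted_pattern(self):
        rng = np.random.default_rng(42)
        n_bins = 40
        pattern = rng.normal(size=n_bins)
        pattern /= np.linalg.norm(pattern)
        X = rng.normal(0, 1.0, size=(12, n_bins))
        labels = ["a"] * 6 + ["b"] * 6
        X[:6] += 9.0 * pattern  # conditions differ only along the pattern
        mat = matrix_from_values(X - X.min() + 1, labels)
        res = pca_topography(mat)
        k = res.separating_component
        r = np.corrcoef(res.loadings[k], pattern)[0, 1]
        assert abs(r) > 0.9

    def test_too_few_subjects(self):
        X = np.random.default_rng(0).normal(20.0, 1.0, size=(2, 5))
        mat = matrix_from_values(X, ["a", "b"])
        with pytest.raises(ValueError):
            pca_topography(mat)

    def test_score_invariance_to_bin_constant_shift(self, rng):
        X = rng.poisson(5.0, size=(8, 10)).astype(float)
        mat1 = matrix_from_values(X, ["a"] * 4 + ["b"] * 4)
        X2 = X.copy()
        X2[:, 3] += 100.0  # constant added to one bin for every subject
        mat2 = matrix_from_values(X2, ["a"] * 4 + ["b"] * 4)
        s1 = pca_topography(mat1).scores
        s2 = pca_topography(mat2).scores
        for k in range(s1.shape[1]):
            r = np.corrcoef(s1[:, k], s2[:, k])[0, 1]
            assert abs(abs(r) - 1.0) < 1e-8


def random_group_table(rng, n_per_group=(6, 6), p=3, shift=0.0):
    rows, groups = [], []
    for gi, n in enumerate(n_per_group):
        mu = np.zeros(p)
        if gi == 1:
            mu += shift
        rows.append(rng.normal(mu, 1.0, size=(n, p)))
        groups += [f"g{gi}"] * n
    X = np.vstack(rows)
    return pd.DataFrame(X, columns=[f"r{j}" for j in range(p)]), np.array(groups)


class TestMda:
    def test_two_group_equals_fisher_discriminant(self, rng):
        table, groups = random_group_table(rng, (8, 8), p=3, shift=1.5)
        res = mda(table, groups)
        X = table.to_numpy()
        a, b = X[groups == "g0"], X[groups == "g1"]
        W = ((a - a.mean(0)).T @ (a - a.mean(0))
             + (b - b.mean(0)).T @ (b - b.mean(0)))
        fisher = np.linalg.solve(W, a.mean(0) - b.mean(0))
        v = res.coefficients[:, 0]
        cos = abs(fisher @ v) / (np.linalg.norm(fisher) * np.linalg.norm(v))
        assert cos == pytest.approx(1.0, abs=1e-8)

    def test_canonical_correlations_match_eigen_oracle(self, rng):
        table, groups = random_group_table(rng, (6, 6), p=3, shift=1.0)
        res = mda(table, groups)
        # independent route: eigenvalues of W^-1 B
        X = table.to_numpy()
        conds = sorted(set(groups))
        grand = X.mean(0)
        W = np.zeros((3, 3))
        B = np.zeros((3, 3))
        for c in conds:
            sub = X[groups == c]
            d = sub - sub.mean(0)
            W += d.T @ d
            B += len(sub) * np.outer(sub.mean(0) - grand, sub.mean(0) - grand)
        lams = np.sort(np.real(np.linalg.eigvals(np.linalg.solve(W, B))))[::-1]
        expected = np.sqrt(np.clip(lams[:1], 0, None) /
                           (1 + np.clip(lams[:1], 0, None)))
        np.testing.assert_allclose(res.canonical_correlations, expected,
                                   atol=1e-8)

    def test_correlations_in_unit_interval_and_sorted(self, rng):
        table, groups = random_group_table(rng, (7, 7, 7), p=4, shift=1.0)
        res = mda(table, groups)
        cc = res.canonical_correlations
        assert ((cc >= 0) & (cc <= 1)).all()
        assert (np.diff(cc) <= 1e-10).all()
        assert res.n_variates == min(3 - 1, 4)

    def test_affine_predictor_rescaling_invariance(self, rng):
        table, groups = random_group_table(rng, (8, 8), p=3, shift=1.0)
        res1 = mda(table, groups)
        scaled = table.copy()
        scaled["r0"] = scaled["r0"] * 13.0 - 7.0
        scaled["r2"] = scaled["r2"] * 0.01 + 100.0
        res2 = mda(scaled, groups)
        np.testing.assert_allclose(res1.canonical_correlations,
                                   res2.canonical_correlations, atol=1e-9)

    def test_permutation_null_vs_effect(self, rng):
        def perm_quantile(table, groups, n_perm=500):
            obs = mda(table, groups).canonical_correlations[0]
            local = np.random.default_rng(0)
            null = np.empty(n_perm)
            for i in range(n_perm):
                null[i] = mda(table,
                              local.permutation(groups)
                              ).canonical_correlations[0]
            return obs, np.quantile(null, 0.95)

        t_null, g_null = random_group_table(rng, (8, 8), p=3, shift=0.0)
        obs, q95 = perm_quantile(t_null, g_null)
        assert obs <= q95
        t_eff, g_eff = random_group_table(rng, (8, 8), p=3, shift=2.5)
        obs, q95 = perm_quantile(t_eff, g_eff)
        assert obs > q95

    def test_insufficient_subjects_advises_reduction(self, rng):
        table, groups = random_group_table(rng, (3, 3), p=6)
        with pytest.raises(ValueError, match="reduce the predictor"):
            mda(table, groups)

    def test_top_predictor_identified(self, rng):
        table, groups = random_group_table(rng, (10, 10), p=3, shift=0.0)
        table["r1"] += (groups == "g1") * 5.0  # separation only via r1
        res = mda(table, groups)
        assert res.top_predictor == "r1"


class TestConditionAnova:
    def test_single_region_reduces_to_anova(self, rng):
        table, groups = random_group_table(rng, (6, 6), p=1, shift=1.0)
        res = condition_anova(table, groups)
        f_o, p_o = anova_f([table.to_numpy()[groups == g, 0]
                            for g in sorted(set(groups))])
        assert res.f == pytest.approx(f_o, rel=1e-9)
        assert res.p == pytest.approx(p_o, rel=1e-9)
        assert res.per_region["F"].iloc[0] == pytest.approx(f_o, rel=1e-9)

    def test_per_region_matches_oracle(self, rng):
        table, groups = random_group_table(rng, (7, 7, 7), p=4, shift=0.8)
        res = condition_anova(table, groups)
        for j, row in res.per_region.iterrows():
            f_o, p_o = anova_f([table.to_numpy()[groups == g, j]
                                for g in sorted(set(groups))])
            assert row["F"] == pytest.approx(f_o, rel=1e-9)

    def test_null_type_one_error(self):
        n_rep = 1000
        hits = 0
        rng = np.random.default_rng(2024)
        for _ in range(n_rep):
            table, groups = random_group_table(rng, (8, 8), p=2, shift=0.0)
            hits += condition_anova(table, groups).significant
        rate = hits / n_rep
        mc_sd = np.sqrt(0.05 * 0.95 / n_rep)
        assert abs(rate - 0.05) < 3 * mc_sd

    def test_wilks_in_unit_interval(self, rng):
        table, groups = random_group_table(rng, (8, 8), p=3, shift=1.0)
        res = condition_anova(table, groups)
        assert 0.0 <= res.wilks_lambda <= 1.0
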