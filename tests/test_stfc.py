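"""GLM, suprathreshold component formation, and permutation correction."""

import numpy as np
import pandas as pd
import pytest
from scipy import stats

from stfckit import (
    ClusterFeatureTable,
    NeighborhoodGraph,
    STFCRunConfig,
    fit_glm,
    fit_glm_table,
    form_stfcs,
    permutation_correct,
    run_stfc,
    threshold_clusters,
)
from stfckit.features import NeighborhoodGraph as NG

from _oracles import (
    exhaustive_stfc_pvalues,
    ols_sex_test,
    path_graph_edges,
    stfc_components,
)


def _table(values, sex, age, ids=None):
    values = np.atleast_2d(np.asarray(values, dtype=float))
    n, c = values.shape
    subjects = [f"s{i}" for i in range(n)]
    ids = ids or [f"c{j}" for j in range(c)]
    return ClusterFeatureTable(
        values=pd.DataFrame(values, index=subjects, columns=ids),
        subject_meta=pd.DataFrame({"sex": sex, "age": age}, index=subjects),
    )


def _path_graph(ids, k=1):
    frame = pd.DataFrame(
        [(a, b, 1.0) for a, b in path_graph_edges(ids)],
        columns=["node_a", "node_b", "distance_mm"],
    )
    return NG.from_edge_frame(frame, nodes=ids, k=k)


class TestGLM:
    def test_matches_statsmodels_on_random_designs(self, rng):
        for _ in range(50):
            n = int(rng.integers(8, 30))
            n_f = int(rng.integers(2, n - 2))
            sex = np.zeros(n)
            sex[rng.choice(n, n_f, replace=False)] = 1
            age = rng.normal(28, 3, n)
            y = rng.normal(0.5, 0.05, n) + 0.02 * sex
            got = fit_glm(y, sex, age)
            beta, t, p = ols_sex_test(y, sex, age)
            assert got["beta_group"] == pytest.approx(beta, abs=1e-10)
            assert got["t_stat"] == pytest.approx(t, abs=1e-10)
            assert got["p_unc"] == pytest.approx(p, abs=1e-10)
            assert got["n_used"] == n

    def test_constant_age_reduces_to_two_sample_t(self, rng):
        n = 24
        sex = np.repeat([1.0, 0.0], n // 2)
        y = rng.normal(size=n) + 0.5 * sex
        got = fit_glm(y, sex, np.full(n, 28.0))
        t, p = stats.ttest_ind(y[sex == 1], y[sex == 0], equal_var=True)
        assert got["t_stat"] == pytest.approx(t, abs=1e-10)
        assert got["p_unc"] == pytest.approx(p, abs=1e-10)

    def test_exact_null_gives_p_one(self):
        # identical value multisets and age distributions in the two groups
        vals = np.array([0.1, 0.2, 0.3, 0.1, 0.2, 0.3])
        sex = np.array([1, 1, 1, 0, 0, 0])
        age = np.array([25.0, 28.0, 31.0, 25.0, 28.0, 31.0])
        got = fit_glm(vals, sex, age)
        assert got["beta_group"] == pytest.approx(0.0, abs=1e-12)
        assert got["p_unc"] == pytest.approx(1.0)

    def test_age_is_a_fitted_covariate(self, rng):
        # a strong age trend must be absorbed by the age coefficient, not
        # contaminate the sex effect
        n = 40
        sex = np.repeat([1.0, 0.0], n // 2)
        age = np.concatenate([rng.uniform(22, 29, n // 2), rng.uniform(30, 37, n // 2)])
        y = 0.01 * age + rng.normal(0, 1e-6, n)
        got = fit_glm(y, sex, age)
        assert abs(got["beta_group"]) < 1e-3
        naive = stats.ttest_ind(y[sex == 1], y[sex == 0]).pvalue
        assert naive < 0.01 and got["p_unc"] > 0.01

    def test_untestable_and_degenerate_flags(self):
        sex = np.array([1, 1, 0, 0, 0], dtype=float)
        age = np.array([25, 26, 27, 28.0, 29.0])
        missing_group = np.array([np.nan, np.nan, 0.1, 0.2, 0.3])
        got = fit_glm(missing_group, sex, age)
        assert got["flag"] == "untestable" and got["p_unc"] == 1.0 and got["direction"] == 0
        exact = 0.3 + 0.1 * sex  # zero residual variance
        got = fit_glm(exact, sex, age)
        assert got["flag"] == "degenerate" and got["p_unc"] == 1.0

    def test_vectorized_table_equals_per_cluster_fit(self, rng):
        n, c = 20, 8
        sex = np.zeros(n)
        sex[rng.choice(n, 9, replace=False)] = 1
        age = rng.normal(28, 3, n)
        Y = rng.normal(0.5, 0.05, (n, c))
        table = _table(Y, sex, age)
        frame = fit_glm_table(table).table
        for j, row in frame.iterrows():
            ref = fit_glm(Y[:, j], sex, age)
            for key in ("beta_group", "t_stat", "p_unc"):
                assert row[key] == pytest.approx(ref[key], abs=1e-12)

    def test_missing_entries_dropped_listwise_per_cluster(self, rng):
        n = 16
        sex = np.repeat([1.0, 0.0], n // 2)
        age = rng.normal(28, 3, n)
        Y = rng.normal(0.5, 0.05, (n, 3))
        Y[2, 0] = np.nan
        Y[[4, 9], 1] = np.nan
        frame = fit_glm_table(_table(Y, sex, age)).table
        keep = ~np.isnan(Y[:, 1])
        ref = fit_glm(Y[keep, 1], sex[keep], age[keep])
        row = frame.iloc[1]
        assert row["n_used"] == keep.sum()
        assert row["p_unc"] == pytest.approx(ref["p_unc"], abs=1e-12)


class TestThresholdAndComponents:
    def test_strict_threshold(self):
        glm = fit_glm_table(_table(np.zeros((4, 3)), [1, 1, 0, 0], [25, 26, 27, 28]))
        glm.table["p_unc"] = [0.04, 0.05, 0.06]
        glm.table["direction"] = 1
        picked = threshold_clusters(glm, 0.05)
        assert list(picked["cluster"]) == ["c0"]

    @pytest.mark.parametrize("pvals,expect", [(np.ones(5), 0), (np.full(5, 1e-9), 5)])
    def test_null_and_saturated_selection(self, pvals, expect):
        glm = fit_glm_table(_table(np.zeros((4, 5)), [1, 1, 0, 0], [25, 26, 27, 28]))
        glm.table["p_unc"] = pvals
        glm.table["direction"] = 1
        assert len(threshold_clusters(glm, 0.05)) == expect

    def test_path_graph_components_match_flood_fill(self):
        ids = [1, 2, 3, 4, 5]
        graph = _path_graph(ids)
        supra = pd.DataFrame({"cluster": [1, 2, 4], "direction": [1, 1, 1]})
        got = form_stfcs(supra, graph)
        sizes = {s.member_clusters: s.size for s in got}
        assert sizes == {frozenset({1, 2}): 2, frozenset({4}): 1}
        oracle = stfc_components([1, 2, 4], {1: 1, 2: 1, 4: 1}, path_graph_edges(ids))
        assert set(sizes) == set(oracle)

    def test_opposite_signs_split_into_singletons(self):
        graph = _path_graph([1, 2, 3])
        supra = pd.DataFrame({"cluster": [1, 2], "direction": [1, -1]})
        split = form_stfcs(supra, graph, "split_by_sign")
        assert sorted(s.size for s in split) == [1, 1]
        merged = form_stfcs(supra, graph, "ignore_sign")
        assert [s.size for s in merged] == [2]
        assert merged[0].direction == 0

    def test_empty_suprathreshold_set(self):
        graph = _path_graph([1, 2, 3])
        assert form_stfcs(pd.DataFrame({"cluster": [], "direction": []}), graph) == []


class TestPermutationCorrection:
    def test_exhaustive_mode_matches_brute_force_enumeration(self):
        rng = np.random.default_rng(88)
        n, c = 8, 20
        sex = np.repeat([1.0, 0.0], 4)
        age = rng.normal(28, 3, n)
        Y = rng.normal(0.5, 0.05, (n, c))
        Y[:, :3] += 0.12 * sex[:, None]  # make something suprathreshold
        ids = list(range(c))
        table = _table(Y, sex, age, ids=ids)
        graph = _path_graph(ids)
        cfg = STFCRunConfig(n_permutations=70, seed=1)
        result = permutation_correct(table, graph, cfg)
        assert result.exhaustive and result.n_permutations_used == 70
        observed, oracle_p = exhaustive_stfc_pvalues(
            Y, sex, age, path_graph_edges(ids)
        )
        assert {s.member_clusters for s in result.stfcs} == set(observed)
        for s in result.stfcs:
            assert s.p_corrected == oracle_p[s.member_clusters]

    def test_extreme_rank_bound_in_monte_carlo_mode(self):
        rng = np.random.default_rng(5)
        n = 40
        sex = np.repeat([1.0, 0.0], n // 2)
        age = rng.normal(28, 3, n)
        Y = rng.normal(0.5, 0.02, (n, 8))
        Y[:, :4] += 0.03 * sex[:, None]  # clear but not label-dominating effect
        table = _table(Y, sex, age, ids=list(range(8)))
        graph = _path_graph(list(range(8)))
        cfg = STFCRunConfig(n_permutations=50, seed=2, exhaustive=False)
        result = permutation_correct(table, graph, cfg)
        top = min(result.stfcs, key=lambda s: s.p_corrected)
        assert top.size == 4
        # observed max exceeds every permuted max -> p hits its lower bound
        assert (result.null_max_sizes < top.size).all()
        assert top.p_corrected == pytest.approx(1 / 51)

    def test_more_clusters_never_shrink_corrected_p(self):
        """Max-statistic correction grows with the search space: appending
        noise-only clusters can only keep or raise an observed STFC's p."""
        rng = np.random.default_rng(17)
        n = 30
        sex = np.repeat([1.0, 0.0], n // 2)
        age = rng.normal(28, 3, n)
        signal = rng.normal(0.5, 0.02, (n, 10))
        signal[:, :3] += 0.04 * sex[:, None]
        noise = rng.normal(0.5, 0.02, (n, 10))
        ids_small = list(range(10))
        ids_big = list(range(20))
        small = _table(signal, sex, age, ids=ids_small)
        big = _table(np.hstack([signal, noise]), sex, age, ids=ids_big)
        g_small = _path_graph(ids_small)
        edges = path_graph_edges(ids_small) + path_graph_edges(ids_big[10:])
        frame = pd.DataFrame([(a, b, 1.0) for a, b in edges], columns=["node_a", "node_b", "distance_mm"])
        g_big = NG.from_edge_frame(frame, nodes=ids_big, k=1)
        cfg = STFCRunConfig(n_permutations=300, seed=9, exhaustive=False)
        res_small = permutation_correct(small, g_small, cfg)
        res_big = permutation_correct(big, g_big, cfg)
        p_small = {s.member_clusters: s.p_corrected for s in res_small.stfcs}
        p_big = {s.member_clusters: s.p_corrected for s in res_big.stfcs}
        shared = set(p_small) & set(p_big)
        assert shared
        for comp in shared:
            assert p_big[comp] >= p_small[comp]

    def test_run_stfc_recovers_planted_region(self, effect_cohort):
        cfg = STFCRunConfig(n_permutations=300, seed=3)
        result = run_stfc(effect_cohort.feature_table, effect_cohort.graph, cfg)
        sig = [s for s in result.stfcs if s.p_corrected < 0.05]
        assert sig
        best = max(sig, key=lambda s: s.size)
        truth = effect_cohort.truth_ids
        jacc = len(best.member_clusters & truth) / len(best.member_clusters | truth)
        assert jacc >= 0.5
        assert best.direction == 1  # effect planted as female > male

    def test_report_layout_and_group_summaries(self, effect_cohort):
        result = run_stfc(
            effect_cohort.feature_table, effect_cohort.graph,
            STFCRunConfig(n_permutations=100, seed=4),
        )
        report = result.report
        assert list(report.columns[:4]) == [
            "stfc_index", "stfc_size", "anatomical_structure", "p_value"
        ]
        assert {"female_mean", "female_sd", "male_mean", "male_sd"} <= set(report.columns)
        row = report.iloc[0]
        members = row["member_clusters"].split(";")
        sex = effect_cohort.feature_table.subject_meta["sex"]
        sub = effect_cohort.feature_table.values[members]
        expect = sub[sex == 1].mean(axis=0).mean()
        assert row["female_mean"] == pytest.approx(expect)
        assert row["stfc_size"] == len(members)

    def test_deterministic_given_seed(self, null_cohort):
        cfg = STFCRunConfig(n_permutations=80, seed=11, exhaustive=False)
        a = permutation_correct(null_cohort.feature_table, null_cohort.graph, cfg)
        b = permutation_correct(null_cohort.feature_table, null_cohort.graph, cfg)
        np.testing.assert_array_equal(a.null_max_sizes, b.null_max_sizes)
        assert [s.p_corrected for s in a.stfcs] == [s.p_corrected for s in b.stfcs]

    def test_config_validation(self):
        with pytest.raises(ValueError):
            STFCRunConfig(alpha_unc=0.0)
        with pytest.raises(ValueError):
            STFCRunConfig(n_permutations=0)
        with pytest.raises(ValueError):
            STFCRunConfig(sign_handling="bogus")
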