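import numpy as np
import pandas as pd
import pytest
from scipy import stats

import botanitox as bt
from botanitox import profiling


def call(substance, endpoint, label, pod=None, wauc=0.0, n_sig=2, n_runs=3):
    return bt.EndpointCall(substance, endpoint, label, n_sig, n_runs,
                           pod, None, None, wauc)


def simple_endpoints(n=3, counters=0):
    eps = {f"ep{i:02d}": bt.EndpointSpec(f"ep{i:02d}") for i in range(1, n + 1)}
    for i in range(1, counters + 1):
        eps[f"ctr{i:02d}"] = bt.EndpointSpec(
            f"ctr{i:02d}", is_counter_screen=True, paired_primary="ep01"
        )
    return eps


def matrices_from_wauc(wauc: pd.DataFrame, groups=None, imputation=1000.0):
    pod = pd.DataFrame(3.0, index=wauc.index, columns=wauc.columns)
    if groups is None:
        groups = pd.Series("g", index=wauc.index)
    return profiling.ProfileMatrices(pod, wauc, groups, imputation)


class TestBuildMatrices:
    def _inputs(self):
        endpoints = simple_endpoints(2, counters=1)
        substances = [
            bt.SubstanceSpec("s1", "gA"),
            bt.SubstanceSpec("s2", "gA"),
            bt.SubstanceSpec("s3", "gB", excluded=True),
        ]
        calls = []
        for s in ("s1", "s2", "s3"):
            calls.append(call(s, "ep01", "active" if s == "s1" else "inactive",
                              pod=10.0 if s == "s1" else None,
                              wauc=0.5 if s == "s1" else 0.0))
            calls.append(call(s, "ep02", "inconclusive"))
            calls.append(call(s, "ctr01", "inactive"))
        return calls, substances, endpoints

    def test_imputation_and_log_transform(self):
        calls, substances, endpoints = self._inputs()
        m = profiling.build_matrices(calls, substances, endpoints)
        assert m.log10_pod.loc["s1", "ep01"] == pytest.approx(1.0)  # log10(10)
        assert m.log10_pod.loc["s2", "ep01"] == pytest.approx(3.0)  # log10(1000)
        # inconclusive imputed exactly like inactive
        assert m.log10_pod.loc["s1", "ep02"] == pytest.approx(3.0)

    def test_wauc_matrix_covers_counter_screens(self):
        calls, substances, endpoints = self._inputs()
        m = profiling.build_matrices(calls, substances, endpoints)
        assert list(m.wauc.columns) == ["ep01", "ep02", "ctr01"]
        assert list(m.log10_pod.columns) == ["ep01", "ep02"]
        assert m.wauc.loc["s1", "ep01"] == 0.5
        assert m.wauc.loc["s2", "ep01"] == 0.0

    def test_excluded_substances_dropped(self):
        calls, substances, endpoints = self._inputs()
        m = profiling.build_matrices(calls, substances, endpoints)
        assert "s3" not in m.log10_pod.index

    def test_missing_cells_are_integrity_error(self):
        calls, substances, endpoints = self._inputs()
        with pytest.raises(bt.IntegrityError):
            profiling.build_matrices(calls[:-1][:4], substances, endpoints)


class TestClusterOrders:
    def test_identical_rows_merge_first_with_hand_heights(self):
        matrix = pd.DataFrame([[0.0, 0.0], [0.0, 0.0], [3.0, 4.0]],
                              index=["a", "b", "c"], columns=["e1", "e2"])
        result = profiling.cluster_orders(matrix)
        np.testing.assert_allclose(result.row_linkage[:, 2], [0.0, 5.0])
        # the two identical rows are adjacent leaves
        ra, rb = result.row_order.index("a"), result.row_order.index("b")
        assert abs(ra - rb) == 1

    def test_single_row_matrix_trivial(self):
        matrix = pd.DataFrame([[1.0, 2.0, 3.0]], index=["only"])
        result = profiling.cluster_orders(matrix)
        assert result.row_order == ["only"] and result.row_linkage is None

    def test_constant_matrix_still_orders_deterministically(self):
        matrix = pd.DataFrame(1.0, index=list("dcba"), columns=["e1", "e2"])
        r1 = profiling.cluster_orders(matrix)
        r2 = profiling.cluster_orders(matrix)
        assert r1.row_order == r2.row_order
        assert sorted(r1.row_order) == ["a", "b", "c", "d"]


class TestPairwiseCorrelation:
    def test_assignment_rules(self):
        wauc = pd.DataFrame(
            {
                "e1": [0.0, 0.0, 1.0, 6.0],
                "e2": [0.0, 0.0, 2.0, 5.0],
                "e3": [0.0, 0.0, 3.0, 4.0],
                "e4": [0.0, 0.0, 4.0, 3.0],
                "e5": [0.0, 0.0, 5.0, 2.0],
                "e6": [0.0, 0.0, 6.0, 1.0],
            },
            index=["z1", "z2", "up", "down"],
        )
        corr = profiling.pairwise_correlation(matrices_from_wauc(wauc))
        assert corr.loc["z1", "z2"] == 1.0  # both all-zero
        assert corr.loc["z1", "up"] == 0.0  # exactly one all-zero
        assert corr.loc["up", "down"] == 0.0  # raw Spearman rho = -1 -> 0

    def test_matrix_is_valid_correlation_surface(self):
        rng = np.random.default_rng(5)
        wauc = pd.DataFrame(rng.normal(0, 1, (12, 8)))
        wauc.iloc[3] = 0.0
        wauc.iloc[7] = 0.0
        corr = profiling.pairwise_correlation(matrices_from_wauc(wauc))
        v = corr.to_numpy()
        assert np.allclose(v, v.T)
        assert np.allclose(np.diag(v), 1.0)
        assert (v >= 0).all() and (v <= 1).all()

    def test_agrees_with_scipy_on_well_behaved_pairs(self):
        rng = np.random.default_rng(6)
        wauc = pd.DataFrame(rng.normal(0, 1, (6, 10)))
        corr = profiling.pairwise_correlation(matrices_from_wauc(wauc))
        for i in range(6):
            for j in range(i + 1, 6):
                rho = stats.spearmanr(wauc.iloc[i], wauc.iloc[j]).statistic
                assert corr.iloc[i, j] == pytest.approx(max(rho, 0.0), abs=1e-12)


class TestGroupCorrelationCurves:
    def _setup(self):
        ids = [f"A{i}" for i in range(3)] + [f"B{i}" for i in range(3)] + ["C0", "C1"]
        groups = pd.Series([i[0] for i in ids], index=ids)
        rng = np.random.default_rng(7)
        wauc = pd.DataFrame(rng.normal(0, 1, (8, 6)), index=ids)
        wauc.loc["A0"] = wauc.loc["A1"] = wauc.loc["A2"]  # identical group A
        corr = profiling.pairwise_correlation(matrices_from_wauc(wauc, groups))
        activity = pd.DataFrame(
            {"n_active": [3, 1, 1, 2, 1, 1, 1, 1], "sum_wauc": 1.0}, index=ids
        )
        return corr, groups, activity

    def test_within_pair_count_is_choose_two(self):
        corr, groups, activity = self._setup()
        out = profiling.group_correlation_curves(corr, groups, activity)
        a_within = out[(out.group == "A") & (out.kind == "within")]
        assert len(a_within) == 3  # C(3,2)

    def test_identical_members_concentrate_at_one(self):
        corr, groups, activity = self._setup()
        out = profiling.group_correlation_curves(corr, groups, activity)
        a_within = out[(out.group == "A") & (out.kind == "within")]
        assert (a_within.value == 1.0).all()

    def test_groups_below_min_size_excluded(self):
        corr, groups, activity = self._setup()
        out = profiling.group_correlation_curves(corr, groups, activity)
        assert "C" not in set(out.group)  # only 2 members
        # but C still serves as a comparator group for between-curves
        assert "C" in set(out[out.kind == "between"].other_group)

    def test_between_uses_most_active_lot(self):
        corr, groups, activity = self._setup()
        out = profiling.group_correlation_curves(corr, groups, activity)
        b_vs_a = out[(out.group == "B") & (out.other_group == "A")]
        expected = sorted(corr.loc[m, "A0"] for m in ["B0", "B1", "B2"])
        np.testing.assert_allclose(sorted(b_vs_a.value), expected)


class TestEnrichment:
    def test_hand_computed_two_group_f(self):
        # groups {1,2} vs {3,4}: SSB=4 (df 1), SSW=1 (df 2) -> F=8
        f, flag = profiling.one_way_f(np.array([1.0, 2.0, 3.0, 4.0]),
                                      np.array(["a", "a", "b", "b"]))
        assert f == pytest.approx(8.0, abs=1e-12) and flag == ""

    def test_matches_reference_anova_on_random_layouts(self):
        rng = np.random.default_rng(9)
        for _ in range(100):
            k = int(rng.integers(2, 6))
            sizes = rng.integers(2, 8, k)
            values = np.concatenate([rng.normal(rng.normal(), 1, n) for n in sizes])
            labels = np.concatenate([[f"g{i}"] * n for i, n in enumerate(sizes)])
            f, flag = profiling.one_way_f(values, labels)
            ref = stats.f_oneway(*[values[labels == g] for g in np.unique(labels)])
            assert flag == ""
            assert f == pytest.approx(ref.statistic, abs=1e-10)

    def test_degenerate_and_infinite_flags(self):
        f, flag = profiling.one_way_f(np.ones(6), np.array(list("aabbcc")))
        assert np.isnan(f) and flag == "degenerate"
        f, flag = profiling.one_way_f(np.array([1.0, 1.0, 2.0, 2.0]),
                                      np.array(["a", "a", "b", "b"]))
        assert np.isinf(f) and flag == "infinite"

    def _matrices(self):
        # group A potent on ep01 (pod 1 ug/mL), everyone else imputed flat;
        # constituents amplified on ep01
        ids = ["A-l1", "A-l2", "A-c1", "B-l1", "B-l2", "B-c1"]
        pod = pd.DataFrame(3.0, index=ids, columns=["ep01", "ep02"])
        pod.loc[["A-l1", "A-l2"], "ep01"] = [0.0, 0.2]
        pod.loc["A-c1", "ep01"] = -1.0
        pod["ep02"] = [2.9, 3.0, 3.1, 2.95, 3.0, 3.05]
        wauc = pd.DataFrame(0.0, index=ids, columns=["ep01", "ep02"])
        groups = pd.Series([i[0] for i in ids], index=ids)
        return profiling.ProfileMatrices(pod, wauc, groups, 1000.0)

    def test_designated_endpoint_attains_top_f_rank(self):
        m = self._matrices()
        coarse = {s: s[0] for s in m.log10_pod.index}
        out = profiling.endpoint_enrichment(m, coarse)
        assert out.iloc[0].endpoint_id == "ep01"
        assert out.iloc[0]["rank"] == 1

    def test_constituent_amplification_gives_f_ratio_above_one(self):
        m = self._matrices()
        coarse = {s: s[0] for s in m.log10_pod.index}
        fine = {s: f"{s[0]}:{'c' if '-c' in s else 'l'}" for s in m.log10_pod.index}
        out = profiling.endpoint_enrichment(m, coarse, fine)
        row = out[out.endpoint_id == "ep01"].iloc[0]
        assert row.f_ratio > 1.0

    def test_ratio_of_known_fs(self):
        m = self._matrices()
        out = pd.DataFrame({"f_value_1": [8.0], "f_value_2": [16.0]})
        assert (out.f_value_2 / out.f_value_1).iloc[0] == 2.0


class TestRankings:
    def _inputs(self):
        endpoints = simple_endpoints(3)
        substances = [bt.SubstanceSpec(s, "g") for s in ("s1", "s2", "s3")]
        calls = [
            call("s1", "ep01", "active", pod=10.0, wauc=0.5),
            call("s1", "ep02", "active", pod=0.5, wauc=0.7),
            call("s1", "ep03", "active", pod=100.0, wauc=0.1),
            call("s2", "ep01", "active", pod=50.0, wauc=0.2),
            call("s2", "ep02", "inactive"),
            call("s2", "ep03", "inactive"),
            call("s3", "ep01", "inactive"),
            call("s3", "ep02", "inactive"),
            call("s3", "ep03", "inconclusive"),
        ]
        m = profiling.build_matrices(calls, substances, endpoints)
        return m, calls, endpoints

    def test_counts_min_pod_and_imputation_for_inactives(self):
        m, calls, endpoints = self._inputs()
        out = profiling.rank_substances(m, calls, endpoints).set_index("substance_id")
        assert out.loc["s1", "n_active"] == 3
        assert out.loc["s1", "min_pod"] == 0.5
        assert out.loc["s3", "n_active"] == 0
        assert out.loc["s3", "min_pod"] == 1000.0  # imputation POD

    def test_dense_ranks_with_ties(self):
        m, calls, endpoints = self._inputs()
        out = profiling.rank_substances(m, calls, endpoints).set_index("substance_id")
        assert out.loc["s1", "rank_n_active"] == 1
        assert out.loc["s3", "rank_min_pod"] == 3

    def test_n_active_invariant_to_monotone_wauc_rescale(self):
        m, calls, endpoints = self._inputs()
        base = profiling.rank_substances(m, calls, endpoints)
        m.wauc = m.wauc * 7.5 + 0.0  # monotone rescale
        rescaled = profiling.rank_substances(m, calls, endpoints)
        assert base.rank_n_active.tolist() == rescaled.rank_n_active.tolist()

    def test_sum_z_invariant_to_affine_per_endpoint_rescale(self):
        m, calls, endpoints = self._inputs()
        base = profiling.rank_substances(m, calls, endpoints, zscore_on="all")
        rng = np.random.default_rng(11)
        for e in m.wauc.columns:
            m.wauc[e] = m.wauc[e] * rng.uniform(0.5, 4.0) + rng.normal()
        rescaled = profiling.rank_substances(m, calls, endpoints, zscore_on="all")
        np.testing.assert_allclose(base.sum_z_wauc, rescaled.sum_z_wauc, atol=1e-9)

    def test_single_substance_z_degenerate(self):
        endpoints = simple_endpoints(1)
        substances = [bt.SubstanceSpec("s1", "g")]
        calls = [call("s1", "ep01", "active", pod=1.0, wauc=0.4)]
        m = profiling.build_matrices(calls, substances, endpoints)
        out = profiling.rank_substances(m, calls, endpoints)
        assert out.sum_z_wauc.iloc[0] == 0.0 and bool(out.z_degenerate.iloc[0])

    def test_unknown_scheme_rejected(self):
        m, calls, endpoints = self._inputs()
        with pytest.raises(bt.ConfigError):
            profiling.rank_substances(m, calls, endpoints, scheme="nope")


class TestEmbed2d:
    def _matrices(self, n=24, seed=13):
        rng = np.random.default_rng(seed)
        wauc = pd.DataFrame(rng.normal(0, 1, (n, 6)),
                            index=[f"s{i:02d}" for i in range(n)])
        wauc.iloc[1] = wauc.iloc[0]  # identical pair
        return matrices_from_wauc(wauc)

    def test_shape_and_determinism(self):
        m = self._matrices()
        a = profiling.embed_2d(m, perplexity=5, iterations=400, seed=3)
        b = profiling.embed_2d(m, perplexity=5, iterations=400, seed=3)
        assert a.shape == (24, 2)
        pd.testing.assert_frame_equal(a, b)

    def test_identical_profiles_embed_together(self):
        m = self._matrices()
        coords = profiling.embed_2d(m, perplexity=5, iterations=600, seed=3).to_numpy()
        from scipy.spatial.distance import pdist, squareform

        d = squareform(pdist(coords))
        pair = d[0, 1]
        offdiag = d[np.triu_indices_from(d, k=1)]
        assert pair <= np.quantile(offdiag, 0.05)

    def test_too_few_substances_rejected(self):
        with pytest.raises(ValueError):
            profiling.embed_2d(self._matrices(n=3))

    def test_oversized_perplexity_reduced_with_warning(self):
        m = self._matrices(n=10)
        with pytest.warns(UserWarning, match="perplexity"):
            profiling.embed_2d(m, perplexity=30, iterations=300, seed=0)
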