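"""Imputation, moderated tests, BH, ANOVA, normalization and clustering."""

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st
from scipy import stats as sps
from scipy.cluster.hierarchy import fcluster

from phosphomrm.stats import (
    ImputationParams,
    RatioMatrix,
    StatsError,
    anova_tukey,
    bh_adjust,
    categorize_and_transform,
    cluster_samples,
    estimate_imputation_params,
    export_causalpath_table,
    impute_missing,
    median_mad_normalize,
    moderated_t_one_sample,
    moderated_t_two_sample,
)
from phosphomrm.synth import StudyDesign, simulate_study


def _matrix(values, categories=None, cols=None):
    values = pd.DataFrame(values, columns=cols)
    if categories is None:
        categories = pd.DataFrame(
            np.where(values.isna(), 3, 1), index=values.index, columns=values.columns
        )
    else:
        categories = pd.DataFrame(categories, index=values.index, columns=values.columns)
    return RatioMatrix(values, categories)


class TestCategorize:
    def test_toy_table_matches_hand_computation(self):
        records = pd.DataFrame(
            {
                "peptide": ["p1", "p1", "p2", "p2"],
                "sample": ["a", "b", "a", "b"],
                "par": [1.0, 4.0, 0.25, 0.0],
                "category": [1, 1, 2, 3],
            }
        )
        m = categorize_and_transform(records)
        assert m.values.loc["p1", "a"] == 0.0
        assert m.values.loc["p1", "b"] == 2.0
        assert m.values.loc["p2", "a"] == -2.0
        assert np.isnan(m.values.loc["p2", "b"])
        assert m.categories.loc["p2", "b"] == 3

    def test_nonpositive_quantified_ratio_rejected(self):
        records = pd.DataFrame(
            {"peptide": ["p"], "sample": ["a"], "par": [0.0], "category": [1]}
        )
        with pytest.raises(StatsError):
            categorize_and_transform(records)


class TestImputation:
    def test_params_from_category2_moments(self):
        m = _matrix([[-2.0, -1.0, 0.0]], categories=[[2, 2, 2]])
        params = estimate_imputation_params(m)
        assert params.mu == pytest.approx(-1.0)
        assert params.sd == pytest.approx(1.0)

    def test_no_missing_cells_unchanged(self):
        m = _matrix([[1.0, 2.0], [3.0, 4.0]], categories=[[1, 2], [2, 1]])
        out = impute_missing(m, seed=1)
        pd.testing.assert_frame_equal(out.values, m.values)

    def test_observed_cells_untouched_and_seed_reproducible(self):
        vals = [[1.0, np.nan, 0.5], [np.nan, -0.5, -1.5]]
        cats = [[1, 3, 2], [3, 2, 2]]
        m = _matrix(vals, categories=cats)
        out1 = impute_missing(m, seed=42)
        out2 = impute_missing(m, seed=42)
        pd.testing.assert_frame_equal(out1.values, out2.values)
        mask = np.asarray(cats) != 3
        assert np.array_equal(
            out1.values.to_numpy()[mask], np.asarray(vals)[mask]
        )
        assert not out1.values.isna().any().any()

    def test_draw_moments_match_downshifted_normal(self):
        """10,000 imputed draws average to mu - 1*sd within 3 standard errors
        and their spread matches sd within 5%."""
        n = 10_000
        vals = np.full((n, 2), np.nan)
        vals[:, 1] = 0.0
        cats = np.full((n, 2), 3)
        cats[:, 1] = 1
        m = _matrix(vals, categories=cats)
        params = ImputationParams(mu=-1.0, sd=0.8)
        out = impute_missing(m, params=params, seed=7)
        draws = out.values.iloc[:, 0].to_numpy()
        se = params.sd / np.sqrt(n)
        assert abs(draws.mean() - (-1.0 - 0.8)) < 3 * se
        assert abs(draws.std(ddof=1) - 0.8) / 0.8 < 0.05

    def test_insufficient_category2_values_error(self):
        m = _matrix([[np.nan, 1.0]], categories=[[3, 1]])
        with pytest.raises(StatsError, match="explicit"):
            impute_missing(m, seed=0)


class TestModeratedTwoSample:
    def test_identical_group_means_give_t0_p1(self):
        vals = pd.DataFrame(
            {"a1": [1.0, 2.0], "a2": [3.0, 1.0], "b1": [1.0, 2.0], "b2": [3.0, 1.0]}
        )
        res = moderated_t_two_sample(vals, ["a1", "a2"], ["b1", "b2"])
        assert np.allclose(res.table["t"], 0.0)
        assert np.allclose(res.table["p_value"], 1.0)

    def test_d0_zero_equals_ordinary_student_t(self, rng):
        vals = pd.DataFrame(rng.normal(size=(40, 8)))
        vals.columns = [f"a{i}" for i in range(4)] + [f"b{i}" for i in range(4)]
        a_cols, b_cols = list(vals.columns[:4]), list(vals.columns[4:])
        res = moderated_t_two_sample(vals, a_cols, b_cols, d0=0.0, s0_squared=1.0)
        t_ref, p_ref = sps.ttest_ind(vals[a_cols], vals[b_cols], axis=1)
        assert np.allclose(res.table["t"], t_ref)
        assert np.allclose(res.table["p_value"], p_ref)

    def test_matches_limma_reference_values(self):
        """Frozen oracle: the same 8x6 matrix analysed with Bioconductor
        limma lmFit/eBayes (contrast A - B)."""
        data = pd.DataFrame(
            [
                [1.060943, 0.792003, 1.15009, 0.188113, -0.390207, -0.260436],
                [1.06392, 0.841879, 0.991599, -0.426522, 0.439699, 0.388896],
                [0.066031, 1.127241, 0.467509, -0.859292, 0.368751, -0.958883],
                [0.263535, -0.014978, -0.055459, -0.204279, 0.366762, -0.046359],
                [-0.342662, -0.281707, 0.425847, 0.292355, 0.330186, 0.344657],
                [0.856659, -0.162566, -0.204897, -0.325509, 0.246392, 0.451589],
                [-0.170921, -1.260235, -1.236722, 0.975889, 1.114881, 0.814731],
                [-0.166377, 0.05804, 0.029171, 0.054672, 0.217857, 0.055899],
            ],
            columns=["A0", "A1", "A2", "B0", "B1", "B2"],
        )
        res = moderated_t_two_sample(data, ["A0", "A1", "A2"], ["B0", "B1", "B2"])
        assert res.d0 == pytest.approx(4.358013, abs=1e-4)
        assert res.s0_squared == pytest.approx(0.1038963, rel=1e-4)
        limma_t = [4.8664327, 3.0199776, 2.5208307, 0.1096077,
                   -1.5200876, 0.1124975, -5.8318265, -0.6801834]
        limma_p = [0.0010986162, 0.0157453255, 0.0345831558, 0.9153067226,
                   0.1653742344, 0.9130841890, 0.0003310242, 0.5147844242]
        assert np.allclose(res.table["t"], limma_t, atol=1e-5)
        assert np.allclose(res.table["p_value"], limma_p, atol=1e-7)

    def test_type_I_error_calibrated_under_null(self):
        """2,000 null rows, n = 4+4: the fraction of p < 0.05 lies in
        [0.04, 0.06]."""
        matrix, _ = simulate_study(
            StudyDesign(n_rows=2000, groups={"a": 4, "b": 4}, effect_fraction=0.0,
                        censor_quantile=0.0, low_quantile=0.05),
            seed=11,
        )
        cols = list(matrix.values.columns)
        res = moderated_t_two_sample(matrix, cols[:4], cols[4:])
        frac = float((res.table["p_value"] < 0.05).mean())
        assert 0.04 <= frac <= 0.06

    def test_underpowered_rows_flagged(self):
        vals = pd.DataFrame(
            {"a1": [1.0, np.nan], "a2": [2.0, np.nan], "b1": [0.0, 1.0], "b2": [0.5, 2.0]}
        )
        res = moderated_t_two_sample(vals, ["a1", "a2"], ["b1", "b2"])
        assert bool(res.table["tested"].iloc[0])
        assert not bool(res.table["tested"].iloc[1])
        assert np.isnan(res.table["t"].iloc[1])


class TestModeratedOneSample:
    def test_all_zero_values(self):
        vals = pd.DataFrame(np.zeros((5, 4)))
        res = moderated_t_one_sample(vals)
        assert np.allclose(res.table["t"], 0.0)

    def test_constant_rows_stay_finite_through_shrinkage(self, rng):
        """Rows with zero within-row variance diverge under the ordinary t;
        the shrunk variance keeps the statistic finite."""
        vals = pd.DataFrame(rng.normal(0, 1, size=(30, 4)))
        vals.iloc[0] = [0.7, 0.7, 0.7, 0.7]
        res = moderated_t_one_sample(vals)
        t0 = res.table["t"].iloc[0]
        assert np.isfinite(t0) and t0 > 0

    def test_type_I_error_calibrated_under_null(self, rng):
        vals = pd.DataFrame(rng.normal(size=(2000, 4)))
        res = moderated_t_one_sample(vals)
        frac = float((res.table["p_value"] < 0.05).mean())
        assert 0.04 <= frac <= 0.06


def naive_bh(p):
    """O(n^2) step-up oracle."""
    p = list(p)
    n = len(p)
    order = sorted(range(n), key=lambda i: p[i])
    adj = [None] * n
    for rank_from_top in range(n - 1, -1, -1):
        i = order[rank_from_top]
        candidate = p[i] * n / (rank_from_top + 1)
        if rank_from_top == n - 1:
            adj[i] = min(1.0, candidate)
        else:
            adj[i] = min(adj[order[rank_from_top + 1]], min(1.0, candidate))
    return adj


class TestBH:
    def test_single_p_unchanged(self):
        assert bh_adjust([0.03]) == pytest.approx([0.03])

    def test_hand_worked_example(self):
        assert bh_adjust([0.01, 0.02, 0.03, 0.04]) == pytest.approx([0.04] * 4)

    @settings(max_examples=100, deadline=None)
    @given(st.lists(st.floats(0, 1), min_size=1, max_size=50))
    def test_equals_naive_oracle(self, p):
        assert bh_adjust(p) == pytest.approx(naive_bh(p))

    def test_agrees_with_statsmodels(self, rng):
        from statsmodels.stats.multitest import multipletests

        p = rng.uniform(size=200)
        assert np.allclose(bh_adjust(p), multipletests(p, method="fdr_bh")[1])

    @settings(max_examples=50, deadline=None)
    @given(st.lists(st.floats(0, 1), min_size=2, max_size=30), st.randoms())
    def test_permutation_equivariance(self, p, rnd):
        perm = list(range(len(p)))
        rnd.shuffle(perm)
        base = bh_adjust(p)
        shuffled = bh_adjust([p[i] for i in perm])
        assert shuffled == pytest.approx([base[i] for i in perm])

    def test_out_of_range_rejected(self):
        with pytest.raises(StatsError):
            bh_adjust([0.5, 1.2])


class TestAnovaTukey:
    def test_identical_groups_f_zero(self):
        vals = pd.DataFrame([[1.0, 1.0, 1.0, 1.0, 1.0, 1.0]],
                            columns=list("abcdef"))
        groups = {"g1": ["a", "b"], "g2": ["c", "d"], "g3": ["e", "f"]}
        anova, _ = anova_tukey(vals, groups)
        assert anova["F"].iloc[0] == 0.0

    def test_two_groups_f_equals_t_squared(self, rng):
        vals = pd.DataFrame(rng.normal(size=(20, 6)),
                            columns=["a1", "a2", "a3", "b1", "b2", "b3"])
        groups = {"A": ["a1", "a2", "a3"], "B": ["b1", "b2", "b3"]}
        anova, _ = anova_tukey(vals, groups)
        t, _ = sps.ttest_ind(vals[groups["A"]], vals[groups["B"]], axis=1)
        assert np.allclose(anova["F"], t**2)

    def test_three_group_hand_worked_table(self):
        """Classic one-way layout: groups {1,2,3}, {2,3,4}, {4,5,6};
        SSB = 14, SSW = 6, F = (14/2)/(6/6) = 7."""
        vals = pd.DataFrame([[1, 2, 3, 2, 3, 4, 4, 5, 6]], dtype=float,
                            columns=[f"s{i}" for i in range(9)])
        groups = {"g1": ["s0", "s1", "s2"], "g2": ["s3", "s4", "s5"],
                  "g3": ["s6", "s7", "s8"]}
        anova, pairs = anova_tukey(vals, groups)
        assert anova["F"].iloc[0] == pytest.approx(7.0)
        assert len(pairs) == 3
        assert (pairs["adj_p_value"] >= pairs["p_value"] - 1e-12).all()

    def test_small_group_dropped_with_flag(self):
        vals = pd.DataFrame([[1.0, 2.0, 1.5, 2.5, 9.0]],
                            columns=["a1", "a2", "b1", "b2", "c1"])
        groups = {"A": ["a1", "a2"], "B": ["b1", "b2"], "C": ["c1"]}
        anova, _ = anova_tukey(vals, groups)
        assert anova["dropped_groups"].iloc[0] == "C"


class TestMedianMad:
    def test_hand_computation(self):
        vals = pd.DataFrame([[1.0, 2.0, 3.0]])
        out, flagged = median_mad_normalize(vals)
        assert out.iloc[0].tolist() == [-1.0, 0.0, 1.0]
        assert not flagged

    def test_constant_row_zeros_and_flag(self):
        vals = pd.DataFrame([[2.0, 2.0, 2.0]], index=["r"])
        out, flagged = median_mad_normalize(vals)
        assert out.iloc[0].tolist() == [0.0, 0.0, 0.0]
        assert flagged == ["r"]

    def test_rows_have_zero_median(self, rng):
        vals = pd.DataFrame(rng.normal(size=(10, 7)))
        out, _ = median_mad_normalize(vals)
        assert np.allclose(out.median(axis=1), 0.0)


class TestClustering:
    def test_identical_samples_merge_first_at_zero(self, rng):
        base = rng.normal(size=20)
        vals = pd.DataFrame({"a": base, "b": base, "c": rng.normal(size=20)})
        z, labels = cluster_samples(vals)
        assert z[0, 2] == pytest.approx(0.0, abs=1e-12)
        first = {labels[int(z[0, 0])], labels[int(z[0, 1])]}
        assert first == {"a", "b"}

    def test_duplicate_pairs_merge_adjacently(self, rng):
        """Four samples duplicated with small noise: every pair merges
        before any cross-pair merge."""
        n = 40
        cols = {}
        for k in range(4):
            base = rng.normal(size=n)
            cols[f"s{k}_x"] = base + rng.normal(0, 0.01, n)
            cols[f"s{k}_y"] = base + rng.normal(0, 0.01, n)
        vals = pd.DataFrame(cols)
        z, labels = cluster_samples(vals)
        assignments = fcluster(z, t=4, criterion="maxclust")
        by_cluster = {}
        for lab, cl in zip(labels, assignments):
            by_cluster.setdefault(cl, []).append(lab)
        assert sorted(map(sorted, by_cluster.values())) == sorted(
            [[f"s{k}_x", f"s{k}_y"] for k in range(4)]
        )

    def test_matches_brute_force_complete_linkage(self, rng):
        vals = pd.DataFrame(rng.normal(size=(30, 5)), columns=list("edcba"))
        z, labels = cluster_samples(vals)
        # independent oracle: naive agglomeration over the same distances
        cols = sorted(vals.columns)
        x = vals[cols].to_numpy()
        d = {}
        for i in range(5):
            for j in range(i + 1, 5):
                rho = sps.spearmanr(x[:, i], x[:, j]).statistic
                d[frozenset((i, j))] = 1 - rho
        clusters = {i: {i} for i in range(5)}
        heights = []
        next_id = 5
        while len(clusters) > 1:
            best = min(
                (
                    (max(d[frozenset((a, b))] for a in ca for b in cb), ka, kb)
                    for ka, ca in clusters.items()
                    for kb, cb in clusters.items()
                    if ka < kb
                ),
            )
            h, ka, kb = best
            heights.append(h)
            clusters[next_id] = clusters.pop(ka) | clusters.pop(kb)
            next_id += 1
        assert np.allclose(sorted(z[:, 2]), sorted(heights))

    def test_constant_sample_rejected(self, rng):
        vals = pd.DataFrame(
            {"a": rng.normal(size=10), "b": np.ones(10), "c": rng.normal(size=10)}
        )
        with pytest.raises(StatsError, match="b"):
            cluster_samples(vals)

    def test_too_few_samples(self, rng):
        with pytest.raises(StatsError):
            cluster_samples(pd.DataFrame(rng.normal(size=(10, 2))))


class TestCausalPathExport:
    def test_empty_results_header_only(self, tmp_path):
        path = tmp_path / "cp.tsv"
        out = export_causalpath_table(
            pd.DataFrame(columns=["effect", "adj_p_value"]), path
        )
        assert out.empty
        assert path.read_text().strip() == "gene\tsite\teffect_sign\tadj_p_value"

    def test_rows_sorted_by_adjusted_p_and_round_trip(self, tmp_path):
        res = pd.DataFrame(
            {"effect": [1.5, -0.5, 0.2], "adj_p_value": [0.2, 0.001, 0.05]},
            index=["GENE1 pS10", "GENE2 pY20", "GENE3 pT30"],
        )
        path = tmp_path / "cp.tsv"
        out = export_causalpath_table(res, path)
        assert out["gene"].tolist() == ["GENE2", "GENE3", "GENE1"]
        assert out["effect_sign"].tolist() == [-1, 1, 1]
        back = pd.read_csv(path, sep="\t")
        assert np.allclose(back["adj_p_value"], out["adj_p_value"], atol=1e-6)


def test_power_recovered_at_strong_effect():
    """Parameter recovery through the full simulate -> impute -> moderated-t
    path: a 2 log2-unit effect with within-group sd 0.5 and duplicate samples
    is recovered for most truly differential rows at BH 0.05."""
    design = StudyDesign(n_rows=500, groups={"drug": 2, "vehicle": 2},
                         within_sd=0.5, effect_size=2.0, effect_fraction=0.1,
                         censor_quantile=0.02, low_quantile=0.08)
    matrix, truth = simulate_study(design, seed=3)
    matrix = impute_missing(matrix, seed=4)
    cols = list(matrix.values.columns)
    res = moderated_t_two_sample(matrix, cols[:2], cols[2:])
    hits = res.table["adj_p_value"] < 0.05
    power = float(hits[truth["is_differential"]].mean())
    assert power > 0.5
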