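import numpy as np
import pandas as pd
import pytest
from scipy import stats

from lfqpipe import (
    ContrastThresholds,
    DifferentialAbundanceModel,
    anova_per_protein,
    benjamini_hochberg,
    classify_significant,
    fc_threshold,
    tukey_hsd,
)
from lfqpipe.diffstats import _studentized_range_sf


def _ss_anova_oracle(groups_data):
    """Hand sums-of-squares decomposition of one-way ANOVA."""
    allv = np.concatenate(groups_data)
    grand = allv.mean()
    ssb = sum(len(g) * (g.mean() - grand) ** 2 for g in groups_data)
    ssw = sum(((g - g.mean()) ** 2).sum() for g in groups_data)
    k, N = len(groups_data), len(allv)
    F = (ssb / (k - 1)) / (ssw / (N - k))
    return F, stats.f.sf(F, k - 1, N - k)


class TestAnova:
    def test_all_values_identical(self):
        res = anova_per_protein(np.full((1, 20), 7.0), ["a"] * 5 + ["b"] * 5 + ["c"] * 5 + ["d"] * 5)
        assert res["F"].iloc[0] == 0.0
        assert res["pvalue"].iloc[0] == 1.0

    def test_two_groups_equals_t_squared(self, rng):
        x = rng.normal(size=10)
        groups = ["a"] * 5 + ["b"] * 5
        res = anova_per_protein(x[None, :], groups)
        t, p_t = stats.ttest_ind(x[:5], x[5:])
        assert res["F"].iloc[0] == pytest.approx(t**2, rel=1e-12)
        assert res["pvalue"].iloc[0] == pytest.approx(p_t, rel=1e-12)

    def test_three_group_toy_matches_hand_ss(self):
        data = [np.array([2.0, 4.0]), np.array([6.0, 8.0]), np.array([10.0, 12.0])]
        F, p = _ss_anova_oracle(data)
        res = anova_per_protein(np.concatenate(data)[None, :], ["a", "a", "b", "b", "c", "c"])
        assert res["F"].iloc[0] == pytest.approx(F, rel=1e-12)
        assert res["pvalue"].iloc[0] == pytest.approx(p, rel=1e-12)

    def test_matches_scipy_f_oneway_rowwise(self, rng):
        X = rng.normal(size=(40, 20))
        groups = ["a"] * 5 + ["b"] * 5 + ["c"] * 5 + ["d"] * 5
        res = anova_per_protein(X, groups)
        for i in range(40):
            F, p = stats.f_oneway(X[i, :5], X[i, 5:10], X[i, 10:15], X[i, 15:])
            assert res["F"].iloc[i] == pytest.approx(F, rel=1e-10)
            assert res["pvalue"].iloc[i] == pytest.approx(p, rel=1e-10)

    def test_zero_within_variance_unequal_means(self):
        x = np.array([1.0, 1.0, 2.0, 2.0])
        res = anova_per_protein(x[None, :], ["a", "a", "b", "b"])
        assert res["pvalue"].iloc[0] > 0
        assert res["pvalue"].iloc[0] < 1e-300


class TestBenjaminiHochberg:
    def test_single_p(self):
        q, rej = benjamini_hochberg([0.03], fdr=0.05)
        assert q[0] == pytest.approx(0.03)
        assert rej[0]

    def test_four_vector_step_up_by_hand(self):
        # q_(i) = min_{j>=i} m p_(j) / j = (0.04, 0.04, 0.04, 0.04)
        q, _ = benjamini_hochberg([0.01, 0.02, 0.03, 0.04])
        assert np.allclose(q, [0.04, 0.04, 0.04, 0.04])

    def test_all_ones_no_rejections(self):
        _, rej = benjamini_hochberg([1.0] * 5)
        assert not rej.any()

    def test_rejections_nested_across_levels(self, rng):
        p = rng.uniform(size=200) ** 2
        _, rej_10 = benjamini_hochberg(p, fdr=0.10)
        _, rej_05 = benjamini_hochberg(p, fdr=0.05)
        assert set(np.flatnonzero(rej_05)) <= set(np.flatnonzero(rej_10))

    def test_qvalues_invariant_to_order(self, rng):
        p = rng.uniform(size=50)
        perm = rng.permutation(50)
        q, _ = benjamini_hochberg(p)
        q_perm, _ = benjamini_hochberg(p[perm])
        assert np.allclose(q[perm], q_perm)

    def test_q_at_least_p(self, rng):
        p = rng.uniform(size=100)
        q, _ = benjamini_hochberg(p)
        assert (q >= p - 1e-15).all()


class TestTukey:
    def test_null_case_all_means_equal(self, rng):
        base = rng.normal(size=5)
        x = np.concatenate([base - base.mean() + 5 for _ in range(3)])
        tab = tukey_hsd(x[None, :], ["a"] * 5 + ["b"] * 5 + ["c"] * 5)
        assert (tab["p_tukey"] > 0.99).all()

    def test_two_groups_reduces_to_pooled_t(self, rng):
        x = rng.normal(size=12)
        tab = tukey_hsd(x[None, :], ["a"] * 6 + ["b"] * 6)
        _, p_t = stats.ttest_ind(x[:6], x[6:])
        assert tab["p_tukey"].iloc[0] == pytest.approx(p_t, rel=1e-6)

    def test_three_groups_matches_scipy_tukey_hsd(self, rng):
        g = [rng.normal(loc, 1, size=5) for loc in (0.0, 1.0, 2.5)]
        tab = tukey_hsd(np.concatenate(g)[None, :], ["a"] * 5 + ["b"] * 5 + ["c"] * 5)
        ref = stats.tukey_hsd(*g)
        ours = {(r["group_a"], r["group_b"]): r["p_tukey"] for _, r in tab.iterrows()}
        labels = ["a", "b", "c"]
        for i in range(3):
            for j in range(i + 1, 3):
                assert ours[(labels[i], labels[j])] == pytest.approx(
                    ref.pvalue[i, j], rel=1e-5, abs=1e-10
                )

    def test_sf_against_monte_carlo(self, rng):
        # independent simulation oracle for the studentized range tail
        k, n = 3, 5
        df = k * (n - 1)
        draws = rng.normal(size=(100_000, k, n))
        means = draws.mean(axis=2)
        s2 = draws.var(axis=2, ddof=1).mean(axis=1)
        q_sim = (means.max(axis=1) - means.min(axis=1)) / np.sqrt(s2 / n)
        for q0 in (2.0, 3.0, 4.0):
            emp = (q_sim > q0).mean()
            se = np.sqrt(emp * (1 - emp) / q_sim.size)
            exact = float(_studentized_range_sf(np.array([q0]), k, df)[0])
            assert abs(exact - emp) < 4 * se + 1e-4

    def test_interpolated_tail_matches_exact(self):
        q = np.linspace(0.05, 12.0, 300)  # > 64 values forces the interpolant
        approx = _studentized_range_sf(q, 4, 16)
        exact = stats.studentized_range.sf(q, 4, 16)
        assert np.allclose(approx, exact, rtol=5e-4, atol=1e-9)

    def test_pairwise_p_at_least_unadjusted_pooled_t(self, rng):
        # the unadjusted t here shares Tukey's pooled MSE and N-k df, so the
        # ordering is exact (q crit = sqrt(2)*t crit only at k = 2)
        X = rng.normal(size=(20, 15))
        groups = ["a"] * 5 + ["b"] * 5 + ["c"] * 5
        tab = tukey_hsd(X, groups)
        idx = {"a": slice(0, 5), "b": slice(5, 10), "c": slice(10, 15)}
        df2 = 12
        for _, row in tab.iterrows():
            i = int(row["protein"])
            parts = [X[i, idx[g]] for g in ("a", "b", "c")]
            mse = sum(((p - p.mean()) ** 2).sum() for p in parts) / df2
            a, b = X[i, idx[row["group_a"]]], X[i, idx[row["group_b"]]]
            t = abs(a.mean() - b.mean()) / np.sqrt(mse * (1 / 5 + 1 / 5))
            p_t = 2 * stats.t.sf(t, df2)
            assert row["p_tukey"] >= p_t - 1e-9


class TestFcThresholdAndClassification:
    def test_constant_vector_warns_zero(self):
        with pytest.warns(UserWarning):
            assert fc_threshold([0.5, 0.5, 0.5]) == 0.0

    def test_alternating_unit_vector(self):
        assert fc_threshold([1, -1, 1, -1]) == pytest.approx(1.1547, abs=1e-4)

    @pytest.mark.parametrize(
        "q,p_tukey,log2fc,expected",
        [
            (0.01, 0.01, 1.0, "up"),
            (0.01, 0.01, 0.45, "ns"),   # strict inequality at the cutoff
            (0.2, 0.001, 2.0, "ns"),    # ANOVA-BH gate fails
            (0.01, 0.2, 2.0, "ns"),     # Tukey gate fails
            (0.01, 0.01, -1.0, "down"),
        ],
    )
    def test_gate_combinations(self, q, p_tukey, log2fc, expected):
        tab = pd.DataFrame(
            {"protein": ["p"], "log2fc": [log2fc], "p_tukey": [p_tukey]}
        )
        out = classify_significant(tab, {"p": q}, fc_cutoff=0.45)
        assert out["regulation"].iloc[0] == expected


class TestModelResults:
    def _model(self):
        rng = np.random.default_rng(42)
        X = rng.normal(20, 1, size=(50, 20))
        X[:5, 5:10] += 3.0  # planted effect in group b
        cols = [f"s{i}" for i in range(20)]
        groups = ["a"] * 5 + ["b"] * 5 + ["c"] * 5 + ["d"] * 5
        df = pd.DataFrame(X, columns=cols, index=[f"p{i}" for i in range(50)])
        return DifferentialAbundanceModel(df, groups, reference="a")

    def test_fit_detects_planted_shift(self):
        res = self._model().fit()
        up_in_b = res.contrast(("b", "a")).query("regulation == 'up'").index
        assert set(up_in_b) == {f"p{i}" for i in range(5)}

    def test_default_contrasts_vs_reference(self):
        res = self._model().fit()
        assert sorted(res.contrast_table["contrast"].unique()) == [
            "b_vs_a", "c_vs_a", "d_vs_a",
        ]

    def test_qvalue_consistency_with_anova_order(self):
        res = self._model().fit()
        tab = res.anova.sort_values("pvalue")
        assert (np.diff(tab["qvalue"].to_numpy()) >= -1e-12).all()

    def test_summary_mentions_gates(self):
        res = self._model().fit(ContrastThresholds(fc_cutoff=0.5))
        s = res.summary()
        assert "Tukey" in s and "0.5" in s

    def test_results_roundtrip_tsv(self, tmp_path):
        res = self._model().fit()
        res.to_tsv(tmp_path)
        out = pd.read_csv(tmp_path / "differential_results.tsv", sep="\t")
        assert {"protein", "contrast", "log2fc", "p_tukey", "regulation",
                "F", "pvalue", "qvalue"} <= set(out.columns)
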