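import itertools
import math

import numpy as np
import pandas as pd
import pytest

from lfqpipe import (
    AnnotationCollection,
    enrich,
    enrich_clusters,
    hierarchical_cluster,
    pca_samples,
    read_gmt,
    write_gmt,
    zscore_proteins,
)
from lfqpipe.annotations import AnnotationTerm


class TestPca:
    def test_collinear_data_is_rank_one(self):
        t = np.arange(5.0)
        X = pd.DataFrame(np.outer([1.0, 2.0, -0.5], t) + 7.0,
                         columns=[f"s{i}" for i in range(5)])
        _, frac = pca_samples(X)
        assert frac[0] == pytest.approx(1.0)
        assert frac[1:].sum() == pytest.approx(0.0, abs=1e-12)

    def test_variance_fractions_sorted_and_bounded(self, rng):
        X = pd.DataFrame(rng.normal(size=(30, 8)))
        _, frac = pca_samples(X)
        assert (np.diff(frac) <= 1e-9).all()
        assert frac.sum() <= 1 + 1e-9

    def test_toy_scores_match_brute_force_eigendecomposition(self, rng):
        # 3 samples x 4 features, oracle = eigh of the centered covariance
        X = rng.normal(size=(4, 3))  # proteins x samples
        df = pd.DataFrame(X, columns=["s1", "s2", "s3"])
        scores, frac = pca_samples(df)
        S = X.T  # samples x features
        C = S - S.mean(axis=0)
        cov = C @ C.T  # sample Gram matrix shares eigvals with covariance
        w, v = np.linalg.eigh(cov)
        w, v = w[::-1], v[:, ::-1]
        assert frac[: len(w)] == pytest.approx(w / w.sum(), abs=1e-10)
        for j in range(2):  # rank 2 after centering 3 samples
            proj = v[:, j] * math.sqrt(w[j])
            assert np.allclose(np.abs(scores.iloc[:, j]), np.abs(proj), atol=1e-8)

    def test_scores_preserve_centered_geometry(self, rng):
        # full reconstruction <=> pairwise distances of scores equal those of
        # the centered sample vectors
        X = pd.DataFrame(rng.normal(size=(40, 6)))
        scores, _ = pca_samples(X)
        S = X.to_numpy().T
        C = S - S.mean(axis=0)
        for i in range(6):
            for j in range(i + 1, 6):
                d_raw = np.linalg.norm(C[i] - C[j])
                d_pca = np.linalg.norm(scores.iloc[i] - scores.iloc[j])
                assert d_pca == pytest.approx(d_raw, abs=1e-8)

    def test_single_sample_errors(self):
        with pytest.raises(ValueError):
            pca_samples(pd.DataFrame({"s": [1.0, 2.0]}))


class TestZScore:
    def test_hand_formula_three_singleton_groups(self):
        df = pd.DataFrame([[1.0, 2.0, 3.0]], columns=["s1", "s2", "s3"])
        z = zscore_proteins(df, ["g1", "g2", "g3"])
        assert np.allclose(z.z.iloc[0], [-1, 0, 1])
        assert np.allclose(z.group_means.iloc[0], [-1, 0, 1])

    def test_constant_row_warns_and_zeros(self):
        df = pd.DataFrame([[4.0] * 6], columns=list("abcdef"))
        with pytest.warns(UserWarning):
            z = zscore_proteins(df, ["g1"] * 3 + ["g2"] * 3)
        assert (z.z.to_numpy() == 0).all()

    def test_rows_have_zero_mean_unit_sd(self, rng):
        df = pd.DataFrame(rng.normal(size=(20, 10)))
        z = zscore_proteins(df, ["g1"] * 5 + ["g2"] * 5)
        assert np.allclose(z.z.mean(axis=1), 0, atol=1e-9)
        assert np.allclose(z.z.std(axis=1, ddof=1), 1, atol=1e-9)


class TestHierarchicalCluster:
    def test_k1_single_cluster(self, rng):
        df = pd.DataFrame(rng.normal(size=(10, 4)))
        assert set(hierarchical_cluster(df, 1).labels) == {1}

    def test_separated_blobs_recovered(self, rng):
        a = rng.normal(0, 0.1, size=(15, 4))
        b = rng.normal(10, 0.1, size=(10, 4))
        df = pd.DataFrame(np.vstack([a, b]), index=[f"p{i}" for i in range(25)])
        labels = hierarchical_cluster(df, 2).labels
        assert len(set(labels.iloc[:15])) == 1
        assert len(set(labels.iloc[15:])) == 1
        assert labels.iloc[0] != labels.iloc[-1]

    def test_row_permutation_invariance(self, rng):
        df = pd.DataFrame(rng.normal(size=(30, 4)), index=[f"p{i}" for i in range(30)])
        perm = df.sample(frac=1, random_state=1)
        a = hierarchical_cluster(df, 4).labels
        b = hierarchical_cluster(perm, 4).labels.loc[a.index]
        # identical partitions up to relabelling
        mapping = {}
        for x, y in zip(a, b):
            assert mapping.setdefault(x, y) == y

    def test_bad_k(self, rng):
        df = pd.DataFrame(rng.normal(size=(5, 2)))
        with pytest.raises(ValueError):
            hierarchical_cluster(df, 0)
        with pytest.raises(ValueError):
            hierarchical_cluster(df, 6)


def _hypergeom_tail_by_enumeration(N, K, n, k_obs):
    """P(overlap >= k_obs) by exhaustive enumeration of n-subsets."""
    universe = list(range(N))
    term = set(range(K))
    total = hits = 0
    for subset in itertools.combinations(universe, n):
        total += 1
        if len(term & set(subset)) >= k_obs:
            hits += 1
    return hits / total


class TestEnrichment:
    def _collection(self, terms):
        return AnnotationCollection(
            terms=[AnnotationTerm(t, t, frozenset(m)) for t, m in terms.items()]
        )

    def test_saturated_term_p_one(self):
        uni = [f"g{i}" for i in range(8)]
        coll = self._collection({"all": uni})
        out = enrich(uni[:3], coll, uni)
        assert out["pvalue"].iloc[0] == pytest.approx(1.0)

    def test_perfect_overlap_is_1_over_252(self):
        uni = [f"g{i}" for i in range(10)]
        coll = self._collection({"t": uni[:5]})
        out = enrich(uni[:5], coll, uni)
        assert out["pvalue"].iloc[0] == pytest.approx(1 / 252, rel=1e-9)

    def test_zero_overlap_p_one(self):
        uni = [f"g{i}" for i in range(10)]
        coll = self._collection({"t": uni[:5]})
        out = enrich(uni[5:], coll, uni)
        assert out["pvalue"].iloc[0] == pytest.approx(1.0)

    @pytest.mark.parametrize("N,K,n", [(10, 4, 5), (12, 6, 4), (9, 3, 3)])
    def test_matches_exhaustive_enumeration(self, rng, N, K, n):
        uni = [f"g{i}" for i in range(N)]
        coll = self._collection({"t": uni[:K]})
        members = list(rng.choice(uni, size=n, replace=False))
        out = enrich(members, coll, uni)
        k_obs = len(set(members) & set(uni[:K]))
        expected = _hypergeom_tail_by_enumeration(N, K, n, k_obs)
        assert out["pvalue"].iloc[0] == pytest.approx(expected, rel=1e-9)

    def test_member_outside_universe_errors(self):
        coll = self._collection({"t": ["g1"]})
        with pytest.raises(ValueError, match="outside"):
            enrich(["zzz"], coll, ["g1", "g2"])

    def test_empty_universe_errors(self):
        coll = self._collection({"t": ["g1"]})
        with pytest.raises(ValueError, match="universe"):
            enrich([], coll, [])

    def test_per_cluster_tables(self, rng):
        uni = [f"g{i}" for i in range(20)]
        coll = self._collection({"t1": uni[:10], "t2": uni[10:]})
        df = pd.DataFrame(np.vstack([rng.normal(0, 0.1, size=(10, 3)),
                                     rng.normal(5, 0.1, size=(10, 3))]), index=uni)
        assign = hierarchical_cluster(df, 2)
        out = enrich_clusters(assign, coll, uni)
        assert set(out["cluster"]) == {1, 2}
        # each cluster is exactly one term -> minimal achievable p, flagged
        best = out.groupby("cluster")["pvalue"].min()
        assert (best < 0.05).all()


class TestGmtIO:
    def test_roundtrip(self, tmp_path):
        coll = AnnotationCollection(
            terms=[AnnotationTerm("GO:1", "iron homeostasis", frozenset({"Ftl1", "Fth1"}))]
        )
        path = tmp_path / "sets.gmt"
        write_gmt(coll, path)
        back = read_gmt(path)
        assert back.get("GO:1").members == {"Ftl1", "Fth1"}
        assert back.get("GO:1").name == "iron homeostasis"

    def test_short_line_rejected(self, tmp_path):
        path = tmp_path / "bad.gmt"
        path.write_text("only_one_field\n")
        with pytest.raises(ValueError, match="GMT"):
            read_gmt(path)

    def test_restrict_drops_empty_terms(self):
        coll = AnnotationCollection(terms=[
            AnnotationTerm("a", "a", frozenset({"X", "Y"})),
            AnnotationTerm("b", "b", frozenset({"Z"})),
        ])
        out = coll.restrict_to(["x", "y"])
        assert [t.term_id for t in out] == ["a"]
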