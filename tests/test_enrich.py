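import itertools
import math

import numpy as np
import pandas as pd
import pytest

from adrenosig.enrich import (
    PathwayDB,
    cluster_by_similarity,
    hypergeometric_ora,
    ks_cluster_test,
    pathway_impact,
    tanimoto,
)


def _exact_ora_oracle(universe_size, pathway_size, n_hits, overlap):
    """P(X >= overlap) by enumerating all hit subsets of the universe."""
    universe = list(range(universe_size))
    pathway = set(range(pathway_size))
    count = total = 0
    for hits in itertools.combinations(universe, n_hits):
        total += 1
        if len(pathway & set(hits)) >= overlap:
            count += 1
    return count / total


class TestHypergeometricOra:
    def test_worked_example(self):
        """|U|=10, pathway 4, hits 3, overlap 2 -> p = (36+4)/120 = 1/3."""
        universe = {f"m{i}" for i in range(10)}
        db = PathwayDB(members={"pw": {"m0", "m1", "m2", "m3"}})
        hits = {"m0", "m1", "m9"}
        table = hypergeometric_ora(hits, universe, db)
        assert table.loc["pw", "overlap"] == 2
        assert table.loc["pw", "p"] == pytest.approx(1 / 3)

    def test_zero_overlap_gives_p_one(self):
        universe = {f"m{i}" for i in range(8)}
        db = PathwayDB(members={"pw": {"m0", "m1"}})
        table = hypergeometric_ora({"m6", "m7"}, universe, db)
        assert table.loc["pw", "p"] == 1.0

    def test_pathway_equals_universe_degenerate(self):
        universe = {f"m{i}" for i in range(5)}
        db = PathwayDB(members={"pw": set(universe)})
        table = hypergeometric_ora({"m0", "m1"}, universe, db)
        assert table.loc["pw", "overlap"] == 2
        assert table.loc["pw", "p"] == pytest.approx(1.0)

    @pytest.mark.parametrize(
        "u,s,h,k",
        [(8, 3, 3, 1), (10, 4, 3, 2), (12, 5, 4, 3), (9, 6, 2, 2), (7, 2, 5, 2)],
    )
    def test_matches_exact_enumeration(self, u, s, h, k):
        universe = {f"m{i}" for i in range(u)}
        db = PathwayDB(members={"pw": {f"m{i}" for i in range(s)}})
        hits = {f"m{i}" for i in range(s - k, s - k + h)}  # exactly k in pathway
        assert len(hits & db.members["pw"]) == k
        table = hypergeometric_ora(hits, universe, db)
        assert table.loc["pw", "p"] == pytest.approx(_exact_ora_oracle(u, s, h, k))

    def test_hits_outside_universe_rejected(self):
        with pytest.raises(ValueError, match="subset"):
            hypergeometric_ora({"x"}, {"a"}, PathwayDB(members={"pw": {"a"}}))


class TestPathwayImpact:
    @staticmethod
    def _p3_db():
        import networkx as nx

        g = nx.path_graph(["a", "b", "c"])
        return PathwayDB(members={"p3": {"a", "b", "c"}}, graph=g)

    def test_middle_node_carries_all_betweenness(self):
        assert pathway_impact({"b"}, self._p3_db())["p3"] == pytest.approx(1.0)

    def test_leaf_has_zero_impact(self):
        assert pathway_impact({"a"}, self._p3_db())["p3"] == pytest.approx(0.0)

    def test_all_nodes_hit_gives_one(self):
        assert pathway_impact({"a", "b", "c"}, self._p3_db())["p3"] == pytest.approx(1.0)

    def test_missing_graph_gives_nan(self):
        db = PathwayDB(members={"pw": {"a"}})
        assert np.isnan(pathway_impact({"a"}, db)["pw"])


class TestTanimoto:
    def test_identical_fingerprints(self):
        assert tanimoto("10110", "10110") == 1.0

    def test_disjoint_fingerprints(self):
        assert tanimoto("1100", "0011") == 0.0

    def test_set_arithmetic_example(self):
        # bits {1,2,3} vs {2,3,4}: intersection 2, union 4
        assert tanimoto("01110", "00111") == 0.5

    def test_both_empty_defined_zero(self):
        assert tanimoto("0000", "0000") == 0.0

    def test_length_mismatch_rejected(self):
        with pytest.raises(ValueError, match="length"):
            tanimoto("101", "10")


class TestClustering:
    FPS = pd.Series(
        {
            "a": "111000",
            "b": "110000",  # sim(a,b)=2/3
            "c": "000111",
            "d": "000110",  # sim(c,d)=2/3
        }
    )

    def test_threshold_zero_single_cluster(self):
        labels = cluster_by_similarity(self.FPS, threshold=0.0)
        assert labels.nunique() == 1

    def test_threshold_above_one_all_singletons(self):
        labels = cluster_by_similarity(self.FPS, threshold=1.01)
        assert labels.nunique() == len(self.FPS)

    def test_two_pairs_at_default_threshold(self):
        labels = cluster_by_similarity(self.FPS, threshold=0.6)
        assert labels["a"] == labels["b"]
        assert labels["c"] == labels["d"]
        assert labels["a"] != labels["c"]
        # brute-force component check
        sims = {(i, j): tanimoto(self.FPS[i], self.FPS[j]) for i in self.FPS.index for j in self.FPS.index}
        for i, j in [("a", "b"), ("c", "d")]:
            assert sims[(i, j)] >= 0.6
        assert sims[("a", "c")] < 0.6

    def test_order_invariant_labels(self):
        shuffled = self.FPS.iloc[[2, 0, 3, 1]]
        a = cluster_by_similarity(self.FPS, threshold=0.6)
        b = cluster_by_similarity(shuffled, threshold=0.6)
        pd.testing.assert_series_equal(a, b)


class TestKsClusterTest:
    def test_strongly_enriched_cluster(self):
        """All member p ~ 1e-6: KS D ~ 1, exact one-sided p below 1e-4."""
        labels = pd.Series({f"m{i}": 0 for i in range(5)})
        raw_p = pd.Series({f"m{i}": 1e-6 * (i + 1) for i in range(5)})
        fc = pd.Series({f"m{i}": 0.5 for i in range(5)})
        table = ks_cluster_test(labels, raw_p, fc)
        # brute-force D+ = max_i (i/n - p_(i))
        sorted_p = np.sort(raw_p.to_numpy())
        d_oracle = max((i + 1) / 5 - sorted_p[i] for i in range(5))
        assert table["ks_statistic"].iloc[0] == pytest.approx(d_oracle)
        assert table["p"].iloc[0] < 1e-4
        assert table["key_compound"].iloc[0] == "m0"

    def test_exact_small_sample_ks_p(self):
        """One-sided exact P(D+ >= d) for n=1 equals 1 - d."""
        labels = pd.Series({"a": 0})
        table = ks_cluster_test(labels, pd.Series({"a": 0.2}), pd.Series({"a": 2.0}), min_size=1)
        # D+ = 1 - 0.2 = 0.8; P(U <= 0.2) = 0.2 is the exact tail
        assert table["p"].iloc[0] == pytest.approx(0.2)

    def test_null_clusters_rarely_significant(self):
        rng = np.random.default_rng(0)
        n_sig = 0
        for trial in range(200):
            ids = [f"m{trial}_{i}" for i in range(6)]
            labels = pd.Series(0, index=ids)
            raw_p = pd.Series(rng.uniform(size=6), index=ids)
            fc = pd.Series(rng.uniform(0.5, 2.0, 6), index=ids)
            table = ks_cluster_test(labels, raw_p, fc)
            if table["q_fdr"].iloc[0] < 0.05:
                n_sig += 1
        assert n_sig <= 20  # >= 90% non-significant

    def test_up_down_counting_semantics(self):
        """All significant members decreased -> n_up 0, n_down = count."""
        ids = [f"m{i}" for i in range(4)]
        labels = pd.Series(0, index=ids)
        raw_p = pd.Series([0.001, 0.002, 0.003, 0.5], index=ids)
        fc = pd.Series([0.4, 0.6, 0.8, 1.5], index=ids)
        table = ks_cluster_test(labels, raw_p, fc)
        assert table["n_up"].iloc[0] == 0
        assert table["n_down"].iloc[0] == 3

    def test_small_clusters_skipped(self):
        labels = pd.Series({"a": 0, "b": 0, "c": 1, "d": 1, "e": 1})
        raw_p = pd.Series(0.5, index=labels.index)
        fc = pd.Series(1.2, index=labels.index)
        table = ks_cluster_test(labels, raw_p, fc, min_size=3)
        assert list(table.index) == [1]
        assert table.attrs["skipped_clusters"] == [(0, 2)]
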