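import math

import networkx as nx
import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

from metcensus import go_network as gn
from metcensus import synthetic_data as sd


def hypergeom_tail_oracle(N, K, n, k):
    """Upper-tail hypergeometric by direct combinatorial summation."""
    denom = math.comb(N, n)
    return sum(
        math.comb(K, j) * math.comb(N - K, n - j)
        for j in range(k, min(K, n) + 1)
    ) / denom


def _annotation_map(N, K, n, k):
    """N proteins (first n form the test set); term GO:T on k of the test
    set and K-k of the rest (requires k <= K, K-k <= N-n)."""
    ann = {}
    rest_with_term = K - k
    for i in range(N):
        terms = {"GO:BG"}
        if (i < k) or (n <= i < n + rest_with_term):
            terms.add("GO:T")
        ann[f"P{i}"] = terms
    return ann


class TestJaccard:
    def test_identical_sets(self):
        assert gn.jaccard({"a", "b"}, {"a", "b"}) == 1.0

    def test_disjoint_sets(self):
        assert gn.jaccard({"a"}, {"b"}) == 0.0

    def test_quarter_meets_threshold(self):
        j = gn.jaccard({"a", "b", "c"}, {"a", "d"})
        assert j == pytest.approx(0.25)
        assert j >= gn.JACCARD_THRESHOLD  # inclusive edge rule

    def test_both_empty_defined_zero(self):
        assert gn.jaccard(set(), set()) == 0.0

    @settings(derandomize=True, max_examples=100)
    @given(st.sets(st.integers(0, 30)), st.sets(st.integers(0, 30)))
    def test_symmetric_and_bounded(self, a, b):
        assert gn.jaccard(a, b) == gn.jaccard(b, a)
        assert 0.0 <= gn.jaccard(a, b) <= 1.0


class TestBuildGraph:
    def test_identical_annotations_complete_graph(self):
        ann = {f"P{i}": {"x", "y"} for i in range(6)}
        labels = {f"P{i}": "MR" for i in range(6)}
        g = gn.build_graph(ann, labels)
        assert g.number_of_edges() == 15

    def test_disjoint_annotations_edgeless_with_nodes_kept(self):
        ann = {f"P{i}": {f"t{i}"} for i in range(5)}
        g = gn.build_graph(ann, {f"P{i}": "MR" for i in range(5)})
        assert g.number_of_edges() == 0 and g.number_of_nodes() == 5

    def test_hand_example(self):
        ann = {"p1": {"a", "b", "c", "d"}, "p2": {"a", "b", "c", "e"}, "p3": {"x"}}
        g = gn.build_graph(ann, {k: "MR" for k in ann})
        assert set(map(frozenset, g.edges)) == {frozenset({"p1", "p2"})}


class TestAssortativity:
    def test_two_monochromatic_cliques(self):
        g = nx.Graph()
        for grp, lab in (("a", "MR"), ("b", "NonMR")):
            for i in range(4):
                g.add_node(f"{grp}{i}", label=lab)
            for i in range(4):
                for j in range(i + 1, 4):
                    g.add_edge(f"{grp}{i}", f"{grp}{j}")
        assert gn.assortativity(g) == 1.0

    def test_balanced_complete_bipartite(self):
        g = nx.complete_bipartite_graph(5, 5)
        nx.set_node_attributes(g, {n: "MR" if n < 5 else "NonMR" for n in g}, "label")
        assert gn.assortativity(g) == pytest.approx(-1.0)

    def test_edgeless_not_evaluable(self):
        g = nx.empty_graph(4)
        nx.set_node_attributes(g, {n: "MR" for n in g}, "label")
        assert np.isnan(gn.assortativity(g))

    def test_matches_networkx_on_random_graphs(self):
        """Mixing-matrix implementation equals the independent reference on
        200 random labelled graphs to 1e-10."""
        for s in range(200):
            g = nx.gnp_random_graph(25, 0.12, seed=s)
            if g.number_of_edges() == 0:
                continue
            rng = np.random.default_rng(s)
            labs = {n: ("MR" if rng.random() < 0.4 else "NonMR") for n in g.nodes}
            nx.set_node_attributes(g, labs, "label")
            ref = nx.attribute_assortativity_coefficient(g, "label")
            assert gn.assortativity(g) == pytest.approx(ref, abs=1e-10)

    def test_random_labels_mean_near_zero(self):
        """Uniformly random relabelings of a fixed graph average r near 0,
        up to the finite-size bias: with equal 20/20 labels a random distinct
        pair shares a label with probability 19/39, so E[r] is approximately
        (19/39 - 1/2) / (1 - 1/2) = -1/39, not exactly zero."""
        g = nx.gnp_random_graph(40, 0.2, seed=3)
        nx.set_node_attributes(g, {n: "MR" if n % 2 else "NonMR" for n in g}, "label")
        _, _, null = gn.relabel_test(g, reps=10_000, seed=5)
        se = null.std() / np.sqrt(len(null))
        expected = (19 / 39 - 0.5) / 0.5
        assert abs(null.mean() - expected) < max(3 * se, 0.01)
        assert abs(null.mean()) < 0.05  # still close to zero on the r scale


class TestPermutationControls:
    def _planted_graph(self, seed=0):
        ann, lab = sd.generate_go_annotations(15, 15, 8, 0.8, 0.1, seed=seed)
        return ann, gn.build_graph(ann, dict(zip(lab.accession, lab.label)))

    def test_planted_assortativity_significant(self):
        """within_overlap >> between_overlap plants r > 0 and a small
        relabeling p-value in nearly every generator seed."""
        wins = 0
        for s in range(20):
            _, g = self._planted_graph(seed=s)
            r, p, _ = gn.relabel_test(g, reps=500, seed=s)
            wins += (r > 0) and (p < 0.05)
        assert wins / 20 > 0.9

    def test_relabel_determinism(self):
        _, g = self._planted_graph()
        assert gn.relabel_test(g, reps=300, seed=9)[1] == gn.relabel_test(g, reps=300, seed=9)[1]

    def test_low_observed_r_gives_large_p(self):
        _, g = self._planted_graph()
        null = gn.relabel_test(g, reps=500, seed=2)[2]
        # pretend the observed value sat below the permutation median
        p = float(np.mean(null >= np.quantile(null, 0.2)))
        assert p > 0.5

    def test_resample_single_rep_p_in_01(self):
        ann, g = self._planted_graph()
        r = gn.assortativity(g)
        p, n_eval = gn.resample_test(ann, r, 10, 0.5, reps=1, seed=3)
        assert p in (0.0, 1.0) and n_eval == 1

    def test_resample_determinism(self):
        ann, g = self._planted_graph()
        r = gn.assortativity(g)
        a = gn.resample_test(ann, r, 12, 0.5, reps=40, seed=4)
        b = gn.resample_test(ann, r, 12, 0.5, reps=40, seed=4)
        assert a == b

    def test_resample_identical_pool_extreme_observed(self):
        """Identically annotated pool: every rep is a complete graph with
        random labels, r concentrates near 0, so extreme observed r wins."""
        pool = {f"P{i}": {"t1", "t2"} for i in range(40)}
        p, n_eval = gn.resample_test(pool, 0.99, 12, 0.5, reps=60, seed=5)
        assert n_eval == 60 and p < 0.1


class TestEnrichment:
    def test_equal_proportions_fold_one(self):
        ann = {f"P{i}": {"GO:1"} for i in range(20)}
        df = gn.enrichment({f"P{i}" for i in range(5)}, set(ann), ann)
        assert df.fold.iloc[0] == pytest.approx(1.0)

    def test_perfect_enrichment_closed_form(self):
        """All 10 test proteins carry a term present in 10 of 100:
        p = 1/C(100,10), fold = 10."""
        ann = {f"P{i}": ({"GO:X"} if i < 10 else {"GO:Y"}) for i in range(100)}
        test = {f"P{i}" for i in range(10)}
        df = gn.enrichment(test, set(ann), ann).set_index("term")
        assert df.loc["GO:X", "p"] == pytest.approx(1 / math.comb(100, 10), rel=1e-9)
        assert df.loc["GO:X", "fold"] == pytest.approx(10.0)

    def test_zero_hits_p_one(self):
        ann = {f"P{i}": ({"GO:X"} if i >= 10 else {"GO:Y"}) for i in range(100)}
        df = gn.enrichment({f"P{i}" for i in range(10)}, set(ann), ann).set_index("term")
        assert df.loc["GO:X", "p"] == 1.0

    def test_matches_tail_sum_oracle(self):
        """Enrichment p equals direct combinatorial summation to 1e-12 on
        random annotation configurations."""
        rng = np.random.default_rng(13)
        for _ in range(100):
            N = int(rng.integers(20, 120))
            K = int(rng.integers(1, N + 1))
            n = int(rng.integers(1, N + 1))
            k_max = max(0, n - (N - K))
            k = int(rng.integers(k_max, min(K, n) + 1))
            ann = _annotation_map(N, K, n, k)
            test = {f"P{i}" for i in range(n)}
            df = gn.enrichment(test, set(ann), ann).set_index("term")
            assert df.loc["GO:T", "p"] == pytest.approx(
                hypergeom_tail_oracle(N, K, n, k), abs=1e-12
            )

    def test_bonferroni_capped(self):
        ann = {f"P{i}": {f"GO:{j}" for j in range(30)} for i in range(20)}
        df = gn.enrichment({f"P{i}" for i in range(5)}, set(ann), ann)
        assert (df.p_bonferroni <= 1.0).all()

    def test_test_not_subset_raises(self):
        with pytest.raises(ValueError):
            gn.enrichment({"A"}, {"B"}, {})
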