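
import networkx as nx
import numpy as np
import pandas as pd
import pytest
from hypothesis import given
from hypothesis import strategies as st
from scipy import stats

from crossmut import features as ft
from crossmut.io import ChromatinStateTable, ExpressionMatrix, PathwayCollection


class TestAccessibility:
    @pytest.mark.parametrize(
        "state,expect",
        [
            ("Active Transcription", True),
            ("Strong transcription", True),
            ("Transcribed - 5' preferential", True),
            ("Transcribed – 3’ preferential", True),  # typographic variants
            ("Quiescent", False),
            ("Enhancer", False),
            ("totally unknown state", False),
        ],
    )
    def test_label_mapping(self, state, expect):
        assert ft.accessibility_label(state) is expect

    @pytest.mark.parametrize(
        "states,expect",
        [((True, True, False), True), ((True, False), False), ((False,), False)],
    )
    def test_strict_majority(self, states, expect):
        assert ft.aggregate_states(states) is expect

    def test_empty_aggregation_is_error(self):
        with pytest.raises(ValueError):
            ft.aggregate_states([])

    @given(st.lists(st.booleans(), min_size=1, max_size=9))
    def test_majority_idempotent_under_replicate_duplication(self, states):
        assert ft.aggregate_states(states) == ft.aggregate_states(states * 2)

    def test_binarize_with_replicates_and_categories(self):
        labels = pd.DataFrame(
            {
                "E1": ["Active Transcription", "Quiescent", "Active Transcription"],
                "E2": ["Active Transcription", "Quiescent", "Quiescent"],
                "E3": ["Quiescent", "Quiescent", "Active Transcription"],
                "E4": ["Active Transcription", "Quiescent", "Quiescent"],
            },
            index=["gOn", "gOff", "gDiff"],
        )
        table = ChromatinStateTable(
            labels=labels,
            epigenome_tissues={"E1": "brain", "E2": "brain", "E3": "brain", "E4": "liver"},
        )
        acc = ft.binarize_chromatin(table)
        # brain has 3 replicate epigenomes: strict majority decides
        assert bool(acc.binary.loc["gOn", "brain"]) is True  # 2/3 ON
        assert bool(acc.binary.loc["gDiff", "brain"]) is True  # 2/3 ON
        assert bool(acc.binary.loc["gDiff", "liver"]) is False
        assert acc.category.loc["gOn"] == "EpiAllON"
        assert acc.category.loc["gOff"] == "EpiAllOFF"
        assert acc.category.loc["gDiff"] == "EpiDIFF"


class TestNeighbors:
    def test_path_graph_distances(self):
        g = nx.path_graph(["a", "b", "c"])
        assert ft.nth_degree_neighbors(g, "b", 1) == {"a", "c"}
        assert ft.nth_degree_neighbors(g, "a", 2) == {"c"}

    def test_triangle_has_no_distance_two(self):
        g = nx.complete_graph(["a", "b", "c"])
        assert ft.nth_degree_neighbors(g, "a", 2) == set()

    def test_absent_gene_gives_empty_set(self):
        assert ft.nth_degree_neighbors(nx.Graph(), "zzz", 1) == set()


def _expr(n_genes=40, seed=0, tissues=("t1", "t2")):
    rng = np.random.default_rng(seed)
    vals = rng.uniform(1, 100, (n_genes, len(tissues)))
    return ExpressionMatrix(values=pd.DataFrame(
        vals, index=[f"g{i}" for i in range(n_genes)], columns=list(tissues)))


class TestActivityScore:
    def test_extreme_tail_hits_pseudocount_bound(self):
        values = np.arange(100.0)
        sc = ft.activity_score(1e6, 3, "t", values, n_null=500, seed=0)
        assert sc.p == pytest.approx(1 / 501)
        assert sc.score == pytest.approx(np.log(501))

    def test_median_singleton_scores_near_half(self):
        values = np.arange(101.0)  # median = 50
        sc = ft.activity_score(50.0, 1, "t", values, n_null=4000, seed=1)
        assert abs(sc.p - 0.5) < 0.03

    def test_random_target_gives_uniform_pvalues(self):
        rng = np.random.default_rng(2)
        values = rng.normal(size=300)
        ps = [
            ft.activity_score(values[rng.integers(300)], 1, "t", values,
                              n_null=2000, seed=int(s)).p
            for s in rng.integers(0, 2**31, size=200)
        ]
        assert stats.kstest(ps, "uniform").pvalue > 0.01

    def test_exhaustive_matches_sampling_within_mc_error(self):
        values = np.array([3.0, 1.0, 4.0, 1.5, 9.0, 2.6, 5.3, 0.5])
        obs = values[:2].mean()
        exact = ft.activity_score(obs, 2, "t", values, exhaustive=True)
        n = 20_000
        sampled = ft.activity_score(obs, 2, "t", values, n_null=n, seed=3)
        se = np.sqrt(exact.p * (1 - exact.p) / n)
        assert abs(sampled.p - exact.p) < 3 * se + 2 / n

    def test_set_larger_than_universe_is_error(self):
        with pytest.raises(ValueError):
            ft.activity_score(1.0, 10, "t", np.arange(5.0), n_null=10, seed=0)


class TestFeatureWrappers:
    def test_pathway_minimum_p_rule(self):
        expr = _expr(seed=4)
        pws = PathwayCollection(
            members={"pw1": {"g0", "g1", "g2"}, "pw2": {"g0", "g30", "g31"}},
            membership_fallback=True,
        )
        sc = ft.pathway_activity("g0", pws, expr, "t1", n_null=2000, seed=5)
        one = ft._set_activity("g0", {"g1", "g2"}, expr, "t1", 2000, 5)
        two = ft._set_activity("g0", {"g30", "g31"}, expr, "t1", 2000, 5)
        assert sc.p <= max(one.p, two.p) + 1e-12

    def test_gene_without_pathway_is_excluded(self):
        expr = _expr()
        pws = PathwayCollection(members={"pw1": {"g1", "g2"}}, membership_fallback=True)
        with pytest.raises(ValueError):
            ft.pathway_activity("g0", pws, expr, "t1", n_null=100, seed=0)

    def test_single_partner_ppi_equals_partner_expression_activity(self):
        expr = _expr(seed=6)
        net = nx.Graph([("g0", "g7")])
        a = ft.ppi_activity("g0", net, expr, "t1", n_null=500, seed=9, exhaustive=True)
        b = ft.expression_activity("g7", expr, "t1", n_null=500, seed=9, exhaustive=True)
        assert a.p == b.p

    def test_top_expressed_gene_has_maximal_score(self):
        expr = _expr(seed=8)
        top = expr.values["t1"].idxmax()
        sc = ft.expression_activity(top, expr, "t1", n_null=1000, seed=0, exhaustive=True)
        others = [
            ft.expression_activity(g, expr, "t1", n_null=1000, seed=0, exhaustive=True).score
            for g in list(expr.genes[:10]) if g != top
        ]
        assert sc.score >= max(others)


class TestControlFeature:
    def test_pool_of_exactly_five_is_forced(self):
        # star of chains: center c, five arms of length 3 -> distance-3 pool = 5 tips
        g = nx.Graph()
        tips = []
        for i in range(5):
            g.add_edges_from([("c", f"a{i}"), (f"a{i}", f"b{i}"), (f"b{i}", f"t{i}")])
            tips.append(f"t{i}")
        expr = ExpressionMatrix(values=pd.DataFrame(
            np.arange(32.0).reshape(16, 2),
            index=["c"] + [f"a{i}" for i in range(5)] + [f"b{i}" for i in range(5)] + tips,
            columns=["t1", "t2"]))
        values, picked = ft.control_feature("c", g, expr, seed=0)
        assert set(picked) == set(tips)
        assert values["t1"] == pytest.approx(expr.values.loc[tips, "t1"].mean())

    def test_radius_one_star_center_is_excluded(self):
        g = nx.star_graph(["c", "x", "y", "z", "w", "v"])
        expr = _expr(seed=1)
        with pytest.raises(ValueError):
            ft.control_feature("c", g, expr, seed=0)

    def test_fixed_seed_reproduces_selection(self, small_bundle):
        from crossmut.io import znormalize

        z = znormalize(small_bundle.expression)
        gene = small_bundle.truth.index[0]
        for gene in small_bundle.truth.index:
            try:
                _, p1 = ft.control_feature(gene, small_bundle.ppi, z, seed=123)
                _, p2 = ft.control_feature(gene, small_bundle.ppi, z, seed=123)
                assert p1 == p2
                break
            except ValueError:
                continue
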