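import itertools
import math

import numpy as np
import pandas as pd
import pytest
from hypothesis import given
from hypothesis import strategies as st

from crossmut import enrichment as enr
from crossmut.synthetic import make_ranked_scenario


def _ranked(member_positions, N):
    membership = np.zeros(N, bool)
    membership[list(member_positions)] = True
    return enr.RankedList(
        genes=[f"g{i:03d}" for i in range(N)],
        pvalues=np.linspace(0.01, 0.99, N),
        membership=membership,
    )


class TestRanking:
    def test_ascending_p_order(self):
        df = pd.DataFrame({"gene": ["g1", "g2", "g3"], "p": [0.5, 0.01, 0.2]})
        ranked = enr.rank_genes(df, {"g1"})
        assert ranked.genes == ["g2", "g3", "g1"]

    def test_ties_broken_lexicographically(self):
        df = pd.DataFrame({"gene": ["BRAF", "APC"], "p": [0.01, 0.01]})
        ranked = enr.rank_genes(df, {"APC"})
        assert ranked.genes == ["APC", "BRAF"]

    def test_set_members_outside_universe_dropped_from_k(self):
        df = pd.DataFrame({"gene": ["g1", "g2"], "p": [0.1, 0.2]})
        ranked = enr.rank_genes(df, {"g1", "not_here"})
        assert ranked.K == 1

    def test_empty_set_in_universe_is_error(self):
        df = pd.DataFrame({"gene": ["g1"], "p": [0.1]})
        with pytest.raises(ValueError):
            enr.rank_genes(df, {"absent"})


class TestWalks:
    def test_perfect_enrichment_walk(self):
        ranked = _ranked(range(5), 20)
        obs = enr.observed_walk(ranked)
        assert np.array_equal(obs.y, np.minimum(np.arange(1, 21), 5))

    def test_anti_enrichment_walk(self):
        ranked = _ranked(range(15, 20), 20)
        obs = enr.observed_walk(ranked)
        assert np.array_equal(obs.y, np.maximum(0, np.arange(1, 21) - 15))

    @given(st.integers(2, 40), st.data())
    def test_walk_terminates_at_k(self, n, data):
        k = data.draw(st.integers(1, n))
        pos = data.draw(st.sets(st.integers(0, n - 1), min_size=k, max_size=k))
        obs = enr.observed_walk(_ranked(pos, n))
        assert obs.y[-1] == k
        assert (np.diff(obs.y) >= 0).all()

    def test_expected_walk_equals_hypergeometric_mean_line(self):
        rng = np.random.default_rng(5)
        for _ in range(10):
            N = int(rng.integers(2, 200))
            K = int(rng.integers(1, N + 1))
            w = enr.expected_walk(N, K)
            assert np.abs(w.y - np.arange(1, N + 1) * K / N).max() < 1e-9

    def test_joint_of_identical_lists_is_univariate(self):
        ranked = _ranked([2, 5, 9], 12)
        joint = enr.joint_walk(ranked, ranked)
        assert np.array_equal(joint.y, enr.observed_walk(ranked).y)

    def test_four_gene_union_counts_both_leaders(self):
        # members a, b; list1 ranks a first, list2 ranks b first -> y(1) = 2
        l1 = enr.RankedList(genes=["a", "c", "d", "b"], pvalues=np.arange(4) / 4,
                            membership=np.array([1, 0, 0, 1], bool))
        l2 = enr.RankedList(genes=["b", "d", "c", "a"], pvalues=np.arange(4) / 4,
                            membership=np.array([1, 0, 0, 1], bool))
        joint = enr.joint_walk(l1, l2)
        assert joint.y[0] == 2

    def test_joint_dominates_univariate_walks(self, rng):
        for _ in range(10):
            perm1 = rng.permutation(30)
            perm2 = rng.permutation(30)
            members = set(rng.choice(30, 6, replace=False))
            genes = [f"g{i}" for i in range(30)]
            mk = lambda perm: enr.RankedList(
                genes=[genes[i] for i in perm], pvalues=np.linspace(0, 1, 30),
                membership=np.array([perm[j] in members for j in range(30)]))
            r1, r2 = mk(perm1), mk(perm2)
            joint = enr.joint_walk(r1, r2)
            y1, y2 = enr.observed_walk(r1).y, enr.observed_walk(r2).y
            assert (joint.y >= np.maximum(y1, y2) - 1e-12).all()
            assert set(np.unique(np.diff(np.concatenate([[0], joint.y])))) <= {0.0, 1.0, 2.0}


class TestConditionalMachinery:
    def test_extra_genes_pmf_small_case(self):
        # N=4, n=2: enumerate all C(4,2)=6 random top-2 lists against a fixed one
        assert enr.extra_genes_pmf(4, 2, 0) == pytest.approx(1 / 6)
        assert enr.extra_genes_pmf(4, 2, 1) == pytest.approx(4 / 6)
        assert enr.extra_genes_pmf(4, 2, 2) == pytest.approx(1 / 6)

    def test_extra_genes_pmf_degenerate_and_normalized(self):
        assert enr.extra_genes_pmf(5, 0, 0) == 1.0
        for N in range(1, 13):
            for n in range(N + 1):
                total = sum(enr.extra_genes_pmf(N, n, e) for e in range(N + 1))
                assert total == pytest.approx(1.0)

    def test_extra_cancer_pmf_exhausted_set(self):
        assert enr.extra_cancer_pmf(10, 3, 5, 3, 2, 0) == pytest.approx(
            1.0 - sum(enr.extra_cancer_pmf(10, 3, 5, 3, 2, ke) for ke in range(1, 3))
        )
        assert enr.extra_cancer_pmf(10, 3, 5, 3, 2, 1) == 0.0

    def test_extra_cancer_pmf_matches_enumeration(self):
        # N=6, K=2, n=2, k=1: draw n_extra=2 from the 4 remaining genes (1 member)
        remaining = [1, 0, 0, 0]  # membership indicators
        counts = {0: 0, 1: 0}
        for combo in itertools.combinations(range(4), 2):
            counts[sum(remaining[i] for i in combo)] += 1
        total = math.comb(4, 2)
        for ke, cnt in counts.items():
            assert enr.extra_cancer_pmf(6, 2, 2, 1, 2, ke) == pytest.approx(cnt / total)

    def test_expected_extra_matches_double_sum(self):
        for N in (6, 9, 12):
            K, n, k = 3, N // 2, 1
            double = sum(
                enr.extra_genes_pmf(N, n, ne)
                * sum(
                    enr.extra_cancer_pmf(N, K, n, k, ne, ke) * ke
                    for ke in range(0, min(ne, K - k) + 1)
                )
                for ne in range(0, min(n, N - n) + 1)
            )
            assert enr.expected_extra_members(N, K, n, k) == pytest.approx(double)

    def test_conditional_walk_saturates_at_k(self):
        ranked = _ranked(range(4), 10)
        cond = enr.conditional_walk(enr.observed_walk(ranked))
        assert cond.y[3] == pytest.approx(4 + 4 * (4 - 4) / 10)  # k = K already
        assert cond.y[-1] == pytest.approx(4.0)
        assert (cond.y >= enr.observed_walk(ranked).y - 1e-12).all()

    def test_conditional_walk_matches_monte_carlo_union_oracle(self, rng):
        N, K = 100, 20
        r1 = np.sort(rng.choice(np.arange(1, N + 1), K, replace=False))
        y1 = np.bincount(r1, minlength=N + 1)[1:].cumsum().astype(float)
        f1 = enr.WalkCurve(x=np.arange(1, N + 1), y=y1, kind="observed",
                           N=N, K=K, member_ranks=r1)
        cond = enr.conditional_walk(f1)
        reps = 5000
        acc = np.zeros((reps, N))
        for rep in range(reps):
            r2 = rng.permutation(N)[:K] + 1
            acc[rep] = np.bincount(np.minimum(r1, r2), minlength=N + 1)[1:].cumsum()
        se = acc.std(axis=0, ddof=1) / np.sqrt(reps)
        dev = np.abs(acc.mean(axis=0) - cond.y)
        assert (dev <= 3 * se + 1e-9).all()


class TestWalkPvalues:
    def test_identical_curves_are_not_significant(self):
        ranked = _ranked(np.arange(0, 100, 10), 100)
        obs = enr.observed_walk(ranked)
        p = enr.walk_pvalue(obs, obs, n_perm=3000, seed=0)
        assert p >= 0.3

    def test_extreme_enrichment_is_significant(self):
        ranked = _ranked(range(10), 100)
        obs = enr.observed_walk(ranked)
        exp = enr.expected_walk(100, 10)
        assert enr.walk_pvalue(obs, exp, n_perm=10_000, seed=1) <= 0.01

    def test_permuted_membership_gives_uniformish_p(self, rng):
        exp = enr.expected_walk(80, 8)
        ps = []
        for i in range(150):
            pos = rng.choice(80, 8, replace=False)
            obs = enr.observed_walk(_ranked(pos, 80))
            ps.append(enr.walk_pvalue(obs, exp, n_perm=400, seed=i))
        ps = np.array(ps)
        from scipy import stats
        assert stats.kstest(ps, "uniform").pvalue > 0.01

    def test_zero_reference_is_hard_error(self):
        ranked = _ranked([0], 5)
        obs = enr.observed_walk(ranked)
        zero = enr.WalkCurve(x=np.arange(1, 6), y=np.zeros(5), kind="expected", N=5, K=1)
        with pytest.raises(ValueError):
            enr.walk_pvalue(obs, zero, n_perm=100, seed=0)


class TestBivariate:
    @pytest.mark.parametrize("pa,pb,expect", [
        (0.001, 0.001, "both indispensable"),
        (0.001, 0.5, "F2 superior"),
        (0.5, 0.001, "F1 superior"),
        (0.5, 0.5, "neither/overlapped"),
    ])
    def test_classification_rule_table(self, pa, pb, expect):
        out = enr.classify_bivariate(pa, pb, alpha=0.05)
        assert out.classification == expect

    @pytest.mark.parametrize("kind,expect", [
        ("copy", "neither/overlapped"),
        ("independent", "both indispensable"),
        ("one_informative", "F1 superior"),
    ])
    def test_designed_scenarios_classify_as_planted(self, kind, expect):
        hits = 0
        for seed in range(10):
            r1, r2, members = make_ranked_scenario(kind, seed=seed)
            out = enr.bivariate_gsea(r1, r2, members, alpha=0.05,
                                     n_perm=2000, seed=seed)
            hits += out.classification == expect
        assert hits >= 8

    def test_harmonization_recomputes_k_on_shared_universe(self):
        df1 = pd.DataFrame({"gene": ["a", "b", "c", "d"], "p": [0.1, 0.2, 0.3, 0.4]})
        df2 = pd.DataFrame({"gene": ["b", "c", "d", "e"], "p": [0.1, 0.2, 0.3, 0.4]})
        r1 = enr.rank_genes(df1, {"a", "b"})
        r2 = enr.rank_genes(df2, {"b", "e"})
        h1, h2 = enr.harmonize_universes(r1, r2, {"a", "b", "e"})
        assert set(h1.genes) == {"b", "c", "d"} == set(h2.genes)
        assert h1.K == h2.K == 1
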