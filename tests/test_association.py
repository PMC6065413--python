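import itertools

import numpy as np
import pandas as pd
import pytest
from hypothesis import given
from hypothesis import strategies as st
from scipy import stats

from crossmut import association as assoc


class TestGapSplit:
    def test_toy_profile_splits_at_largest_gap(self, toy_freqs):
        s = assoc.gap_split(toy_freqs)
        assert set(s.group1) == {"t1", "t2"}
        assert set(s.group2) == {"t3", "t4"}
        assert s.gap == pytest.approx(0.49)

    def test_two_tissues(self):
        s = assoc.gap_split(pd.Series({"lo": 0.0, "hi": 1.0}))
        assert s.group1 == ["lo"] and s.group2 == ["hi"]

    def test_all_equal_raises_no_split(self):
        with pytest.raises(assoc.NoSplitError):
            assoc.gap_split(pd.Series([0.1, 0.1, 0.1], index=list("abc")))

    @given(
        st.lists(st.integers(0, 30), min_size=2, max_size=12).filter(
            lambda xs: len(set(xs)) > 1
        ),
        st.integers(0, 2**31 - 1),
    )
    def test_matches_brute_force_boundary_enumeration(self, raw, seed):
        freqs = pd.Series(
            np.array(raw) / 30.0, index=[f"t{i:02d}" for i in range(len(raw))]
        )
        s = assoc.gap_split(freqs)
        order = sorted(freqs.index, key=lambda t: (freqs[t], t))
        vals = freqs.loc[order].values
        best = max(
            range(len(vals) - 1), key=lambda i: (vals[i + 1] - vals[i], -i)
        )
        assert s.boundary_index == best
        assert s.gap == pytest.approx(vals[best + 1] - vals[best])
        assert set(s.group1) | set(s.group2) == set(freqs.index)
        assert max(freqs[t] for t in s.group1) <= min(freqs[t] for t in s.group2)


class TestAssociationStatistic:
    def test_median_difference(self):
        feat = pd.Series({"a": 1, "b": 2, "c": 3, "d": 4, "e": 5, "f": 6}, dtype=float)
        assert assoc.association_statistic(feat, ["a", "b", "c"], ["d", "e", "f"]) == 3.0

    def test_identical_groups_give_zero(self):
        feat = pd.Series({"a": 2.0, "b": 2.0})
        assert assoc.association_statistic(feat, ["a"], ["b"]) == 0.0

    def test_chromatin_style_median_arithmetic(self):
        freqs = pd.Series({"on1": 0.2, "on2": 0.4, "off1": 0.0, "off2": 0.0})
        stat = assoc.association_statistic(freqs, ["off1", "off2"], ["on1", "on2"])
        assert stat == pytest.approx(0.3)


class TestPermutationAssociation:
    def test_constant_feature_gives_p_one(self, toy_freqs):
        feat = pd.Series(1.0, index=toy_freqs.index)
        r = assoc.permutation_association(feat, freqs=toy_freqs, n_perm=500, seed=0)
        assert r.statistic == 0.0
        assert r.p == 1.0
        assert r.direction == "none"

    def test_self_association_is_strong(self, rng):
        tissues = [f"t{i}" for i in range(12)]
        freqs = pd.Series(np.concatenate([rng.uniform(0, 0.02, 8),
                                          rng.uniform(0.4, 0.5, 4)]), index=tissues)
        ex = assoc.permutation_association(freqs.copy(), freqs=freqs, exact=True)
        assert ex.p <= 0.01
        assert ex.direction == "positive"
        sm = assoc.permutation_association(freqs.copy(), freqs=freqs,
                                           n_perm=10_000, seed=1)
        assert abs(sm.p - ex.p) < 3 * np.sqrt(ex.p * (1 - ex.p) / 10_000) + 1e-3

    def test_null_pvalues_uniform_with_randomized_ties(self, rng):
        tissues = [f"t{i}" for i in range(12)]
        ps = []
        for i in range(400):
            freqs = pd.Series(rng.integers(0, 8, 12) / 100.0, index=tissues)
            feat = pd.Series(rng.normal(size=12), index=tissues)
            r = assoc.permutation_association(feat, freqs=freqs, n_perm=500,
                                              seed=i, tie_break="randomized")
            if r.flag == "":
                ps.append(r.p)
        assert stats.kstest(ps, "uniform").pvalue > 0.01

    def test_fast_null_equals_literal_null_for_five_tissues(self):
        """Enumerating all 120 frequency permutations (re-deriving the split
        each time) gives exactly the group-assignment null distribution."""
        freqs = pd.Series([0.0, 0.1, 0.15, 0.5, 0.6], index=list("abcde"))
        feat = pd.Series([0.3, -1.2, 0.5, 2.0, 1.7], index=list("abcde"))
        split = assoc.gap_split(freqs)
        literal = []
        vals = freqs.values
        for perm in itertools.permutations(range(5)):
            pf = pd.Series(vals[list(perm)], index=freqs.index)
            s = assoc.gap_split(pf)
            literal.append(round(feat[s.group2].median() - feat[s.group1].median(), 9))
        fast = assoc._exact_median_diffs(
            feat.loc[split.group2 + split.group1].values, len(split.group2)
        )
        n_rep = len(literal) // len(fast)
        assert sorted(literal) == sorted(np.round(np.repeat(fast, n_rep), 9))

    def test_exact_enumeration_matches_sampled_p(self, rng):
        tissues = [f"t{i}" for i in range(8)]
        freqs = pd.Series(np.sort(rng.random(8)), index=tissues)
        feat = pd.Series(rng.normal(size=8), index=tissues)
        ex = assoc.permutation_association(feat, freqs=freqs, exact=True)
        sm = assoc.permutation_association(feat, freqs=freqs, n_perm=20_000, seed=2)
        se = np.sqrt(ex.p * (1 - ex.p) / 20_000)
        assert abs(sm.p - ex.p) < 3 * se + 1e-3

    def test_power_monotone_in_effect_size(self, rng):
        tissues = [f"t{i}" for i in range(12)]
        power = []
        for shift in (0.0, 1.0, 2.0, 3.0):
            det = 0
            for i in range(60):
                freqs = pd.Series(np.concatenate([rng.uniform(0, 0.02, 10),
                                                  [0.4, 0.45]]), index=tissues)
                feat = pd.Series(np.concatenate([rng.normal(0, 1, 10),
                                                 rng.normal(shift, 1, 2)]),
                                 index=tissues)
                r = assoc.permutation_association(feat, freqs=freqs,
                                                  n_perm=500, seed=1000 + i)
                det += r.p < 0.05
            power.append(det / 60)
        assert all(b >= a - 0.1 for a, b in zip(power, power[1:]))
        assert power[-1] > power[0] + 0.3


class TestFdrAndSummary:
    def _null_inputs(self, n_genes=60, seed=0):
        rng = np.random.default_rng(seed)
        tissues = [f"t{i}" for i in range(12)]
        genes = [f"g{i}" for i in range(n_genes)]
        freq = pd.DataFrame(rng.integers(0, 8, (n_genes, 12)) / 100.0,
                            index=genes, columns=tissues)
        feat = pd.DataFrame(rng.normal(size=(n_genes, 12)),
                            index=genes, columns=tissues)
        return feat, freq

    def test_zero_significant_flags_undefined(self):
        feat, freq = self._null_inputs()
        results = pd.DataFrame(
            {"gene": feat.index, "feature": "x", "statistic": 0.1,
             "p": 0.9, "direction": "none", "gap": 0.1,
             "n_group1": 6, "n_group2": 6, "flag": ""})
        fdr, flag = assoc.estimate_fdr(results, feat, freq, "x",
                                       n_label_perm=2, n_perm=200, seed=0)
        assert np.isnan(fdr) and flag == "no-significant-genes"

    def test_null_data_fdr_near_one(self):
        feat, freq = self._null_inputs(n_genes=150, seed=3)
        results = assoc.associate_feature(feat, freq, "x", n_perm=400,
                                          alpha=0.1, seed=5)
        fdr, flag = assoc.estimate_fdr(results, feat, freq, "x",
                                       n_label_perm=5, n_perm=400,
                                       alpha=0.1, seed=6)
        assert flag == ""
        n_sig = int((results[results.flag == ""]["p"] < 0.1).sum())
        n_perm_calls = int((results.flag == "").sum()) * 5
        se = fdr * np.sqrt(1 / max(n_sig, 1) + 1 / (0.1 * n_perm_calls))
        assert abs(fdr - 1.0) < 3 * se

    @pytest.mark.parametrize("n_sig,n_total,expect", [
        (11, 91, 0.1209), (98, 432, 0.2269), (40, 119, 0.3361), (50, 254, 0.1969),
    ])
    def test_fraction_arithmetic(self, n_sig, n_total, expect):
        results = pd.DataFrame({
            "gene": [f"g{i}" for i in range(n_total)],
            "feature": "f",
            "statistic": 1.0,
            "p": [0.001] * n_sig + [0.5] * (n_total - n_sig),
            "direction": "positive",
            "gap": 0.3, "n_group1": 6, "n_group2": 6, "flag": "",
        })
        summary = assoc.summarize_feature(results, alpha=0.03)
        assert round(summary.fraction_significant, 4) == expect

    def test_no_significant_positive_fraction_is_nan(self):
        results = pd.DataFrame({
            "gene": [f"g{i}" for i in range(10)], "feature": "f",
            "statistic": 1.0, "p": 0.9, "direction": "none",
            "gap": 0.1, "n_group1": 6, "n_group2": 6, "flag": "",
        })
        s = assoc.summarize_feature(results, alpha=0.03)
        assert s.n_significant == 0 and s.fraction_significant == 0.0
        assert np.isnan(s.positive_fraction)

    def test_class_crosstab_directions(self):
        results = pd.DataFrame({
            "gene": ["g1", "g2", "g3"], "feature": "f",
            "statistic": [1.0, -1.0, 2.0], "p": [0.001, 0.002, 0.5],
            "direction": ["positive", "negative", "none"],
            "gap": 0.3, "n_group1": 6, "n_group2": 6, "flag": "",
        })
        classes = pd.Series({"g1": "oncogene", "g2": "TSG"})
        s = assoc.summarize_feature(results, alpha=0.03, gene_class_table=classes)
        assert s.class_crosstab.loc["positive", "oncogene"] == 1
        assert s.class_crosstab.loc["negative", "TSG"] == 1
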