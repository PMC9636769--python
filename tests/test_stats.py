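"""Diversity, distances, permutation tests, enrichment: oracles and invariants."""

import itertools
import math

import numpy as np
import pandas as pd
import pytest

from viramg import stats as vs
from viramg.amg import AMGCall


def bray_oracle(x, y):
    """Direct evaluation of sum|x-y| / sum(x+y)."""
    num = sum(abs(a - b) for a, b in zip(x, y))
    den = sum(a + b for a, b in zip(x, y))
    return num / den if den else 0.0


class TestDiversity:
    def test_uniform_single_and_mixed_profiles(self):
        assert vs.diversity([1, 1, 1, 1]).shannon == pytest.approx(math.log(4))
        single = vs.diversity([0, 5, 0])
        assert (single.richness, single.shannon) == (1, 0.0)
        mixed = vs.diversity([8, 2, 0])
        assert mixed.richness == 2
        assert mixed.shannon == pytest.approx(
            -(0.8 * math.log(0.8) + 0.2 * math.log(0.2))
        )
        empty = vs.diversity([0, 0])
        assert (empty.richness, empty.shannon) == (0, 0.0)

    def test_shannon_bounded_by_log_richness(self):
        rng = np.random.default_rng(0)
        for _ in range(50):
            profile = rng.integers(0, 20, size=10)
            res = vs.diversity(profile)
            if res.richness:
                assert res.shannon <= math.log(res.richness) + 1e-12


class TestBrayCurtis:
    def test_identity_disjoint_and_worked_example(self):
        df = pd.DataFrame(
            {"a": [1, 1], "b": [1, 1], "c": [0, 2], "d": [2, 0]},
            index=["f1", "f2"],
        )
        dm = vs.bray_curtis(df)
        get = lambda i, j: dm.data[dm.labels.index(i), dm.labels.index(j)]
        assert get("a", "b") == 0.0
        assert get("c", "d") == 1.0  # disjoint supports
        assert get("a", "c") == pytest.approx(0.5)  # (1+1)/(1+3)

    def test_matches_brute_force_oracle_on_random_matrices(self):
        rng = np.random.default_rng(7)
        for _ in range(10):
            df = pd.DataFrame(rng.integers(0, 30, size=(5, 5)).astype(float),
                              columns=list("abcde"))
            dm = vs.bray_curtis(df)
            for i, j in itertools.combinations(range(5), 2):
                assert dm.data[i, j] == pytest.approx(
                    bray_oracle(df.iloc[:, i], df.iloc[:, j])
                )

    def test_all_zero_pair_is_zero_by_convention(self):
        df = pd.DataFrame({"a": [0, 0], "b": [0, 0], "c": [1, 2]})
        dm = vs.bray_curtis(df)
        assert dm.data[0, 1] == 0.0


class TestPermanova:
    def _profiles(self, seed=0, n=12, separated=False):
        rng = np.random.default_rng(seed)
        x = rng.lognormal(size=(30, n))
        if separated:
            x[:15, : n // 2] = 0.0
            x[15:, n // 2:] = 0.0
        return pd.DataFrame(x, columns=[f"s{i}" for i in range(n)])

    def test_statistic_matches_skbio(self):
        skbio = pytest.importorskip("skbio")
        from skbio.stats.distance import permanova as sk_permanova

        df = self._profiles(3)
        dm = vs.bray_curtis(df)
        groups = ["a"] * 6 + ["b"] * 6
        mine = vs.permanova(dm, groups, seed=0)
        ref = sk_permanova(
            skbio.DistanceMatrix(dm.data, ids=dm.labels), grouping=groups,
            permutations=99,
        )
        assert mine.statistic == pytest.approx(ref["test statistic"], rel=1e-10)

    def test_r_squared_partition_sums_to_one(self):
        df = self._profiles(5)
        dm = vs.bray_curtis(df)
        res = vs.permanova(dm, ["a"] * 6 + ["b"] * 6, seed=1)
        d2 = dm.data**2
        ss_total = d2.sum() / (2 * 12)
        ss_within = vs._permanova_ss(
            d2, [np.arange(6), np.arange(6, 12)]
        )
        assert res.r_squared + ss_within / ss_total == pytest.approx(1.0, abs=1e-10)

    def test_planted_disjoint_groups_reach_minimum_p(self):
        df = self._profiles(2, separated=True)
        dm = vs.bray_curtis(df)
        res = vs.permanova(dm, ["a"] * 6 + ["b"] * 6, n_perm=999, seed=0)
        assert res.p_value == pytest.approx(1 / 1000)

    def test_relabelling_invariance(self):
        df = self._profiles(9)
        dm = vs.bray_curtis(df)
        groups = ["a"] * 6 + ["b"] * 6
        order = np.r_[6:12, 0:6]
        dm2 = vs.DistanceMatrix(
            tuple(dm.labels[i] for i in order), dm.data[np.ix_(order, order)]
        )
        res1 = vs.permanova(dm, groups, seed=0)
        res2 = vs.permanova(dm2, ["b"] * 6 + ["a"] * 6, seed=0)
        assert res1.statistic == pytest.approx(res2.statistic)

    def test_single_member_group_rejected(self):
        df = self._profiles(1, n=5)
        dm = vs.bray_curtis(df)
        with pytest.raises(ValueError):
            vs.permanova(dm, ["a"] * 4 + ["b"], seed=0)


class TestMantel:
    def _dm(self, seed=0, n=10):
        rng = np.random.default_rng(seed)
        df = pd.DataFrame(rng.lognormal(size=(20, n)),
                          columns=[f"s{i}" for i in range(n)])
        return vs.bray_curtis(df)

    def test_perfect_linear_and_reversed_relations(self):
        d1 = self._dm(4)
        d2 = vs.DistanceMatrix(d1.labels, 2 * d1.data)
        assert vs.mantel(d1, d2, seed=0).statistic == pytest.approx(1.0)
        anti = d1.data.max() - d1.data
        np.fill_diagonal(anti, 0.0)
        d3 = vs.DistanceMatrix(d1.labels, anti)
        assert vs.mantel(d1, d3, seed=0).statistic == pytest.approx(-1.0)

    def test_statistic_matches_skbio(self):
        pytest.importorskip("skbio")
        import skbio
        from skbio.stats.distance import mantel as sk_mantel

        d1, d2 = self._dm(5), self._dm(6)
        mine = vs.mantel(d1, d2, seed=0)
        r_ref, _, _ = sk_mantel(
            skbio.DistanceMatrix(d1.data, ids=d1.labels),
            skbio.DistanceMatrix(d2.data, ids=d2.labels),
            permutations=0,
        )
        assert mine.statistic == pytest.approx(r_ref, rel=1e-10)

    def test_constant_distance_vector_is_an_error(self):
        labels = ("a", "b", "c")
        ones = np.ones((3, 3)) - np.eye(3)
        d1 = vs.DistanceMatrix(labels, ones)
        with pytest.raises(ValueError):
            vs.mantel(d1, d1, seed=0)


class TestFisherEnrichment:
    @staticmethod
    def fisher_oracle(a, ta, b, tb):
        """Two-sided exact p by enumerating tables with fixed margins."""
        from math import comb

        k = a + b  # carriers total
        denom = comb(ta + tb, k)
        probs = {
            x: comb(ta, x) * comb(tb, k - x) / denom
            for x in range(max(0, k - tb), min(ta, k) + 1)
        }
        p_obs = probs[a]
        return sum(p for p in probs.values() if p <= p_obs + 1e-12)

    @pytest.mark.parametrize(
        "a,ta,b,tb,expected",
        [
            (3, 3, 0, 3, 0.1),
            (2, 4, 2, 4, 1.0),
            (30, 100, 30, 100, 1.0),
        ],
    )
    def test_exact_p_values_match_enumeration_oracle(self, a, ta, b, tb, expected):
        res = vs.fisher_enrichment("u", a, ta, b, tb)
        assert res.p_value == pytest.approx(expected)
        assert res.p_value == pytest.approx(self.fisher_oracle(a, ta, b, tb))

    def test_direction_follows_frequencies(self):
        assert vs.fisher_enrichment("u", 30, 100, 30, 100).direction == "none"
        assert vs.fisher_enrichment("u", 40, 100, 5, 100).direction == "a"
        assert vs.fisher_enrichment("u", 5, 100, 40, 100).direction == "b"

    def test_zero_totals_rejected(self):
        with pytest.raises(ValueError):
            vs.fisher_enrichment("u", 0, 0, 1, 10)


class TestPathwayOccurrence:
    def _calls(self, spec):
        """spec: list of (votu, pathway) retained AMG memberships."""
        return [
            AMGCall(f"g{i}", votu, "K1", "x", pathways=frozenset({pathway}))
            for i, (votu, pathway) in enumerate(spec)
        ]

    def test_presence_absence_counting_matches_distinct_virus_oracle(self):
        groups = {f"L{i}": "lytic" for i in range(10)}
        groups.update({f"T{i}": "temperate" for i in range(10)})
        spec = [(f"L{i}", "P") for i in range(4)]
        spec += [("L0", "P"), ("L0", "P")]  # same virus repeated: counts once
        res = vs.pathway_occurrence(groups, self._calls(spec))
        (r,) = res
        assert (r.group_a_count, r.group_b_count) == (4, 0)
        assert r.frequency_a == pytest.approx(0.4)
        assert r.frequency_b == 0.0

    def test_pathway_with_no_carrier_is_omitted(self):
        groups = {"L0": "lytic", "T0": "temperate"}
        assert vs.pathway_occurrence(groups, []) == []

    def test_multi_group_runs_one_vs_rest(self):
        groups = {"a1": "A", "a2": "A", "b1": "B", "b2": "B", "c1": "C", "c2": "C"}
        res = vs.pathway_occurrence(groups, self._calls([("a1", "P"), ("b1", "P")]))
        assert {r.group_a for r in res} == {"A", "B", "C"}
        assert all(r.group_b == "rest" for r in res)


class TestHabitatEnrichment:
    def test_hand_computed_kruskal_wallis_on_three_pairs(self):
        # Groups {1,2},{3,4},{5,6}: rank sums 3,7,11 so
        # H = 12/(6*7) * (9+49+121)/2 - 3*7 = 32/7.
        df = pd.DataFrame([[1, 2, 3, 4, 5, 6]], index=["K1"],
                          columns=list("abcdef"))
        habitat_of = {"a": "FL", "b": "FL", "c": "PA", "d": "PA",
                      "e": "SE", "f": "SE"}
        out = vs.habitat_enrichment(df, habitat_of)
        assert out.loc["K1", "H"] == pytest.approx(32 / 7)
        # chi2 p for H=32/7 on 2 df is ~0.10, above the default alpha,
        # so no habitat tag; with a looser alpha the top-rank habitat wins.
        assert out.loc["K1", "enriched_habitat"] == ""
        loose = vs.habitat_enrichment(df, habitat_of, alpha=0.2)
        assert loose.loc["K1", "enriched_habitat"] == "SE"

    def test_identical_distributions_are_null(self):
        df = pd.DataFrame([[1.0] * 6], index=["K1"], columns=list("abcdef"))
        habitat_of = dict(zip("abcdef", ["FL", "FL", "PA", "PA", "SE", "SE"]))
        out = vs.habitat_enrichment(df, habitat_of)
        assert out.loc["K1", "H"] == 0.0
        assert out.loc["K1", "p_value"] == 1.0
        assert out.loc["K1", "enriched_habitat"] == ""

    def test_habitat_exclusive_ko_is_tagged_to_that_habitat(self):
        df = pd.DataFrame([[0, 0, 0, 0, 0, 0, 5, 6, 7]], index=["K1"],
                          columns=[f"s{i}" for i in range(9)])
        habitat_of = {f"s{i}": h for i, h in enumerate(
            ["FL"] * 3 + ["PA"] * 3 + ["SE"] * 3)}
        out = vs.habitat_enrichment(df, habitat_of)
        assert out.loc["K1", "p_value"] < 0.05
        assert out.loc["K1", "enriched_habitat"] == "SE"

    def test_undersampled_habitat_is_an_error(self):
        df = pd.DataFrame([[1, 2, 3]], index=["K1"], columns=list("abc"))
        with pytest.raises(ValueError):
            vs.habitat_enrichment(df, {"a": "FL", "b": "FL", "c": "SE"})


class TestRankTests:
    @staticmethod
    def mw_oracle(x, y):
        """Exact two-sided p by enumerating all rank assignments."""
        pooled = sorted(x + y)
        n = len(x)
        u_obs = sum(1 for xi in x for yi in y if xi > yi) \
            + 0.5 * sum(1 for xi in x for yi in y if xi == yi)
        us = []
        for combo in itertools.combinations(range(len(pooled)), n):
            xs = [pooled[i] for i in combo]
            ys = [pooled[i] for i in range(len(pooled)) if i not in combo]
            us.append(sum(1 for xi in xs for yi in ys if xi > yi))
        mean_u = len(x) * len(y) / 2
        tail = sum(1 for u in us if abs(u - mean_u) >= abs(u_obs - mean_u) - 1e-12)
        return tail / len(us)

    def test_separated_samples_match_enumeration_oracle(self):
        u, p = vs.mann_whitney([1, 2, 3], [4, 5, 6])
        assert u == 0.0
        assert p == pytest.approx(0.1)
        assert p == pytest.approx(self.mw_oracle([1, 2, 3], [4, 5, 6]))

    def test_identical_samples_give_p_one(self):
        _, p = vs.mann_whitney([1, 2, 3], [1, 2, 3])
        assert p == pytest.approx(1.0)

    def test_empty_group_rejected(self):
        with pytest.raises(ValueError):
            vs.mann_whitney([], [1.0])

    def test_spearman_monotone(self):
        rho, _ = vs.spearman([1, 2, 3, 4], [10, 20, 25, 90])
        assert rho == pytest.approx(1.0)

    def test_benjamini_hochberg_monotone_adjustment(self):
        adj = vs.benjamini_hochberg([0.01, 0.02, 0.5])
        assert adj[0] <= adj[1] <= adj[2]
        assert adj[2] == pytest.approx(0.5)
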