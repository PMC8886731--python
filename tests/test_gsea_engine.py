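import math

import numpy as np
import pytest

from phosphokin.gsea_engine import (
    EnrichmentResult,
    RankedList,
    classify_kinases,
    enrichment_score,
    ora,
    permutation_test,
    rank_sites,
)
from phosphokin.ksr_predict import calibrate_threshold, predict_ksrs, substrate_sets

from conftest import make_table


def brute_force_es(items, values, member_set, weight_p):
    """Materialize the running sum step by step, in plain Python."""
    hits = set(member_set)
    n = len(items)
    nh = sum(1 for it in items if it in hits)
    nr = sum(abs(v) ** weight_p for it, v in zip(items, values) if it in hits)
    running = 0.0
    peak = -math.inf
    trough = math.inf
    for it, v in zip(items, values):
        if it in hits:
            running += (abs(v) ** weight_p) / nr if nr > 0 else 1.0 / nh
        else:
            running -= 1.0 / (n - nh)
        peak = max(peak, running)
        trough = min(trough, running)
    # same tie rule as the engine: positive side wins an exact tie
    return peak if peak + trough >= -1e-9 else trough


def random_instance(rng, max_n=50):
    n = int(rng.integers(5, max_n + 1))
    items = [f"i{j}" for j in range(n)]
    values = np.sort(rng.normal(0, 1, size=n))[::-1]
    k = int(rng.integers(1, n))
    members = list(rng.choice(items, size=k, replace=False))
    return RankedList(items=tuple(items), values=values), members


class TestRankedList:
    def test_descending_with_lexicographic_tie_break(self):
        ranked = RankedList.from_pairs([("b", 1.0), ("a", 1.0), ("c", 2.0)])
        assert ranked.items == ("c", "a", "b")

    def test_duplicate_ids_rejected(self):
        with pytest.raises(ValueError, match="duplicate"):
            RankedList(items=("a", "a"), values=np.array([1.0, 0.5]))

    def test_rank_sites_site_level_order(self):
        table = make_table([("A", 1, "S", 4.0), ("B", 1, "S", 0.5), ("C", 1, "S", 2.0)])
        ranked = rank_sites(table, level="site")
        assert ranked.items == ("A_1", "C_1", "B_1")

    def test_rank_sites_protein_level_averages(self):
        table = make_table([("A", 1, "S", 2.0), ("A", 2, "S", 0.5), ("B", 1, "S", 2.0)])
        ranked = rank_sites(table, level="protein")
        value_by_item = dict(zip(ranked.items, ranked.values))
        assert value_by_item["A"] == pytest.approx(0.0)  # mean of +1 and -1 in log2
        assert value_by_item["B"] == pytest.approx(1.0)


class TestEnrichmentScore:
    def test_single_top_member_unweighted_es_is_one(self):
        ranked = RankedList.from_pairs([(f"i{j}", float(10 - j)) for j in range(10)])
        es, _ = enrichment_score(ranked, {"i0"}, weight_p=0)
        assert es == pytest.approx(1.0)

    def test_bottom_set_has_negative_es(self):
        ranked = RankedList.from_pairs([(f"i{j}", float(20 - j)) for j in range(20)])
        es, _ = enrichment_score(ranked, {"i17", "i18", "i19"}, weight_p=0)
        assert es < 0

    @pytest.mark.parametrize("weight_p", [0.0, 1.0, 2.0])
    def test_matches_brute_force_oracle(self, weight_p):
        rng = np.random.default_rng(21)
        for _ in range(200):
            ranked, members = random_instance(rng)
            es, _ = enrichment_score(ranked, members, weight_p=weight_p)
            oracle = brute_force_es(ranked.items, ranked.values, members, weight_p)
            assert es == pytest.approx(oracle, abs=1e-12)

    def test_es_bounded(self):
        rng = np.random.default_rng(3)
        for _ in range(100):
            ranked, members = random_instance(rng)
            es, _ = enrichment_score(ranked, members, weight_p=1.0)
            assert -1 - 1e-12 <= es <= 1 + 1e-12

    def test_reversing_list_negates_unweighted_es(self):
        rng = np.random.default_rng(8)
        ranked, members = random_instance(rng)
        es, _ = enrichment_score(ranked, members, weight_p=0)
        reversed_ranked = RankedList(
            items=tuple(reversed(ranked.items)), values=ranked.values[::-1].copy()
        )
        es_rev, _ = enrichment_score(reversed_ranked, members, weight_p=0)
        assert es_rev == pytest.approx(-es, abs=1e-12)

    def test_scaling_values_leaves_weighted_es_unchanged(self):
        rng = np.random.default_rng(13)
        ranked, members = random_instance(rng)
        es, _ = enrichment_score(ranked, members, weight_p=1.0)
        scaled = RankedList(items=ranked.items, values=3.7 * ranked.values)
        es_scaled, _ = enrichment_score(scaled, members, weight_p=1.0)
        assert es_scaled == pytest.approx(es, abs=1e-12)

    def test_set_equal_to_universe_rejected(self):
        ranked = RankedList.from_pairs([("a", 2.0), ("b", 1.0)])
        with pytest.raises(ValueError, match="universe"):
            enrichment_score(ranked, {"a", "b"})


class TestPermutationTest:
    def test_same_seed_reproduces_results(self):
        rng = np.random.default_rng(5)
        ranked, members = random_instance(rng, max_n=40)
        sets = {"s": members}
        first = permutation_test(ranked, sets, n_perm=200, seed=11)
        second = permutation_test(ranked, sets, n_perm=200, seed=11)
        assert first[0].nes == second[0].nes
        assert first[0].p_nominal == second[0].p_nominal

    def test_seed_is_mandatory(self):
        ranked = RankedList.from_pairs([(f"i{j}", float(j)) for j in range(10)])
        with pytest.raises(ValueError, match="seed"):
            permutation_test(ranked, {"s": ["i1", "i2", "i3"]}, n_perm=200)

    def test_undersized_sets_skipped_with_warning(self, caplog):
        import logging

        ranked = RankedList.from_pairs([(f"i{j}", float(j)) for j in range(10)])
        with caplog.at_level(logging.WARNING):
            results = permutation_test(ranked, {"tiny": ["i1"]}, n_perm=200, seed=1)
        assert results == []
        assert any("skipped" in r.message for r in caplog.records)

    def test_planted_active_kinase_set_is_positive(self, sim_result):
        for p in sim_result.profiles:
            calibrate_threshold(p, list(sim_result.sites.frame["window"][:400]), fpr=0.06)
        edges = predict_ksrs(sim_result.sites, sim_result.profiles, ppi=sim_result.ppi)
        ranked = rank_sites(sim_result.sites)
        results = permutation_test(ranked, substrate_sets(edges), n_perm=500, seed=2)
        by_name = {r.set_name: r for r in results}
        assert by_name["KIN1"].nes > 0 and by_name["KIN1"].p_nominal < 0.05
        assert by_name["KIN2"].nes < 0 and by_name["KIN2"].p_nominal < 0.05

    def test_leading_edge_is_subset_of_set_and_rank(self):
        rng = np.random.default_rng(30)
        ranked, _ = random_instance(rng, max_n=40)
        members = list(rng.choice(ranked.items, size=6, replace=False))
        results = permutation_test(ranked, {"s": members}, n_perm=200, seed=3)
        assert set(results[0].leading_edge) <= set(members) & set(ranked.items)


class TestClassifyKinases:
    @pytest.mark.parametrize(
        "nes,p,expected",
        [
            (2.1, 0.002, "positive"),
            (-1.8, 0.01, "negative"),
            (1.5, 0.2, "not_significant"),
        ],
    )
    def test_direction_labels(self, nes, p, expected):
        result = EnrichmentResult("K", math.copysign(0.5, nes), nes, p, p, [], 5)
        assert classify_kinases([result])[0].direction == expected


def hypergeom_tail_oracle(overlap, universe, set_size, n_hits):
    """P(X >= overlap) by direct enumeration of the hypergeometric pmf."""
    total = 0.0
    for x in range(overlap, min(set_size, n_hits) + 1):
        if n_hits - x > universe - set_size:
            continue
        total += (
            math.comb(set_size, x)
            * math.comb(universe - set_size, n_hits - x)
            / math.comb(universe, n_hits)
        )
    return total


class TestOra:
    def test_exact_case_universe_ten(self):
        universe = [f"g{i}" for i in range(10)]
        hits = universe[:5]
        sets = {"s": universe[1:5]}  # set of 4, overlap 4
        frame = ora(hits, universe, sets)
        assert frame.iloc[0]["overlap"] == 4
        assert frame.iloc[0]["p"] == pytest.approx(hypergeom_tail_oracle(4, 10, 4, 5), rel=1e-10)

    def test_disjoint_set_reports_zero_overlap(self):
        universe = [f"g{i}" for i in range(8)]
        frame = ora(universe[:3], universe, {"s": universe[5:]})
        assert frame.iloc[0]["overlap"] == 0
        assert frame.iloc[0]["p"] == pytest.approx(1.0)

    def test_hits_equal_universe(self):
        universe = [f"g{i}" for i in range(6)]
        frame = ora(universe, universe, {"s": universe[:4]})
        assert frame.iloc[0]["overlap"] == 4
        assert frame.iloc[0]["p"] == pytest.approx(1.0)

    def test_stray_hit_rejected(self):
        with pytest.raises(ValueError, match="universe"):
            ora(["x"], ["a", "b"], {"s": ["a"]})

    def test_q_values_are_bh_adjusted(self):
        universe = [f"g{i}" for i in range(30)]
        hits = universe[:10]
        sets = {f"s{j}": universe[j : j + 6] for j in range(0, 24, 3)}
        frame = ora(hits, universe, sets)
        order = frame["p"].argsort()
        q_sorted = frame["q"].to_numpy()[order]
        assert np.all(np.diff(q_sorted) >= -1e-12)
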