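from math import comb

import numpy as np
import pytest

from dhgomics import io
from dhgomics.pathways import (EnrichmentResult, PathwayError, PathwayRank,
                               combined_rank, extract_pathway_members,
                               go_display_selection, intersect_pathways,
                               max_symptom_score, ora, ppi_core,
                               symptom_score, topk_coverage)


def hypergeom_upper_tail_oracle(N, K, n, k):
    """Exact enumeration: P(overlap >= k) for |universe|=N, |pathway|=K,
    |hits|=n."""
    total = comb(N, n)
    return sum(comb(K, j) * comb(N - K, n - j)
               for j in range(k, min(K, n) + 1)) / total


def er(pid, p, n_hits=2, n_members=5, q=None):
    return EnrichmentResult(pid, "", n_hits, n_members, p, q if q is not None else p)


class TestOra:
    def test_matches_enumeration_on_worked_example(self):
        # universe 20, pathway 5, hits 10, overlap 4
        universe = {f"x{i}" for i in range(20)}
        members = {f"x{i}" for i in range(5)}
        hits = {f"x{i}" for i in range(4)} | {f"x{i}" for i in range(10, 16)}
        assert len(hits & members) == 4
        expected = hypergeom_upper_tail_oracle(20, 5, 10, 4)
        assert expected == pytest.approx(0.1517, abs=5e-4)
        res = ora(hits, {"PW": ("d", members)}, universe)[0]
        assert res.p_value == pytest.approx(expected, rel=1e-9)
        assert res.enrichment_score == pytest.approx(-np.log10(expected))

    def test_zero_overlap_gives_p_one(self):
        universe = {f"x{i}" for i in range(10)}
        db = {"PW": ("d", {"x0", "x1"})}
        res = ora({"x5", "x6"}, db, universe)[0]
        assert res.p_value == pytest.approx(1.0)

    def test_hits_equal_universe_degenerate(self):
        universe = {f"x{i}" for i in range(8)}
        db = {"PW": ("d", {"x0", "x1", "x2"})}
        res = ora(set(universe), db, universe)[0]
        assert res.n_hits == res.n_members == 3
        assert res.p_value == pytest.approx(1.0)

    def test_hit_outside_universe_is_listed(self):
        with pytest.raises(PathwayError, match="ghost"):
            ora({"ghost"}, {"PW": ("d", {"a"})}, {"a"})

    def test_matches_enumeration_on_random_small_universes(self):
        rng = np.random.default_rng(4)
        for _ in range(15):
            N = int(rng.integers(8, 26))
            universe = {f"x{i}" for i in range(N)}
            K = int(rng.integers(2, N))
            n = int(rng.integers(2, N))
            members = set(rng.choice(sorted(universe), K, replace=False))
            hits = set(rng.choice(sorted(universe), n, replace=False))
            k = len(hits & members)
            res = ora(hits, {"PW": ("d", members)}, universe)[0]
            assert res.p_value == pytest.approx(
                hypergeom_upper_tail_oracle(N, K, n, k), rel=1e-9)


class TestIntersect:
    def test_disjoint_significant_sets_empty(self):
        met = [er("A", 0.01), er("B", 0.5)]
        prot = [er("B", 0.5), er("C", 0.01)]
        assert intersect_pathways(met, prot) == []

    def test_identical_sets_full(self):
        met = [er("A", 0.01), er("B", 0.001)]
        assert intersect_pathways(met, list(met)) == ["B", "A"]  # by score sum


class TestGoDisplaySelection:
    def test_single_hit_terms_excluded(self):
        results = [(er("T1", 1e-9, n_hits=1), "up"), (er("T2", 0.04, n_hits=3), "up")]
        picked = go_display_selection(results)
        assert [r.pathway_id for r, _ in picked] == ["T2"]

    def test_ten_smallest_p_per_direction(self):
        ups = [(er(f"U{i:02d}", 0.001 * (i + 1), n_hits=2), "up") for i in range(12)]
        downs = [(er(f"D{i:02d}", 0.002 * (i + 1), n_hits=2), "down") for i in range(3)]
        picked = go_display_selection(ups + downs)
        up_ids = [r.pathway_id for r, d in picked if d == "up"]
        assert up_ids == [f"U{i:02d}" for i in range(10)]
        assert len([1 for _, d in picked if d == "down"]) == 3

    def test_tie_at_tenth_broken_lexicographically(self):
        results = [(er(f"T{i:02d}", 0.01, n_hits=2), "up") for i in range(11)]
        picked = go_display_selection(results)
        assert [r.pathway_id for r, _ in picked] == [f"T{i:02d}" for i in range(10)]


class TestPpiCore:
    def test_star_graph_hub_survives_induction(self):
        edges = [("HUB", f"P{i:02d}") for i in range(30)]
        core = ppi_core(edges)
        # hub degree 30 -> top-25 keeps hub + 24 leaves -> hub degree 24 > 5
        assert core == ["HUB"]

    def test_path_graph_has_no_core(self):
        edges = [("A", "B"), ("B", "C"), ("C", "D")]
        assert ppi_core(edges) == []

    def test_duplicates_and_order_do_not_matter(self):
        rng = np.random.default_rng(5)
        edges = [(f"P{int(a)}", f"P{int(b)}")
                 for a, b in rng.integers(0, 30, size=(120, 2)) if a != b]
        doubled = edges + edges[::-1]
        shuffled = [edges[i] for i in rng.permutation(len(edges))]
        assert ppi_core(edges) == ppi_core(doubled) == ppi_core(shuffled)

    def test_empty_edge_list(self):
        assert ppi_core([]) == []


class TestSymptomScore:
    @pytest.fixture()
    def symptoms(self):
        return io.load_table3_fixture()

    def test_primary_plus_tongue_pulse(self, symptoms):
        links = [("PW", "Fever and heaviness"), ("PW", "Red tongue")]
        assert symptom_score("PW", links, symptoms) == 4  # 3 + 1

    def test_all_eleven_symptoms_score_22(self, symptoms):
        links = [("PW", s) for s in symptoms.symptoms]
        assert symptom_score("PW", links, symptoms) == 22  # 3*3 + 5*2 + 3*1
        assert max_symptom_score(symptoms) == 22

    def test_unlinked_pathway_scores_zero(self, symptoms):
        assert symptom_score("PW", [("OTHER", "Red tongue")], symptoms) == 0

    def test_unknown_symptom_is_an_error(self, symptoms):
        with pytest.raises(PathwayError, match="Itchy"):
            symptom_score("PW", [("PW", "Itchy elbow")], symptoms)

    def test_score_monotone_under_edge_addition(self, symptoms):
        links = []
        last = 0
        for s in symptoms.symptoms:
            links.append(("PW", s))
            score = symptom_score("PW", links, symptoms)
            assert score >= last
            last = score


class TestCombinedRank:
    def test_double_winner_ranks_first(self):
        enr = [er("A", 1e-6), er("B", 1e-3), er("C", 0.01)]
        ranking = combined_rank(enr, {"A": 10, "B": 5, "C": 1})
        assert ranking[0].pathway_id == "A"
        assert ranking[0].combined_rank == 1

    def test_swapped_criteria_tie_broken_by_enrichment(self):
        enr = [er("A", 1e-6), er("B", 1e-3)]
        ranking = combined_rank(enr, {"A": 5, "B": 10})  # ranks (1,2) vs (2,1)
        assert [r.pathway_id for r in ranking] == ["A", "B"]

    def test_matches_brute_force_oracle_on_random_scores(self):
        rng = np.random.default_rng(6)
        pids = [f"PW{i:02d}" for i in range(18)]
        enr = [er(pid, float(rng.uniform(1e-8, 0.5))) for pid in pids]
        scores = {pid: int(rng.integers(0, 23)) for pid in pids}
        ranking = combined_rank(enr, scores)
        # oracle: explicit rank construction via two independent sorts
        es = {r.pathway_id: r.enrichment_score for r in enr}
        r1 = {p: i + 1 for i, p in enumerate(
            sorted(pids, key=lambda p: (-es[p], p)))}
        r2 = {p: i + 1 for i, p in enumerate(
            sorted(pids, key=lambda p: (-scores[p], p)))}
        expected = sorted(pids, key=lambda p: (r1[p] + r2[p], -es[p], p))
        assert [r.pathway_id for r in ranking] == expected
        assert [r.combined_rank for r in ranking] == list(range(1, 19))

    def test_order_of_input_is_immaterial(self):
        rng = np.random.default_rng(7)
        enr = [er(f"PW{i}", float(rng.uniform(0, 1))) for i in range(9)]
        scores = {r.pathway_id: int(rng.integers(0, 10)) for r in enr}
        a = [r.pathway_id for r in combined_rank(enr, scores)]
        b = [r.pathway_id for r in combined_rank(enr[::-1], scores)]
        assert a == b

    def test_missing_symptom_score_is_an_error(self):
        with pytest.raises(PathwayError):
            combined_rank([er("A", 0.1)], {})


class TestTopkCoverage:
    @pytest.fixture()
    def symptoms(self):
        return io.load_table3_fixture()

    def make_ranking(self, pids):
        return [PathwayRank(p, 1.0, 0, i + 1) for i, p in enumerate(pids)]

    def test_constructed_minimal_k_recovered(self, symptoms):
        names = symptoms.symptoms
        pids = ["P1", "P2", "P3", "P4"]
        links = [(pids[i % 4], s) for i, s in enumerate(names)]
        sel, covered, k, full = topk_coverage(self.make_ranking(pids), links,
                                              symptoms)
        assert (k, full) == (4, True)
        assert covered == frozenset(names)

    def test_single_all_covering_pathway(self, symptoms):
        links = [("P1", s) for s in symptoms.symptoms] + [("P2", "Red tongue")]
        sel, _, k, full = topk_coverage(self.make_ranking(["P1", "P2"]), links,
                                        symptoms)
        assert (sel, k, full) == (["P1"], 1, True)

    def test_no_full_coverage_returns_everything_with_flag(self, symptoms):
        links = [("P1", "Red tongue")]
        sel, covered, k, full = topk_coverage(self.make_ranking(["P1", "P2"]),
                                              links, symptoms)
        assert not full
        assert sel == ["P1", "P2"]
        assert covered == frozenset({"Red tongue"})

    def test_explicit_k_prefix(self, symptoms):
        names = symptoms.symptoms
        links = [("P1", names[0]), ("P2", names[1])]
        sel, covered, k, full = topk_coverage(self.make_ranking(["P1", "P2"]),
                                              links, symptoms, k=1)
        assert sel == ["P1"] and k == 1 and not full


class TestExtractMembers:
    def test_partition_and_set_semantics(self):
        db = {"P1": ("", {"m1", "m2", "p1"}), "P2": ("", {"m2", "p2"}),
              "P3": ("", {"m9"})}
        met, prot = extract_pathway_members(["P1", "P2"], db,
                                            {"m1", "m2", "m9"}, {"p2"})
        assert met == {"m1", "m2"}  # m2 once despite two pathways; m9 not selected pathway's
        assert prot == {"p2"}

    def test_no_selected_features_in_pathways(self):
        met, prot = extract_pathway_members(["P1"], {"P1": ("", {"x"})},
                                            {"m"}, {"p"})
        assert met == set() and prot == set()
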