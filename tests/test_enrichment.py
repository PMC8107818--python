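import itertools
import math
import random

import pytest
from hypothesis import given, settings, strategies as st

from qenp.enrichment import (
    EnrichmentRow,
    GeneSet,
    GeneSetCollection,
    bh_adjust,
    enrich_and_rerank,
    hypergeometric_p,
    read_gmt,
    run_ora,
    write_enrichment_table,
    read_enrichment_table,
)
from qenp.errors import FormatError, ValidationError
from qenp.target_sets import make_target_set
from qenp.weight_engine import TargetWeight


def enumerate_hypergeom_tail(k, n, K, N):
    """Oracle: exhaustively enumerate all C(N, n) draws from a population of
    N items of which K are marked; return the fraction with >= k marked."""
    population = range(N)
    marked = set(range(K))
    hits = total = 0
    for draw in itertools.combinations(population, n):
        total += 1
        if len(marked.intersection(draw)) >= k:
            hits += 1
    return hits / total


def bh_step_up_oracle(ps):
    """Oracle: literal step-up rule, p(i)*m/i with a cumulative min from the top."""
    m = len(ps)
    indexed = sorted(enumerate(ps), key=lambda t: t[1])
    out = [0.0] * m
    cummin = math.inf
    for rank in range(m, 0, -1):
        idx, p = indexed[rank - 1]
        cummin = min(cummin, p * m / rank)
        out[idx] = min(1.0, cummin)
    return out


class TestReadGmt:
    def test_dedup_members(self, tmp_path):
        p = tmp_path / "s.gmt"
        p.write_text("S1\tdesc\tA\tB\tA\n")
        coll = read_gmt(p)
        assert coll.sets[0].members == {"A", "B"}

    def test_empty_file_rejected(self, tmp_path):
        p = tmp_path / "e.gmt"
        p.write_text("")
        with pytest.raises(FormatError):
            read_gmt(p)

    def test_malformed_line_reports_number(self, tmp_path):
        p = tmp_path / "bad.gmt"
        p.write_text("S1\tdesc\tA\nS2\tonly-two-fields\n")
        with pytest.raises(FormatError, match=":2"):
            read_gmt(p)

    def test_three_line_fixture_exact(self, tmp_path):
        p = tmp_path / "three.gmt"
        p.write_text(
            "S1\tfirst\tA\tB\n"
            "S2\tsecond\tb\tC\tD\n"
            "S3\tthird\tE\n"
        )
        coll = read_gmt(p)
        assert len(coll) == 3
        assert [s.set_id for s in coll] == ["S1", "S2", "S3"]
        assert coll.sets[1].members == {"B", "C", "D"}

    def test_duplicate_set_id_rejected(self, tmp_path):
        p = tmp_path / "dup.gmt"
        p.write_text("S1\td\tA\nS1\td\tB\n")
        with pytest.raises(ValidationError):
            read_gmt(p)


class TestHypergeometricP:
    def test_k_zero_is_one(self):
        assert hypergeometric_p(0, 5, 4, 10) == 1.0

    def test_set_equals_universe(self):
        assert hypergeometric_p(5, 5, 10, 10) == 1.0

    def test_frozen_enumeration_example(self):
        # 66 of the C(10,5)=252 draws contain >=3 of the 4 marked items
        assert hypergeometric_p(3, 5, 4, 10) == pytest.approx(66 / 252)
        assert enumerate_hypergeom_tail(3, 5, 4, 10) == pytest.approx(66 / 252)

    def test_inconsistent_counts_rejected(self):
        with pytest.raises(ValidationError):
            hypergeometric_p(6, 5, 4, 10)
        with pytest.raises(ValidationError):
            hypergeometric_p(1, 5, 11, 10)

    @settings(max_examples=200, deadline=None)
    @given(st.data())
    def test_matches_enumeration_for_small_universes(self, data):
        N = data.draw(st.integers(min_value=1, max_value=15))
        K = data.draw(st.integers(min_value=0, max_value=N))
        n = data.draw(st.integers(min_value=0, max_value=N))
        k = data.draw(st.integers(min_value=0, max_value=min(n, K)))
        assert hypergeometric_p(k, n, K, N) == pytest.approx(
            enumerate_hypergeom_tail(k, n, K, N), abs=1e-12
        )


class TestBhAdjust:
    def test_single_p_unchanged(self):
        assert bh_adjust([0.123]) == [0.123]

    def test_hand_oracle_example(self):
        assert bh_adjust([0.01, 0.02, 0.03]) == pytest.approx([0.03, 0.03, 0.03])

    def test_all_equal_stay_equal(self):
        assert bh_adjust([0.2, 0.2, 0.2, 0.2]) == pytest.approx([0.2] * 4)

    def test_out_of_range_rejected(self):
        with pytest.raises(ValidationError):
            bh_adjust([0.0])
        with pytest.raises(ValidationError):
            bh_adjust([1.5])

    @settings(max_examples=100, deadline=None)
    @given(st.lists(st.floats(min_value=1e-9, max_value=1.0), min_size=1, max_size=40))
    def test_matches_step_up_oracle(self, ps):
        assert bh_adjust(ps) == pytest.approx(bh_step_up_oracle(ps))

    @given(st.lists(st.floats(min_value=1e-9, max_value=1.0), min_size=1, max_size=40))
    def test_never_below_raw_and_capped(self, ps):
        adj = bh_adjust(ps)
        for p, a in zip(ps, adj):
            assert a >= p - 1e-15
            assert a <= 1.0

    def test_monotone_when_sorted(self):
        ps = sorted([0.001, 0.3, 0.02, 0.9, 0.07])
        adj = bh_adjust(ps)
        assert all(b >= a for a, b in zip(adj, adj[1:]))

    def test_matches_statsmodels(self):
        # dual-route check against an established implementation
        from statsmodels.stats.multitest import multipletests

        rng = random.Random(4)
        ps = [rng.random() for _ in range(25)]
        _, expected, _, _ = multipletests(ps, method="fdr_bh")
        assert bh_adjust(ps) == pytest.approx(list(expected))


def toy_collection():
    sets = [
        GeneSet("S1", "one", frozenset({"A", "B", "C", "D", "E"})),
        GeneSet("S2", "two", frozenset({"D", "E", "F", "G", "H"})),
        GeneSet("S3", "three", frozenset({"I", "J", "K", "L", "M"})),
    ]
    return GeneSetCollection(sets=tuple(sets), namespace="pathway")


class TestRunOra:
    def test_empty_hits(self):
        out = run_ora(make_target_set("h", set()), toy_collection())
        assert out == []

    def test_exact_membership_attains_min_p(self):
        coll = toy_collection()
        hits = make_target_set("h", {"A", "B", "C", "D", "E"})
        rows = run_ora(hits, coll, min_size=1, max_size=500)
        assert rows[0].set_id == "S1"
        assert rows[0].rank_before == 1
        assert rows[0].p_value == min(r.p_value for r in rows)

    def test_rows_match_enumeration_oracle(self):
        rng = random.Random(7)
        symbols = [f"G{i}" for i in range(14)]
        sets = tuple(
            GeneSet(f"S{j}", "", frozenset(rng.sample(symbols, rng.randint(3, 7))))
            for j in range(10)
        )
        coll = GeneSetCollection(sets=sets)
        universe = make_target_set("u", symbols)
        hits = make_target_set("h", rng.sample(symbols, 6))
        rows = run_ora(hits, coll, universe, min_size=1, max_size=500)
        assert rows  # fixture produces at least one overlap
        for r in rows:
            assert r.p_value == pytest.approx(
                enumerate_hypergeom_tail(r.k, r.n, r.K, r.N), abs=1e-12
            )

    def test_zero_overlap_rows_excluded(self):
        coll = toy_collection()
        hits = make_target_set("h", {"A", "B"})
        rows = run_ora(hits, coll, min_size=1, max_size=500)
        assert {r.set_id for r in rows} == {"S1"}

    def test_size_gates(self):
        coll = toy_collection()
        hits = make_target_set("h", {"A", "D", "I"})
        rows = run_ora(hits, coll, min_size=6, max_size=500)
        assert rows == []

    def test_rank_before_is_permutation(self):
        coll = toy_collection()
        hits = make_target_set("h", {"A", "D", "I", "F"})
        rows = run_ora(hits, coll, min_size=1, max_size=500)
        assert sorted(r.rank_before for r in rows) == list(range(1, len(rows) + 1))

    def test_empty_universe_rejected(self):
        with pytest.raises(ValidationError):
            run_ora(
                make_target_set("h", {"A"}),
                toy_collection(),
                make_target_set("u", set()),
            )

    def test_hits_outside_universe_dropped(self):
        coll = toy_collection()
        universe = make_target_set("u", coll.all_symbols())
        hits = make_target_set("h", {"A", "ZZZ_NOT_IN_UNIVERSE"})
        rows = run_ora(hits, coll, universe, min_size=1, max_size=500)
        assert all(r.n == 1 for r in rows)

    def test_p_adjusted_at_least_p(self):
        coll = toy_collection()
        hits = make_target_set("h", {"A", "B", "D", "I"})
        for r in run_ora(hits, coll, min_size=1, max_size=500):
            assert r.p_adjusted >= r.p_value


class TestEnrichAndRerank:
    def test_equal_weights_order_by_count_then_p(self):
        # one compound-equivalent weight per target: pathway weight is then
        # proportional to the scored-member count k
        coll = toy_collection()
        hits = make_target_set("h", {"A", "B", "D", "F", "I"})
        weights = {s: 1.0 for s in coll.all_symbols()}
        rows = enrich_and_rerank(hits, weights, coll, min_size=1, max_size=500)
        ks = [r.k for r in rows]
        assert ks == sorted(ks, reverse=True)

    def test_planted_heavy_pathway_promoted(self):
        # S3 overlaps least (worst p) but its targets carry all the weight
        coll = toy_collection()
        hits = make_target_set("h", {"A", "B", "D", "E", "I"})
        weights = [TargetWeight("I", 100.0)]
        rows = enrich_and_rerank(hits, weights, coll, min_size=1, max_size=500)
        planted = next(r for r in rows if r.set_id == "S3")
        # manual weight sums on the fixture: S3 carries 100, others 0
        assert planted.rank_after == 1
        assert planted.rank_after < planted.rank_before

    def test_top_m_one_returns_weight_maximum(self):
        coll = toy_collection()
        hits = make_target_set("h", {"A", "D", "I"})
        weights = {"D": 5.0}
        rows = enrich_and_rerank(hits, weights, coll, top_m=1, min_size=1, max_size=500)
        assert len(rows) == 1
        assert rows[0].rank_after == 1

    def test_reranking_preserves_set_of_pathways(self):
        coll = toy_collection()
        hits = make_target_set("h", {"A", "B", "D", "F", "I", "J"})
        before = run_ora(hits, coll, min_size=1, max_size=500)
        after = enrich_and_rerank(hits, {"A": 3.0}, coll, top_m=None,
                                  min_size=1, max_size=500)
        assert {r.set_id for r in before} == {r.set_id for r in after}

    def test_rank_permutations(self):
        coll = toy_collection()
        hits = make_target_set("h", {"A", "B", "D", "F", "I", "J"})
        rows = enrich_and_rerank(hits, {"A": 3.0, "F": 1.0}, coll, top_m=None,
                                 min_size=1, max_size=500)
        m = len(rows)
        assert sorted(r.rank_before for r in rows) == list(range(1, m + 1))
        assert sorted(r.rank_after for r in rows) == list(range(1, m + 1))


def test_results_table_roundtrip(tmp_path):
    coll = toy_collection()
    hits = make_target_set("h", {"A", "B", "D", "I"})
    rows = enrich_and_rerank(hits, {"A": 2.0}, coll, min_size=1, max_size=500)
    p = tmp_path / "enr.tsv"
    write_enrichment_table(rows, p)
    back = read_enrichment_table(p)
    assert [r.set_id for r in back] == [r.set_id for r in rows]
    assert [r.rank_after for r in back] == [r.rank_after for r in rows]
    for a, b in zip(back, rows):
        assert a.p_value == pytest.approx(b.p_value, rel=1e-5)
        assert a.p_weight == pytest.approx(b.p_weight, rel=1e-5)
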