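import pytest

from happhase.placement import (AlignmentRecord, HaplotigPlacement, PafError,
                                chain_placements, filter_placements, read_paf,
                                read_placements, write_placements)


def rec(q="h1", ql=1000, qs=0, qe=100, strand="+", t="p1", tl=10_000,
        ts=0, te=100, matches=None, bl=None):
    span = te - ts
    return AlignmentRecord(q, ql, qs, qe, strand, t, tl, ts, te,
                           span if matches is None else matches,
                           span if bl is None else bl)


class TestReadPaf:
    def test_maps_fields_verbatim(self, tmp_path):
        p = tmp_path / "a.paf"
        p.write_text("h1\t100\t0\t100\t+\tp1\t1000\t200\t300\t95\t100\t60\n")
        (r,) = read_paf(p)
        assert (r.target_start, r.target_end) == (200, 300)
        assert (r.query_id, r.target_id, r.strand) == ("h1", "p1", "+")
        assert (r.matches, r.block_len) == (95, 100)

    def test_empty_file_gives_empty_list(self, tmp_path):
        p = tmp_path / "empty.paf"
        p.write_text("")
        assert read_paf(p) == []

    def test_short_line_names_line_number(self, tmp_path):
        p = tmp_path / "bad.paf"
        p.write_text("h1\t100\t0\t100\t+\tp1\t1000\t200\t300\t95\t100\t60\n"
                     "h2\t100\t0\t100\t+\tp1\t1000\t200\t300\t95\t100\n")
        with pytest.raises(PafError, match="line 2"):
            read_paf(p)

    def test_bad_coordinates_rejected(self, tmp_path):
        p = tmp_path / "bad.paf"
        p.write_text("h1\t100\t90\t10\t+\tp1\t1000\t200\t300\t95\t100\t60\n")
        with pytest.raises(PafError, match="line 1"):
            read_paf(p)


class TestChaining:
    def test_two_colinear_subalignments_merge(self):
        # brute-force over the 3 possible chains: {a}, {b}, {a,b}; the
        # colinear pair wins with score 80 + 120 = 200
        a = rec(qs=0, qe=100, ts=100, te=200, matches=80, bl=100)
        b = rec(qs=150, qe=300, ts=250, te=400, matches=120, bl=150)
        (p,) = chain_placements([a, b])
        assert (p.p_start, p.p_end, p.score) == (100, 400, 200)

    def test_single_subalignment_is_identity(self):
        a = rec(qs=10, qe=60, ts=500, te=550, matches=45, bl=50)
        (p,) = chain_placements([a])
        assert (p.p_start, p.p_end, p.score, p.strand) == (500, 550, 45, "+")

    def test_different_primaries_yield_separate_candidates(self):
        a = rec(t="p1", ts=0, te=100)
        b = rec(t="p2", ts=0, te=100)
        ps = chain_placements([a, b])
        assert sorted(p.primary_id for p in ps) == ["p1", "p2"]

    def test_non_colinear_pair_keeps_best_single(self):
        # both cover the same query span: cannot chain
        a = rec(qs=0, qe=100, ts=100, te=200, matches=90, bl=100)
        b = rec(qs=0, qe=100, ts=300, te=400, matches=70, bl=100)
        (p,) = chain_placements([a, b])
        assert (p.p_start, p.p_end, p.score) == (100, 200, 90)

    def test_minus_strand_chains_query_decreasing(self):
        a = rec(strand="-", qs=200, qe=300, ts=100, te=200, matches=90, bl=100)
        b = rec(strand="-", qs=0, qe=100, ts=300, te=400, matches=80, bl=100)
        (p,) = chain_placements([a, b])
        assert (p.p_start, p.p_end, p.score) == (100, 400, 170)

    def test_score_bounded_by_total_matches(self):
        recs = [rec(qs=i * 100, qe=i * 100 + 50, ts=i * 200, te=i * 200 + 50,
                    matches=40, bl=50) for i in range(4)]
        (p,) = chain_placements(recs)
        assert p.score == sum(r.matches for r in recs)  # all mutually colinear


class TestFiltering:
    def test_clear_winner_kept(self):
        ps = [HaplotigPlacement("h1", "p1", 0, 5000, "+", 200),
              HaplotigPlacement("h1", "p2", 0, 5000, "+", 50)]
        out = filter_placements(ps, uniqueness_ratio=0.8)
        assert [(p.haplotig_id, p.primary_id) for p in out] == [("h1", "p1")]

    def test_near_tie_discarded_as_non_unique(self):
        # 99/100 > 0.8 means ambiguous mapping
        ps = [HaplotigPlacement("h1", "p1", 0, 5000, "+", 100),
              HaplotigPlacement("h1", "p2", 0, 5000, "+", 99)]
        assert filter_placements(ps, uniqueness_ratio=0.8) == []

    def test_contained_placement_removed(self):
        ps = [HaplotigPlacement("h1", "p1", 100, 4000, "+", 300),
              HaplotigPlacement("h2", "p1", 1200, 1800, "+", 50)]
        out = filter_placements(ps)
        assert [p.haplotig_id for p in out] == ["h1"]

    def test_partial_overlap_trimmed_to_disjoint(self):
        ps = [HaplotigPlacement("h1", "p1", 0, 5000, "+", 500),
              HaplotigPlacement("h2", "p1", 3000, 9000, "+", 400)]
        out = filter_placements(ps, min_len=1000)
        assert [(p.p_start, p.p_end) for p in out] == [(0, 5000), (5000, 9000)]

    def test_trimmed_below_min_len_dropped(self):
        ps = [HaplotigPlacement("h1", "p1", 0, 5000, "+", 500),
              HaplotigPlacement("h2", "p1", 4500, 5400, "+", 400)]
        out = filter_placements(ps, min_len=1000)
        assert [p.haplotig_id for p in out] == ["h1"]

    def test_idempotent(self):
        ps = [HaplotigPlacement("h1", "p1", 0, 5000, "+", 500),
              HaplotigPlacement("h2", "p1", 3000, 9000, "+", 400),
              HaplotigPlacement("h3", "p1", 8000, 8500, "+", 100)]
        once = filter_placements(ps)
        assert filter_placements(once) == once

    def test_result_sorted_and_non_nested(self, small_sim):
        out = filter_placements(small_sim["placements"])
        by_primary = {}
        for p in out:
            by_primary.setdefault(p.primary_id, []).append(p)
        for plist in by_primary.values():
            assert plist == sorted(plist, key=lambda p: p.p_start)
            for a, b in zip(plist, plist[1:]):
                assert a.p_end <= b.p_start  # disjoint, hence non-nested


def test_placement_table_round_trip(tmp_path, small_sim):
    path = tmp_path / "placements.tsv"
    write_placements(small_sim["placements"], path)
    assert read_placements(path) == list(small_sim["placements"])
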