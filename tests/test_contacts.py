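import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from happhase.contacts import (ContactMatrix, ReadPairRecord, build_matrix,
                               count_re_sites, normalize_matrix,
                               pair_passes_filter, read_matrix,
                               read_pairs_alignments, read_pairs_tsv,
                               write_matrix)


def pair(seg_i="s1", seg_j="s2", mq=(30, 30), nm=(0, 0), rid="r1"):
    return ReadPairRecord(rid, seg_i, seg_j, mq[0], mq[1], nm[0], nm[1])


class TestPairFilter:
    @pytest.mark.parametrize("mq,nm,expected", [
        ((30, 30), (0, 0), True),
        ((10, 30), (0, 0), False),   # MAPQ exactly 10 fails (strict >)
        ((30, 10), (0, 0), False),
        ((11, 11), (4, 4), True),    # just inside both strict bounds
        ((30, 30), (5, 0), False),   # NM exactly 5 fails (strict <)
        ((30, 30), (0, 5), False),
        ((0, 0), (0, 0), False),
    ])
    def test_strict_thresholds(self, mq, nm, expected):
        assert pair_passes_filter(pair(mq=mq, nm=nm)) is expected

    def test_monotone_in_mapq_threshold(self):
        pairs = [pair(mq=(q1, q2), rid=f"r{q1}_{q2}")
                 for q1 in range(0, 61, 5) for q2 in range(0, 61, 5)]
        kept = [sum(pair_passes_filter(p, mapq_min=t) for p in pairs)
                for t in range(0, 61, 10)]
        assert kept == sorted(kept, reverse=True)


class TestReSites:
    @pytest.mark.parametrize("seq,motif,expected", [
        ("GATCGATC", "GATC", 2),
        ("AAAA", "GATC", 0),
        ("AAAA", "AA", 3),         # overlapping occurrences count
        ("gatcGATC", "GATC", 2),   # case-insensitive
    ])
    def test_counts(self, seq, motif, expected):
        assert count_re_sites(seq, motif) == expected

    def test_overlap_matches_brute_force(self):
        rng = np.random.default_rng(0)
        for _ in range(20):
            seq = "".join(rng.choice(list("ACGT"), 200))
            motif = "".join(rng.choice(list("ACGT"), 3))
            brute = sum(seq[i:i + 3] == motif for i in range(198))
            assert count_re_sites(seq, motif) == brute

    def test_empty_motif_rejected(self):
        with pytest.raises(ValueError):
            count_re_sites("ACGT", "")

    def test_motif_list_sums(self):
        assert count_re_sites("GATCAAGCTT", ["GATC", "AAGCTT"]) == 2


class TestBuildMatrix:
    def test_pair_counts_symmetric(self):
        cm = build_matrix([pair(rid=f"r{i}") for i in range(3)], ["s1", "s2"])
        assert cm.raw("s1", "s2") == cm.raw("s2", "s1") == 3

    def test_no_pairs_zero_matrix(self):
        cm = build_matrix([], ["s1", "s2"])
        assert not cm.M.any()

    def test_self_pairs_on_diagonal(self):
        pairs = [pair(rid="a"), pair(rid="b"),
                 pair("s1", "s1", rid="c")]
        cm = build_matrix(pairs, ["s1", "s2"])
        assert cm.raw("s1", "s2") == 2
        assert cm.raw("s1", "s1") == 1

    def test_unknown_segment_raises(self):
        with pytest.raises(KeyError, match="unknown segment"):
            build_matrix([pair(seg_j="nope")], ["s1", "s2"])

    def test_filter_applied_unless_prefiltered(self):
        pairs = [pair(rid="good"), pair(rid="bad", mq=(10, 30))]
        assert build_matrix(pairs, ["s1", "s2"]).raw("s1", "s2") == 1
        assert build_matrix(pairs, ["s1", "s2"],
                            prefiltered=True).raw("s1", "s2") == 2


class TestNormalize:
    def test_direct_arithmetic(self):
        cm = build_matrix([pair(rid=f"r{i}") for i in range(10)], ["s1", "s2"])
        normalize_matrix(cm, {"s1": 3, "s2": 2})
        assert cm.normalized("s1", "s2") == pytest.approx(10 / 5)

    def test_zero_sites_convention(self):
        cm = build_matrix([pair(rid=f"r{i}") for i in range(7)], ["s1", "s2"])
        normalize_matrix(cm, {"s1": 0, "s2": 0})
        assert cm.normalized("s1", "s2") == 0.0

    def test_zero_counts_stay_zero(self):
        cm = build_matrix([], ["s1", "s2"])
        normalize_matrix(cm, {"s1": 4, "s2": 4})
        assert cm.normalized("s1", "s2") == 0.0

    @settings(deadline=None, max_examples=25)
    @given(st.integers(0, 2**31 - 1))
    def test_randomized_symmetry_and_scaling(self, seed):
        rng = np.random.default_rng(seed)
        n = int(rng.integers(2, 8))
        segs = [f"s{i}" for i in range(n)]
        M = rng.integers(0, 50, (n, n))
        M = M + M.T
        z = rng.integers(0, 10, n)
        cm = ContactMatrix(segments=segs, M=M.astype(np.int64))
        normalize_matrix(cm, z.astype(np.int64))
        assert np.allclose(cm.Mhat, cm.Mhat.T)
        denom = z[:, None] + z[None, :]
        expect = np.where(denom > 0, M / np.where(denom > 0, denom, 1), 0.0)
        assert np.allclose(cm.Mhat, expect)
        # doubling every z halves every defined entry
        cm2 = ContactMatrix(segments=segs, M=M.astype(np.int64))
        normalize_matrix(cm2, (2 * z).astype(np.int64))
        assert np.allclose(cm2.Mhat, expect / 2)


class TestIO:
    def test_pair_tsv_six_and_seven_columns(self, tmp_path):
        p = tmp_path / "pairs.tsv"
        p.write_text("r1\ts1\ts2\t30\t40\t2\n"
                     "r2\ts1\ts2\t30\t40\t1\t3\n")
        a, b = list(read_pairs_tsv(p))
        assert (a.nm_1, a.nm_2) == (2, 2)
        assert (b.nm_1, b.nm_2) == (1, 3)

    def test_matrix_round_trip(self, tmp_path):
        pairs = [pair(rid=f"r{i}") for i in range(5)] + \
                [pair("s2", "s3", rid=f"q{i}") for i in range(2)]
        cm = build_matrix(pairs, ["s1", "s2", "s3"])
        normalize_matrix(cm, {"s1": 1, "s2": 2, "s3": 0})
        write_matrix(cm, tmp_path / "m.tsv", tmp_path / "s.tsv")
        cm2 = read_matrix(tmp_path / "m.tsv", tmp_path / "s.tsv")
        assert cm2.segments == cm.segments
        assert np.array_equal(cm2.M, cm.M)
        assert np.allclose(cm2.Mhat, cm.Mhat)

    def test_sam_pairing(self, tmp_path):
        sam = tmp_path / "pairs.sam"
        sam.write_text(
            "@HD\tVN:1.6\tSO:queryname\n"
            "@SQ\tSN:s1\tLN:1000\n@SQ\tSN:s2\tLN:1000\n"
            "r1\t65\ts1\t100\t60\t10M\t=\t1\t0\tACGTACGTAC\t*\tNM:i:1\n"
            "r1\t129\ts2\t200\t60\t10M\t=\t1\t0\tACGTACGTAC\t*\tNM:i:2\n"
            # secondary alignment must be ignored, not treated as a mate
            "r2\t321\ts1\t300\t60\t10M\t=\t1\t0\tACGTACGTAC\t*\tNM:i:0\n"
            "r2\t65\ts1\t300\t60\t10M\t=\t1\t0\tACGTACGTAC\t*\tNM:i:0\n"
            "r2\t129\ts2\t400\t60\t10M\t=\t1\t0\tACGTACGTAC\t*\tNM:i:0\n")
        got = list(read_pairs_alignments(sam))
        assert len(got) == 2
        assert {g.read_id for g in got} == {"r1", "r2"}
        r1 = next(g for g in got if g.read_id == "r1")
        assert {r1.seg_i, r1.seg_j} == {"s1", "s2"}
        assert {r1.nm_1, r1.nm_2} == {1, 2}

    def test_sam_missing_mate_raises(self, tmp_path):
        sam = tmp_path / "orphan.sam"
        sam.write_text(
            "@HD\tVN:1.6\tSO:queryname\n@SQ\tSN:s1\tLN:1000\n"
            "r1\t65\ts1\t100\t60\t10M\t=\t1\t0\tACGTACGTAC\t*\tNM:i:1\n")
        with pytest.raises(ValueError, match="mate"):
            list(read_pairs_alignments(sam))
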