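import numpy as np
import pytest

from happhase.benchmarks import random_phasing_instance
from happhase.contacts import ContactMatrix, normalize_matrix
from happhase.mince import PhaseBlock, PhaseBlockIndex
from happhase.phaser import (PhasingConfig, alpha, beta, exhaustive_phase,
                             gamma, phase_freq, run_phasing,
                             run_phasing_contig)


def two_block_matrix(aa=0.0, bb=0.0, ab=0.0, ba=0.0):
    """Mhat over segments [A1, B1, A2, B2] with the four inter-block
    entries set explicitly."""
    M = np.zeros((4, 4))
    C = np.array([[0, 1], [2, 3]])
    M[0, 2] = M[2, 0] = aa
    M[1, 3] = M[3, 1] = bb
    M[0, 3] = M[3, 0] = ab
    M[1, 2] = M[2, 1] = ba
    return M, C


class TestLinkFunctions:
    def test_gamma_is_equality_indicator(self):
        assert gamma(0, 1, [1, 1]) == 1
        assert gamma(0, 1, [1, 0]) == 0
        T = [0, 1, 1, 0]
        for i in range(4):
            for j in range(4):
                if i != j:
                    assert gamma(i, j, T) == gamma(j, i, T)

    def test_alpha_sums_cross_entries(self):
        M, C = two_block_matrix(ab=0.4, ba=0.6)
        assert alpha(1, 0, M, C) == pytest.approx(1.0)

    def test_alpha_zero_on_empty_matrix(self):
        M, C = two_block_matrix()
        assert alpha(0, 1, M, C) == 0.0

    def test_beta_sums_all_four_entries_and_bounds_alpha(self):
        M, C = two_block_matrix(aa=0.1, bb=0.2, ab=0.4, ba=0.6)
        assert beta(0, 1, M, C) == pytest.approx(1.3)
        assert beta(0, 1, M, C) == beta(1, 0, M, C)
        assert alpha(0, 1, M, C) <= beta(0, 1, M, C)

    def test_phase_freq_splits_consistent_mass(self):
        # same assignment: support is the cis_same share (beta - alpha)/beta
        M, C = two_block_matrix(aa=0.1, bb=0.1, ab=0.4, ba=0.4)
        assert phase_freq(1, [1, 1], M, C) == pytest.approx(0.2 / 1.0)
        # different assignment: support is the alpha share
        assert phase_freq(1, [0, 1], M, C) == pytest.approx(0.8 / 1.0)

    def test_phase_freq_no_links_is_half(self):
        M, C = two_block_matrix()
        assert phase_freq(1, [0, 1], M, C) == 0.5

    def test_phase_freq_always_a_probability(self):
        rng = np.random.default_rng(5)
        for _ in range(30):
            m = int(rng.integers(2, 7))
            Mhat, C, _ = random_phasing_instance(m, rng, snr=rng.uniform(1, 8))
            T = rng.integers(0, 2, m)
            for i in range(1, m):
                assert 0.0 <= phase_freq(i, T, Mhat, C) <= 1.0


class TestRunPhasing:
    CFG = PhasingConfig(n=20_000, b=2_000, seed=0)

    def test_same_phase_signal_gives_matching_assignment(self):
        # exhaustive oracle over the 2 configurations picks [0, 0]
        M, C = two_block_matrix(aa=1.0, bb=1.0)
        assert exhaustive_phase(M, C).tolist() == [0, 0]
        hits = 0
        for seed in range(100):
            rng = np.random.default_rng(seed)
            st = run_phasing_contig(M, C, self.CFG, rng)
            hits += st.R.tolist() == [0, 0]
        assert hits >= 99

    def test_cross_phase_signal_gives_opposite_assignment(self):
        M, C = two_block_matrix(ab=1.0, ba=1.0)
        assert exhaustive_phase(M, C).tolist() == [0, 1]
        hits = 0
        for seed in range(100):
            rng = np.random.default_rng(seed)
            st = run_phasing_contig(M, C, self.CFG, rng)
            hits += st.R.tolist() == [0, 1]
        assert hits >= 99

    def test_single_block_uniform_and_reproducible(self):
        M = np.zeros((2, 2))
        C = np.array([[0, 1]])
        draws = {run_phasing_contig(M, C, self.CFG,
                                    np.random.default_rng(s)).R[0]
                 for s in range(20)}
        assert draws == {0, 1}
        a = run_phasing_contig(M, C, self.CFG, np.random.default_rng(7)).R
        b = run_phasing_contig(M, C, self.CFG, np.random.default_rng(7)).R
        assert np.array_equal(a, b)

    def test_block_zero_pinned(self):
        rng = np.random.default_rng(3)
        Mhat, C, _ = random_phasing_instance(5, rng)
        for seed in range(5):
            st = run_phasing_contig(Mhat, C, self.CFG,
                                    np.random.default_rng(seed))
            assert st.R[0] == 0

    def test_invalid_budget_rejected(self):
        with pytest.raises(ValueError):
            PhasingConfig(n=100, b=100, seed=0)
        with pytest.raises(ValueError):
            PhasingConfig(n=100, b=200, seed=0)

    def test_phase_flip_symmetry(self):
        # swapping the A/B members of every block except block 0 flips R
        rng = np.random.default_rng(11)
        Mhat, C, _ = random_phasing_instance(5, rng, snr=8.0)
        C_flipped = C.copy()
        C_flipped[1:] = C_flipped[1:, ::-1]
        r1 = exhaustive_phase(Mhat, C)
        r2 = exhaustive_phase(Mhat, C_flipped)
        assert np.array_equal(r2[1:], 1 - r1[1:])
        st1 = run_phasing_contig(Mhat, C, self.CFG, np.random.default_rng(1))
        st2 = run_phasing_contig(Mhat, C_flipped, self.CFG,
                                 np.random.default_rng(1))
        assert np.array_equal(st2.R[1:], 1 - st1.R[1:])

    def test_seeded_determinism_across_contig_order(self):
        rng = np.random.default_rng(2)
        Mhat, C, _ = random_phasing_instance(4, rng)
        segs = [f"s{i}" for i in range(8)]
        cm = ContactMatrix(segments=segs, M=np.zeros((8, 8), dtype=np.int64))
        cm.Mhat = Mhat

        def index_for(pid, C):
            blocks = [PhaseBlock(k, segs[a], segs[b], "+", k * 10, k * 10 + 5)
                      for k, (a, b) in enumerate(C)]
            return PhaseBlockIndex(primary_id=pid, blocks=blocks)

        idx_a = index_for("pA", C)
        idx_b = index_for("pB", C)
        cfg = PhasingConfig(n=5_000, b=500, seed=9)
        fwd = run_phasing(cm, {"pA": idx_a, "pB": idx_b}, cfg)
        rev = run_phasing(cm, {"pB": idx_b, "pA": idx_a}, cfg)
        for pid in ("pA", "pB"):
            assert np.array_equal(fwd[pid].R, rev[pid].R)


class TestExhaustiveOracle:
    def test_all_zero_matrix_lexicographic_tie_break(self):
        M = np.zeros((6, 6))
        C = np.arange(6).reshape(3, 2)
        assert exhaustive_phase(M, C).tolist() == [0, 0, 0]

    def test_matches_truth_on_strong_signal(self):
        rng = np.random.default_rng(17)
        for _ in range(20):
            m = int(rng.integers(3, 9))
            Mhat, C, truth = random_phasing_instance(m, rng, snr=20.0)
            assert np.array_equal(exhaustive_phase(Mhat, C), truth)

    def test_too_many_blocks_rejected(self):
        C = np.arange(40).reshape(20, 2)
        with pytest.raises(ValueError, match="exceeds"):
            exhaustive_phase(np.zeros((40, 40)), C)


def test_accuracy_degrades_with_noise():
    """Recovery should trend downward as cross-phase noise grows."""
    from happhase.benchmarks import run_clean_pipeline
    from happhase.simulate import SimConfig

    means = []
    for noise in (0.0, 0.15, 0.3, 0.4, 0.5):
        accs = []
        for seed in range(3):
            cfg = SimConfig(n_contigs=4, contig_len=60_000, n_blocks=4,
                            block_len=6_000, n_pairs=20_000,
                            decay_scale=15_000.0, noise_fraction=noise,
                            seed=100 + seed)
            res = run_clean_pipeline(cfg, n_iter=20_000, burn_in=2_000,
                                     kmer_eval=False)
            accs.append(res.block_accuracy)
        means.append(np.mean(accs))
    assert means[0] >= 0.99
    assert means[0] >= means[2] >= means[4] - 0.05
    assert means[-1] < 0.8
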