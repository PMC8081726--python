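"""Validation experiments on simulated data.

These runners drive the whole package — simulator, placement chaining,
mincing, contact counting, the stochastic sweep, emission and the parental
k-mer scorer — and measure the quantities the package is validated by:
agreement of the sweep with exhaustive enumeration, end-to-end phasing
accuracy on clean simulations, the no-signal null, and the before/after
parental k-mer contrast.  Both the test suite and ``scripts/acceptance.py``
call into this module so the numbers they report come from one code path.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Iterator, Sequence

import numpy as np
import pandas as pd

from .contacts import (ReadPairRecord, build_matrix, count_re_sites,
                       normalize_matrix)
from .emit import emit_contig
from .evaluate import build_marker_set, score_sequences
from .mince import mince_assembly
from .model import ContigPhasingModel
from .phaser import PhasingConfig, exhaustive_phase, run_phasing_contig
from .placement import chain_placements, filter_placements
from .simulate import (SimConfig, score_phasing, simulate_assembly,
                       simulate_pairs)

__all__ = [
    "random_phasing_instance",
    "oracle_agreement",
    "run_clean_pipeline",
    "clean_recovery",
    "null_block_accuracy",
    "CleanRunResult",
]

TEST_ITERATIONS = 100_000
TEST_BURN_IN = 10_000


def random_phasing_instance(
    m: int, rng: np.random.Generator, snr: float = 5.0
) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    """A synthetic normalized matrix over ``m`` blocks with a known truth.

    Every inter-block segment pair gets a link weight drawn U(0.5, 1.5);
    the two entries consistent with the truth configuration are scaled by
    ``snr``, so normalized cis links outweigh trans links ``snr``-fold.
    Returns (Mhat, C, truth).
    """
    truth = np.zeros(m, dtype=np.int8)
    truth[1:] = rng.integers(0, 2, size=m - 1)
    n_seg = 2 * m
    C = np.arange(n_seg, dtype=np.int64).reshape(m, 2)  # [A_k, B_k] = [2k, 2k+1]
    Mhat = np.zeros((n_seg, n_seg))
    for i in range(m):
        for j in range(i):
            aa, bb, ab, ba = rng.uniform(0.5, 1.5, size=4)
            if truth[i] == truth[j]:
                aa *= snr
                bb *= snr
            else:
                ab *= snr
                ba *= snr
            Ai, Bi = C[i]
            Aj, Bj = C[j]
            for (x, y, v) in ((Ai, Aj, aa), (Bi, Bj, bb),
                              (Ai, Bj, ab), (Bi, Aj, ba)):
                Mhat[x, y] = Mhat[y, x] = v
    return Mhat, C, truth


def oracle_agreement(
    n_instances: int = 100,
    seed: int = 0,
    n_iter: int = TEST_ITERATIONS,
    burn_in: int = TEST_BURN_IN,
    snr: float = 5.0,
    block_range: tuple[int, int] = (3, 8),
) -> dict:
    """Fraction of random instances on which the stochastic sweep returns
    exactly the configuration exhaustive enumeration finds optimal."""
    master = np.random.default_rng(seed)
    config = PhasingConfig(n=n_iter, b=burn_in, seed=seed)
    agree = 0
    for _ in range(n_instances):
        m = int(master.integers(block_range[0], block_range[1] + 1))
        Mhat, C, _truth = random_phasing_instance(m, master, snr=snr)
        rng = np.random.default_rng(master.integers(2**31))
        state = run_phasing_contig(Mhat, C, config, rng)
        oracle = exhaustive_phase(Mhat, C)
        agree += int(np.array_equal(state.R, oracle))
    return {"agreement_rate": agree / n_instances, "n": n_instances}


def _pairs_to_records(pairs: pd.DataFrame) -> Iterator[ReadPairRecord]:
    for row in pairs.itertuples(index=False):
        yield ReadPairRecord(row.read_id, row.seg_i, row.seg_j,
                             row.mapq_1, row.mapq_2, row.nm_1, row.nm_2)


@dataclass
class CleanRunResult:
    """Measurements from one simulated end-to-end run."""

    block_accuracy: float
    kmer_accuracy_after: float
    kmer_accuracy_before: float
    informative_fraction_observed: float
    min_adjacent_pair_count: int
    per_contig_accuracy: dict[str, float] = field(repr=False, default_factory=dict)


def run_clean_pipeline(
    cfg: SimConfig,
    n_iter: int = TEST_ITERATIONS,
    burn_in: int = TEST_BURN_IN,
    kmer_eval: bool = True,
    k: int = 21,
) -> CleanRunResult:
    """Simulate one dataset and push it through the full pipeline in
    memory, measuring block-level and parental k-mer accuracy."""
    asm = simulate_assembly(cfg)
    placements = filter_placements(chain_placements(asm.alignments),
                                   min_len=min(1000, cfg.block_len))
    segments, indexes = mince_assembly(asm.primaries, placements, asm.haplotigs)
    rng = np.random.default_rng(cfg.seed + 1)
    pairs = simulate_pairs(cfg, asm, indexes, rng)

    matrix = build_matrix(_pairs_to_records(pairs), segments)
    z = {s.seg_id: count_re_sites(s.sequence, cfg.re_motif) for s in segments}
    normalize_matrix(matrix, z)

    model = ContigPhasingModel(matrix, indexes)
    results = model.fit(n_iter=n_iter, burn_in=burn_in, seed=cfg.seed)
    block_acc, per_contig = score_phasing(asm.truth, results.phases)

    # informative fraction actually emitted, and the sparsest adjacent link
    inf_obs = len(pairs) / cfg.n_pairs if cfg.n_pairs else float("nan")
    adjacent = pairs[(pairs.block_j - pairs.block_i).abs() == 1]
    if cfg.n_blocks >= 2 and cfg.n_contigs >= 1:
        counts = adjacent.groupby(
            ["contig", adjacent[["block_i", "block_j"]].min(axis=1)]
        ).size()
        expected = cfg.n_contigs * (cfg.n_blocks - 1)
        min_adj = int(counts.min()) if len(counts) == expected else 0
    else:
        min_adj = 0

    if not kmer_eval:
        return CleanRunResult(block_acc, float("nan"), float("nan"),
                              inf_obs, min_adj, per_contig)

    seg_map = {s.seg_id: s for s in segments}
    phased_seqs: dict[str, str] = {}
    for pid, idx in indexes.items():
        pair_out = emit_contig(seg_map, idx, results.phases[pid])
        phased_seqs[f"{pid}_phase0"] = pair_out.phase0_seq
        phased_seqs[f"{pid}_phase1"] = pair_out.phase1_seq

    markers = build_marker_set(asm.parent_genomes[0].values(),
                               asm.parent_genomes[1].values(),
                               k=k, min_count=1)
    _, acc_after = score_sequences(markers, phased_seqs)
    _, acc_before = score_sequences(markers, asm.primaries)
    return CleanRunResult(block_acc, acc_after, acc_before, inf_obs,
                          min_adj, per_contig)


def clean_recovery(
    seeds: Sequence[int],
    n_iter: int = TEST_ITERATIONS,
    burn_in: int = TEST_BURN_IN,
    **sim_kwargs,
) -> list[CleanRunResult]:
    """The end-to-end recovery experiment at default study conditions, one
    run per seed."""
    out = []
    for s in seeds:
        cfg = SimConfig(seed=int(s), **sim_kwargs)
        out.append(run_clean_pipeline(cfg, n_iter=n_iter, burn_in=burn_in))
    return out


def null_block_accuracy(
    seeds: Sequence[int],
    n_iter: int = TEST_ITERATIONS,
    burn_in: int = TEST_BURN_IN,
) -> list[float]:
    """Block accuracy when half of all informative pairs are cross-phase:
    the matrix carries no net signal, so accuracy should sit at chance.
    Run at a reduced geometry so 20 replicates cost seconds."""
    accs = []
    for s in seeds:
        cfg = SimConfig(
            n_contigs=8, contig_len=150_000, n_blocks=16, block_len=5_000,
            n_pairs=80_000, decay_scale=15_000.0, noise_fraction=0.5,
            seed=int(s))
        res = run_clean_pipeline(cfg, n_iter=n_iter, burn_in=burn_in,
                                 kmer_eval=False)
        accs.append(res.block_accuracy)
    return accs
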