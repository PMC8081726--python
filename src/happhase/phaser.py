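"""Stochastic phase assignment of A/B haplotype blocks along a contig.

Each phase block k on a primary contig is an (A_k, B_k) pair of minced
segments carrying the two parental haplotypes of one heterozygous region.
The block's diploid configuration is binary: 0 for [0, 1] (A in output
haplotype 0, B in haplotype 1) or 1 for [1, 0].  Hi-C read pairs connect
segments of the *same* parental chromosome far more often than segments of
different chromosomes, so the restriction-site-normalized contact matrix
``Mhat`` carries the signal needed to co-phase the blocks.

For an ordered pair of blocks (i, j) four inter-block entries of ``Mhat``
exist.  Two of them support *equal* configurations (``T[i] == T[j]``)::

    cis_same(i, j) = Mhat[A_i, A_j] + Mhat[B_i, B_j]

and two support *opposite* configurations::

    cis_diff(i, j) = Mhat[A_i, B_j] + Mhat[B_i, A_j]        (alpha)

with normalizing constant::

    beta(i, j) = cis_same(i, j) + cis_diff(i, j)

The sampler sweeps the blocks of each contig in order.  Visiting block i it
hypothesizes configuration 1 and computes the fraction of normalized link
mass to all *past* blocks j < i that is consistent with that hypothesis::

    phase_freq(i) = sum_{j<i} [ T[j]==1 ? cis_same(i,j) : cis_diff(i,j) ]
                    / sum_{j<i} beta(i, j)

then keeps T[i] = 1 iff a uniform draw falls below phase_freq (a zero
denominator — no links to the past — yields 0.5, an uninformed coin flip).
Block 0 is pinned to configuration 0 since per-contig phase labels are
arbitrary.  After a burn-in of ``b`` sweeps, each of the remaining ``n - b``
sweeps scores every block's state; the final assignment ``R[k]`` is the
majority state, ties resolved to 1.

``exhaustive_phase`` enumerates all configurations of small instances and
is the independent oracle the stochastic sweep is tested against.
"""

from __future__ import annotations

import hashlib
import itertools
from dataclasses import dataclass, field
from typing import Mapping, Sequence

import numpy as np

from .contacts import ContactMatrix
from .mince import PhaseBlockIndex

__all__ = [
    "PhasingConfig",
    "PhasingState",
    "gamma",
    "alpha",
    "beta",
    "phase_freq",
    "block_link_arrays",
    "run_phasing_contig",
    "run_phasing",
    "exhaustive_phase",
]

DEFAULT_ITERATIONS = 1_000_000
DEFAULT_BURN_IN = 100_000


@dataclass(frozen=True)
class PhasingConfig:
    """Sweep budget: ``n`` total sweeps, the first ``b`` discarded as
    burn-in, and the master RNG seed."""

    n: int = DEFAULT_ITERATIONS
    b: int = DEFAULT_BURN_IN
    seed: int = 0

    def __post_init__(self) -> None:
        if not (0 <= self.b < self.n):
            raise ValueError(f"need 0 <= burn-in < iterations, got b={self.b}, n={self.n}")


@dataclass
class PhasingState:
    """Result of one contig's sweep: final assignment ``R`` plus the
    per-block fraction of scored sweeps spent in state 1."""

    R: np.ndarray
    phase1_freq: np.ndarray

    @property
    def m(self) -> int:
        return len(self.R)


def gamma(i: int, j: int, T: Sequence[int]) -> int:
    """Same-configuration indicator: 1 iff ``T[i] == T[j]``."""
    if i == j:
        raise ValueError("gamma is defined for distinct blocks")
    return 1 if T[i] == T[j] else 0


def _block_pair_entries(i: int, j: int, Mhat: np.ndarray, C: np.ndarray
                        ) -> tuple[float, float, float, float]:
    ai, bi = C[i]
    aj, bj = C[j]
    return (Mhat[ai, aj], Mhat[bi, bj], Mhat[ai, bj], Mhat[bi, aj])


def alpha(i: int, j: int, Mhat: np.ndarray, C: np.ndarray) -> float:
    """Cross-member link weight ``Mhat[A_i,B_j] + Mhat[B_i,A_j]`` — the
    normalized link mass supporting *opposite* configurations of blocks i
    and j."""
    _, _, ab, ba = _block_pair_entries(i, j, Mhat, C)
    return float(ab + ba)


def beta(i: int, j: int, Mhat: np.ndarray, C: np.ndarray) -> float:
    """All four inter-block entries — the normalizing constant
    ``Mhat[A_i,A_j] + Mhat[B_i,B_j] + Mhat[A_i,B_j] + Mhat[B_i,A_j]``."""
    aa, bb, ab, ba = _block_pair_entries(i, j, Mhat, C)
    return float(aa + bb + ab + ba)


def phase_freq(i: int, T: Sequence[int], Mhat: np.ndarray, C: np.ndarray) -> float:
    """Fraction of normalized Hi-C link mass between block i and all past
    blocks j < i that is consistent with the current hypothesis ``T[i]``.

    Consistent mass for a past block j is ``cis_same = beta - alpha`` when
    ``T[j] == T[i]`` and ``alpha`` otherwise.  Returns 0.5 when block i has
    no links to any past block.
    """
    num = 0.0
    den = 0.0
    for j in range(i):
        a = alpha(i, j, Mhat, C)
        b = beta(i, j, Mhat, C)
        num += (b - a) if gamma(i, j, T) else a
        den += b
    if den <= 0.0:
        return 0.5
    return num / den


def block_link_arrays(Mhat: np.ndarray, C: np.ndarray
                      ) -> tuple[np.ndarray, np.ndarray]:
    """Precompute the (m, m) ``cis_same`` and ``cis_diff`` arrays for one
    contig's block index ``C`` (an (m, 2) array of [A, B] segment indices)."""
    A = C[:, 0]
    B = C[:, 1]
    cis_same = Mhat[np.ix_(A, A)] + Mhat[np.ix_(B, B)]
    cis_diff = Mhat[np.ix_(A, B)] + Mhat[np.ix_(B, A)]
    return cis_same, cis_diff


def _sweep_kernel(cis_same: np.ndarray, cis_diff: np.ndarray,
                  denom: np.ndarray, T: np.ndarray, P: np.ndarray,
                  u: np.ndarray, n: int, b: int) -> None:
    """n sweeps over blocks 1..m-1; block 0 stays pinned.  ``u`` holds the
    pre-drawn uniforms, shape (n, m-1).  Counts post-burn-in state-1 visits
    into P."""
    m = T.shape[0]
    for sweep in range(n):
        for i in range(1, m):
            num = 0.0
            for j in range(i):
                if T[j] == 1:
                    num += cis_same[i, j]
                else:
                    num += cis_diff[i, j]
            den = denom[i]
            pf = 0.5 if den <= 0.0 else num / den
            t = 1 if pf >= u[sweep, i - 1] else 0
            T[i] = t
            if sweep >= b:
                P[i] += t


try:  # pragma: no cover - exercised implicitly everywhere
    from numba import njit

    _sweep_kernel_jit = njit(cache=True)(_sweep_kernel)
except ImportError:  # pragma: no cover
    _sweep_kernel_jit = _sweep_kernel


def _contig_seed(master_seed: int, primary_id: str) -> np.random.SeedSequence:
    """Independent, contig-order-invariant stream per primary contig."""
    digest = hashlib.blake2b(primary_id.encode(), digest_size=8).digest()
    return np.random.SeedSequence([int(master_seed), int.from_bytes(digest, "big")])


def run_phasing_contig(Mhat: np.ndarray, C: np.ndarray,
                       config: PhasingConfig,
                       rng: np.random.Generator) -> PhasingState:
    """Phase the ordered blocks of one contig.

    ``C`` is the (m, 2) array of [A, B] segment indices into ``Mhat``.
    m == 0 returns an empty state; m == 1 draws the single block uniformly
    (its label is unconstrained); otherwise block 0 is pinned to 0, the
    rest are randomly initialized once and resampled for ``config.n``
    sweeps, the last ``n - b`` of which are scored.
    """
    m = len(C)
    if m == 0:
        return PhasingState(R=np.zeros(0, dtype=np.int8),
                            phase1_freq=np.zeros(0))
    if m == 1:
        r = int(rng.integers(0, 2))
        return PhasingState(R=np.array([r], dtype=np.int8),
                            phase1_freq=np.array([float(r)]))

    cis_same, cis_diff = block_link_arrays(Mhat, C)
    btot = cis_same + cis_diff
    denom = np.array([btot[i, :i].sum() for i in range(m)])

    T = np.zeros(m, dtype=np.int8)
    T[1:] = rng.integers(0, 2, size=m - 1).astype(np.int8)
    P = np.zeros(m, dtype=np.int64)
    # uniforms are pre-drawn in sweep-major order so results are identical
    # with and without the JIT-compiled kernel
    chunk = 200_000  # cap the uniform buffer at ~m*chunk doubles
    done = 0
    scored = config.n - config.b
    while done < config.n:
        step = min(chunk, config.n - done)
        u = rng.random((step, m - 1))
        _sweep_kernel_jit(cis_same, cis_diff, denom, T, P, u,
                          step, max(0, config.b - done))
        done += step
    freq = P / scored
    R = (freq >= 0.5).astype(np.int8)
    R[0] = 0
    freq[0] = 0.0
    return PhasingState(R=R, phase1_freq=freq)


def run_phasing(matrix: ContactMatrix,
                indexes: Mapping[str, PhaseBlockIndex],
                config: PhasingConfig) -> dict[str, PhasingState]:
    """Phase every contig of a minced assembly.

    Each contig gets an independent RNG stream derived from the master seed
    and the contig name, so contig order never changes results.  Requires a
    normalized matrix (``Mhat``).
    """
    if matrix.Mhat is None:
        raise ValueError("contact matrix is not normalized; call normalize_matrix")
    results: dict[str, PhasingState] = {}
    for pid, idx in indexes.items():
        C = np.array(
            [[matrix.idx(b.a_seg), matrix.idx(b.b_seg)] for b in idx.blocks],
            dtype=np.int64,
        ).reshape(-1, 2)
        rng = np.random.Generator(np.random.PCG64(_contig_seed(config.seed, pid)))
        results[pid] = run_phasing_contig(matrix.Mhat, C, config, rng)
    return results


def exhaustive_phase(Mhat: np.ndarray, C: np.ndarray, max_blocks: int = 16
                     ) -> np.ndarray:
    """Brute-force oracle: enumerate all 2^(m-1) configurations with block 0
    pinned to 0 and return the one maximizing total assignment-consistent
    normalized link mass, ties broken lexicographically.

    Intended for tests and tiny instances only (m <= ``max_blocks``).
    """
    m = len(C)
    if m > max_blocks:
        raise ValueError(f"{m} blocks exceeds exhaustive limit {max_blocks}")
    if m == 0:
        return np.zeros(0, dtype=np.int8)
    if m == 1:
        return np.zeros(1, dtype=np.int8)
    cis_same, cis_diff = block_link_arrays(Mhat, C)
    best_R = None
    best_score = -np.inf
    for bits in itertools.product((0, 1), repeat=m - 1):
        R = np.array((0,) + bits, dtype=np.int8)
        score = 0.0
        for i in range(m):
            for j in range(i):
                score += cis_same[i, j] if R[i] == R[j] else cis_diff[i, j]
        if score > best_score + 1e-12:
            best_score = score
            best_R = R
    return best_R
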