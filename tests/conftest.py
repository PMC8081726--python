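import numpy as np
import pytest

from happhase.mince import mince_assembly
from happhase.placement import chain_placements, filter_placements
from happhase.simulate import SimConfig, simulate_assembly, simulate_pairs


@pytest.fixture(scope="session")
def small_cfg() -> SimConfig:
    """A fast simulated diploid: 3 contigs of 60 kb with three 8 kb blocks."""
    return SimConfig(
        n_contigs=3, contig_len=60_000, n_blocks=3, block_len=8_000,
        heterozygosity=0.01, n_pairs=30_000, informative_fraction=0.25,
        decay_scale=20_000.0, noise_fraction=0.02, seed=42)


@pytest.fixture(scope="session")
def small_sim(small_cfg):
    """Simulated assembly + placements + minced segments + pairs, shared
    across tests that only read it."""
    asm = simulate_assembly(small_cfg)
    placements = filter_placements(chain_placements(asm.alignments))
    segments, indexes = mince_assembly(asm.primaries, placements, asm.haplotigs)
    rng = np.random.default_rng(small_cfg.seed + 1)
    pairs = simulate_pairs(small_cfg, asm, indexes, rng)
    return {
        "cfg": small_cfg,
        "asm": asm,
        "placements": placements,
        "segments": segments,
        "indexes": indexes,
        "pairs": pairs,
    }
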