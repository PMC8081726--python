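"""Model/Results interface over the stochastic phasing sweep.

``ContigPhasingModel`` binds the data — a normalized contact matrix and the
ordered phase-block index of each primary contig — and ``fit`` runs the
sampler, returning a ``PhasingResults`` object carrying the point estimate
(the majority-vote assignment per block), its support (the fraction of
scored sweeps each block spent in configuration 1, a posterior-frequency
style uncertainty), and a ``summary()`` table.
"""

from __future__ import annotations

from pathlib import Path
from typing import Mapping, Sequence

import numpy as np
import pandas as pd

from .contacts import ContactMatrix, read_matrix
from .mince import PhaseBlockIndex, read_index
from .phaser import (DEFAULT_BURN_IN, DEFAULT_ITERATIONS, PhasingConfig,
                     PhasingState, exhaustive_phase, run_phasing)

__all__ = ["ContigPhasingModel", "PhasingResults"]


class ContigPhasingModel:
    """Joint phase-assignment model for the blocks of a minced assembly.

    Parameters
    ----------
    matrix
        Restriction-site-normalized Hi-C contact matrix over minced
        segments (``normalize_matrix`` must have been applied).
    indexes
        Ordered phase-block index per primary contig.
    """

    def __init__(self, matrix: ContactMatrix,
                 indexes: Mapping[str, PhaseBlockIndex]):
        if matrix.Mhat is None:
            raise ValueError("matrix must be normalized before modelling")
        for idx in indexes.values():
            for b in idx.blocks:
                matrix.idx(b.a_seg), matrix.idx(b.b_seg)  # validate coverage
        self.matrix = matrix
        self.indexes = dict(indexes)

    @classmethod
    def from_files(cls, edges_tsv: str | Path, segments_tsv: str | Path,
                   index_tsv: str | Path) -> "ContigPhasingModel":
        """Build the model from the on-disk edge list, segment table and
        phase-block index."""
        return cls(read_matrix(edges_tsv, segments_tsv), read_index(index_tsv))

    @property
    def n_blocks(self) -> int:
        return sum(idx.m for idx in self.indexes.values())

    def fit(self, n_iter: int = DEFAULT_ITERATIONS,
            burn_in: int = DEFAULT_BURN_IN, seed: int = 0) -> "PhasingResults":
        """Run the stochastic sweep (``n_iter`` sweeps, first ``burn_in``
        discarded) on every contig and collect the majority-vote phases."""
        config = PhasingConfig(n=n_iter, b=burn_in, seed=seed)
        states = run_phasing(self.matrix, self.indexes, config)
        return PhasingResults(self, config, states)

    def fit_exhaustive(self) -> "PhasingResults":
        """Enumerate all configurations per contig (tiny instances only) —
        the deterministic oracle counterpart of :meth:`fit`."""
        states = {}
        for pid, idx in self.indexes.items():
            C = np.array(
                [[self.matrix.idx(b.a_seg), self.matrix.idx(b.b_seg)]
                 for b in idx.blocks], dtype=np.int64).reshape(-1, 2)
            R = exhaustive_phase(self.matrix.Mhat, C)
            states[pid] = PhasingState(R=R, phase1_freq=R.astype(float))
        return PhasingResults(self, None, states)


class PhasingResults:
    """Fitted phase assignments.

    ``phases`` maps each contig to its 0/1 block assignment;
    ``support`` to the fraction of scored sweeps spent in state 1 (values
    near 0 or 1 indicate a confidently phased block, values near 0.5 an
    uninformative one)."""

    def __init__(self, model: ContigPhasingModel,
                 config: PhasingConfig | None,
                 states: Mapping[str, PhasingState]):
        self.model = model
        self.config = config
        self.states = dict(states)

    @property
    def phases(self) -> dict[str, np.ndarray]:
        return {pid: st.R for pid, st in self.states.items()}

    @property
    def support(self) -> dict[str, np.ndarray]:
        return {pid: st.phase1_freq for pid, st in self.states.items()}

    def to_frame(self) -> pd.DataFrame:
        """Phase table: one row per block with its assignment and the
        sampler's state-1 frequency."""
        rows = []
        for pid, st in sorted(self.states.items()):
            idx = self.model.indexes[pid]
            for k, block in enumerate(idx.blocks):
                rows.append({
                    "primary_id": pid, "rank": k,
                    "a_seg": block.a_seg, "b_seg": block.b_seg,
                    "phase": int(st.R[k]),
                    "phase1_freq": float(st.phase1_freq[k]),
                })
        return pd.DataFrame(
            rows, columns=["primary_id", "rank", "a_seg", "b_seg",
                           "phase", "phase1_freq"])

    def to_tsv(self, path: str | Path) -> None:
        self.to_frame().to_csv(path, sep="\t", index=False)

    def summary(self) -> str:
        """Human-readable fit summary."""
        df = self.to_frame()
        n_contigs = len(self.states)
        n_blocks = len(df)
        decisive = ((df.phase1_freq - 0.5).abs() >= 0.4).sum() if n_blocks else 0
        lines = [
            "Contig phasing model",
            "=" * 52,
            f"contigs:            {n_contigs}",
            f"phase blocks:       {n_blocks}",
        ]
        if self.config is not None:
            lines += [
                f"sweeps (burn-in):   {self.config.n} ({self.config.b})",
                f"seed:               {self.config.seed}",
            ]
            if n_blocks:
                lines.append(
                    f"decisive blocks:    {decisive} "
                    f"(|state-1 freq - 0.5| >= 0.4)")
        else:
            lines.append("method:             exhaustive enumeration")
        if n_blocks:
            lines.append("-" * 52)
            with pd.option_context("display.max_rows", 40):
                lines.append(df.to_string(index=False))
        return "\n".join(lines)


def read_phases(path: str | Path) -> dict[str, list[int]]:
    """Read a phase table written by :meth:`PhasingResults.to_tsv` into the
    contig -> assignment mapping the emitter consumes."""
    df = pd.read_csv(path, sep="\t")
    out: dict[str, list[int]] = {}
    for pid, grp in df.groupby("primary_id", sort=True):
        out[pid] = grp.sort_values("rank").phase.astype(int).tolist()
    return out
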