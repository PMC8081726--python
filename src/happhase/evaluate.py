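"""Parent-marker phasing accuracy.

With sequence data from both parents of the assembled individual, k-mers
present in one parent and absent from the other are haplotype markers: a
perfectly phased output sequence carries markers of a single parent, while
a phase switch mixes the two.  This module builds the two disjoint marker
sets (canonical k-mers, default k=21) and scores phased FASTA outputs with
a stringent marker-weighted measure: every sequence is assigned its
majority parent and *every* minority marker occurrence counts as an error,

    accuracy = sum_over_sequences(majority-parent marker count)
               / sum_over_sequences(total marker count).
"""

from __future__ import annotations

import gzip
from dataclasses import dataclass
from pathlib import Path
from typing import Iterable, Sequence

import numpy as np
import pandas as pd
from Bio import SeqIO

from ._kmers import canonical_kmers

__all__ = [
    "MarkerSet",
    "build_marker_set",
    "score_sequences",
    "read_seqs",
]

DEFAULT_K = 21
DEFAULT_MIN_COUNT = 2


@dataclass
class MarkerSet:
    """Disjoint parent-specific canonical k-mer sets, stored as sorted
    uint64 code arrays."""

    k: int
    parent1_specific: np.ndarray
    parent2_specific: np.ndarray

    def __post_init__(self) -> None:
        self.parent1_specific = np.sort(np.asarray(self.parent1_specific,
                                                   dtype=np.uint64))
        self.parent2_specific = np.sort(np.asarray(self.parent2_specific,
                                                   dtype=np.uint64))
        if _in_sorted(self.parent1_specific, self.parent2_specific).any():
            raise ValueError("marker sets must be disjoint")

    def swapped(self) -> "MarkerSet":
        return MarkerSet(self.k, self.parent2_specific, self.parent1_specific)


def _count_kmers(seqs: Iterable[str], k: int) -> tuple[np.ndarray, np.ndarray]:
    parts = [canonical_kmers(s, k) for s in seqs]
    allk = np.concatenate(parts) if parts else np.zeros(0, dtype=np.uint64)
    return np.unique(allk, return_counts=True)


def _in_sorted(values: np.ndarray, sorted_arr: np.ndarray) -> np.ndarray:
    """Membership of ``values`` in a sorted array, via binary search."""
    if sorted_arr.size == 0:
        return np.zeros(values.shape, dtype=bool)
    pos = np.searchsorted(sorted_arr, values)
    pos[pos == sorted_arr.size] = sorted_arr.size - 1
    return sorted_arr[pos] == values


def build_marker_set(
    parent1_seqs: Iterable[str],
    parent2_seqs: Iterable[str],
    k: int = DEFAULT_K,
    min_count: int = DEFAULT_MIN_COUNT,
) -> MarkerSet:
    """Identify parent-specific canonical k-mers.

    A k-mer is parent-1-specific when it occurs at least ``min_count``
    times in parent 1 and never in parent 2 (and vice versa).  For raw
    sequencing reads ``min_count`` >= 2 suppresses error k-mers; for
    assembled parental sequences use ``min_count=1``.
    """
    if k < 1:
        raise ValueError("k must be >= 1")
    if min_count < 1:
        raise ValueError("min_count must be >= 1")
    k1, c1 = _count_kmers(parent1_seqs, k)
    k2, c2 = _count_kmers(parent2_seqs, k)
    p1 = k1[(c1 >= min_count) & ~_in_sorted(k1, k2)]
    p2 = k2[(c2 >= min_count) & ~_in_sorted(k2, k1)]
    return MarkerSet(k=k, parent1_specific=p1, parent2_specific=p2)


def score_sequences(
    markers: MarkerSet,
    sequences: dict[str, str] | Sequence[tuple[str, str]],
) -> tuple[pd.DataFrame, float]:
    """Count each parent's markers in every sequence and compute overall
    accuracy.

    Returns a per-sequence table (name, length, count1, count2, assigned
    parent, accuracy) plus the marker-weighted overall accuracy; sequences
    containing no markers are reported with parent 0 (unassigned) and do
    not contribute.  Swapping parent labels leaves the overall accuracy
    unchanged.
    """
    items = sequences.items() if isinstance(sequences, dict) else sequences
    # one merged sorted lookup array: markers below the boundary are
    # parent 1's, at or above parent 2's
    merged = np.concatenate([markers.parent1_specific, markers.parent2_specific])
    order = np.argsort(merged, kind="stable")
    merged_sorted = merged[order]
    is_p1_sorted = order < markers.parent1_specific.size
    rows = []
    correct = 0
    total = 0
    for name, seq in items:
        kmers = np.sort(canonical_kmers(seq, markers.k))  # sorted: fast lookup
        c1 = c2 = 0
        if kmers.size and merged_sorted.size:
            pos = np.searchsorted(merged_sorted, kmers)
            pos[pos == merged_sorted.size] = merged_sorted.size - 1
            hit = merged_sorted[pos] == kmers
            c1 = int(np.count_nonzero(is_p1_sorted[pos[hit]]))
            c2 = int(np.count_nonzero(hit)) - c1
        n = c1 + c2
        maj = max(c1, c2)
        rows.append({
            "name": name,
            "length": len(seq),
            "count1": c1,
            "count2": c2,
            "assigned_parent": 0 if n == 0 else (1 if c1 >= c2 else 2),
            "accuracy": maj / n if n else float("nan"),
        })
        correct += maj
        total += n
    table = pd.DataFrame(rows)
    overall = correct / total if total else float("nan")
    return table, overall


def read_seqs(path: str | Path) -> dict[str, str]:
    """Read FASTA/FASTQ (optionally gzipped) into a name -> sequence dict."""
    path = Path(path)
    name = path.name.lower()
    fmt = "fastq" if any(name.endswith(s) for s in
                         (".fq", ".fastq", ".fq.gz", ".fastq.gz")) else "fasta"
    opener = gzip.open if name.endswith(".gz") else open
    with opener(path, "rt") as fh:
        return {rec.id: str(rec.seq) for rec in SeqIO.parse(fh, fmt)}
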