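"""Haplotig placement: read PAF alignments, chain, and filter to one clean
placement per haplotig.

A partially phased diploid assembly consists of long primary contigs plus
shorter alternate haplotigs, each representing the second haplotype of a
heterozygous ("unzipped") region.  Aligners report a haplotig against its
primary contig as several sub-alignments; this module chains them in one
dimension into a single placement interval per (haplotig, primary, strand)
group, then filters the candidates down to at most one placement per haplotig
such that placements on any primary contig are mutually disjoint — the
precondition for mincing.

Coordinates are 0-based half-open throughout, matching PAF.
"""

from __future__ import annotations

from dataclasses import dataclass, replace
from pathlib import Path
from typing import Iterable, Sequence

__all__ = [
    "AlignmentRecord",
    "HaplotigPlacement",
    "PafError",
    "read_paf",
    "chain_placements",
    "filter_placements",
    "write_placements",
    "read_placements",
]

DEFAULT_UNIQUENESS_RATIO = 0.8
DEFAULT_MIN_PLACEMENT_LEN = 1000


class PafError(ValueError):
    """Raised for malformed PAF input."""


@dataclass(frozen=True)
class AlignmentRecord:
    """One PAF line: a sub-alignment of a haplotig (query) on a primary
    contig (target)."""

    query_id: str
    query_len: int
    query_start: int
    query_end: int
    strand: str
    target_id: str
    target_len: int
    target_start: int
    target_end: int
    matches: int
    block_len: int

    def __post_init__(self) -> None:
        if not (0 <= self.query_start < self.query_end <= self.query_len):
            raise ValueError(
                f"bad query interval for {self.query_id}: "
                f"[{self.query_start},{self.query_end}) / {self.query_len}"
            )
        if not (0 <= self.target_start < self.target_end <= self.target_len):
            raise ValueError(
                f"bad target interval for {self.query_id} on {self.target_id}: "
                f"[{self.target_start},{self.target_end}) / {self.target_len}"
            )
        if self.strand not in "+-":
            raise ValueError(f"bad strand {self.strand!r}")
        if self.matches > self.block_len:
            raise ValueError("matches cannot exceed alignment block length")


@dataclass(frozen=True)
class HaplotigPlacement:
    """A single placement of a haplotig on its primary contig.

    ``score`` is the total number of matched bases of the chained
    sub-alignments supporting the placement.
    """

    haplotig_id: str
    primary_id: str
    p_start: int
    p_end: int
    strand: str
    score: int

    def __post_init__(self) -> None:
        if self.p_start >= self.p_end:
            raise ValueError(
                f"empty placement interval for {self.haplotig_id}: "
                f"[{self.p_start},{self.p_end})"
            )

    @property
    def length(self) -> int:
        return self.p_end - self.p_start

    def contains(self, other: "HaplotigPlacement") -> bool:
        return (
            self.primary_id == other.primary_id
            and self.p_start <= other.p_start
            and other.p_end <= self.p_end
        )


def read_paf(path: str | Path) -> list[AlignmentRecord]:
    """Parse a PAF file (12 mandatory tab-separated columns; extra columns
    ignored) into :class:`AlignmentRecord` rows.

    Raises :class:`PafError` naming the offending line on malformed input.
    """
    records: list[AlignmentRecord] = []
    with open(path) as fh:
        for lineno, line in enumerate(fh, start=1):
            line = line.rstrip("\n")
            if not line:
                continue
            fields = line.split("\t")
            if len(fields) < 12:
                raise PafError(
                    f"{path}: line {lineno}: expected >=12 PAF columns, "
                    f"got {len(fields)}"
                )
            try:
                rec = AlignmentRecord(
                    query_id=fields[0],
                    query_len=int(fields[1]),
                    query_start=int(fields[2]),
                    query_end=int(fields[3]),
                    strand=fields[4],
                    target_id=fields[5],
                    target_len=int(fields[6]),
                    target_start=int(fields[7]),
                    target_end=int(fields[8]),
                    matches=int(fields[9]),
                    block_len=int(fields[10]),
                )
            except ValueError as exc:
                raise PafError(f"{path}: line {lineno}: {exc}") from exc
            records.append(rec)
    return records


def _colinear(a: AlignmentRecord, b: AlignmentRecord) -> bool:
    # b follows a on the target; the query must advance in the strand-aware
    # direction. Strictly increasing on both axes, no overlap, zero gap cost.
    if b.target_start < a.target_end:
        return False
    if a.strand == "+":
        return b.query_start >= a.query_end
    return b.query_end <= a.query_start


def chain_placements(records: Iterable[AlignmentRecord]) -> list[HaplotigPlacement]:
    """Chain sub-alignments in one dimension per (haplotig, primary, strand)
    group and return one candidate placement per group.

    The chain maximizes total matched bases over colinear sub-alignments
    (strictly increasing on both query and target, strand-aware, no gap
    penalty); the placement spans the chain's outermost target coordinates.
    A group with no colinear pair yields its single best record.
    """
    groups: dict[tuple[str, str, str], list[AlignmentRecord]] = {}
    for rec in records:
        groups.setdefault((rec.query_id, rec.target_id, rec.strand), []).append(rec)

    placements: list[HaplotigPlacement] = []
    for (query_id, target_id, strand), group in sorted(groups.items()):
        group.sort(key=lambda r: (r.target_start, r.target_end))
        n = len(group)
        best_score = [r.matches for r in group]
        prev = [-1] * n
        for i in range(n):
            for j in range(i):
                if _colinear(group[j], group[i]):
                    cand = best_score[j] + group[i].matches
                    if cand > best_score[i]:
                        best_score[i] = cand
                        prev[i] = j
        end = max(range(n), key=lambda i: best_score[i])
        chain = []
        i = end
        while i != -1:
            chain.append(group[i])
            i = prev[i]
        chain.reverse()
        placements.append(
            HaplotigPlacement(
                haplotig_id=query_id,
                primary_id=target_id,
                p_start=min(r.target_start for r in chain),
                p_end=max(r.target_end for r in chain),
                strand=strand,
                score=best_score[end],
            )
        )
    return placements


def filter_placements(
    placements: Sequence[HaplotigPlacement],
    uniqueness_ratio: float = DEFAULT_UNIQUENESS_RATIO,
    min_len: int = DEFAULT_MIN_PLACEMENT_LEN,
) -> list[HaplotigPlacement]:
    """Reduce candidate placements to a clean, disjoint set.

    1. Per haplotig, keep the highest-scoring candidate; if the second-best
       score exceeds ``uniqueness_ratio`` x best, the haplotig maps
       non-uniquely and is discarded entirely.
    2. Per primary contig, in descending score order: drop placements fully
       contained in an already-retained placement; trim placements that
       partially overlap a retained one (largest surviving piece kept),
       dropping them if trimmed below ``min_len``.

    The result has at most one placement per haplotig and pairwise-disjoint
    intervals per primary contig; the function is idempotent.
    """
    by_haplotig: dict[str, list[HaplotigPlacement]] = {}
    for p in placements:
        by_haplotig.setdefault(p.haplotig_id, []).append(p)

    unique: list[HaplotigPlacement] = []
    for hid in sorted(by_haplotig):
        cands = sorted(by_haplotig[hid], key=lambda p: -p.score)
        if len(cands) > 1 and cands[1].score > uniqueness_ratio * cands[0].score:
            continue  # non-unique mapping
        unique.append(cands[0])

    # Containment removal + overlap trimming, highest score wins.
    unique.sort(key=lambda p: (-p.score, p.primary_id, p.p_start, p.haplotig_id))
    kept: dict[str, list[HaplotigPlacement]] = {}
    for p in unique:
        retained = kept.setdefault(p.primary_id, [])
        start, end = p.p_start, p.p_end
        dead = False
        for q in retained:
            if q.p_start <= start and end <= q.p_end:
                dead = True
                break
            # trim the overlap away, keeping the larger surviving side
            if q.p_start < end and start < q.p_end:
                left = (start, min(end, q.p_start))
                right = (max(start, q.p_end), end)
                start, end = max((left, right), key=lambda iv: iv[1] - iv[0])
                if end - start <= 0:
                    dead = True
                    break
        if dead or end - start < min_len:
            continue
        retained.append(replace(p, p_start=start, p_end=end))

    out = [p for plist in kept.values() for p in plist]
    out.sort(key=lambda p: (p.primary_id, p.p_start))
    return out


def write_placements(placements: Sequence[HaplotigPlacement], path: str | Path) -> None:
    """Write the placement table (TSV: haplotig_id, primary_id, p_start,
    p_end, strand, score)."""
    with open(path, "w") as fh:
        fh.write("haplotig_id\tprimary_id\tp_start\tp_end\tstrand\tscore\n")
        for p in placements:
            fh.write(
                f"{p.haplotig_id}\t{p.primary_id}\t{p.p_start}\t{p.p_end}"
                f"\t{p.strand}\t{p.score}\n"
            )


def read_placements(path: str | Path) -> list[HaplotigPlacement]:
    placements = []
    with open(path) as fh:
        header = fh.readline()
        if not header.startswith("haplotig_id"):
            raise ValueError(f"{path}: not a placement table")
        for line in fh:
            hid, pid, s, e, strand, score = line.rstrip("\n").split("\t")
            placements.append(
                HaplotigPlacement(hid, pid, int(s), int(e), strand, int(score))
            )
    return placements
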