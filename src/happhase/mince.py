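"""Mince primary contigs at haplotig placement boundaries.

Each placement interval on a primary contig defines a phase block: the
haplotig itself is the block's A member, the homologous primary sub-sequence
its B member.  The remaining primary intervals are collapsed haplotypes
(both parental haplotypes merged).  Mincing cuts every primary contig into
B and collapsed segments that tile it exactly, pairs each B with its A
haplotig, and records the ordered pairing per contig in a phase-block index
(the list of (A, B) tuples the phasing algorithm consumes).

Segment naming: B and collapsed segments are named ``<primary>:<start>-<end>``
(0-based half-open); A segments keep the haplotig name.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path
from typing import Mapping, Sequence

from Bio import SeqIO
from Bio.Seq import Seq
from Bio.SeqRecord import SeqRecord

from .placement import HaplotigPlacement

__all__ = [
    "MincedSegment",
    "PhaseBlock",
    "PhaseBlockIndex",
    "mince_contig",
    "mince_assembly",
    "write_minced",
    "read_minced",
    "write_index",
    "read_index",
]


@dataclass(frozen=True)
class MincedSegment:
    """A piece of the minced assembly.

    ``category`` is ``"A"`` (the haplotig, coordinates on itself),
    ``"B"`` (primary sub-sequence under a placement) or ``"collapsed"``
    (primary sub-sequence outside all placements).
    """

    seg_id: str
    source_id: str
    start: int
    end: int
    category: str
    sequence: str

    def __post_init__(self) -> None:
        if self.category not in ("A", "B", "collapsed"):
            raise ValueError(f"bad category {self.category!r}")
        if self.end - self.start != len(self.sequence):
            raise ValueError(
                f"{self.seg_id}: interval [{self.start},{self.end}) does not "
                f"match sequence length {len(self.sequence)}"
            )

    @property
    def length(self) -> int:
        return self.end - self.start


@dataclass(frozen=True)
class PhaseBlock:
    """One A/B haplotype pair, ordered along its primary contig."""

    rank: int
    a_seg: str
    b_seg: str
    strand: str
    start: int  # B interval on the primary
    end: int


@dataclass
class PhaseBlockIndex:
    """Ordered phase blocks and interleaved collapsed segments of one
    primary contig."""

    primary_id: str
    blocks: list[PhaseBlock] = field(default_factory=list)
    collapsed: list[str] = field(default_factory=list)  # seg_ids in order

    @property
    def m(self) -> int:
        return len(self.blocks)


def _interval_name(source: str, start: int, end: int) -> str:
    return f"{source}:{start}-{end}"


def mince_contig(
    primary_id: str,
    primary_seq: str,
    placements: Sequence[HaplotigPlacement],
    haplotigs: Mapping[str, str],
) -> tuple[list[MincedSegment], PhaseBlockIndex]:
    """Cut one primary contig at placement boundaries.

    Placements must already be sorted, disjoint and within contig bounds
    (the contract :func:`happhase.placement.filter_placements` provides);
    violations raise ``ValueError``.  Returns the minced segments (A, B and
    collapsed) plus the contig's phase-block index.  The B and collapsed
    segments, concatenated in order, reproduce the primary contig exactly.
    """
    L = len(primary_seq)
    segments: list[MincedSegment] = []
    index = PhaseBlockIndex(primary_id=primary_id)

    prev_end = 0
    for rank, p in enumerate(placements):
        if p.primary_id != primary_id:
            raise ValueError(f"placement {p.haplotig_id} is not on {primary_id}")
        if p.p_start < prev_end:
            raise ValueError(
                f"{primary_id}: overlapping/unsorted placements at {p.p_start}"
            )
        if p.p_end > L:
            raise ValueError(
                f"{primary_id}: placement [{p.p_start},{p.p_end}) exceeds "
                f"contig length {L}"
            )
        if p.haplotig_id not in haplotigs:
            raise ValueError(f"unknown haplotig {p.haplotig_id}")
        if p.p_start > prev_end:
            cid = _interval_name(primary_id, prev_end, p.p_start)
            segments.append(
                MincedSegment(cid, primary_id, prev_end, p.p_start, "collapsed",
                              primary_seq[prev_end:p.p_start])
            )
            index.collapsed.append(cid)
        bid = _interval_name(primary_id, p.p_start, p.p_end)
        segments.append(
            MincedSegment(bid, primary_id, p.p_start, p.p_end, "B",
                          primary_seq[p.p_start:p.p_end])
        )
        hap_seq = haplotigs[p.haplotig_id]
        segments.append(
            MincedSegment(p.haplotig_id, p.haplotig_id, 0, len(hap_seq), "A",
                          hap_seq)
        )
        index.blocks.append(
            PhaseBlock(rank=rank, a_seg=p.haplotig_id, b_seg=bid,
                       strand=p.strand, start=p.p_start, end=p.p_end)
        )
        prev_end = p.p_end
    if prev_end < L:
        cid = _interval_name(primary_id, prev_end, L)
        segments.append(
            MincedSegment(cid, primary_id, prev_end, L, "collapsed",
                          primary_seq[prev_end:L])
        )
        index.collapsed.append(cid)
    return segments, index


def mince_assembly(
    primaries: Mapping[str, str],
    placements: Sequence[HaplotigPlacement],
    haplotigs: Mapping[str, str],
) -> tuple[list[MincedSegment], dict[str, PhaseBlockIndex]]:
    """Mince every primary contig; placements are grouped and sorted per
    contig internally."""
    by_primary: dict[str, list[HaplotigPlacement]] = {pid: [] for pid in primaries}
    for p in placements:
        if p.primary_id not in by_primary:
            raise ValueError(f"placement on unknown primary {p.primary_id}")
        by_primary[p.primary_id].append(p)
    segments: list[MincedSegment] = []
    indexes: dict[str, PhaseBlockIndex] = {}
    for pid in primaries:
        plist = sorted(by_primary[pid], key=lambda p: p.p_start)
        segs, idx = mince_contig(pid, primaries[pid], plist, haplotigs)
        segments.extend(segs)
        indexes[pid] = idx
    return segments, indexes


def write_minced(
    segments: Sequence[MincedSegment],
    indexes: Mapping[str, PhaseBlockIndex],
    outdir: str | Path,
    line_width: int = 80,
) -> dict[str, Path]:
    """Write A/B/collapsed FASTA files plus the phase-block index table.

    Returns the paths written, keyed ``A``, ``B``, ``collapsed``, ``index``.
    """
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    paths = {
        "A": outdir / "A_haplotigs.fasta",
        "B": outdir / "B_haplotigs.fasta",
        "collapsed": outdir / "collapsed_haplotypes.fasta",
        "index": outdir / "phase_block_index.tsv",
    }
    for cat in ("A", "B", "collapsed"):
        recs = [
            SeqRecord(Seq(s.sequence), id=s.seg_id,
                      description=f"{s.source_id}:{s.start}-{s.end}")
            for s in segments if s.category == cat
        ]
        writer = SeqIO.FastaIO.FastaWriter(str(paths[cat]), wrap=line_width)
        writer.write_file(recs)
    write_index(indexes, paths["index"])
    return paths


def write_index(indexes: Mapping[str, PhaseBlockIndex], path: str | Path) -> None:
    with open(path, "w") as fh:
        fh.write("primary_id\trank\ta_seg\tb_seg\tstrand\n")
        for pid in indexes:
            for b in indexes[pid].blocks:
                fh.write(f"{pid}\t{b.rank}\t{b.a_seg}\t{b.b_seg}\t{b.strand}\n")


def _parse_interval_name(seg_id: str) -> tuple[str, int, int]:
    source, _, span = seg_id.rpartition(":")
    s, _, e = span.partition("-")
    return source, int(s), int(e)


def read_index(path: str | Path) -> dict[str, PhaseBlockIndex]:
    """Read the index table back; collapsed ordering is re-derived from B
    segment coordinates when the minced FASTAs are re-read."""
    indexes: dict[str, PhaseBlockIndex] = {}
    with open(path) as fh:
        header = fh.readline()
        if not header.startswith("primary_id"):
            raise ValueError(f"{path}: not a phase-block index table")
        for line in fh:
            pid, rank, a_seg, b_seg, strand = line.rstrip("\n").split("\t")
            _, start, end = _parse_interval_name(b_seg)
            idx = indexes.setdefault(pid, PhaseBlockIndex(primary_id=pid))
            idx.blocks.append(
                PhaseBlock(int(rank), a_seg, b_seg, strand, start, end)
            )
    for idx in indexes.values():
        idx.blocks.sort(key=lambda b: b.rank)
    return indexes


def read_minced(outdir: str | Path) -> tuple[list[MincedSegment], dict[str, PhaseBlockIndex]]:
    """Round-trip reader for :func:`write_minced` output."""
    outdir = Path(outdir)
    segments: list[MincedSegment] = []
    for cat, fname in (("A", "A_haplotigs.fasta"),
                       ("B", "B_haplotigs.fasta"),
                       ("collapsed", "collapsed_haplotypes.fasta")):
        for rec in SeqIO.parse(str(outdir / fname), "fasta"):
            # description carries "source:start-end"
            source, start, end = _parse_interval_name(rec.description.split()[-1])
            segments.append(
                MincedSegment(rec.id, source, start, end, cat, str(rec.seq))
            )
    indexes = read_index(outdir / "phase_block_index.tsv")
    # restore collapsed ordering per primary
    coll = [s for s in segments if s.category == "collapsed"]
    coll.sort(key=lambda s: (s.source_id, s.start))
    for s in coll:
        if s.source_id in indexes:
            indexes[s.source_id].collapsed.append(s.seg_id)
        else:
            indexes.setdefault(s.source_id, PhaseBlockIndex(primary_id=s.source_id)) \
                   .collapsed.append(s.seg_id)
    return segments, indexes
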