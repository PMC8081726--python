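"""Join minced segments into two full-length phased sequences per contig.

Traversing a primary contig's segments in coordinate order, collapsed
segments are copied into both outputs while at each phase block the two
outputs take complementary members of the (A, B) pair according to the
block's assignment ``R[k]``:

* ``R[k] == 0`` — phase 0 takes B (the primary's own sub-sequence), phase 1
  takes A.  With an all-zero assignment the phase-0 output therefore
  reproduces the input primary contig byte for byte.
* ``R[k] == 1`` — the members swap.

A haplotigs placed on the minus strand are reverse-complemented on emission
so both outputs read in primary-contig orientation.  In ``unzip`` mode the
phase-0 traversal is emitted as a primary-like record and the phase-1 block
members as separate haplotig records with placement metadata, mirroring the
input assembly's format.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path
from typing import Mapping, Sequence

from Bio import SeqIO
from Bio.Seq import Seq
from Bio.SeqRecord import SeqRecord

from .mince import MincedSegment, PhaseBlockIndex

__all__ = [
    "BlockMapEntry",
    "PseudoHaplotypePair",
    "emit_contig",
    "emit_pseudohaplotypes",
    "write_block_bed",
]


@dataclass(frozen=True)
class BlockMapEntry:
    """Provenance of one emitted interval: which segment filled
    [start, end) of which output phase."""

    phase: int
    start: int
    end: int
    seg_id: str
    category: str


@dataclass
class PseudoHaplotypePair:
    """The two emitted full-length sequences of one primary contig."""

    primary_id: str
    phase0_seq: str
    phase1_seq: str
    block_map: list[BlockMapEntry] = field(default_factory=list)


def _revcomp(seq: str) -> str:
    return str(Seq(seq).reverse_complement())


def emit_contig(
    segments: Mapping[str, MincedSegment],
    index: PhaseBlockIndex,
    R: Sequence[int],
) -> PseudoHaplotypePair:
    """Emit the phase-0/phase-1 pair for one primary contig.

    ``R`` must cover every block of the index; missing segments or
    assignments raise ``KeyError``/``ValueError``.
    """
    if len(R) != index.m:
        raise ValueError(
            f"{index.primary_id}: {index.m} blocks but {len(R)} phase entries"
        )
    events: list[tuple[int, str, object]] = []
    for cid in index.collapsed:
        seg = segments[cid]
        events.append((seg.start, "collapsed", seg))
    for k, block in enumerate(index.blocks):
        events.append((block.start, "block", (k, block)))
    events.sort(key=lambda e: e[0])

    out = {0: [], 1: []}
    maps = {0: [], 1: []}
    pos = {0: 0, 1: 0}

    def push(phase: int, seq: str, seg_id: str, category: str) -> None:
        out[phase].append(seq)
        maps[phase].append(
            BlockMapEntry(phase, pos[phase], pos[phase] + len(seq), seg_id, category)
        )
        pos[phase] += len(seq)

    for _, kind, payload in events:
        if kind == "collapsed":
            seg = payload
            for phase in (0, 1):
                push(phase, seg.sequence, seg.seg_id, "collapsed")
        else:
            k, block = payload
            a = segments[block.a_seg]
            b = segments[block.b_seg]
            a_seq = _revcomp(a.sequence) if block.strand == "-" else a.sequence
            if R[k] == 0:
                push(0, b.sequence, b.seg_id, "B")
                push(1, a_seq, a.seg_id, "A")
            else:
                push(0, a_seq, a.seg_id, "A")
                push(1, b.sequence, b.seg_id, "B")

    return PseudoHaplotypePair(
        primary_id=index.primary_id,
        phase0_seq="".join(out[0]),
        phase1_seq="".join(out[1]),
        block_map=maps[0] + maps[1],
    )


def emit_pseudohaplotypes(
    segments: Sequence[MincedSegment] | Mapping[str, MincedSegment],
    indexes: Mapping[str, PhaseBlockIndex],
    phases: Mapping[str, Sequence[int]],
    outdir: str | Path,
    mode: str = "pseudohap",
    line_width: int = 80,
) -> dict[str, PseudoHaplotypePair]:
    """Emit all contigs to FASTA plus a BED provenance track per phase.

    ``pseudohap`` mode writes ``phase0.fasta``/``phase1.fasta`` with records
    ``<primary>_phase0`` / ``<primary>_phase1``.  ``unzip`` mode writes
    ``primary.fasta`` (the phase-0 traversal under the original contig
    name) and ``haplotigs.fasta`` holding each phase-1 block member as
    ``<primary>_block<k>_hap`` with its placement on the emitted primary in
    the description.
    """
    if mode not in ("pseudohap", "unzip"):
        raise ValueError(f"unknown emit mode {mode!r}")
    if not isinstance(segments, Mapping):
        segments = {s.seg_id: s for s in segments}
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)

    pairs: dict[str, PseudoHaplotypePair] = {}
    for pid, index in indexes.items():
        if pid not in phases and index.m > 0:
            raise ValueError(f"no phase assignment for contig {pid}")
        pairs[pid] = emit_contig(segments, index, phases.get(pid, []))

    if mode == "pseudohap":
        for phase in (0, 1):
            recs = [
                SeqRecord(
                    Seq(p.phase0_seq if phase == 0 else p.phase1_seq),
                    id=f"{p.primary_id}_phase{phase}", description="",
                )
                for p in pairs.values()
            ]
            writer = SeqIO.FastaIO.FastaWriter(
                str(outdir / f"phase{phase}.fasta"), wrap=line_width)
            writer.write_file(recs)
    else:
        prim_recs, hap_recs = [], []
        for pid, p in pairs.items():
            prim_recs.append(SeqRecord(Seq(p.phase0_seq), id=pid, description=""))
            rank = 0
            for e in p.block_map:
                if e.phase == 1 and e.category != "collapsed":
                    seg_seq = p.phase1_seq[e.start:e.end]
                    hap_recs.append(
                        SeqRecord(
                            Seq(seg_seq),
                            id=f"{pid}_block{rank}_hap",
                            description=f"source={e.seg_id} placement={pid}:{e.start}-{e.end}",
                        )
                    )
                    rank += 1
        SeqIO.FastaIO.FastaWriter(str(outdir / "primary.fasta"),
                                  wrap=line_width).write_file(prim_recs)
        SeqIO.FastaIO.FastaWriter(str(outdir / "haplotigs.fasta"),
                                  wrap=line_width).write_file(hap_recs)

    with open(outdir / "blocks.bed", "w") as fh:
        for p in pairs.values():
            fh.write(format_block_bed(p))
    return pairs


def format_block_bed(pair: PseudoHaplotypePair) -> str:
    lines = []
    for e in pair.block_map:
        name = f"{pair.primary_id}_phase{e.phase}"
        lines.append(
            f"{name}\t{e.start}\t{e.end}\t{e.seg_id}\t{e.category}\t{e.phase}\n"
        )
    return "".join(lines)


def write_block_bed(pair: PseudoHaplotypePair, path: str | Path) -> None:
    """Write the provenance track of one emitted pair: BED intervals on each
    output sequence labeled with source segment, category and phase."""
    with open(path, "w") as fh:
        fh.write(format_block_bed(pair))
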