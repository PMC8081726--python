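"""Hi-C contact matrix over minced segments.

Read pairs aligned to the minced assembly are filtered down to the
haplotype-specific set — both mates primary, map quality strictly above
``mapq_min`` (default Q10) and edit distance strictly below ``nm_max``
(default 5) — then counted into a symmetric raw contact matrix ``M``.
Because longer segments accumulate more Hi-C ligation junctions, each entry
is normalized by the restriction-site content of the two segments::

    Mhat[i, j] = M[i, j] / (z_i + z_j)

where ``z_i`` counts occurrences of the restriction-enzyme motif in segment
``i``.  Segment pairs with no restriction sites get ``Mhat = 0`` rather than
a division error, which mutes signal-free segments.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Iterator, Mapping, Sequence

import numpy as np

from .mince import MincedSegment

__all__ = [
    "ReadPairRecord",
    "ContactMatrix",
    "EXCLUDE_FLAG_MASK",
    "pair_passes_filter",
    "count_re_sites",
    "count_re_sites_per_segment",
    "build_matrix",
    "normalize_matrix",
    "read_pairs_tsv",
    "read_pairs_alignments",
    "write_matrix",
    "read_matrix",
]

#: unmapped (4) | mate unmapped (8) | secondary (256) | supplementary (2048)
EXCLUDE_FLAG_MASK = 2316

DEFAULT_MAPQ_MIN = 10
DEFAULT_NM_MAX = 5


@dataclass(frozen=True)
class ReadPairRecord:
    """A Hi-C mate pair reduced to what filtering and counting need."""

    read_id: str
    seg_i: str
    seg_j: str
    mapq_1: int
    mapq_2: int
    nm_1: int
    nm_2: int


def pair_passes_filter(
    pair: ReadPairRecord,
    mapq_min: int = DEFAULT_MAPQ_MIN,
    nm_max: int = DEFAULT_NM_MAX,
) -> bool:
    """Haplotype-specificity filter: both mates need map quality strictly
    greater than ``mapq_min`` and edit distance strictly less than
    ``nm_max``.  A mate with MAPQ exactly 10 or NM exactly 5 fails."""
    return (
        pair.mapq_1 > mapq_min
        and pair.mapq_2 > mapq_min
        and pair.nm_1 < nm_max
        and pair.nm_2 < nm_max
    )


def count_re_sites(sequence: str, motif: str | Sequence[str]) -> int:
    """Count forward-strand occurrences of the restriction motif(s),
    overlapping occurrences included.  A list of motifs is summed
    (multi-enzyme kits)."""
    if isinstance(motif, str):
        motifs = [motif]
    else:
        motifs = list(motif)
    if not motifs or any(not m for m in motifs):
        raise ValueError("restriction motif must be non-empty")
    seq = sequence.upper()
    total = 0
    for m in motifs:
        m = m.upper()
        start = 0
        while True:
            pos = seq.find(m, start)
            if pos < 0:
                break
            total += 1
            start = pos + 1  # overlapping matches count
    return total


def count_re_sites_per_segment(
    segments: Iterable[MincedSegment], motif: str | Sequence[str]
) -> dict[str, int]:
    return {s.seg_id: count_re_sites(s.sequence, motif) for s in segments}


@dataclass
class ContactMatrix:
    """Symmetric contact counts over an ordered set of minced segments.

    ``M`` holds raw pair counts, ``z`` per-segment restriction-site counts,
    ``Mhat`` the site-normalized matrix (filled by
    :func:`normalize_matrix`).
    """

    segments: list[str]
    M: np.ndarray
    z: np.ndarray | None = None
    Mhat: np.ndarray | None = None
    _index: dict[str, int] = field(default_factory=dict, repr=False)

    def __post_init__(self) -> None:
        if not self._index:
            self._index = {s: i for i, s in enumerate(self.segments)}
        n = len(self.segments)
        if self.M.shape != (n, n):
            raise ValueError("matrix shape does not match segment count")

    def idx(self, seg_id: str) -> int:
        return self._index[seg_id]

    def raw(self, seg_a: str, seg_b: str) -> int:
        return int(self.M[self.idx(seg_a), self.idx(seg_b)])

    def normalized(self, seg_a: str, seg_b: str) -> float:
        if self.Mhat is None:
            raise ValueError("call normalize_matrix first")
        return float(self.Mhat[self.idx(seg_a), self.idx(seg_b)])


def build_matrix(
    pairs: Iterable[ReadPairRecord],
    segments: Sequence[str] | Sequence[MincedSegment],
    mapq_min: int = DEFAULT_MAPQ_MIN,
    nm_max: int = DEFAULT_NM_MAX,
    prefiltered: bool = False,
) -> ContactMatrix:
    """Count retained pairs into the raw matrix ``M``.

    Each pair increments ``M[i, j]`` (and ``M[j, i]`` for i != j) once;
    self-pairs land on the diagonal once.  A pair naming an unknown segment
    raises ``KeyError``.  Set ``prefiltered=True`` when the caller has
    already applied :func:`pair_passes_filter`.
    """
    seg_ids = [s.seg_id if isinstance(s, MincedSegment) else s for s in segments]
    cm = ContactMatrix(segments=seg_ids,
                       M=np.zeros((len(seg_ids), len(seg_ids)), dtype=np.int64))
    index = cm._index
    M = cm.M
    for pair in pairs:
        if not prefiltered and not pair_passes_filter(pair, mapq_min, nm_max):
            continue
        try:
            i = index[pair.seg_i]
            j = index[pair.seg_j]
        except KeyError as exc:
            raise KeyError(
                f"pair {pair.read_id} references unknown segment {exc.args[0]}"
            ) from None
        M[i, j] += 1
        if i != j:
            M[j, i] += 1
    return cm


def normalize_matrix(
    matrix: ContactMatrix,
    z: Mapping[str, int] | np.ndarray | None = None,
) -> ContactMatrix:
    """Fill ``Mhat[i,j] = M[i,j] / (z_i + z_j)``, with 0 where
    ``z_i + z_j == 0``.  ``z`` may be passed here or set on the matrix
    beforehand."""
    if z is not None:
        if isinstance(z, Mapping):
            matrix.z = np.array([z[s] for s in matrix.segments], dtype=np.int64)
        else:
            matrix.z = np.asarray(z, dtype=np.int64)
    if matrix.z is None:
        raise ValueError("restriction-site counts z are required")
    if matrix.z.shape != (len(matrix.segments),):
        raise ValueError("z length does not match segment count")
    denom = matrix.z[:, None] + matrix.z[None, :]
    with np.errstate(divide="ignore", invalid="ignore"):
        Mhat = np.where(denom > 0, matrix.M / np.where(denom > 0, denom, 1), 0.0)
    matrix.Mhat = Mhat
    return matrix


def read_pairs_tsv(path: str | Path) -> Iterator[ReadPairRecord]:
    """Stream the 6/7-column pair table.

    Columns: read_id, seg_i, seg_j, mapq_1, mapq_2, nm_1[, nm_2].  With six
    columns the last is taken as the pair's worst (maximum) edit distance
    and applied to both mates.  Lines starting with ``#`` are skipped.
    """
    with open(path) as fh:
        for lineno, line in enumerate(fh, start=1):
            line = line.rstrip("\n")
            if not line or line.startswith("#"):
                continue
            fields = line.split("\t")
            if len(fields) not in (6, 7):
                raise ValueError(
                    f"{path}: line {lineno}: expected 6 or 7 columns, "
                    f"got {len(fields)}"
                )
            nm_1 = int(fields[5])
            nm_2 = int(fields[6]) if len(fields) == 7 else nm_1
            yield ReadPairRecord(
                read_id=fields[0], seg_i=fields[1], seg_j=fields[2],
                mapq_1=int(fields[3]), mapq_2=int(fields[4]),
                nm_1=nm_1, nm_2=nm_2,
            )


def read_pairs_alignments(path: str | Path) -> Iterator[ReadPairRecord]:
    """Stream mate pairs from a name-sorted SAM/BAM of Hi-C alignments.

    Unmapped, secondary and supplementary records (flag mask 2316) are
    dropped before pairing, so each surviving read name carries exactly two
    records: its two mates.  A read name with only one surviving record
    raises ``ValueError`` (missing mate).
    """
    import pysam

    pending: dict[str, object] = {}
    mode = "rb" if str(path).endswith(".bam") else "r"
    with pysam.AlignmentFile(str(path), mode, check_sq=False) as fh:
        for rec in fh:
            if rec.flag & EXCLUDE_FLAG_MASK:
                continue
            mate = pending.pop(rec.query_name, None)
            if mate is None:
                pending[rec.query_name] = rec
                continue
            yield ReadPairRecord(
                read_id=rec.query_name,
                seg_i=mate.reference_name,
                seg_j=rec.reference_name,
                mapq_1=mate.mapping_quality,
                mapq_2=rec.mapping_quality,
                nm_1=int(mate.get_tag("NM")) if mate.has_tag("NM") else 0,
                nm_2=int(rec.get_tag("NM")) if rec.has_tag("NM") else 0,
            )
    if pending:
        missing = sorted(pending)[:3]
        raise ValueError(
            f"{len(pending)} reads lack a primary mate record "
            f"(e.g. {', '.join(missing)}); is the file name-sorted?"
        )


def write_matrix(matrix: ContactMatrix, edges_path: str | Path,
                 segments_path: str | Path,
                 lengths: Mapping[str, int] | None = None) -> None:
    """Write the matrix as a text edge list (seg_i, seg_j, count; upper
    triangle incl. diagonal) plus a segment table with z (and lengths when
    provided)."""
    with open(edges_path, "w") as fh:
        fh.write("seg_i\tseg_j\tcount\n")
        n = len(matrix.segments)
        for i in range(n):
            for j in range(i, n):
                c = matrix.M[i, j]
                if c:
                    fh.write(f"{matrix.segments[i]}\t{matrix.segments[j]}\t{int(c)}\n")
    with open(segments_path, "w") as fh:
        fh.write("seg_id\tlength\tz\n")
        z = matrix.z if matrix.z is not None else np.zeros(len(matrix.segments), int)
        for s, zi in zip(matrix.segments, z):
            L = lengths.get(s, 0) if lengths else 0
            fh.write(f"{s}\t{L}\t{int(zi)}\n")


def read_matrix(edges_path: str | Path, segments_path: str | Path) -> ContactMatrix:
    """Read :func:`write_matrix` output and re-normalize."""
    seg_ids: list[str] = []
    zs: list[int] = []
    with open(segments_path) as fh:
        header = fh.readline()
        if not header.startswith("seg_id"):
            raise ValueError(f"{segments_path}: not a segment table")
        for line in fh:
            sid, _length, z = line.rstrip("\n").split("\t")
            seg_ids.append(sid)
            zs.append(int(z))
    cm = ContactMatrix(segments=seg_ids,
                       M=np.zeros((len(seg_ids), len(seg_ids)), dtype=np.int64))
    with open(edges_path) as fh:
        header = fh.readline()
        if not header.startswith("seg_i"):
            raise ValueError(f"{edges_path}: not an edge list")
        for line in fh:
            a, b, c = line.rstrip("\n").split("\t")
            i, j = cm.idx(a), cm.idx(b)
            cm.M[i, j] += int(c)
            if i != j:
                cm.M[j, i] += int(c)
    return normalize_matrix(cm, np.array(zs, dtype=np.int64))
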