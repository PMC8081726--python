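"""Synthetic diploid assemblies with known phase truth.

The generator emulates the input regime of a partially phased long-read
assembly: each simulated primary contig alternates collapsed (homozygous)
intervals with heterozygous phase blocks where the two parental haplotypes
differ by SNVs at a configurable per-base rate.  The primary contig carries
a random parent's haplotype at every block (the mosaic a collapsing
assembler produces) and the alternate haplotig carries the other parent,
with an exact PAF placement row.  Hi-C read pairs are then drawn along the
true parental chromosomes with exponential distance decay; only the
haplotype-specific (uniquely mapping) fraction is emitted, mirroring the
map-quality filtering that discards uninformative pairs, and a configurable
fraction of the informative pairs is flipped to the wrong haplotype to
model residual mismapping noise.

SNVs only, no indels: the A and B members of every block have equal length,
so emission length identities are exact.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path
from typing import Mapping, Sequence

import numpy as np
import pandas as pd

from .mince import PhaseBlockIndex
from .placement import AlignmentRecord

__all__ = [
    "SimConfig",
    "SimulatedAssembly",
    "simulate_assembly",
    "simulate_pairs",
    "write_pairs_tsv",
    "score_phasing",
]

_BASES = np.frombuffer(b"ACGT", dtype=np.uint8)


@dataclass(frozen=True)
class SimConfig:
    """Study conditions for one simulated dataset.

    Defaults model a modestly heterozygous diploid at desk scale: 20 Mb of
    primary sequence in 20 contigs, half of each contig unzipped into ten
    50 kb phase blocks, 0.5% SNV heterozygosity inside blocks, GATC
    (Sau3AI/MboI/DpnII) restriction sites, and a Hi-C library whose
    informative (haplotype-specific) fraction and cross-phase noise sit in
    the middle of the range real libraries show.
    """

    n_contigs: int = 20
    contig_len: int = 1_000_000
    n_blocks: int = 10
    block_len: int = 50_000
    heterozygosity: float = 0.005
    re_motif: str = "GATC"
    n_pairs: int = 800_000
    informative_fraction: float = 0.25
    decay_scale: float = 150_000.0
    noise_fraction: float = 0.05
    minus_strand_fraction: float = 0.25
    seed: int = 0

    def __post_init__(self) -> None:
        for name in ("informative_fraction", "noise_fraction",
                     "minus_strand_fraction", "heterozygosity"):
            v = getattr(self, name)
            if not 0.0 <= v <= 1.0:
                raise ValueError(f"{name} must be in [0, 1], got {v}")
        if self.n_blocks > 0 and self.n_blocks * self.block_len >= self.contig_len:
            raise ValueError(
                "blocks do not fit: n_blocks * block_len must be < contig_len"
            )


@dataclass
class SimulatedAssembly:
    """A simulated assembly plus its ground truth.

    ``truth`` has one row per phase block: contig, rank, haplotig_id,
    b_start, b_end, strand, and ``primary_parent`` — which parent's
    haplotype the primary contig carries at that block (the haplotig
    carries the other)."""

    config: SimConfig
    primaries: dict[str, str]
    haplotigs: dict[str, str]
    alignments: list[AlignmentRecord]
    truth: pd.DataFrame
    parent_genomes: tuple[dict[str, str], dict[str, str]]

    def write(self, outdir: str | Path) -> dict[str, Path]:
        """Write primary/haplotig/parent FASTAs, the placement PAF and the
        truth table (all synthetic data)."""
        from Bio import SeqIO
        from Bio.Seq import Seq
        from Bio.SeqRecord import SeqRecord

        outdir = Path(outdir)
        outdir.mkdir(parents=True, exist_ok=True)
        paths = {}

        def _write_fasta(name: str, seqs: Mapping[str, str]) -> None:
            p = outdir / name
            recs = [SeqRecord(Seq(s), id=n, description="") for n, s in seqs.items()]
            SeqIO.FastaIO.FastaWriter(str(p), wrap=80).write_file(recs)
            paths[name] = p

        _write_fasta("primary.fasta", self.primaries)
        _write_fasta("haplotigs.fasta", self.haplotigs)
        _write_fasta("parent1.fasta", self.parent_genomes[0])
        _write_fasta("parent2.fasta", self.parent_genomes[1])
        paf = outdir / "placements.paf"
        with open(paf, "w") as fh:
            for r in self.alignments:
                fh.write(
                    f"{r.query_id}\t{r.query_len}\t{r.query_start}\t{r.query_end}"
                    f"\t{r.strand}\t{r.target_id}\t{r.target_len}\t{r.target_start}"
                    f"\t{r.target_end}\t{r.matches}\t{r.block_len}\t60\n"
                )
        paths["placements.paf"] = paf
        truth_p = outdir / "truth.tsv"
        self.truth.to_csv(truth_p, sep="\t", index=False)
        paths["truth.tsv"] = truth_p
        return paths


def _revcomp_codes(codes: np.ndarray) -> np.ndarray:
    comp = np.array([3, 2, 1, 0], dtype=np.uint8)
    return comp[codes][::-1]


def _to_str(codes: np.ndarray) -> str:
    return _BASES[codes].tobytes().decode("ascii")


def _block_geometry(cfg: SimConfig, rng: np.random.Generator) -> np.ndarray:
    """Random block start positions: n_blocks + 1 gaps of at least 1 bp
    drawn from a flat Dirichlet over the spare length."""
    n = cfg.n_blocks
    spare = cfg.contig_len - n * cfg.block_len - (n + 1)
    gaps = np.ones(n + 1, dtype=np.int64)
    if spare > 0:
        w = rng.dirichlet(np.ones(n + 1))
        extra = np.floor(w * spare).astype(np.int64)
        extra[-1] += spare - extra.sum()
        gaps += extra
    starts = np.empty(n, dtype=np.int64)
    pos = 0
    for k in range(n):
        pos += gaps[k]
        starts[k] = pos
        pos += cfg.block_len
    return starts


def simulate_assembly(cfg: SimConfig,
                      rng: np.random.Generator | None = None) -> SimulatedAssembly:
    """Generate the diploid assembly, placements and truth table."""
    if rng is None:
        rng = np.random.default_rng(cfg.seed)
    primaries: dict[str, str] = {}
    haplotigs: dict[str, str] = {}
    parent1: dict[str, str] = {}
    parent2: dict[str, str] = {}
    alignments: list[AlignmentRecord] = []
    rows = []

    for c in range(cfg.n_contigs):
        cid = f"ctg{c:03d}"
        bg = rng.integers(0, 4, size=cfg.contig_len, dtype=np.int64).astype(np.uint8)
        starts = _block_geometry(cfg, rng) if cfg.n_blocks else np.zeros(0, np.int64)
        primary = bg.copy()
        par1 = bg.copy()
        par2 = bg.copy()
        for k, s in enumerate(starts):
            e = s + cfg.block_len
            hap_a = bg[s:e].copy()  # parent-1 allele == background
            hap_b = bg[s:e].copy()  # parent-2 allele carries the SNVs
            n_snv = rng.binomial(cfg.block_len, cfg.heterozygosity)
            if n_snv:
                pos = rng.choice(cfg.block_len, size=n_snv, replace=False)
                shift = rng.integers(1, 4, size=n_snv).astype(np.uint8)
                hap_b[pos] = (hap_b[pos] + shift) % 4
            par2[s:e] = hap_b
            p = int(rng.integers(0, 2))  # parent carried by the primary
            primary[s:e] = hap_b if p else hap_a
            hap_codes = hap_a if p else hap_b
            strand = "-" if rng.random() < cfg.minus_strand_fraction else "+"
            hid = f"{cid}_h{k:02d}"
            hap_out = _revcomp_codes(hap_codes) if strand == "-" else hap_codes
            haplotigs[hid] = _to_str(hap_out)
            alignments.append(AlignmentRecord(
                query_id=hid, query_len=cfg.block_len,
                query_start=0, query_end=cfg.block_len, strand=strand,
                target_id=cid, target_len=cfg.contig_len,
                target_start=int(s), target_end=int(e),
                matches=cfg.block_len - int(n_snv), block_len=cfg.block_len,
            ))
            rows.append({
                "contig": cid, "rank": k, "haplotig_id": hid,
                "b_start": int(s), "b_end": int(e), "strand": strand,
                "primary_parent": p, "n_snv": int(n_snv),
            })
        primaries[cid] = _to_str(primary)
        parent1[cid] = _to_str(par1)
        parent2[cid] = _to_str(par2)

    truth = pd.DataFrame(
        rows, columns=["contig", "rank", "haplotig_id", "b_start", "b_end",
                       "strand", "primary_parent", "n_snv"])
    return SimulatedAssembly(
        config=cfg, primaries=primaries, haplotigs=haplotigs,
        alignments=alignments, truth=truth,
        parent_genomes=(parent1, parent2),
    )


def simulate_pairs(
    cfg: SimConfig,
    assembly: SimulatedAssembly,
    indexes: Mapping[str, PhaseBlockIndex],
    rng: np.random.Generator | None = None,
) -> pd.DataFrame:
    """Draw Hi-C pairs over the minced segments of the simulated assembly.

    Of ``cfg.n_pairs`` library pairs, each is haplotype-specific with
    probability ``cfg.informative_fraction``; only those are emitted (the
    rest fail the map-quality filter upstream).  Informative pairs pick a
    parental chromosome uniformly, one endpoint uniform over the contig's
    phase blocks and the second at an exponential distance (scale
    ``decay_scale``, random direction, redrawn until it lands in a block).
    Endpoints map to the A or B segment carrying that parent at their
    block; with probability ``noise_fraction`` the second endpoint is
    flipped to the wrong haplotype's segment.

    Returns the pair table with truth columns (source parent, blocks,
    flipped) alongside the alignment columns the contacts module consumes.
    """
    if rng is None:
        rng = np.random.default_rng(cfg.seed + 1)
    contigs = list(assembly.primaries)
    truth = assembly.truth
    n_inf = int(rng.binomial(cfg.n_pairs, cfg.informative_fraction))
    if n_inf == 0 or truth.empty:
        return pd.DataFrame(columns=[
            "read_id", "seg_i", "seg_j", "mapq_1", "mapq_2", "nm_1", "nm_2",
            "contig", "block_i", "block_j", "parent", "flipped"])

    which = rng.integers(0, len(contigs), size=n_inf)
    frames = []
    serial = 0
    for ci in np.unique(which):
        cid = contigs[ci]
        cnt = int(np.count_nonzero(which == ci))
        tc = truth[truth.contig == cid].sort_values("rank")
        m = len(tc)
        if m == 0:
            continue
        starts = tc.b_start.to_numpy()
        parents = tc.primary_parent.to_numpy()
        idx = indexes[cid]
        a_segs = np.array([b.a_seg for b in idx.blocks])
        b_segs = np.array([b.b_seg for b in idx.blocks])
        L = cfg.block_len
        U = m * L

        # endpoint 1: uniform over the block union (unzipped coordinates)
        u1 = rng.uniform(0, U, size=cnt)
        blk1 = np.minimum((u1 // L).astype(np.int64), m - 1)
        x = starts[blk1] + (u1 - blk1 * L)
        # endpoint 2: exponential decay, redrawn until inside a block
        y = np.empty(cnt)
        blk2 = np.full(cnt, -1, dtype=np.int64)
        todo = np.arange(cnt)
        for _ in range(200):
            if todo.size == 0:
                break
            d = rng.exponential(cfg.decay_scale, size=todo.size)
            sign = rng.integers(0, 2, size=todo.size) * 2 - 1
            cand = x[todo] + sign * d
            k = np.searchsorted(starts, cand, side="right") - 1
            ok = (k >= 0) & (cand >= 0)
            kk = np.clip(k, 0, m - 1)
            ok &= cand < starts[kk] + L
            hit = todo[ok]
            y[hit] = cand[ok]
            blk2[hit] = kk[ok]
            todo = todo[~ok]
        if todo.size:  # pathological geometry: fall back to a same-block pair
            y[todo] = x[todo]
            blk2[todo] = blk1[todo]

        parent = rng.integers(0, 2, size=cnt)
        flip = rng.random(cnt) < cfg.noise_fraction

        # parent h sits on B where primary_parent == h, on A elsewhere
        def seg_for(blocks: np.ndarray, hap: np.ndarray) -> np.ndarray:
            on_b = parents[blocks] == hap
            return np.where(on_b, b_segs[blocks], a_segs[blocks])

        seg_i = seg_for(blk1, parent)
        seg_j = seg_for(blk2, np.where(flip, 1 - parent, parent))

        frames.append(pd.DataFrame({
            "read_id": [f"pair{serial + t:08d}" for t in range(cnt)],
            "seg_i": seg_i, "seg_j": seg_j,
            "mapq_1": 60, "mapq_2": 60, "nm_1": 0, "nm_2": 0,
            "contig": cid, "block_i": blk1, "block_j": blk2,
            "parent": parent, "flipped": flip,
        }))
        serial += cnt
    return pd.concat(frames, ignore_index=True)


def write_pairs_tsv(pairs: pd.DataFrame, path: str | Path) -> None:
    """Write the 7-column pair table the contacts module reads."""
    cols = ["read_id", "seg_i", "seg_j", "mapq_1", "mapq_2", "nm_1", "nm_2"]
    pairs[cols].to_csv(path, sep="\t", index=False, header=False)


def score_phasing(
    truth: pd.DataFrame,
    phases: Mapping[str, Sequence[int]],
) -> tuple[float, dict[str, float]]:
    """Block-level phasing accuracy against the simulation truth.

    Per-contig phase labels are arbitrary and anchored at the first block
    (which the sampler pins), so each contig is scored under the global
    flip that aligns block 0 with its truth; the overall value is the
    block-weighted mean.  Returns (overall, per-contig).
    """
    per_contig: dict[str, float] = {}
    correct = 0
    total = 0
    for cid, tc in truth.groupby("contig", sort=True):
        t = tc.sort_values("rank").primary_parent.to_numpy()
        if cid not in phases:
            raise ValueError(f"no phase assignment for contig {cid}")
        r = np.asarray(phases[cid], dtype=np.int64)
        if len(r) != len(t):
            raise ValueError(
                f"{cid}: truth has {len(t)} blocks, assignment has {len(r)}")
        flip = int(r[0] != t[0])
        match = (r ^ flip) == t
        per_contig[cid] = float(match.mean())
        correct += int(match.sum())
        total += len(t)
    overall = correct / total if total else float("nan")
    return overall, per_contig
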