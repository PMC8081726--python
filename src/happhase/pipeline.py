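"""End-to-end pipeline: placement -> mince -> contacts -> phase -> emit.

Stages are plain functions invoked sequentially; every run writes its
artifacts (placement table, minced FASTAs, index, contact matrix, phase
table, emitted FASTAs) plus a JSON run report into the output directory
and logs the resolved configuration and seed for reproducibility.
"""

from __future__ import annotations

import json
import logging
from dataclasses import asdict, dataclass
from pathlib import Path
from typing import Mapping

import yaml
from Bio import SeqIO

from . import contacts as _contacts
from . import emit as _emit
from . import mince as _mince
from . import placement as _placement
from .model import ContigPhasingModel
from .phaser import DEFAULT_BURN_IN, DEFAULT_ITERATIONS

__all__ = ["RunConfig", "PipelineError", "run_pipeline"]

logger = logging.getLogger(__name__)


class PipelineError(RuntimeError):
    """A stage failure, named after the stage that raised it."""

    def __init__(self, stage: str, cause: Exception):
        super().__init__(f"stage {stage!r} failed: {cause}")
        self.stage = stage
        self.cause = cause


@dataclass
class RunConfig:
    """Resolved configuration of one pipeline run."""

    primary_fasta: str
    haplotig_fasta: str
    paf: str
    pairs: str  # pair TSV or name-sorted SAM/BAM
    outdir: str
    motif: str = "GATC"
    mapq_min: int = _contacts.DEFAULT_MAPQ_MIN
    nm_max: int = _contacts.DEFAULT_NM_MAX
    iterations: int = DEFAULT_ITERATIONS
    burn_in: int = DEFAULT_BURN_IN
    seed: int = 0
    emit_mode: str = "pseudohap"
    uniqueness_ratio: float = _placement.DEFAULT_UNIQUENESS_RATIO
    min_placement_len: int = _placement.DEFAULT_MIN_PLACEMENT_LEN

    def validate(self) -> None:
        if not (0 <= self.burn_in < self.iterations):
            raise ValueError(
                f"need 0 <= burn_in < iterations, got {self.burn_in} / "
                f"{self.iterations}")
        if self.emit_mode not in ("pseudohap", "unzip"):
            raise ValueError(f"unknown emit mode {self.emit_mode!r}")
        for field in ("primary_fasta", "haplotig_fasta", "paf", "pairs"):
            p = getattr(self, field)
            if not Path(p).exists():
                raise FileNotFoundError(f"{field}: {p} does not exist")

    @classmethod
    def from_yaml(cls, path: str | Path, **overrides) -> "RunConfig":
        with open(path) as fh:
            data = yaml.safe_load(fh) or {}
        data.update({k: v for k, v in overrides.items() if v is not None})
        return cls(**data)


def _read_fasta(path: str | Path) -> dict[str, str]:
    return {rec.id: str(rec.seq) for rec in SeqIO.parse(str(path), "fasta")}


def run_pipeline(config: RunConfig) -> dict:
    """Run all stages; returns the run report (also written to
    ``run_report.json``).  A stage failure raises :class:`PipelineError`
    with partial artifacts left in place."""
    config.validate()
    outdir = Path(config.outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    logger.info("run configuration: %s", asdict(config))
    with open(outdir / "run_config.yaml", "w") as fh:
        yaml.safe_dump(asdict(config), fh)
    report: dict = {"config": asdict(config)}

    def stage(name):
        logger.info("stage %s", name)
        return name

    try:
        name = stage("placement")
        records = _placement.read_paf(config.paf)
        placements = _placement.filter_placements(
            _placement.chain_placements(records),
            uniqueness_ratio=config.uniqueness_ratio,
            min_len=config.min_placement_len)
        _placement.write_placements(placements, outdir / "placements.tsv")
        report["n_alignments"] = len(records)
        report["n_placements"] = len(placements)

        name = stage("mince")
        primaries = _read_fasta(config.primary_fasta)
        haplotigs = _read_fasta(config.haplotig_fasta)
        segments, indexes = _mince.mince_assembly(primaries, placements, haplotigs)
        _mince.write_minced(segments, indexes, outdir / "minced")
        report["n_segments"] = len(segments)
        report["blocks_per_contig"] = {p: idx.m for p, idx in indexes.items()}

        name = stage("contacts")
        pairs_path = str(config.pairs)
        if pairs_path.endswith((".bam", ".sam")):
            pair_iter = _contacts.read_pairs_alignments(pairs_path)
        else:
            pair_iter = _contacts.read_pairs_tsv(pairs_path)
        kept = 0

        def counting(it):
            nonlocal kept
            for p in it:
                if _contacts.pair_passes_filter(p, config.mapq_min, config.nm_max):
                    kept += 1
                    yield p

        matrix = _contacts.build_matrix(counting(pair_iter), segments,
                                        prefiltered=True)
        z = _contacts.count_re_sites_per_segment(segments, config.motif)
        _contacts.normalize_matrix(matrix, z)
        lengths = {s.seg_id: s.length for s in segments}
        _contacts.write_matrix(matrix, outdir / "matrix.tsv",
                               outdir / "segments.tsv", lengths)
        report["n_pairs_retained"] = kept

        name = stage("phase")
        model = ContigPhasingModel(matrix, indexes)
        results = model.fit(n_iter=config.iterations, burn_in=config.burn_in,
                            seed=config.seed)
        results.to_tsv(outdir / "phases.tsv")

        name = stage("emit")
        pairs_out = _emit.emit_pseudohaplotypes(
            segments, indexes, results.phases, outdir / "emitted",
            mode=config.emit_mode)
        report["n_emitted_contigs"] = len(pairs_out)
    except PipelineError:
        raise
    except Exception as exc:
        raise PipelineError(name, exc) from exc

    with open(outdir / "run_report.json", "w") as fh:
        json.dump(report, fh, indent=2)
    return report
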