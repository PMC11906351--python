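"""Per-base depth extraction and coverage-table I/O.

Depth is extracted over the full locus window (zero-coverage positions
included) from indexed BAM/CRAM, or loaded from a 3-column TSV
(chrom, pos, depth; 1-based positions; optionally gzip-compressed).
"""
from __future__ import annotations

import gzip
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np

from .annotation import LocusDefinition


class CoverageError(ValueError):
    pass


@dataclass
class CoverageTrack:
    """Per-base read depth over one locus window."""

    locus: str
    chrom: str
    positions: np.ndarray  # 1-based, strictly increasing
    depth: np.ndarray      # non-negative integers
    sample_id: str | None = None
    mean_depth_genomewide: float | None = None

    def __post_init__(self):
        self.positions = np.asarray(self.positions, dtype=np.int64)
        self.depth = np.asarray(self.depth)
        if len(self.positions) != len(self.depth):
            raise CoverageError("positions and depth have different lengths")
        if len(self.positions) > 1 and not np.all(np.diff(self.positions) > 0):
            raise CoverageError("positions must be strictly increasing")
        if np.any(self.depth < 0):
            raise CoverageError("depth must be non-negative")

    def __len__(self):
        return len(self.positions)


def extract_coverage(alignment_path: str | Path, locus: LocusDefinition,
                     min_mapq: int = 0, min_baseq: int = 0,
                     reference: str | Path | None = None,
                     include_duplicates: bool = False,
                     sample_id: str | None = None) -> CoverageTrack:
    """Per-base depth over the locus span from an indexed BAM/CRAM.

    Defaults mirror plain ``samtools depth`` (no quality filters); duplicate,
    secondary, supplementary and QC-fail reads are excluded unless
    ``include_duplicates`` is set. CRAM input requires ``reference``.
    """
    import pysam

    alignment_path = Path(alignment_path)
    if alignment_path.suffix.lower() == ".cram" and reference is None:
        raise CoverageError(
            f"CRAM input {alignment_path} requires a reference FASTA (pass reference=...)"
        )
    kwargs = {"reference_filename": str(reference)} if reference else {}
    with pysam.AlignmentFile(str(alignment_path), **kwargs) as af:
        if not af.has_index():
            raise CoverageError(f"{alignment_path} has no index; run samtools index first")
        contigs = set(af.references)
        chrom = locus.chrom
        if chrom not in contigs:
            alt = chrom[3:] if chrom.startswith("chr") else "chr" + chrom
            if alt in contigs:
                chrom = alt
            else:
                raise CoverageError(
                    f"chromosome {locus.chrom!r} (or {alt!r}) not found in {alignment_path}"
                )

        bad_flags = 0x4 | 0x100 | 0x200 | 0x800  # unmapped/secondary/qcfail/supplementary
        if not include_duplicates:
            bad_flags |= 0x400

        def keep(read):
            return read.flag & bad_flags == 0 and read.mapping_quality >= min_mapq

        acgt = af.count_coverage(chrom, locus.span_start - 1, locus.span_end,
                                 quality_threshold=min_baseq, read_callback=keep)
    depth = np.sum(np.asarray(acgt, dtype=np.int64), axis=0)
    positions = np.arange(locus.span_start, locus.span_end + 1, dtype=np.int64)
    return CoverageTrack(locus=locus.locus, chrom=locus.chrom, positions=positions,
                         depth=depth, sample_id=sample_id or alignment_path.stem)


def write_coverage_table(track: CoverageTrack, path: str | Path) -> None:
    """Write chrom/pos/depth TSV; gzip if the path ends in .gz."""
    path = Path(path)
    opener = gzip.open if path.suffix == ".gz" else open
    with opener(path, "wt") as fh:
        fh.write("chrom\tpos\tdepth\n")
        for pos, dep in zip(track.positions, track.depth):
            fh.write(f"{track.chrom}\t{pos}\t{dep}\n")


def read_coverage_table(path: str | Path, locus: str | None = None,
                        sample_id: str | None = None) -> CoverageTrack:
    """Read a chrom/pos/depth TSV written by :func:`write_coverage_table`."""
    path = Path(path)
    opener = gzip.open if path.suffix == ".gz" else open
    chroms, positions, depths = [], [], []
    with opener(path, "rt") as fh:
        header = fh.readline().rstrip("\n").split("\t")
        if header[:3] != ["chrom", "pos", "depth"]:
            raise CoverageError(f"{path}: expected header chrom/pos/depth, got {header}")
        for lineno, line in enumerate(fh, start=2):
            parts = line.rstrip("\n").split("\t")
            if len(parts) < 3:
                raise CoverageError(f"{path}: malformed row at line {lineno}: {line!r}")
            try:
                positions.append(int(parts[1]))
                depths.append(int(parts[2]))
            except ValueError as exc:
                raise CoverageError(f"{path}: malformed row at line {lineno}: {line!r}") from exc
            chroms.append(parts[0])
    if not positions:
        raise CoverageError(f"{path}: empty coverage table")
    if len(set(chroms)) > 1:
        raise CoverageError(f"{path}: multiple chromosomes in one coverage table")
    pos = np.asarray(positions, dtype=np.int64)
    if len(pos) > 1 and not np.all(np.diff(pos) > 0):
        bad = int(np.flatnonzero(np.diff(pos) <= 0)[0]) + 3  # +header +1-based +next row
        raise CoverageError(f"{path}: positions not strictly increasing at line {bad}")
    return CoverageTrack(locus=locus or "", chrom=chroms[0], positions=pos,
                         depth=np.asarray(depths, dtype=np.int64),
                         sample_id=sample_id or path.stem.replace(".tsv", ""))
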