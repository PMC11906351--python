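"""Genomic models of the V(D)J loci.

A locus is described by an ordered list of segments (V, D, J and, for IGH,
CONSTANT genes) inside a fixed GRCh38 window, together with baseline regions
that no somatic rearrangement can delete. All genomic coordinates are 1-based
inclusive (the ``samtools depth`` convention).

Orientation is abstracted away at load time: every position is mapped onto a
"deletion axis" that increases from the V region towards the J region (and,
for IGH, onwards through the constant genes). A V(D)J rearrangement joining
segment ``v`` to segment ``j`` excises exactly the axis interval strictly
between the axis end of ``v`` and the axis start of ``j``, so all downstream
modelling is orientation-free.
"""
from __future__ import annotations

import importlib.resources
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Sequence

import pandas as pd

KNOWN_LOCI = ("TCRA", "TCRB", "TCRG", "IGH")
SEGMENT_KINDS = ("V", "D", "J", "CONSTANT")


class AnnotationError(ValueError):
    """Raised when a locus annotation violates its invariants."""


@dataclass(frozen=True)
class SegmentAnnotation:
    """One V/D/J segment or IGH constant gene.

    ``switch_order`` ranks constant genes along the class-switch deletion
    axis (IGHM and IGHD share rank 0); it is required for CONSTANT segments
    and forbidden otherwise.
    """

    name: str
    kind: str
    chrom: str
    start: int  # 1-based inclusive
    end: int    # 1-based inclusive
    switch_order: int | None = None

    def __post_init__(self):
        if self.kind not in SEGMENT_KINDS:
            raise AnnotationError(f"unknown segment kind {self.kind!r} for {self.name}")
        if self.start > self.end:
            raise AnnotationError(f"segment {self.name}: start {self.start} > end {self.end}")
        if (self.switch_order is not None) != (self.kind == "CONSTANT"):
            raise AnnotationError(
                f"segment {self.name}: switch_order must be present iff kind is CONSTANT"
            )


@dataclass
class LocusDefinition:
    """Layout of one receptor locus on the genome and on the deletion axis."""

    locus: str
    chrom: str
    span_start: int
    span_end: int
    orientation: str  # "forward" | "reverse": direction of the V->J axis
    segments: list[SegmentAnnotation]
    baseline_regions: list[tuple[int, int]] = field(default_factory=list)
    cn_proxy_gene: str | None = None

    # ------------------------------------------------------------------ axis
    def axis(self, pos):
        """Map genomic position(s) to the deletion axis (0-based offset)."""
        if self.orientation == "forward":
            return pos - self.span_start
        return self.span_end - pos

    def axis_interval(self, start: int, end: int) -> tuple[int, int]:
        a, b = self.axis(start), self.axis(end)
        return (a, b) if a <= b else (b, a)

    def segment_axis(self, seg: SegmentAnnotation) -> tuple[int, int]:
        return self.axis_interval(seg.start, seg.end)

    # ------------------------------------------------------------ selectors
    @property
    def v_segments(self) -> list[SegmentAnnotation]:
        return [s for s in self.segments if s.kind == "V"]

    @property
    def j_segments(self) -> list[SegmentAnnotation]:
        return [s for s in self.segments if s.kind == "J"]

    @property
    def d_segments(self) -> list[SegmentAnnotation]:
        return [s for s in self.segments if s.kind == "D"]

    @property
    def constant_segments(self) -> list[SegmentAnnotation]:
        return [s for s in self.segments if s.kind == "CONSTANT"]

    def v_boundaries(self):
        """Deletion-axis end of each V segment, in axis order."""
        return [self.segment_axis(s)[1] for s in self.v_segments]

    def j_boundaries(self):
        """Deletion-axis start of each J segment, in axis order."""
        return [self.segment_axis(s)[0] for s in self.j_segments]

    @property
    def deletable_axis(self) -> tuple[int, int]:
        """Axis interval that some V->J rearrangement can delete (V(D)J only)."""
        return (self.v_boundaries()[0], self.j_boundaries()[-1])

    @property
    def last_deletable_axis(self) -> int:
        """End of deletable territory including class-switch deletions (IGH)."""
        vdj_end = self.deletable_axis[1]
        consts = self.constant_segments
        if not consts:
            return vdj_end
        return max(self.segment_axis(c)[1] for c in consts) + 3000

    # ----------------------------------------------------------- validation
    def validate(self) -> None:
        if self.span_start > self.span_end:
            raise AnnotationError(f"{self.locus}: span_start > span_end")
        if self.orientation not in ("forward", "reverse"):
            raise AnnotationError(f"{self.locus}: bad orientation {self.orientation!r}")
        if not self.v_segments or not self.j_segments:
            raise AnnotationError(f"{self.locus}: needs at least one V and one J segment")
        for seg in self.segments:
            if seg.chrom != self.chrom:
                raise AnnotationError(f"{self.locus}: segment {seg.name} on {seg.chrom}, locus on {self.chrom}")
            if seg.start < self.span_start or seg.end > self.span_end:
                raise AnnotationError(
                    f"{self.locus}: segment {seg.name} ({seg.start}-{seg.end}) outside "
                    f"span {self.span_start}-{self.span_end}"
                )
        # same-kind segments must not overlap
        for kind in SEGMENT_KINDS:
            segs = sorted((s for s in self.segments if s.kind == kind), key=lambda s: s.start)
            for a, b in zip(segs, segs[1:]):
                if b.start <= a.end:
                    raise AnnotationError(f"{self.locus}: {kind} segments {a.name} and {b.name} overlap")
        # segments must be ordered along the deletion axis, every V before every J
        axis_starts = [self.segment_axis(s)[0] for s in self.segments]
        if any(b < a for a, b in zip(axis_starts, axis_starts[1:])):
            raise AnnotationError(f"{self.locus}: segments not ordered along the deletion axis")
        if max(self.v_boundaries()) > min(self.j_boundaries()):
            raise AnnotationError(f"{self.locus}: a J segment precedes a V segment on the deletion axis")
        consts = self.constant_segments
        if consts:
            last_j = self.j_boundaries()[-1]
            if any(self.segment_axis(c)[0] < last_j for c in consts):
                raise AnnotationError(f"{self.locus}: a CONSTANT segment precedes a J segment on the deletion axis")
        # baseline regions: inside the span and never deletable
        lo, hi = self.deletable_axis[0], self.last_deletable_axis
        for s, e in self.baseline_regions:
            if s > e or s < self.span_start or e > self.span_end:
                raise AnnotationError(f"{self.locus}: bad baseline region {s}-{e}")
            a, b = self.axis_interval(s, e)
            if a < hi and b > lo:
                raise AnnotationError(
                    f"{self.locus}: baseline region {s}-{e} overlaps deletable territory"
                )

    # -------------------------------------------------------------- export
    def to_bed(self, path: str | Path) -> None:
        """Write segments as BED6 (0-based half-open) for genome browsers."""
        strand = "+" if self.orientation == "forward" else "-"
        with open(path, "w") as fh:
            for seg in self.segments:
                fh.write(f"{seg.chrom}\t{seg.start - 1}\t{seg.end}\t{seg.name}\t0\t{strand}\n")


def _packaged(fname: str):
    return importlib.resources.files("vdjlens").joinpath("data", fname)


def _parse_baseline(spec: str) -> list[tuple[int, int]]:
    out = []
    for part in str(spec).split(";"):
        part = part.strip()
        if not part:
            continue
        s, e = part.split("-")
        out.append((int(s), int(e)))
    return out


def load_locus_definition(locus_name: str, annotation_path: str | Path = "packaged") -> LocusDefinition:
    """Load and validate a locus definition.

    ``annotation_path`` is either ``"packaged"`` (the TSVs shipped with the
    package) or a path to a segment TSV with columns
    name/kind/chrom/start/end/switch_order; in the latter case the packaged
    locus metadata (span, orientation, baseline regions) is still used.
    """
    locus_name = locus_name.upper()
    if locus_name not in KNOWN_LOCI:
        raise AnnotationError(f"unknown locus {locus_name!r}; expected one of {KNOWN_LOCI}")
    meta = pd.read_csv(_packaged("loci.tsv"), sep="\t", dtype=str)
    row = meta[meta["locus"] == locus_name].iloc[0]
    if annotation_path == "packaged":
        seg_src = _packaged(f"{locus_name}_segments.tsv")
    else:
        seg_src = Path(annotation_path)
        if not seg_src.exists():
            raise AnnotationError(f"annotation file not found: {seg_src}")
    try:
        seg_df = pd.read_csv(seg_src, sep="\t", dtype={"name": str, "kind": str, "chrom": str})
    except Exception as exc:  # pragma: no cover - pandas error text varies
        raise AnnotationError(f"malformed annotation file {seg_src}: {exc}") from exc
    required = {"name", "kind", "chrom", "start", "end"}
    if not required.issubset(seg_df.columns):
        raise AnnotationError(f"annotation file {seg_src} missing columns {required - set(seg_df.columns)}")
    segments = []
    for _, r in seg_df.iterrows():
        so = r.get("switch_order")
        so = None if pd.isna(so) or so == "" else int(so)
        segments.append(
            SegmentAnnotation(name=str(r["name"]), kind=str(r["kind"]), chrom=str(r["chrom"]),
                              start=int(r["start"]), end=int(r["end"]), switch_order=so)
        )
    locus = LocusDefinition(
        locus=locus_name,
        chrom=row["chrom"],
        span_start=int(row["span_start"]),
        span_end=int(row["span_end"]),
        orientation=row["orientation"],
        segments=segments,
        baseline_regions=_parse_baseline(row["baseline_regions"]),
        cn_proxy_gene=row["cn_proxy_gene"],
    )
    locus.validate()
    return locus


def deletion_indicator(locus: LocusDefinition, x: int, v: SegmentAnnotation | str,
                       j: SegmentAnnotation | str) -> int:
    """1 iff position ``x`` is excised by a (v, j) rearrangement.

    The excised interval is strictly between the deletion-axis end of ``v``
    and the deletion-axis start of ``j``.
    """
    if not (locus.span_start <= x <= locus.span_end):
        raise ValueError(f"position {x} outside locus span {locus.span_start}-{locus.span_end}")
    by_name = {s.name: s for s in locus.segments}
    if isinstance(v, str):
        v = by_name[v]
    if isinstance(j, str):
        j = by_name[j]
    if v.kind != "V":
        raise ValueError(f"segment {v.name} is not a V segment")
    if j.kind != "J":
        raise ValueError(f"segment {j.name} is not a J segment")
    ax = locus.axis(x)
    return int(locus.segment_axis(v)[1] < ax < locus.segment_axis(j)[0])
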