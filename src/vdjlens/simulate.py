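"""Synthetic coverage generator: the oracle for every estimator.

Per-base depth is Poisson around an expected copy-number curve composed from
V(D)J deletion (the segment-step curve from a known usage truth), class-switch
deletion over the IGH constant blocks, germline CNVs, tumor purity / local
somatic copy number and a smooth GC bias:

    depth(x) ~ Poisson( D * CN(x)/C_flank * bias(gc(x)) / mean(bias) )

Everything is deterministic under a fixed seed, and the truth object is
serialisable alongside each track. Depths from 0.1x to 60x are supported; the
nested-downsampling helper thins an existing track binomially.
"""
from __future__ import annotations

import dataclasses
import json
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np

from .annotation import LocusDefinition
from .class_switch import N_CLASSES, switch_blocks
from .coverage import CoverageTrack
from .vdj import DeletionCurve, PurityCNContext


class SimulationError(ValueError):
    pass


@dataclass
class SimTruth:
    """Ground truth for one simulated sample."""

    locus: str
    f_true: float
    v_usage: np.ndarray
    j_usage: np.ndarray
    isotype: np.ndarray | None = None          # IGH only: simplex over 8 classes
    germline_cnv: list[tuple[int, int, int]] = field(default_factory=list)  # (gstart, gend, cn)
    purity: float = 0.0
    local_cn: float = 2.0
    depth: float = 30.0
    gc_bias: tuple[float, float] = (0.3, -1.0)  # log-linear, log-quadratic coefficients
    dispersion: float | None = None  # None = Poisson; else negative-binomial shape k
    seed: int = 0
    sample_id: str | None = None

    def __post_init__(self):
        self.v_usage = np.asarray(self.v_usage, dtype=float)
        self.j_usage = np.asarray(self.j_usage, dtype=float)
        if self.isotype is not None:
            self.isotype = np.asarray(self.isotype, dtype=float)
            if len(self.isotype) != N_CLASSES or abs(self.isotype.sum() - 1.0) > 1e-8:
                raise SimulationError("isotype truth must be a simplex over the 8 classes")
        for v, lab in ((self.v_usage, "V"), (self.j_usage, "J")):
            if np.any(v < 0) or abs(v.sum() - 1.0) > 1e-8:
                raise SimulationError(f"{lab} usage truth is not a simplex")
        if self.depth <= 0:
            raise SimulationError("depth must be positive")
        if not 0.0 <= self.f_true:
            raise SimulationError("fraction truth must be non-negative")

    @property
    def context(self) -> PurityCNContext:
        return PurityCNContext(purity=self.purity, tumor_cn=self.local_cn)

    def to_json(self, path: str | Path) -> None:
        d = dataclasses.asdict(self)
        for k in ("v_usage", "j_usage", "isotype"):
            if d[k] is not None:
                d[k] = np.asarray(d[k]).tolist()
        Path(path).write_text(json.dumps(d, indent=1))

    @classmethod
    def from_json(cls, path: str | Path) -> "SimTruth":
        d = json.loads(Path(path).read_text())
        d["germline_cnv"] = [tuple(t) for t in d["germline_cnv"]]
        d["gc_bias"] = tuple(d["gc_bias"])
        for k in ("v_usage", "j_usage", "isotype"):
            if d[k] is not None:
                d[k] = np.asarray(d[k])
        return cls(**d)


def synthetic_gc(locus: LocusDefinition, seed: int = 0, block: int = 1000,
                 mean: float = 0.45, sd: float = 0.05,
                 bounds: tuple[float, float] = (0.30, 0.65)) -> np.ndarray:
    """Smooth per-base GC fraction over the locus window (AR(1) over blocks)."""
    rng = np.random.default_rng(seed)
    n = locus.span_end - locus.span_start + 1
    nblocks = n // block + 1
    z = np.empty(nblocks)
    z[0] = rng.normal()
    rho = 0.85
    eps = rng.normal(size=nblocks) * np.sqrt(1 - rho**2)
    for i in range(1, nblocks):
        z[i] = rho * z[i - 1] + eps[i]
    gc = np.clip(mean + sd * z, *bounds)
    return np.repeat(gc, block)[:n]


def _gc_bias(gc: np.ndarray, params: tuple[float, float]) -> np.ndarray:
    b1, b2 = params
    d = gc - 0.5
    bias = np.exp(b1 * d + b2 * d * d)
    return bias / bias.mean()


def expected_cn(truth: SimTruth, locus: LocusDefinition) -> np.ndarray:
    """Expected local copy number per position (genomic order)."""
    positions = np.arange(locus.span_start, locus.span_end + 1)
    ax = locus.axis(positions).astype(float)
    curve = DeletionCurve.from_locus(locus, truth.v_usage, truth.j_usage)
    cf = truth.context.c_flank
    cn = cf - 2.0 * truth.f_true * curve.F(ax)
    if truth.isotype is not None and locus.constant_segments:
        _, bounds = switch_blocks(locus)
        s_by_rank = 1.0 - np.cumsum(truth.isotype)   # S(r) = sum_{c>r} pi_c
        idx = np.searchsorted(bounds, ax, side="right") - 1
        inside = (idx >= 0) & (idx < N_CLASSES)
        s = np.zeros_like(ax)
        s[inside] = s_by_rank[idx[inside]]
        cn = cn - 1.0 * truth.f_true * s
    cn_g = np.full_like(ax, 2.0)
    for gs, ge, c in truth.germline_cnv:
        cn_g[(positions >= gs) & (positions <= ge)] = c
    cn = cn * (cn_g / 2.0)
    if np.any(cn < 0):
        raise SimulationError("inconsistent truth: negative expected copy number")
    return cn


def simulate_coverage(truth: SimTruth, locus: LocusDefinition,
                      gc: np.ndarray | None = None,
                      seed: int | None = None) -> tuple[CoverageTrack, np.ndarray]:
    """Poisson coverage track plus the per-base GC used for the bias.

    Returns (track, gc) so callers can feed the same GC to the normaliser.
    """
    seed = truth.seed if seed is None else seed
    if gc is None:
        gc = synthetic_gc(locus, seed=seed + 1_000_003)
    cn = expected_cn(truth, locus)
    cf = truth.context.c_flank
    lam = truth.depth * (cn / cf) * _gc_bias(gc, truth.gc_bias)
    rng = np.random.default_rng(seed)
    if truth.dispersion is None:
        depth = rng.poisson(lam)
    else:
        # negative binomial via gamma-Poisson mixing: var = lam + lam^2/k
        k = float(truth.dispersion)
        if k <= 0:
            raise SimulationError("dispersion must be positive")
        depth = rng.poisson(rng.gamma(shape=k, scale=lam / k))
    positions = np.arange(locus.span_start, locus.span_end + 1, dtype=np.int64)
    track = CoverageTrack(locus=locus.locus, chrom=locus.chrom, positions=positions,
                          depth=depth, sample_id=truth.sample_id or f"sim_{seed}",
                          mean_depth_genomewide=truth.depth)
    return track, gc


def downsample_track(track: CoverageTrack, target_depth: float,
                     seed: int = 0) -> CoverageTrack:
    """Binomial per-position thinning to a target genome-wide depth.

    Thinning is nested-consistent: thinning 30x->5x is distributed like
    thinning 30x->10x->5x.
    """
    current = track.mean_depth_genomewide
    if current is None:
        current = float(np.mean(track.depth))
    if target_depth > current:
        raise SimulationError(f"cannot downsample {current}x to {target_depth}x")
    ratio = target_depth / current
    if ratio == 1.0:
        return CoverageTrack(locus=track.locus, chrom=track.chrom,
                             positions=track.positions.copy(), depth=track.depth.copy(),
                             sample_id=track.sample_id,
                             mean_depth_genomewide=target_depth)
    rng = np.random.default_rng(seed)
    depth = rng.binomial(np.asarray(track.depth, dtype=np.int64), ratio)
    return CoverageTrack(locus=track.locus, chrom=track.chrom,
                         positions=track.positions.copy(), depth=depth,
                         sample_id=track.sample_id,
                         mean_depth_genomewide=target_depth)


def simulate_cohort(n: int, locus: LocusDefinition, seed: int = 0,
                    f_range: tuple[float, float] = (0.0, 0.5),
                    depth: float = 30.0,
                    usage_concentration: float = 1.0,
                    isotype_alpha: np.ndarray | None = None,
                    purity: float = 0.0, local_cn: float = 2.0,
                    out_dir: str | Path | None = None):
    """Reproducible cohort of (track, gc, truth) triples.

    Usage simplices are Dirichlet(``usage_concentration``); IGH samples draw
    an isotype mix from Dirichlet(``isotype_alpha``) when given. If
    ``out_dir`` is set, tracks and truths are also written to disk with a
    truth-table TSV.
    """
    rng = np.random.default_rng(seed)
    out = []
    rows = []
    for i in range(n):
        f = float(rng.uniform(*f_range))
        v = rng.dirichlet(np.full(len(locus.v_segments), usage_concentration))
        j = rng.dirichlet(np.full(len(locus.j_segments), usage_concentration))
        iso = rng.dirichlet(isotype_alpha) if isotype_alpha is not None else None
        truth = SimTruth(locus=locus.locus, f_true=f, v_usage=v, j_usage=j,
                         isotype=iso, purity=purity, local_cn=local_cn, depth=depth,
                         seed=int(rng.integers(2**31 - 1)), sample_id=f"sim{i:03d}")
        track, gc = simulate_coverage(truth, locus)
        out.append((track, gc, truth))
        rows.append((truth.sample_id, f, depth, purity, local_cn))
    if out_dir is not None:
        from .coverage import write_coverage_table

        out_dir = Path(out_dir)
        out_dir.mkdir(parents=True, exist_ok=True)
        with open(out_dir / "truth.tsv", "w") as fh:
            fh.write("sample_id\tf_true\tdepth\tpurity\tlocal_cn\n")
            for r in rows:
                fh.write("\t".join(str(x) for x in r) + "\n")
        for track, _, truth in out:
            write_coverage_table(track, out_dir / f"{truth.sample_id}.cov.tsv.gz")
            truth.to_json(out_dir / f"{truth.sample_id}.truth.json")
    return out


def write_toy_bam(path: str | Path, chrom: str, chrom_length: int,
                  reads: list[tuple[int, int]], mapq: int = 60) -> None:
    """Tiny sorted+indexed BAM of gapless reads (1-based inclusive intervals).

    Test helper for the coverage extractor; not a read-level simulator.
    """
    import pysam

    path = str(path)
    header = {"HD": {"VN": "1.6", "SO": "coordinate"},
              "SQ": [{"SN": chrom, "LN": chrom_length}]}
    reads = sorted(reads)
    with pysam.AlignmentFile(path, "wb", header=header) as bam:
        for i, (start, end) in enumerate(reads):
            a = pysam.AlignedSegment()
            a.query_name = f"read{i}"
            length = end - start + 1
            a.query_sequence = "A" * length
            a.reference_id = 0
            a.reference_start = start - 1
            a.mapping_quality = mapq
            a.cigar = [(0, length)]
            a.query_qualities = pysam.qualitystring_to_array("I" * length)
            bam.write(a)
    pysam.index(path)
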