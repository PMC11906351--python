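"""Raw depth -> binned, GC-corrected log2 read-depth-ratio (RDR) profiles.

The locus window is tiled with fixed-size bins; each bin gets a mean depth,
a GC fraction, a deletion-axis midpoint and flags (baseline membership,
proximity to a segment boundary). A LOESS trend of log depth on GC, fitted on
baseline bins only, removes GC bias, and depth is expressed as log2 ratio to
the GC-corrected baseline depth. Bin weights are proportional to the expected
read count and feed the heteroscedastic least-squares fit downstream.
"""
from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from .annotation import LocusDefinition
from .coverage import CoverageTrack

PSEUDO_DEPTH = 0.5  # pseudo-count for zero-depth bins


class NormalizationError(ValueError):
    pass


@dataclass
class BinnedCoverage:
    """Mean depth and GC per fixed-size bin over a locus window."""

    locus: str
    chrom: str
    bin_start: np.ndarray  # genomic, 1-based inclusive
    bin_end: np.ndarray
    axis_mid: np.ndarray   # deletion-axis midpoint
    depth: np.ndarray      # mean per-base depth in bin
    gc: np.ndarray         # G+C fraction
    n_bases: np.ndarray
    baseline: np.ndarray   # bool: bin fully inside a baseline region
    boundary: np.ndarray   # bool: bin within +-margin of a segment boundary

    def __len__(self):
        return len(self.bin_start)


@dataclass
class GCModel:
    """Smooth trend of log2 depth on GC fraction, fitted on baseline bins.

    The correction is defined on gc in [0.25, 0.75] and clamped outside.
    ``identity`` marks a degenerate fit (too few bins or no GC spread).
    """

    gc_grid: np.ndarray
    log2_trend: np.ndarray  # trend minus its weighted mean: correction in log2 units
    residual_sd: float
    method: str = "lowess"
    identity: bool = False

    def correction(self, gc: np.ndarray) -> np.ndarray:
        """log2 units to subtract from log2 depth at the given GC."""
        if self.identity:
            return np.zeros_like(np.asarray(gc, dtype=float))
        gc = np.clip(np.asarray(gc, dtype=float), 0.25, 0.75)
        return np.interp(gc, self.gc_grid, self.log2_trend)

    def correct_depth(self, depth: np.ndarray, gc: np.ndarray) -> np.ndarray:
        return np.asarray(depth, dtype=float) * 2.0 ** (-self.correction(gc))


@dataclass
class RatioProfile:
    """Binned, GC-corrected log2 read-depth ratio across a locus."""

    locus: str
    chrom: str
    bin_start: np.ndarray
    bin_end: np.ndarray
    axis_mid: np.ndarray
    log2_rdr: np.ndarray
    weight: np.ndarray
    gc: np.ndarray
    baseline: np.ndarray
    boundary: np.ndarray
    baseline_depth: float
    mean_depth: float  # mean raw depth over the window, in x units

    def __len__(self):
        return len(self.bin_start)

    def to_table(self) -> pd.DataFrame:
        return pd.DataFrame({
            "bin_start": self.bin_start, "bin_end": self.bin_end,
            "gc": self.gc, "log2_rdr": self.log2_rdr, "weight": self.weight,
            "baseline": self.baseline.astype(int), "boundary": self.boundary.astype(int),
        })

    def write(self, path: str | Path) -> None:
        self.to_table().to_csv(path, sep="\t", index=False)


def _gc_fraction(seq_array: np.ndarray) -> np.ndarray:
    return np.isin(seq_array, (b"G", b"C", b"g", b"c"))


def _segment_boundaries(locus: LocusDefinition) -> np.ndarray:
    bounds = list(locus.v_boundaries()) + list(locus.j_boundaries())
    for c in locus.constant_segments:
        bounds.extend(locus.segment_axis(c))
    return np.asarray(sorted(bounds), dtype=float)


def bin_coverage(track: CoverageTrack, locus: LocusDefinition, bin_size: int = 500,
                 reference: str | Path | None = None, gc: np.ndarray | None = None,
                 boundary_margin: int = 250,
                 exclude_regions: list[tuple[int, int]] | None = None) -> BinnedCoverage:
    """Tile the locus span with ``bin_size`` bins of mean depth and GC.

    GC comes either from ``reference`` (an indexed FASTA) or from ``gc``, a
    per-base G+C indicator/fraction array aligned with ``track.positions``.
    Bins overlapping ``exclude_regions`` (e.g. a mappability blacklist) are
    dropped; bins within ``boundary_margin`` of a segment boundary are
    flagged for down-weighting.
    """
    if bin_size < 50:
        raise NormalizationError("bin_size must be >= 50 bp")
    if gc is None and reference is None:
        raise NormalizationError("need a reference FASTA or a per-base gc array")
    pos, depth = track.positions, np.asarray(track.depth, dtype=float)
    if track.chrom != locus.chrom:
        raise NormalizationError(f"track chromosome {track.chrom} != locus chromosome {locus.chrom}")
    if gc is not None:
        gc = np.asarray(gc, dtype=float)
        if len(gc) != len(pos):
            raise NormalizationError("gc array must align with track positions")
    else:
        import pysam
        with pysam.FastaFile(str(reference)) as fa:
            contig = locus.chrom if locus.chrom in fa.references else locus.chrom.removeprefix("chr")
            if contig not in fa.references:
                raise NormalizationError(f"chromosome {locus.chrom} not in reference {reference}")
            seq = fa.fetch(contig, int(pos[0]) - 1, int(pos[-1]))
        arr = np.frombuffer(seq.encode(), dtype="S1")
        base_gc = _gc_fraction(arr).astype(float)
        gc = base_gc[pos - pos[0]]

    edges = np.arange(locus.span_start, locus.span_end + bin_size + 1, bin_size)
    edges[-1] = max(edges[-1], locus.span_end + 1)
    idx = np.searchsorted(edges, pos, side="right") - 1
    nbins = len(edges) - 1
    n = np.bincount(idx, minlength=nbins).astype(float)
    keep = n > 0
    dsum = np.bincount(idx, weights=depth, minlength=nbins)
    gsum = np.bincount(idx, weights=gc, minlength=nbins)
    bin_start = edges[:-1][keep]
    bin_end = np.minimum(edges[1:] - 1, locus.span_end)[keep]
    n = n[keep]
    mean_depth = dsum[keep] / n
    gc_frac = gsum[keep] / n

    mid = (bin_start + bin_end) / 2.0
    axis_mid = locus.axis(mid)

    baseline = np.zeros(len(bin_start), dtype=bool)
    for s, e in locus.baseline_regions:
        baseline |= (bin_start >= s) & (bin_end <= e)

    bounds = _segment_boundaries(locus)
    a_lo = np.minimum(locus.axis(bin_start.astype(float)), locus.axis(bin_end.astype(float)))
    a_hi = np.maximum(locus.axis(bin_start.astype(float)), locus.axis(bin_end.astype(float)))
    lo_idx = np.searchsorted(bounds, a_lo - boundary_margin)
    hi_idx = np.searchsorted(bounds, a_hi + boundary_margin)
    boundary = hi_idx > lo_idx

    drop = np.zeros(len(bin_start), dtype=bool)
    for s, e in exclude_regions or []:
        drop |= (bin_start <= e) & (bin_end >= s)
    sel = ~drop
    return BinnedCoverage(locus=track.locus or locus.locus, chrom=locus.chrom,
                          bin_start=bin_start[sel], bin_end=bin_end[sel],
                          axis_mid=axis_mid[sel], depth=mean_depth[sel], gc=gc_frac[sel],
                          n_bases=n[sel], baseline=baseline[sel], boundary=boundary[sel])


def fit_gc_model(binned: BinnedCoverage, span: float = 0.75,
                 min_bins: int = 30) -> GCModel:
    """LOESS trend of log2 depth on GC over baseline bins.

    Falls back to an identity model (with a warning) when fewer than
    ``min_bins`` baseline bins are usable or the GC spread is < 0.05.
    """
    from statsmodels.nonparametric.smoothers_lowess import lowess

    mask = binned.baseline & (binned.depth > 0)
    gc, dep = binned.gc[mask], binned.depth[mask]
    if mask.sum() < min_bins:
        warnings.warn(f"only {int(mask.sum())} baseline bins; skipping GC correction")
        return GCModel(np.array([0.25, 0.75]), np.zeros(2), 0.0, identity=True)
    if gc.max() - gc.min() < 0.05:
        warnings.warn("degenerate GC range in baseline bins; skipping GC correction")
        return GCModel(np.array([0.25, 0.75]), np.zeros(2), 0.0, identity=True)
    y = np.log2(dep)
    sm = lowess(y, gc, frac=span, it=1, return_sorted=True)
    grid, trend = sm[:, 0], sm[:, 1]
    grid, uniq = np.unique(grid, return_index=True)
    trend = trend[uniq]
    # express the trend relative to its mean so the correction preserves scale
    w = np.interp(gc, grid, trend)
    trend = trend - np.average(w)
    resid = y - np.interp(gc, grid, trend) - np.average(y - np.interp(gc, grid, trend))
    return GCModel(gc_grid=grid, log2_trend=trend, residual_sd=float(np.std(resid)))


def to_ratio_profile(binned: BinnedCoverage, gc_model: GCModel,
                     locus: LocusDefinition, min_baseline_bins: int = 5) -> RatioProfile:
    """GC-correct bin depths and normalise against the baseline regions.

    Zero-depth bins are retained with a pseudo-count so that genuinely deep
    deletions at adequate coverage stay in the fit; weights are proportional
    to the GC-corrected expected read count per bin, with boundary-straddling
    bins retained but flagged.
    """
    corrected = gc_model.correct_depth(binned.depth, binned.gc)
    base = binned.baseline & (corrected > 0)
    if base.sum() < min_baseline_bins:
        raise NormalizationError(
            f"only {int(base.sum())} usable baseline bins (need >= {min_baseline_bins})"
        )
    baseline_depth = float(np.average(corrected[base], weights=binned.n_bases[base]))
    if baseline_depth <= 0:
        raise NormalizationError("baseline depth is not positive")
    dep = np.where(corrected <= 0, PSEUDO_DEPTH / binned.n_bases, corrected)
    log2_rdr = np.log2(dep / baseline_depth)
    weight = np.maximum(dep, PSEUDO_DEPTH / binned.n_bases) * binned.n_bases
    mean_depth = float(np.average(binned.depth, weights=binned.n_bases))
    return RatioProfile(locus=binned.locus, chrom=binned.chrom,
                        bin_start=binned.bin_start, bin_end=binned.bin_end,
                        axis_mid=binned.axis_mid, log2_rdr=log2_rdr, weight=weight,
                        gc=binned.gc, baseline=binned.baseline, boundary=binned.boundary,
                        baseline_depth=baseline_depth, mean_depth=mean_depth)


def write_gc_table(chrom: str, positions: np.ndarray, gc: np.ndarray,
                   path: str | Path) -> None:
    """Per-base GC fractions as chrom/pos/gc TSV (gzip if path ends in .gz)."""
    pd.DataFrame({"chrom": chrom, "pos": positions, "gc": gc}).to_csv(
        path, sep="\t", index=False)


def read_gc_table(path: str | Path) -> np.ndarray:
    """GC array from a table written by :func:`write_gc_table`."""
    df = pd.read_csv(path, sep="\t")
    if not {"pos", "gc"}.issubset(df.columns):
        raise NormalizationError(f"{path}: expected columns pos and gc")
    return df["gc"].to_numpy(dtype=float)


def read_ratio_profile(path: str | Path, locus: LocusDefinition,
                       baseline_depth: float, mean_depth: float) -> RatioProfile:
    """Load a profile written by :meth:`RatioProfile.write`."""
    df = pd.read_csv(path, sep="\t")
    mid = (df["bin_start"].to_numpy() + df["bin_end"].to_numpy()) / 2.0
    return RatioProfile(locus=locus.locus, chrom=locus.chrom,
                        bin_start=df["bin_start"].to_numpy(), bin_end=df["bin_end"].to_numpy(),
                        axis_mid=locus.axis(mid), log2_rdr=df["log2_rdr"].to_numpy(),
                        weight=df["weight"].to_numpy(), gc=df["gc"].to_numpy(),
                        baseline=df["baseline"].to_numpy().astype(bool),
                        boundary=df["boundary"].to_numpy().astype(bool),
                        baseline_depth=baseline_depth, mean_depth=mean_depth)
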