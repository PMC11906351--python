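import numpy as np
import pytest

from vdjlens import (DeletionCurve, LocusDefinition, PurityCNContext,
                     SegmentAnnotation, load_locus_definition)
from vdjlens.normalize import RatioProfile
from vdjlens.vdj import expected_log2_rdr


@pytest.fixture(scope="session")
def tcra():
    return load_locus_definition("TCRA")


@pytest.fixture(scope="session")
def igh():
    return load_locus_definition("IGH")


@pytest.fixture(scope="session")
def all_loci():
    return {name: load_locus_definition(name) for name in ("TCRA", "TCRB", "TCRG", "IGH")}


def make_toy_locus(orientation: str = "forward") -> LocusDefinition:
    """Small 3 V / 2 J locus on a 40 kb window for exact-oracle tests."""
    segs = [
        SegmentAnnotation("V1", "V", "chrT", 2000, 2200),
        SegmentAnnotation("V2", "V", "chrT", 6000, 6200),
        SegmentAnnotation("V3", "V", "chrT", 10000, 10200),
        SegmentAnnotation("J1", "J", "chrT", 25000, 25050),
        SegmentAnnotation("J2", "J", "chrT", 30000, 30050),
    ]
    span = 60000
    if orientation == "reverse":
        segs = [SegmentAnnotation(s.name, s.kind, s.chrom, span + 1 - s.end,
                                  span + 1 - s.start) for s in segs]
        baseline = [(1, 28000), (span - 1500, span)]
    else:
        baseline = [(1, 1500), (31000, span)]
    locus = LocusDefinition(locus="TCRA", chrom="chrT", span_start=1, span_end=span,
                            orientation=orientation, segments=segs,
                            baseline_regions=baseline)
    locus.validate()
    return locus


@pytest.fixture
def toy_locus():
    return make_toy_locus()


def model_profile(locus: LocusDefinition, f: float, p, q,
                  ctx: PurityCNContext | None = None, bin_size: int = 500,
                  noise_sd: float = 0.0, seed: int = 0) -> RatioProfile:
    """Noiseless (or Gaussian-perturbed) RatioProfile straight from the model."""
    ctx = ctx or PurityCNContext()
    curve = DeletionCurve.from_locus(locus, p, q)
    starts = np.arange(locus.span_start, locus.span_end + 1, bin_size)
    ends = np.minimum(starts + bin_size - 1, locus.span_end)
    mids = locus.axis((starts + ends) / 2.0)
    rdr = expected_log2_rdr(f, curve, ctx, mids)
    if noise_sd > 0:
        rdr = rdr + np.random.default_rng(seed).normal(0, noise_sd, len(rdr))
    baseline = np.zeros(len(starts), dtype=bool)
    for s, e in locus.baseline_regions:
        baseline |= (starts >= s) & (ends <= e)
    return RatioProfile(locus=locus.locus, chrom=locus.chrom, bin_start=starts,
                        bin_end=ends, axis_mid=mids, log2_rdr=rdr,
                        weight=np.ones(len(starts)), gc=np.full(len(starts), 0.5),
                        baseline=baseline, boundary=np.zeros(len(starts), dtype=bool),
                        baseline_depth=30.0, mean_depth=30.0)
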