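"""Binning, GC correction and ratio-profile construction."""
import numpy as np
import pytest

from vdjlens import (CoverageTrack, PurityCNContext, SimTruth, bin_coverage,
                     fit_gc_model, simulate_coverage, synthetic_gc,
                     to_ratio_profile)
from vdjlens.normalize import NormalizationError
from vdjlens.vdj import DeletionCurve

from conftest import make_toy_locus


def flat_track(locus, depth=30):
    pos = np.arange(locus.span_start, locus.span_end + 1)
    return CoverageTrack(locus=locus.locus, chrom=locus.chrom, positions=pos,
                         depth=np.full(len(pos), depth), sample_id="flat")


def test_constant_depth_binning(toy_locus):
    track = flat_track(toy_locus, depth=30)
    gc = np.full(len(track), 0.5)
    binned = bin_coverage(track, toy_locus, bin_size=1000, gc=gc)
    assert len(binned) == 60
    assert np.allclose(binned.depth, 30.0)
    assert np.allclose(binned.gc, 0.5)


def test_gc_from_reference_sequence(tmp_path, toy_locus):
    import pysam

    # first kb all A/T, second kb all G/C, rest alternating
    seq = "AT" * 500 + "GC" * 500 + "ACGT" * 14500
    fasta = tmp_path / "ref.fa"
    fasta.write_text(f">chrT\n{seq}\n")
    pysam.faidx(str(fasta))
    track = flat_track(toy_locus)
    binned = bin_coverage(track, toy_locus, bin_size=1000, reference=fasta)
    assert binned.gc[0] == 0.0
    assert binned.gc[1] == 1.0
    assert np.allclose(binned.gc[2:], 0.5)


def test_bin_means_equal_bruteforce(toy_locus):
    rng = np.random.default_rng(1)
    pos = np.arange(toy_locus.span_start, toy_locus.span_end + 1)
    depth = rng.poisson(20, len(pos))
    track = CoverageTrack(locus="TCRA", chrom="chrT", positions=pos, depth=depth)
    binned = bin_coverage(track, toy_locus, bin_size=500, gc=np.full(len(pos), 0.5))
    for i in (0, 7, 79):
        sel = (pos >= binned.bin_start[i]) & (pos <= binned.bin_end[i])
        assert binned.depth[i] == pytest.approx(depth[sel].mean())


def test_gc_model_identity_when_no_bias(toy_locus):
    rng = np.random.default_rng(2)
    pos = np.arange(toy_locus.span_start, toy_locus.span_end + 1)
    depth = rng.poisson(60, len(pos))
    gc = synthetic_gc(toy_locus, seed=3)
    track = CoverageTrack(locus="TCRA", chrom="chrT", positions=pos, depth=depth)
    binned = bin_coverage(track, toy_locus, bin_size=500, gc=gc)
    model = fit_gc_model(binned)
    grid = np.linspace(binned.gc.min(), binned.gc.max(), 50)
    assert np.max(np.abs(model.correction(grid))) < 0.05


def test_gc_bias_is_removed(toy_locus):
    """Depth ~ exp(-4 (gc - 0.5)^2): corrected bins flat within 2% of mean."""
    gc = synthetic_gc(toy_locus, seed=4, sd=0.08)
    pos = np.arange(toy_locus.span_start, toy_locus.span_end + 1)
    depth = np.round(1000 * np.exp(-4 * (gc - 0.5) ** 2)).astype(int)
    track = CoverageTrack(locus="TCRA", chrom="chrT", positions=pos, depth=depth)
    binned = bin_coverage(track, toy_locus, bin_size=500, gc=gc)
    model = fit_gc_model(binned)
    assert not model.identity
    corrected = model.correct_depth(binned.depth, binned.gc)
    assert np.max(np.abs(corrected / corrected.mean() - 1)) < 0.02


def test_gc_model_degenerate_inputs(toy_locus):
    track = flat_track(toy_locus)
    # too few baseline bins
    binned = bin_coverage(track, toy_locus, bin_size=500, gc=synthetic_gc(toy_locus, 5))
    binned.baseline[:] = False
    binned.baseline[:10] = True
    with pytest.warns(UserWarning, match="baseline bins"):
        model = fit_gc_model(binned)
    assert model.identity
    # no GC spread
    binned2 = bin_coverage(track, toy_locus, bin_size=500, gc=np.full(len(track), 0.5))
    with pytest.warns(UserWarning, match="GC range"):
        assert fit_gc_model(binned2).identity


def test_flat_profile_has_zero_rdr(toy_locus):
    track = flat_track(toy_locus, depth=30)
    binned = bin_coverage(track, toy_locus, bin_size=500, gc=synthetic_gc(toy_locus, 6))
    profile = to_ratio_profile(binned, fit_gc_model(binned), toy_locus)
    assert np.max(np.abs(profile.log2_rdr)) < 0.05
    assert profile.baseline_depth == pytest.approx(30.0, rel=0.01)


def test_half_depth_interior_is_minus_one(toy_locus):
    pos = np.arange(toy_locus.span_start, toy_locus.span_end + 1)
    depth = np.full(len(pos), 40)
    interior = (pos > 10200) & (pos < 25000)  # between last V and first J
    depth[interior] = 20
    track = CoverageTrack(locus="TCRA", chrom="chrT", positions=pos, depth=depth)
    binned = bin_coverage(track, toy_locus, bin_size=500, gc=np.full(len(pos), 0.5))
    with pytest.warns(UserWarning):
        profile = to_ratio_profile(binned, fit_gc_model(binned), toy_locus)
    mid = (profile.bin_start + profile.bin_end) / 2
    inner = (mid > 11000) & (mid < 24500)
    assert np.allclose(profile.log2_rdr[inner], -1.0, atol=1e-6)


def test_simulated_profile_matches_analytic_mean(tcra):
    """f = 0.2 TCRA: RDR tracks log2(1 - f F(x)) within the Poisson envelope."""
    p = np.full(40, 1 / 40)
    q = np.full(20, 1 / 20)
    truth = SimTruth(locus="TCRA", f_true=0.2, v_usage=p, j_usage=q, depth=30,
                     seed=11, gc_bias=(0.0, 0.0))
    track, gc = simulate_coverage(truth, tcra)
    binned = bin_coverage(track, tcra, bin_size=500, gc=gc)
    profile = to_ratio_profile(binned, fit_gc_model(binned), tcra)
    curve = DeletionCurve.from_locus(tcra, p, q)
    expected = np.log2(1 - truth.f_true * curve.F(profile.axis_mid))
    n_reads = 30 * 500
    sd = np.sqrt(1 / n_reads) / np.log(2)  # per-bin log2 SD at full CN
    ok = np.abs(profile.log2_rdr - expected) < 4 * sd
    assert ok.mean() > 0.99


def test_scaling_invariance(toy_locus):
    """Multiplying all depths by c > 0 leaves log2 RDR unchanged."""
    rng = np.random.default_rng(7)
    pos = np.arange(toy_locus.span_start, toy_locus.span_end + 1)
    depth = rng.poisson(25, len(pos)) + 1
    gc = synthetic_gc(toy_locus, seed=8)
    profiles = []
    for c in (1, 7):
        track = CoverageTrack(locus="TCRA", chrom="chrT", positions=pos, depth=depth * c)
        binned = bin_coverage(track, toy_locus, bin_size=500, gc=gc)
        profiles.append(to_ratio_profile(binned, fit_gc_model(binned), toy_locus))
    assert np.allclose(profiles[0].log2_rdr, profiles[1].log2_rdr, atol=1e-9)


def test_gc_correction_idempotent(toy_locus):
    rng = np.random.default_rng(9)
    gc = synthetic_gc(toy_locus, seed=9, sd=0.08)
    pos = np.arange(toy_locus.span_start, toy_locus.span_end + 1)
    depth = rng.poisson(50 * np.exp(0.8 * (gc - 0.45)))
    track = CoverageTrack(locus="TCRA", chrom="chrT", positions=pos, depth=depth)
    binned = bin_coverage(track, toy_locus, bin_size=500, gc=gc)
    model = fit_gc_model(binned)
    once = model.correct_depth(binned.depth, binned.gc)
    binned.depth = once
    model2 = fit_gc_model(binned)
    twice = model2.correct_depth(once, binned.gc)
    rms = np.sqrt(np.mean((twice / once - 1) ** 2))
    assert rms < 0.01


def test_baseline_required(toy_locus):
    track = flat_track(toy_locus)
    binned = bin_coverage(track, toy_locus, bin_size=500, gc=np.full(len(track), 0.5))
    binned.baseline[:] = False
    with pytest.warns(UserWarning):
        model = fit_gc_model(binned)
    with pytest.raises(NormalizationError, match="baseline"):
        to_ratio_profile(binned, model, toy_locus)
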