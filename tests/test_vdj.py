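"""Core estimator: forward model, isotonic two-stage fit, purity adjustment."""
import numpy as np
import pytest
from scipy.optimize import minimize

from vdjlens import (DeletionCurve, FitOptions, PurityCNContext, SimTruth,
                     adjust_reported_fraction, expected_log2_rdr, fit_locus,
                     fit_vdj, simulate_coverage)
from vdjlens.vdj import FitError, pava

from conftest import make_toy_locus, model_profile

FAST = FitOptions(n_bootstrap=0)


# ---------------------------------------------------------------- forward model
def test_expected_rdr_closed_forms(toy_locus):
    curve = DeletionCurve.from_locus(toy_locus, [0.2, 0.3, 0.5], [0.4, 0.6])
    ctx = PurityCNContext()
    xs = np.linspace(0, 39000, 50)
    assert np.allclose(expected_log2_rdr(0.0, curve, ctx, xs), 0.0)
    # f = 0.5 on the fully deleted interior: log2(1 - 0.5) = -1
    interior = toy_locus.axis(20000)
    assert expected_log2_rdr(0.5, curve, ctx, interior) == pytest.approx(-1.0)
    # tumor context, hand-computed from CN(x) = C_flank - a f F(x):
    # C_flank = 0.6*3 + 0.4*2 = 2.6; log2((2.6 - 0.2)/2.6) = -0.115477
    tumor = PurityCNContext(purity=0.6, tumor_cn=3)
    assert expected_log2_rdr(0.1, curve, tumor, interior) == \
        pytest.approx(np.log2(2.4 / 2.6), abs=1e-12)
    with pytest.raises(FitError):
        expected_log2_rdr(1.5, curve, ctx, interior)


def test_deletion_curve_shape(toy_locus):
    rng = np.random.default_rng(0)
    curve = DeletionCurve.from_locus(toy_locus, rng.dirichlet(np.ones(3)),
                                     rng.dirichlet(np.ones(2)))
    xs = np.arange(0, 39999, 25.0)
    F = curve.F(xs)
    assert np.all((0 <= F) & (F <= 1))
    vb, jb = max(toy_locus.v_boundaries()), min(toy_locus.j_boundaries())
    assert np.all(np.diff(F[xs <= vb]) >= 0)
    assert np.allclose(F[(xs > vb) & (xs < jb)], 1.0)
    assert np.all(np.diff(F[xs >= jb]) <= 0)
    with pytest.raises(FitError):
        DeletionCurve.from_locus(toy_locus, [0.5, 0.2, 0.2], [0.5, 0.5])


def test_pava_matches_bruteforce():
    rng = np.random.default_rng(3)
    for _ in range(20):
        n = int(rng.integers(2, 12))
        y = rng.normal(size=n)
        w = rng.uniform(0.5, 2.0, size=n)
        fit = pava(y, w, increasing=True)
        assert np.all(np.diff(fit) >= -1e-12)
        # optimality: no feasible direction improves the weighted SS
        obj = np.sum(w * (y - fit) ** 2)
        for _ in range(200):
            cand = np.sort(fit + rng.normal(0, 0.05, n))
            assert np.sum(w * (y - cand) ** 2) >= obj - 1e-9


# ---------------------------------------------------------------- exact oracle
def grid_oracle_objective(profile, locus, d, w, mid):
    """Global weighted-LS optimum by coarse grid + local polish."""
    vb = np.asarray(locus.v_boundaries(), float)
    jb = np.asarray(locus.j_boundaries(), float)

    def unpack(x):
        f, p1, p2, q1 = x
        p = np.array([p1, p2, 1 - p1 - p2])
        q = np.array([q1, 1 - q1])
        return f, p, q

    def objective(x):
        f, p, q = unpack(x)
        if f < 0 or np.any(p < 0) or np.any(q < 0):
            return 1e6
        curve = DeletionCurve(vb, jb, p / p.sum(), q / q.sum())
        return float(np.sum(w * (d - f * curve.F(mid)) ** 2))

    best, best_obj = None, np.inf
    for f in np.linspace(0.0, 0.6, 13):
        for p1 in np.linspace(0.05, 0.9, 6):
            for p2 in np.linspace(0.05, 0.9, 6):
                if p1 + p2 > 0.95:
                    continue
                for q1 in np.linspace(0.05, 0.95, 6):
                    x = (f, p1, p2, q1)
                    o = objective(x)
                    if o < best_obj:
                        best, best_obj = x, o
    res = minimize(objective, best, method="Nelder-Mead",
                   options={"xatol": 1e-10, "fatol": 1e-14, "maxiter": 20000})
    return min(best_obj, float(res.fun))


def test_noiseless_toy_equals_grid_search(toy_locus):
    """Two-stage isotonic fit attains the global weighted-LS optimum."""
    f, p, q = 0.3, np.array([0.2, 0.5, 0.3]), np.array([0.6, 0.4])
    profile = model_profile(toy_locus, f, p, q, bin_size=500)
    fit = fit_vdj(profile, toy_locus, opts=FitOptions(n_bootstrap=0, min_bins=10))
    assert fit.fraction == pytest.approx(f, abs=1e-9)
    assert np.allclose(fit.v_usage_array, p, atol=1e-9)
    assert np.allclose(fit.j_usage_array, q, atol=1e-9)

    vb = np.asarray(toy_locus.v_boundaries(), float)
    jb = np.asarray(toy_locus.j_boundaries(), float)
    inside = (profile.axis_mid > vb[0]) & (profile.axis_mid < jb[-1])
    mid, w = profile.axis_mid[inside], profile.weight[inside]
    d = (1.0 - 2.0 ** profile.log2_rdr[inside])  # C_flank=2, a=2 cancel
    curve = DeletionCurve.from_locus(toy_locus, fit.v_usage_array, fit.j_usage_array)
    iso_obj = float(np.sum(w * (d - fit.fraction * curve.F(mid)) ** 2))
    grid_obj = grid_oracle_objective(profile, toy_locus, d, w, mid)
    assert abs(iso_obj - grid_obj) <= 1e-6


def test_flat_profile_zero_fraction(toy_locus):
    profile = model_profile(toy_locus, 0.0, [0.3, 0.3, 0.4], [0.5, 0.5])
    fit = fit_vdj(profile, toy_locus, opts=FitOptions(n_bootstrap=0, min_bins=10))
    assert fit.fraction < 1e-4
    assert fit.zero_fraction
    # zero-fraction fallback: uniform usage simplices
    assert np.allclose(fit.v_usage_array, 1 / 3)


def test_fit_shape_invariants(toy_locus):
    """Fitted usage is a simplex; fitted curve satisfies the shape constraints."""
    rng = np.random.default_rng(5)
    profile = model_profile(toy_locus, 0.25, [0.5, 0.3, 0.2], [0.7, 0.3],
                            noise_sd=0.02, seed=5)
    fit = fit_vdj(profile, toy_locus, opts=FitOptions(n_bootstrap=0, min_bins=10))
    assert fit.v_usage_array.sum() == pytest.approx(1.0, abs=1e-8)
    assert fit.j_usage_array.sum() == pytest.approx(1.0, abs=1e-8)
    assert np.all(fit.v_usage_array >= 0)
    assert 0 <= fit.fraction <= 1
    assert fit.ci_lower <= fit.fraction <= fit.ci_upper


# ---------------------------------------------------------------- simulations
def test_simulated_recovery_single_sample(tcra):
    """30x TCRA, f = 0.2, uniform usage: fraction within 0.02, usage close."""
    p, q = np.full(40, 1 / 40), np.full(20, 1 / 20)
    truth = SimTruth(locus="TCRA", f_true=0.2, v_usage=p, j_usage=q, depth=30, seed=21)
    track, gc = simulate_coverage(truth, tcra)
    _, fit = fit_locus(track, tcra, gc=gc, opts=FitOptions(n_bootstrap=100))
    assert abs(fit.fraction - 0.2) <= 0.02
    # total-variation distance near the Poisson information floor (~0.16 at
    # 30x with 500 bp bins; see docs/methods.md)
    assert 0.5 * np.abs(fit.v_usage_array - p).sum() <= 0.25
    assert 0.5 * np.abs(fit.j_usage_array - q).sum() <= 0.25
    assert fit.ci_lower <= 0.2 <= fit.ci_upper + 0.01


def test_bootstrap_ci_brackets_fraction(tcra):
    truth = SimTruth(locus="TCRA", f_true=0.1, v_usage=np.full(40, 1 / 40),
                     j_usage=np.full(20, 1 / 20), depth=30, seed=22)
    track, gc = simulate_coverage(truth, tcra)
    _, fit = fit_locus(track, tcra, gc=gc, opts=FitOptions(n_bootstrap=80))
    assert fit.ci_lower <= fit.fraction <= fit.ci_upper
    assert fit.ci_upper - fit.ci_lower < 0.05


def test_tumor_mixture_recovery(tcra):
    """purity 0.6, n_t = 3, immune fraction 0.1 of all cells at 30x."""
    rng = np.random.default_rng(23)
    truth = SimTruth(locus="TCRA", f_true=0.1, v_usage=rng.dirichlet(np.ones(40)),
                     j_usage=rng.dirichlet(np.ones(20)), purity=0.6, local_cn=3,
                     depth=30, seed=23)
    track, gc = simulate_coverage(truth, tcra)
    ctx = PurityCNContext(purity=0.6, tumor_cn=3)
    _, fit = fit_locus(track, tcra, ctx=ctx, gc=gc, opts=FAST)
    assert abs(adjust_reported_fraction(fit, ctx, "all_cells") - 0.1) <= 0.02


def test_adjust_reported_fraction(toy_locus):
    profile = model_profile(toy_locus, 0.0, [1 / 3] * 3, [0.5, 0.5])
    fit = fit_vdj(profile, toy_locus, opts=FitOptions(n_bootstrap=0, min_bins=10))
    fit.fraction = 0.1
    ctx0 = PurityCNContext(purity=0.0)
    assert adjust_reported_fraction(fit, ctx0, "all_cells") == \
        adjust_reported_fraction(fit, ctx0, "nontumor_cells")
    ctx = PurityCNContext(purity=0.5)
    assert adjust_reported_fraction(fit, ctx, "nontumor_cells") == pytest.approx(0.2)
    with pytest.raises(FitError):
        adjust_reported_fraction(fit, PurityCNContext(purity=1.0, tumor_cn=2),
                                 "nontumor_cells")


def test_context_validation():
    with pytest.raises(FitError):
        PurityCNContext(purity=1.2)
    with pytest.raises(FitError):
        PurityCNContext(purity=1.0, tumor_cn=0.0)


def test_too_few_bins_rejected(toy_locus):
    profile = model_profile(toy_locus, 0.1, [1 / 3] * 3, [0.5, 0.5], bin_size=500)
    keep = profile.baseline.copy()
    profile.weight[~keep] = 0.0
    with pytest.raises(FitError, match="usable bins"):
        fit_vdj(profile, toy_locus, opts=FitOptions(min_bins=10))
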