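"""Simulation benchmarks: parameter recovery under known ground truth.

These drive both the test suite and scripts/acceptance.py. Each benchmark
generates a cohort with the simulator, runs the full normalise-and-fit path,
and scores recovery against the truth.
"""
from __future__ import annotations

import numpy as np

from .annotation import load_locus_definition
from .class_switch import call_germline_cnv, fit_class_switch, switch_blocks
from .pipeline import fit_locus, profile_from_track
from .simulate import SimTruth, downsample_track, simulate_cohort, simulate_coverage
from .vdj import FitOptions, PurityCNContext, adjust_reported_fraction

_FAST_OPTS = FitOptions(n_bootstrap=0)

# Blood-like isotype mix: mostly naive/unswitched B cells with modest
# IgG/IgA class-switched compartments and rare IgE.
BLOOD_ISOTYPE_ALPHA = np.array([80.0, 3.0, 6.0, 4.0, 2.0, 1.0, 0.5, 2.0])


def vdj_recovery(locus_name: str = "TCRA", n: int = 100, depth: float = 30.0,
                 f_range: tuple[float, float] = (0.0, 0.5), seed: int = 0,
                 thin_to: float | None = None) -> dict:
    """Fraction recovery over a simulated cohort; optionally after thinning."""
    locus = load_locus_definition(locus_name)
    cohort = simulate_cohort(n, locus, seed=seed, f_range=f_range, depth=depth)
    truths, est = [], []
    for i, (track, gc, truth) in enumerate(cohort):
        if thin_to is not None:
            track = downsample_track(track, thin_to, seed=truth.seed + 7)
        _, fit = fit_locus(track, locus, gc=gc, opts=_FAST_OPTS)
        truths.append(truth.f_true)
        est.append(fit.fraction)
    truths, est = np.asarray(truths), np.asarray(est)
    r = float(np.corrcoef(truths, est)[0, 1])
    return {"r": r, "mae": float(np.mean(np.abs(truths - est))),
            "n": n, "depth": thin_to or depth,
            "f_true": truths, "f_est": est}


def class_switch_recovery(n: int = 50, depth: float = 30.0,
                          f_range: tuple[float, float] = (0.02, 0.2),
                          seed: int = 0,
                          isotype_alpha: np.ndarray = BLOOD_ISOTYPE_ALPHA) -> dict:
    """IGH isotype-aggregate recovery over a simulated cohort."""
    locus = load_locus_definition("IGH")
    cohort = simulate_cohort(n, locus, seed=seed, f_range=f_range, depth=depth,
                             isotype_alpha=isotype_alpha)
    rows = {k: [] for k in ("igm_igd", "igg", "iga")}
    ordering_ok, f_err = [], []
    used = 0
    for track, gc, truth in cohort:
        profile, fit = fit_locus(track, locus, gc=gc, opts=_FAST_OPTS)
        cs = fit_class_switch(profile, fit, locus)
        if not cs.isotypes_defined:
            continue
        used += 1
        pi = truth.isotype
        true_aggs = {
            "igm_igd": truth.f_true * pi[0],
            "igg": truth.f_true * (pi[1] + pi[2] + pi[4] + pi[5]),
            "iga": truth.f_true * (pi[3] + pi[7]),
        }
        est_aggs = {"igm_igd": cs.igm_igd, "igg": cs.igg, "iga": cs.iga}
        for k in rows:
            rows[k].append(abs(est_aggs[k] - true_aggs[k]) / truth.f_true)
        true_cs = truth.f_true - true_aggs["igm_igd"]
        ordering_ok.append((cs.class_switched > cs.igm_igd) == (true_cs > true_aggs["igm_igd"]))
        f_err.append(abs(fit.fraction - truth.f_true))
    return {("rel_mae_" + k): float(np.mean(v)) for k, v in rows.items()} | {
        "ordering_preserved": float(np.mean(ordering_ok)),
        "b_fraction_mae": float(np.mean(f_err)),
        "n": used,
    }


def germline_cnv_accuracy(n: int = 12, depth: float = 30.0, seed: int = 0,
                          cnv_states: tuple[int, ...] = (0, 1, 3, 4)) -> dict:
    """Integer-CN call accuracy for constant-block germline CNVs."""
    locus = load_locus_definition("IGH")
    names, bounds = switch_blocks(locus)
    rng = np.random.default_rng(seed)
    correct, total, low_conf = 0, 0, []
    for i in range(n):
        # pick one constant block per sample and a non-diploid state
        r = int(rng.integers(len(names)))
        cn = int(rng.choice(cnv_states))
        a, b = bounds[r], bounds[r + 1]
        if locus.orientation == "reverse":
            gs, ge = locus.span_end - int(b), locus.span_end - int(a)
        else:
            gs, ge = locus.span_start + int(a), locus.span_start + int(b)
        truth = SimTruth(locus="IGH", f_true=0.05,
                         v_usage=np.full(len(locus.v_segments), 1 / len(locus.v_segments)),
                         j_usage=np.full(len(locus.j_segments), 1 / len(locus.j_segments)),
                         isotype=np.eye(8)[0], germline_cnv=[(gs, ge, cn)],
                         depth=depth, seed=seed * 1000 + i)
        track, gc = simulate_coverage(truth, locus)
        profile = profile_from_track(track, locus, gc=gc)
        calls = call_germline_cnv(profile, locus)
        call = calls.by_region()[names[r]]
        correct += int(call.copy_number == cn and call.masked)
        total += 1
        low_conf.append(calls.low_confidence)
    return {"accuracy": correct / total, "n": total,
            "low_confidence_rate": float(np.mean(low_conf)), "depth": depth}


def purity_adjustment_recovery(depth: float = 30.0, seed: int = 0,
                               purities: tuple[float, ...] = (0.3, 0.6),
                               tumor_cns: tuple[int, ...] = (1, 2, 3, 4),
                               reps: int = 3) -> dict:
    """All-cells fraction recovery in tumor mixtures with known purity/CN."""
    locus = load_locus_definition("TCRA")
    rng = np.random.default_rng(seed)
    errs = []
    for purity in purities:
        for n_t in tumor_cns:
            for rep in range(reps):
                f = float(rng.uniform(0.02, 0.8 * (1 - purity)))
                v = rng.dirichlet(np.full(len(locus.v_segments), 1.0))
                j = rng.dirichlet(np.full(len(locus.j_segments), 1.0))
                truth = SimTruth(locus="TCRA", f_true=f, v_usage=v, j_usage=j,
                                 purity=purity, local_cn=n_t, depth=depth,
                                 seed=int(rng.integers(2**31 - 1)))
                track, gc = simulate_coverage(truth, locus)
                ctx = PurityCNContext(purity=purity, tumor_cn=n_t)
                _, fit = fit_locus(track, locus, ctx=ctx, gc=gc, opts=_FAST_OPTS)
                errs.append(abs(adjust_reported_fraction(fit, ctx, "all_cells") - f))
    return {"mae": float(np.mean(errs)), "n": len(errs), "depth": depth}
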