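"""Segment-step deletion model: lymphocyte fraction and V/J usage from RDR.

Forward model
-------------
Each recombined lymphocyte deletes ``a`` alleles (default 2) of the interval
between its chosen V and J segment. With V usage p and J usage q assumed
independent, the expected deleted-allele-pair fraction at deletion-axis
position x is

    F(x) = PV(x) * QJ(x),   PV(x) = sum of p_v over V ending before x,
                            QJ(x) = sum of q_j over J starting after x,

so the expected local copy number in a sample with flank copy number
C_flank = purity * n_tumor + (1 - purity) * n_germline is

    CN(x) = C_flank - a * f * F(x),      log2 RDR(x) = log2(CN(x) / C_flank),

where f is the lymphocyte fraction of all cells in the sample.

Estimator
---------
A two-stage convex fit. Each bin is transformed to
d(x) = C_flank * (1 - 2**RDR) / a, an unbiased plug-in for f * F(x); bins are
pooled between consecutive segment boundaries; weighted isotonic regression
(pool-adjacent-violators) enforces the shape constraints (non-decreasing over
the V region, non-increasing over the J region, common plateau f over the
interior); the plateau height is then the exact minimiser of the remaining
one-dimensional convex piecewise-quadratic problem. V/J usage follows from
the step increments. Uncertainty comes from a within-pool bin bootstrap.
"""
from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .annotation import LocusDefinition
from .normalize import RatioProfile


class FitError(ValueError):
    pass


# --------------------------------------------------------------------------
# purity / copy-number context
# --------------------------------------------------------------------------
@dataclass
class PurityCNContext:
    """Tumor purity and local copy number at the locus.

    ``tumor_cn`` is the somatic copy number of the nearby proxy gene;
    ``germline_cn`` is the inherited local copy number (2 unless a germline
    CNV is known). For a non-tumor sample leave the defaults.
    """

    purity: float = 0.0
    tumor_cn: float = 2.0
    germline_cn: float = 2.0

    def __post_init__(self):
        if not 0.0 <= self.purity <= 1.0:
            raise FitError(f"purity must be in [0, 1], got {self.purity}")
        if self.tumor_cn < 0 or self.germline_cn < 0:
            raise FitError("copy numbers must be non-negative")
        if self.c_flank <= 0:
            raise FitError("flank copy number purity*n_t + (1-purity)*n_g must be positive")

    @property
    def c_flank(self) -> float:
        return self.purity * self.tumor_cn + (1.0 - self.purity) * self.germline_cn


# --------------------------------------------------------------------------
# deletion curve
# --------------------------------------------------------------------------
@dataclass
class DeletionCurve:
    """Piecewise-constant F(x) = PV(x) * QJ(x) on the deletion axis."""

    v_boundaries: np.ndarray  # axis end of each V segment, ascending
    j_boundaries: np.ndarray  # axis start of each J segment, ascending
    v_usage: np.ndarray       # simplex over V segments
    j_usage: np.ndarray       # simplex over J segments

    def __post_init__(self):
        self.v_boundaries = np.asarray(self.v_boundaries, dtype=float)
        self.j_boundaries = np.asarray(self.j_boundaries, dtype=float)
        self.v_usage = np.asarray(self.v_usage, dtype=float)
        self.j_usage = np.asarray(self.j_usage, dtype=float)
        if len(self.v_usage) != len(self.v_boundaries) or len(self.j_usage) != len(self.j_boundaries):
            raise FitError("usage vectors must match boundary counts")
        for v, label in ((self.v_usage, "V"), (self.j_usage, "J")):
            if np.any(v < -1e-12) or abs(v.sum() - 1.0) > 1e-8:
                raise FitError(f"{label} usage is not a probability simplex")
        self._cum_p = np.clip(np.concatenate([[0.0], np.cumsum(self.v_usage)]), 0.0, 1.0)
        self._cum_q = np.clip(np.concatenate([[0.0], np.cumsum(self.j_usage)]), 0.0, 1.0)
        self._cum_p[-1] = 1.0
        self._cum_q[-1] = 1.0

    @classmethod
    def from_locus(cls, locus: LocusDefinition, v_usage, j_usage) -> "DeletionCurve":
        return cls(np.asarray(locus.v_boundaries(), dtype=float),
                   np.asarray(locus.j_boundaries(), dtype=float),
                   v_usage, j_usage)

    def pv(self, x) -> np.ndarray:
        idx = np.searchsorted(self.v_boundaries, np.asarray(x, dtype=float), side="left")
        return self._cum_p[idx]

    def qj(self, x) -> np.ndarray:
        idx = np.searchsorted(self.j_boundaries, np.asarray(x, dtype=float), side="right")
        return 1.0 - self._cum_q[idx]

    def F(self, x) -> np.ndarray:
        """Deleted fraction of recombined cells covering axis position x."""
        return self.pv(x) * self.qj(x)


def expected_log2_rdr(f: float, curve: DeletionCurve, ctx: PurityCNContext, x,
                      alleles_deleted: float = 2.0) -> np.ndarray:
    """Model log2 RDR at axis position(s) x for lymphocyte fraction f."""
    if f < 0:
        raise FitError("fraction must be non-negative")
    cf = ctx.c_flank
    cn = cf - alleles_deleted * f * curve.F(x)
    if np.any(cn <= 0):
        raise FitError("fraction too large: copy number would be non-positive")
    return np.log2(cn / cf)


# --------------------------------------------------------------------------
# isotonic machinery
# --------------------------------------------------------------------------
def pava(y: np.ndarray, w: np.ndarray, increasing: bool = True) -> np.ndarray:
    """Weighted isotonic regression by pool-adjacent-violators."""
    y = np.asarray(y, dtype=float)
    w = np.asarray(w, dtype=float)
    if not increasing:
        return pava(y[::-1], w[::-1], increasing=True)[::-1]
    n = len(y)
    means = list(y)
    weights = list(w)
    sizes = [1] * n
    i = 0
    while i < len(means) - 1:
        if means[i] > means[i + 1] + 0.0:
            tot = weights[i] + weights[i + 1]
            means[i] = (means[i] * weights[i] + means[i + 1] * weights[i + 1]) / tot
            weights[i] = tot
            sizes[i] += sizes[i + 1]
            del means[i + 1], weights[i + 1], sizes[i + 1]
            while i > 0 and means[i - 1] > means[i]:
                tot = weights[i - 1] + weights[i]
                means[i - 1] = (means[i - 1] * weights[i - 1] + means[i] * weights[i]) / tot
                weights[i - 1] = tot
                sizes[i - 1] += sizes[i]
                del means[i], weights[i], sizes[i]
                i -= 1
        else:
            i += 1
    return np.repeat(means, sizes)


def _plateau_objective(c, dv, wv, yv, dj, wj, yj, d_int, w_int):
    gv = float(np.sum(wv * (dv - np.minimum(yv, c)) ** 2)) if len(dv) else 0.0
    gj = float(np.sum(wj * (dj - np.minimum(yj, c)) ** 2)) if len(dj) else 0.0
    gi = float(np.sum(w_int * (d_int - c) ** 2))
    return gv + gj + gi


def _solve_plateau(dv, wv, yv, dj, wj, yj, d_int, w_int, cmax: float) -> float:
    """Exact minimiser of the convex piecewise-quadratic plateau objective.

    yv / yj are the unconstrained isotonic fits (already clipped below at 0);
    for plateau height c the shape-constrained fit is min(y, c), so the
    objective is quadratic between consecutive fitted values and the global
    minimum is found by scanning the candidate intervals.
    """
    knots = np.unique(np.concatenate([yv, yj, [0.0, cmax]]))
    knots = knots[(knots >= 0.0) & (knots <= cmax)]
    if knots[0] > 0.0:
        knots = np.concatenate([[0.0], knots])
    if knots[-1] < cmax:
        knots = np.concatenate([knots, [cmax]])
    best_c, best_g = 0.0, np.inf
    for lo, hi in zip(knots[:-1], knots[1:]):
        # pools clipped to c on this interval: fitted value >= hi
        act_v = yv >= hi - 1e-15
        act_j = yj >= hi - 1e-15
        sw = wv[act_v].sum() + wj[act_j].sum() + w_int.sum()
        sd = (wv[act_v] * dv[act_v]).sum() + (wj[act_j] * dj[act_j]).sum() + (w_int * d_int).sum()
        c = np.clip(sd / sw, lo, hi) if sw > 0 else lo
        g = _plateau_objective(c, dv, wv, yv, dj, wj, yj, d_int, w_int)
        if g < best_g - 1e-18 or (abs(g - best_g) <= 1e-18 and c < best_c):
            best_c, best_g = float(c), g
    return best_c


def _fill_and_diff(values: np.ndarray, known: np.ndarray, first: float, last: float) -> np.ndarray:
    """Increments across boundaries, splitting across empty pools evenly."""
    n = len(values)
    padded = np.empty(n + 2)
    padded[0], padded[-1] = first, last
    idx = np.arange(1, n + 1, dtype=float)
    kn = np.concatenate([[0.0], idx[known], [float(n + 1)]])
    kv = np.concatenate([[first], values[known], [last]])
    padded[1:-1] = np.interp(idx, kn, kv)
    return np.diff(padded)


# --------------------------------------------------------------------------
# fit
# --------------------------------------------------------------------------
@dataclass
class FitOptions:
    alleles_deleted: float = 2.0   # alleles lost per recombined cell (both, all loci)
    boundary_weight: float = 0.2   # down-weighting of boundary-straddling bins
    n_bootstrap: int = 200
    bootstrap_seed: int = 1234
    zero_fraction_threshold: float = 1e-4
    min_usage: float = 1e-6
    min_bins: int = 20


@dataclass
class VDJFit:
    """Estimated lymphocyte fraction, V/J usage and fit diagnostics."""

    locus: str
    fraction: float
    v_usage: dict[str, float]
    j_usage: dict[str, float]
    ci_lower: float
    ci_upper: float
    objective: float
    n_bins_used: int
    converged: bool
    zero_fraction: bool
    context: PurityCNContext = field(default_factory=PurityCNContext)

    @property
    def v_usage_array(self) -> np.ndarray:
        return np.asarray(list(self.v_usage.values()))

    @property
    def j_usage_array(self) -> np.ndarray:
        return np.asarray(list(self.j_usage.values()))

    def to_dict(self) -> dict:
        return {
            "locus": self.locus,
            "fraction": self.fraction,
            "ci": [self.ci_lower, self.ci_upper],
            "v_usage": self.v_usage,
            "j_usage": self.j_usage,
            "qc": {"n_bins": self.n_bins_used, "objective": self.objective,
                   "converged": self.converged, "zero_fraction": self.zero_fraction,
                   "purity": self.context.purity, "tumor_cn": self.context.tumor_cn},
        }


def _pool_fit(d, w, pool_idx, n_vpool, n_pools, cmax):
    """One plateau fit from bin-level d values; returns (f, yv, yj, pool data)."""
    wsum = np.bincount(pool_idx, weights=w, minlength=n_pools)
    dsum = np.bincount(pool_idx, weights=w * d, minlength=n_pools)
    nonempty = wsum > 0
    dbar = np.zeros(n_pools)
    dbar[nonempty] = dsum[nonempty] / wsum[nonempty]

    v_slice = slice(0, n_vpool)
    j_slice = slice(n_vpool + 1, n_pools)
    v_known = nonempty[v_slice]
    j_known = nonempty[j_slice]
    if not nonempty[n_vpool]:
        raise FitError("no usable bins in the V-J interior; cannot anchor the plateau")

    yv_known = pava(dbar[v_slice][v_known], wsum[v_slice][v_known], increasing=True)
    yj_known = pava(dbar[j_slice][j_known], wsum[j_slice][j_known], increasing=False)
    yv_known = np.maximum(yv_known, 0.0)
    yj_known = np.maximum(yj_known, 0.0)

    f = _solve_plateau(dbar[v_slice][v_known], wsum[v_slice][v_known], yv_known,
                       dbar[j_slice][j_known], wsum[j_slice][j_known], yj_known,
                       dbar[[n_vpool]], wsum[[n_vpool]], cmax)
    return f, yv_known, yj_known, v_known, j_known, wsum, dbar


def fit_vdj(profile: RatioProfile, locus: LocusDefinition,
            ctx: PurityCNContext | None = None,
            opts: FitOptions | None = None) -> VDJFit:
    """Fit lymphocyte fraction and V/J segment usage from a ratio profile."""
    ctx = ctx or PurityCNContext()
    opts = opts or FitOptions()
    a = opts.alleles_deleted
    cf = ctx.c_flank

    vb = np.asarray(locus.v_boundaries(), dtype=float)
    jb = np.asarray(locus.j_boundaries(), dtype=float)
    K, L = len(vb), len(jb)
    edges = np.concatenate([vb, jb])
    n_pools = K + L - 1   # K-1 V pools, 1 interior, L-1 J pools
    n_vpool = K - 1

    usable = np.isfinite(profile.log2_rdr) & (profile.weight > 0)
    inside = (profile.axis_mid > vb[0]) & (profile.axis_mid < jb[-1]) & usable
    n_bins = int(inside.sum())
    if n_bins < opts.min_bins:
        raise FitError(f"only {n_bins} usable bins inside the deletable span (need >= {opts.min_bins})")

    mid = profile.axis_mid[inside]
    pool_idx = np.clip(np.searchsorted(edges, mid, side="right") - 1, 0, n_pools - 1)
    rdr = profile.log2_rdr[inside]
    d = cf * (1.0 - 2.0 ** rdr) / a
    w = profile.weight[inside] * np.where(profile.boundary[inside], opts.boundary_weight, 1.0)

    cmax = min(1.0, cf / a) - 1e-12
    f, yv, yj, v_known, j_known, wsum, dbar = _pool_fit(d, w, pool_idx, n_vpool, n_pools, cmax)

    # usage from step increments of the clipped isotonic fits
    names_v = [s.name for s in locus.v_segments]
    names_j = [s.name for s in locus.j_segments]
    zero = f < opts.zero_fraction_threshold
    if zero:
        p = np.full(K, 1.0 / K)
        q = np.full(L, 1.0 / L)
    else:
        yv_full = np.zeros(n_vpool)
        yv_full[v_known] = np.minimum(yv, f)
        p = _fill_and_diff(yv_full, v_known, 0.0, f) / f
        yj_full = np.zeros(L - 1)
        yj_full[j_known] = np.minimum(yj, f)
        q = -_fill_and_diff(yj_full, j_known, f, 0.0) / f
        for vec in (p, q):
            vec[vec < opts.min_usage] = 0.0
        p = p / p.sum() if p.sum() > 0 else np.full(K, 1.0 / K)
        q = q / q.sum() if q.sum() > 0 else np.full(L, 1.0 / L)

    # weighted RSS of the refit forward model on the bins used
    curve = DeletionCurve.from_locus(locus, p, q)
    f_clip = float(np.clip(f, 0.0, cmax))
    model = expected_log2_rdr(f_clip, curve, ctx, mid, alleles_deleted=a) if not zero \
        else np.zeros_like(mid)
    objective = float(np.sum(w * (rdr - model) ** 2))

    # bootstrap: resample bins within pools
    ci_lo = ci_hi = f_clip
    if opts.n_bootstrap > 0:
        rng = np.random.default_rng(opts.bootstrap_seed)
        order = np.argsort(pool_idx, kind="stable")
        sorted_pools = pool_idx[order]
        starts = np.searchsorted(sorted_pools, np.arange(n_pools), side="left")
        ends = np.searchsorted(sorted_pools, np.arange(n_pools), side="right")
        fb = np.empty(opts.n_bootstrap)
        for b in range(opts.n_bootstrap):
            take = np.concatenate([
                rng.choice(order[s:e], size=e - s, replace=True)
                for s, e in zip(starts, ends) if e > s
            ])
            try:
                fb[b], *_ = _pool_fit(d[take], w[take], pool_idx[take],
                                      n_vpool, n_pools, cmax)
            except FitError:
                fb[b] = np.nan
        fb = fb[np.isfinite(fb)]
        if len(fb):
            ci_lo = float(min(np.quantile(fb, 0.025), f_clip))
            ci_hi = float(max(np.quantile(fb, 0.975), f_clip))

    return VDJFit(locus=locus.locus, fraction=f_clip,
                  v_usage=dict(zip(names_v, p)), j_usage=dict(zip(names_j, q)),
                  ci_lower=ci_lo, ci_upper=ci_hi, objective=objective,
                  n_bins_used=n_bins, converged=True, zero_fraction=bool(zero),
                  context=ctx)


def adjust_reported_fraction(fit: VDJFit, ctx: PurityCNContext,
                             denominator: str = "all_cells") -> float:
    """Re-express the fitted fraction against a chosen cell denominator.

    ``all_cells`` reports the fraction of all cells in the sample (the scale
    the fit operates on); ``nontumor_cells`` rescales by 1/(1 - purity).
    """
    if not fit.converged:
        raise FitError("cannot adjust an unconverged fit")
    if denominator == "all_cells":
        return fit.fraction
    if denominator == "nontumor_cells":
        if ctx.purity >= 1.0:
            raise FitError("nontumor_cells denominator undefined at purity 1")
        return fit.fraction / (1.0 - ctx.purity)
    raise FitError(f"unknown denominator {denominator!r}")
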