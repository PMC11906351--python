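"""IGH class-switch decomposition and germline copy-number calling.

Class-switch recombination (CSR) deletes, on one allele, the constant genes
between the switch mu region and the switch region of the expressed isotype.
A position in the constant-region block of switch rank r is therefore absent
from B cells that switched to any class with rank > r:

    S(r) = sum of pi_c over classes c with rank(c) > rank(r),
    CN(block r) = C_flank - a_cs * f_B * S(r),   a_cs = 1 (single allele).

S is non-increasing along switch order by construction, so the isotype mix
pi is recovered from an isotonic fit of the per-block plug-in values, and
class proportions are the decrements across switch boundaries.

Inherited CNVs are common across the IGH constant genes; a matched-normal
caller assigns each constant block (and V-region chunk) an integer copy
number and masks non-diploid blocks before the CSR fit.
"""
from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .annotation import LocusDefinition, SegmentAnnotation
from .normalize import RatioProfile
from .vdj import FitError, PurityCNContext, VDJFit, pava

CLASS_LABELS = ("IgM/IgD", "IgG3", "IgG1", "IgA1", "IgG2", "IgG4", "IgE", "IgA2")
N_CLASSES = len(CLASS_LABELS)
SWITCH_MARGIN = 3000  # bp of switch region ahead of each constant gene (axis)
A_CS = 1.0            # alleles deleted by CSR per switched cell


class ClassSwitchError(ValueError):
    pass


def switch_blocks(locus: LocusDefinition, margin: int = SWITCH_MARGIN):
    """Axis intervals [b_r, b_{r+1}) of each switch rank's constant block."""
    consts = locus.constant_segments
    if not consts:
        raise ClassSwitchError(f"locus {locus.locus} has no constant genes")
    ranks = sorted({c.switch_order for c in consts})
    if ranks != list(range(N_CLASSES)):
        raise ClassSwitchError(f"expected switch ranks 0..{N_CLASSES - 1}, got {ranks}")
    bounds = []
    for r in range(N_CLASSES):
        genes = [c for c in consts if c.switch_order == r]
        bounds.append(min(locus.segment_axis(g)[0] for g in genes) - margin)
    end = max(locus.segment_axis(g)[1] for g in consts if g.switch_order == N_CLASSES - 1) + margin
    bounds.append(end)
    if any(b >= c for b, c in zip(bounds, bounds[1:])):
        raise ClassSwitchError("constant blocks are not ordered along the switch axis")
    names = []
    for r in range(N_CLASSES):
        genes = [c.name for c in consts if c.switch_order == r]
        names.append("+".join(genes))
    return names, np.asarray(bounds, dtype=float)


def switch_survival(props: np.ndarray | dict, gene: SegmentAnnotation | str,
                    locus: LocusDefinition | None = None) -> float:
    """Proportion of B cells whose class switch deleted constant gene ``gene``."""
    if isinstance(props, dict):
        pi = np.asarray([props[c] for c in CLASS_LABELS], dtype=float)
    else:
        pi = np.asarray(props, dtype=float)
    if len(pi) != N_CLASSES or np.any(pi < -1e-12) or abs(pi.sum() - 1.0) > 1e-8:
        raise ClassSwitchError("isotype proportions must be a simplex over the 8 classes")
    if isinstance(gene, str):
        if locus is None:
            raise ClassSwitchError("locus required to resolve a gene name")
        match = [c for c in locus.constant_segments if c.name == gene]
        if not match:
            raise ClassSwitchError(f"unknown constant gene {gene!r}")
        gene = match[0]
    if gene.kind != "CONSTANT":
        raise ClassSwitchError(f"{gene.name} is not a constant gene")
    r = gene.switch_order
    return float(pi[r + 1:].sum())


# --------------------------------------------------------------------------
# germline CNV caller
# --------------------------------------------------------------------------
@dataclass
class CNVCall:
    region: str
    axis_start: float
    axis_end: float
    copy_number: int
    margin: float       # RDR-distance gap between best and runner-up integer CN
    masked: bool
    n_bins: int


@dataclass
class GermlineCNVCalls:
    calls: list[CNVCall]
    mean_depth: float
    low_confidence: bool  # set when the normal is below the reliable depth
    missing_normal: bool = False

    def masked_blocks(self) -> set[str]:
        return {c.region for c in self.calls if c.masked}

    def by_region(self) -> dict[str, CNVCall]:
        return {c.region: c for c in self.calls}


def _cn_rep(cn: int) -> float:
    # log2(CN/2) with a floor standing in for the -inf of CN 0
    return -3.0 if cn == 0 else float(np.log2(cn / 2.0))


def call_germline_cnv(normal_profile: RatioProfile, locus: LocusDefinition,
                      max_cn: int = 4, min_depth: float = 10.0,
                      margin_threshold: float = 0.2,
                      n_v_chunks: int = 10) -> GermlineCNVCalls:
    """Integer copy number per IGH constant block and V-region chunk.

    Per region the call is the integer CN whose log2(CN/2) is closest to the
    median RDR; the margin is the gap to the runner-up. Non-diploid or
    low-margin regions are masked for class-switch fitting. Calls from
    normals below ``min_depth`` (the reliable-depth floor) carry a
    low-confidence flag.
    """
    names, bounds = switch_blocks(locus)
    regions = list(zip(names, bounds[:-1], bounds[1:]))
    lo, hi = locus.deletable_axis
    chunk_edges = np.linspace(lo, hi, n_v_chunks + 1)
    regions += [(f"V_chunk_{i + 1}", chunk_edges[i], chunk_edges[i + 1])
                for i in range(n_v_chunks)]

    reps = np.array([_cn_rep(c) for c in range(max_cn + 1)])
    calls = []
    ok = np.isfinite(normal_profile.log2_rdr)
    for name, a, b in regions:
        sel = ok & (normal_profile.axis_mid >= a) & (normal_profile.axis_mid < b)
        nb = int(sel.sum())
        if nb == 0:
            calls.append(CNVCall(name, a, b, 2, 0.0, True, 0))
            continue
        med = float(np.median(normal_profile.log2_rdr[sel]))
        dist = np.abs(med - reps)
        order = np.argsort(dist)
        cn = int(order[0])
        margin = float(dist[order[1]] - dist[order[0]])
        masked = cn != 2 or margin < margin_threshold
        calls.append(CNVCall(name, a, b, cn, margin, masked, nb))
    # key the confidence flag on the realized flank depth, with a 5% guard
    # band so nominally at-threshold samples are not flagged by sampling noise
    flank_depth = normal_profile.baseline_depth
    return GermlineCNVCalls(calls=calls, mean_depth=flank_depth,
                            low_confidence=flank_depth < 0.95 * min_depth)


# --------------------------------------------------------------------------
# class-switch fit
# --------------------------------------------------------------------------
@dataclass
class ClassSwitchFit:
    """B cell fraction decomposed into IgM/IgD and class-switched isotypes."""

    b_fraction: float
    isotype_props: dict[str, float] | None  # None when f_B too small to resolve
    igm_igd: float | None
    class_switched: float | None
    igg: float | None
    iga: float | None
    ige: float | None
    isotypes_defined: bool
    n_blocks_used: int
    qc: dict = field(default_factory=dict)

    def to_dict(self) -> dict:
        return {
            "b_fraction": self.b_fraction,
            "isotype_props": self.isotype_props,
            "igm_igd": self.igm_igd, "class_switched": self.class_switched,
            "igg": self.igg, "iga": self.iga, "ige": self.ige,
            "isotypes_defined": self.isotypes_defined,
            "qc": dict(self.qc, n_blocks_used=self.n_blocks_used),
        }


def fit_class_switch(profile: RatioProfile, vdj_fit: VDJFit, locus: LocusDefinition,
                     cnv: GermlineCNVCalls | None = None,
                     ctx: PurityCNContext | None = None,
                     min_b_fraction: float = 1e-3,
                     min_blocks: int = 3) -> ClassSwitchFit:
    """Decompose the IGH B cell fraction into isotype aggregates.

    Conditions on the VDJ-fit B cell fraction ``f_B``; per unmasked constant
    block the plug-in s(r) = C_flank * (1 - ratio) / (a_cs * f_B) estimates
    S(r), which is made non-increasing by isotonic regression before the
    class proportions are read off the switch-boundary decrements.
    """
    ctx = ctx or vdj_fit.context or PurityCNContext()
    cf = ctx.c_flank
    f_b = vdj_fit.fraction
    qc: dict = {"missing_normal": cnv is None, "f_b": f_b}
    if cnv is None:
        masked: set[str] = set()
        qc["warning"] = "no matched normal: germline CNVs not masked"
    else:
        masked = cnv.masked_blocks()
        qc["cnv_low_confidence"] = cnv.low_confidence

    if f_b < min_b_fraction:
        return ClassSwitchFit(b_fraction=f_b, isotype_props=None, igm_igd=None,
                              class_switched=None, igg=None, iga=None, ige=None,
                              isotypes_defined=False, n_blocks_used=0,
                              qc=dict(qc, reason="b_fraction below resolvable threshold"))

    names, bounds = switch_blocks(locus)
    ok = np.isfinite(profile.log2_rdr) & (profile.weight > 0)
    s_vals, s_wts, ranks = [], [], []
    for r, (name, a, b) in enumerate(zip(names, bounds[:-1], bounds[1:])):
        if name in masked:
            continue
        # constant-gene edges are not CSR breakpoints, so boundary-flagged
        # bins inside a block are fully informative here
        sel = ok & (profile.axis_mid >= a) & (profile.axis_mid < b)
        if not sel.any():
            continue
        w = profile.weight[sel]
        ratio = float(np.average(2.0 ** profile.log2_rdr[sel], weights=w))
        s_vals.append(cf * (1.0 - ratio) / (A_CS * f_b))
        s_wts.append(float(w.sum()))
        ranks.append(r)
    if len(s_vals) < min_blocks:
        raise ClassSwitchError(
            f"only {len(s_vals)} unmasked constant blocks with data (need >= {min_blocks})"
        )

    fit = pava(np.asarray(s_vals), np.asarray(s_wts), increasing=False)
    fit = np.clip(fit, 0.0, 1.0)
    # fill masked/missing ranks by nearest known neighbours (flat interpolation)
    s_full = np.interp(np.arange(N_CLASSES, dtype=float), np.asarray(ranks, dtype=float), fit)

    pi = np.empty(N_CLASSES)
    pi[0] = 1.0 - s_full[0]
    pi[1:] = -np.diff(s_full)
    pi = np.clip(pi, 0.0, None)
    # S at the last rank should be ~0; renormalise any residual mass away
    if pi.sum() <= 0:
        raise ClassSwitchError("degenerate isotype fit: no mass after clipping")
    pi = pi / pi.sum()

    props = dict(zip(CLASS_LABELS, pi))
    igm_igd = f_b * pi[0]
    igg = f_b * (props["IgG3"] + props["IgG1"] + props["IgG2"] + props["IgG4"])
    iga = f_b * (props["IgA1"] + props["IgA2"])
    ige = f_b * props["IgE"]
    qc["ige_low_confidence"] = True  # short IGHE block; treat IgE as indicative only
    return ClassSwitchFit(b_fraction=f_b, isotype_props=props,
                          igm_igd=igm_igd, class_switched=f_b - igm_igd,
                          igg=igg, iga=iga, ige=ige, isotypes_defined=True,
                          n_blocks_used=len(s_vals), qc=qc)
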