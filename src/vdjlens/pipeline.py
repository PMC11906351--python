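"""End-to-end orchestration: track -> profile -> fits -> per-sample report."""
from __future__ import annotations

import logging
from pathlib import Path

import numpy as np

from .annotation import LocusDefinition, load_locus_definition
from .class_switch import GermlineCNVCalls, call_germline_cnv, fit_class_switch
from .coverage import CoverageTrack, extract_coverage, read_coverage_table
from .normalize import RatioProfile, bin_coverage, fit_gc_model, to_ratio_profile
from .vdj import FitOptions, PurityCNContext, VDJFit, fit_vdj

logger = logging.getLogger("vdjlens")

LOW_DEPTH_X = 1.0  # below this mean depth the fit is reported but QC-failed


def profile_from_track(track: CoverageTrack, locus: LocusDefinition,
                       reference: str | Path | None = None,
                       gc: np.ndarray | None = None,
                       bin_size: int = 500) -> RatioProfile:
    """Bin, GC-correct and baseline-normalise one coverage track."""
    if gc is None and reference is None:
        # no GC source: flat placeholder, the GC model degenerates to identity
        gc = np.full(len(track), 0.5)
    binned = bin_coverage(track, locus, bin_size=bin_size, reference=reference, gc=gc)
    model = fit_gc_model(binned)
    return to_ratio_profile(binned, model, locus)


def fit_locus(track: CoverageTrack, locus: LocusDefinition,
              ctx: PurityCNContext | None = None, opts: FitOptions | None = None,
              reference: str | Path | None = None, gc: np.ndarray | None = None,
              bin_size: int = 500) -> tuple[RatioProfile, VDJFit]:
    profile = profile_from_track(track, locus, reference=reference, gc=gc, bin_size=bin_size)
    return profile, fit_vdj(profile, locus, ctx=ctx, opts=opts)


def analyze_sample(track: CoverageTrack, locus: LocusDefinition,
                   ctx: PurityCNContext | None = None,
                   opts: FitOptions | None = None,
                   normal_track: CoverageTrack | None = None,
                   reference: str | Path | None = None,
                   gc: np.ndarray | None = None,
                   normal_gc: np.ndarray | None = None,
                   bin_size: int = 500) -> dict:
    """Full per-sample, per-locus report (fraction, usage, IGH extras, QC)."""
    profile, fit = fit_locus(track, locus, ctx=ctx, opts=opts,
                             reference=reference, gc=gc, bin_size=bin_size)
    report = fit.to_dict()
    report["sample_id"] = track.sample_id
    report["qc"]["mean_depth"] = profile.mean_depth
    report["qc"]["baseline_depth"] = profile.baseline_depth
    report["qc"]["low_depth"] = profile.mean_depth < LOW_DEPTH_X
    if locus.constant_segments:
        cnv: GermlineCNVCalls | None = None
        if normal_track is not None:
            normal_profile = profile_from_track(normal_track, locus, reference=reference,
                                                gc=normal_gc, bin_size=bin_size)
            cnv = call_germline_cnv(normal_profile, locus)
            report["germline_cnv"] = [
                {"region": c.region, "cn": c.copy_number, "margin": c.margin,
                 "masked": c.masked} for c in cnv.calls
            ]
            report["qc"]["cnv_low_confidence"] = cnv.low_confidence
        cs = fit_class_switch(profile, fit, locus, cnv=cnv, ctx=ctx)
        report["class_switch"] = cs.to_dict()
    return report


def run_pipeline(config: dict, out_dir: str | Path) -> dict:
    """Run the extract -> normalise -> fit -> report pipeline for a config.

    Config schema (YAML-friendly): top-level ``samples`` list, each with
    ``id``, one of ``bam``/``coverage`` (coverage may be a {locus: path}
    mapping), optional ``purity``, ``local_cn`` ({locus: value}), optional
    ``normal_coverage`` for IGH CNV masking; top-level ``loci`` list,
    optional ``reference``, ``annotation``, ``bin_size``, ``seed``.
    Per-sample failures are isolated and collected in the summary.
    """
    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    loci_names = config.get("loci", ["TCRA", "TCRB", "TCRG", "IGH"])
    annotation = config.get("annotation", "packaged")
    reference = config.get("reference")
    bin_size = int(config.get("bin_size", 500))
    opts = FitOptions(bootstrap_seed=int(config.get("seed", 1234)),
                      n_bootstrap=int(config.get("bootstrap", 200)))
    loci = {name: load_locus_definition(name, annotation) for name in loci_names}
    logger.info("pipeline: %d samples x %s (bin %d bp, seed %d)",
                len(config.get("samples", [])), loci_names, bin_size, opts.bootstrap_seed)

    summary: dict = {"reports": [], "errors": []}
    for sample in config.get("samples", []):
        sid = sample.get("id", "sample")
        for name, locus in loci.items():
            try:
                if sample.get("tumor") and sample.get("purity") is None:
                    raise ValueError(f"sample {sid}: tumor mode requires a purity estimate")
                ctx = PurityCNContext(
                    purity=float(sample.get("purity", 0.0)),
                    tumor_cn=float((sample.get("local_cn") or {}).get(name, 2.0))
                    if isinstance(sample.get("local_cn"), dict)
                    else float(sample.get("local_cn", 2.0)),
                )
                track = _load_track(sample, name, locus, reference)
                gc = None
                if sample.get("gc_track"):
                    from .normalize import read_gc_table
                    gc = read_gc_table(_per_locus(sample["gc_track"], name))
                normal_track = None
                if locus.constant_segments and sample.get("normal_coverage"):
                    normal_track = read_coverage_table(_per_locus(sample["normal_coverage"], name),
                                                       locus=name, sample_id=f"{sid}_normal")
                report = analyze_sample(track, locus, ctx=ctx, opts=opts,
                                        normal_track=normal_track, gc=gc,
                                        normal_gc=gc,
                                        reference=reference, bin_size=bin_size)
                report["sample_id"] = sid
                summary["reports"].append(report)
            except Exception as exc:
                logger.error("sample %s locus %s failed: %s", sid, name, exc)
                summary["errors"].append({"sample_id": sid, "locus": name, "error": str(exc)})
    import json

    (out_dir / "report.json").write_text(json.dumps(summary, indent=1, default=float))
    _write_flat_tsv(summary, out_dir / "report.tsv")
    return summary


def _per_locus(entry, name: str):
    return entry[name] if isinstance(entry, dict) else entry


def _load_track(sample: dict, name: str, locus: LocusDefinition, reference):
    if "bam" in sample:
        return extract_coverage(sample["bam"], locus, reference=reference,
                                sample_id=sample.get("id"))
    if "coverage" in sample:
        return read_coverage_table(_per_locus(sample["coverage"], name),
                                   locus=name, sample_id=sample.get("id"))
    raise ValueError(f"sample {sample.get('id')}: needs 'bam' or 'coverage'")


def _write_flat_tsv(summary: dict, path: Path) -> None:
    cols = ["sample_id", "locus", "fraction", "ci_lower", "ci_upper", "mean_depth",
            "zero_fraction", "igm_igd", "class_switched", "igg", "iga", "ige"]
    with open(path, "w") as fh:
        fh.write("\t".join(cols) + "\n")
        for r in summary["reports"]:
            cs = r.get("class_switch", {})
            row = [r["sample_id"], r["locus"], r["fraction"], r["ci"][0], r["ci"][1],
                   r["qc"]["mean_depth"], r["qc"]["zero_fraction"],
                   cs.get("igm_igd"), cs.get("class_switched"), cs.get("igg"),
                   cs.get("iga"), cs.get("ige")]
            fh.write("\t".join("" if x is None else str(x) for x in row) + "\n")
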