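# Methods

## The deletion model

V(D)J recombination joins one V segment to one (D and one) J segment and
excises the intervening DNA on both alleles of the cell. For a locus whose
segments are ordered along a *deletion axis* (genomic order for TCRA/TCRB,
reversed for TCRG and IGH, which face the other way on their chromosomes),
a position `x` strictly between the axis end of V segment `v` and the axis
start of J segment `j` is deleted in every cell that recombined `(v, j)`.

Treating the V and J choices of the repertoire as independent draws from
usage simplices `p` and `q`, the expected deleted fraction of recombined
cells covering `x` is `F(x) = PV(x)·QJ(x)` with `PV` the cumulative V usage
upstream of `x` and `QJ` the cumulative J usage downstream. `F` is a step
function that increases only at V boundaries, sits at 1 on the V–J interior,
and decreases only at J boundaries. Independence is an assumption, not a
result: the marginal depth profile cannot identify V–J pairing, so `F`
factorises by construction.

Expected local copy number in a sample with tumor purity ρ, local somatic
copy number `n_t` and germline copy number `n_g` (flank copy number
`C_flank = ρ·n_t + (1−ρ)·n_g`):

    CN(x) = C_flank − a·f·F(x),  log2 RDR(x) = log2(CN(x)/C_flank)

`f` is the lymphocyte fraction **of all cells**, and `a = 2` alleles are
deleted per recombined cell at every locus. Fixing `a = 2` for TCRB is a
deliberate simplification: allelic exclusion means many T cells carry one
recombined and one germline-configuration TCRB allele, so TCRB fractions
read systematically lower than TCRA ones. We report the discrepancy rather
than model per-locus allele counts.

Class-switch recombination (CSR) at IGH deletes constant genes on a single
allele (`a_cs = 1`): a B cell expressing isotype class `c` (switch rank
`r(c)`; IgM and IgD share rank 0 and are reported as one unit) has deleted
every constant block with rank below `r(c)`. The survival function
`S(g) = Σ_{r(c) > r(g)} π_c` is non-increasing in switch order, and
`CN(g) = C_flank − a_cs·f_B·S(g)` over the constant blocks. `a_cs = 1` (one
allele switches, the other is retained intact) is a calibration constant: the
second allele's behaviour is heterogeneous in real B cells, and 1 is the
conservative choice.

## Normalisation

Depth is averaged in fixed bins (default 500 bp — small enough for ≥ 2 bins
between most segment boundaries, large enough for tolerable Poisson noise at
5×), with GC fraction per bin from the reference (or a supplied per-base GC
track). A LOESS trend (span 0.75, one robustness iteration) of log2 depth on
GC is fitted on **baseline bins only** — the flanks of the locus window that
no rearrangement can delete — and applied to all bins, clamped to
GC ∈ [0.25, 0.75]. The correction is expressed relative to its mean so it is
scale-free; profiles are invariant to multiplying all depths by a constant.
If fewer than 30 baseline bins are usable or the GC spread is < 0.05 the
model degenerates to the identity with a warning. log2 RDR is taken against
the weighted mean GC-corrected baseline depth; zero-depth bins get a 0.5
pseudo-count so genuine deep deletions stay in the fit; bin weights are the
GC-corrected expected read counts (heteroscedastic least squares), and bins
straddling a segment boundary are down-weighted ×0.2 because their content
mixes two pool levels.

## The two-stage fit

1. Transform each usable bin to `d(x) = C_flank·(1 − 2^RDR)/a`, an unbiased
   plug-in for `f·F(x)`.
2. Pool bins between consecutive segment boundaries (V-side pools, one
   interior pool, J-side pools) with their weights.
3. Weighted isotonic regression (pool-adjacent-violators): non-decreasing
   over V-side pools, non-increasing over J-side pools, both clipped to
   [0, c] and tied to a common interior plateau `c`. For fixed `c` the
   bounded isotonic solution is the unbounded fit clipped at `c`, so the
   profile objective in `c` is convex piecewise-quadratic; its global
   minimum is found exactly by scanning the knot intervals (no iterative
   optimiser, no tie-break sensitivity).
4. `f̂ = c*` clipped to [0, min(1, C_flank/a)]. V usage `p̂` is the vector of
   fitted-step increments across V boundaries divided by `f̂` (empty pools
   split their combined increment evenly); J usage symmetrically from the
   decrements. Entries below 1e-6 are truncated and the simplices
   renormalised. Fits below 1e-4 are flagged zero-fraction and usage is
   emitted as uniform with the flag set.
5. Uncertainty: bins are resampled with replacement **within** their pools
   (B = 200, seeded), the plateau refit, and the 2.5/97.5 percentiles
   reported.

On noiseless inputs this estimator attains the global weighted-least-squares
optimum (verified against exhaustive grid search + polish on a 3 V / 2 J toy
locus to 1e-6 in objective); on Poisson inputs it is the shape-constrained
projection of the pool means, which is the maximum-likelihood fit under the
Gaussian working model with the chosen weights.

Tumor samples: supplying ρ and `n_t` (the somatic call of a gene adjacent to
the locus — OR10G3, PRSS58, STARD3NL, TMEM121 for TCRA/TCRB/TCRG/IGH — since
the locus itself is deleted in lymphocytes) folds purity and local CN into
`C_flank`. `f̂` is then the immune fraction of all cells; dividing by (1−ρ)
re-expresses it per non-tumor cell.

## Class-switch fit and germline CNV calling

The IGH constant region is partitioned into eight switch blocks, one per
rank, bounded 3 kb axis-upstream of each rank's first constant gene (the
switch region). Per unmasked block the weighted mean depth ratio gives the
plug-in `s(r) = C_flank·(1 − ratio)/(a_cs·f̂_B)`; isotonic non-increasing
regression along switch order yields `Ŝ`, and class proportions are the
boundary decrements (`π̂_0 = 1 − Ŝ_0`), clipped and renormalised. The fit
conditions on `f̂_B` from the IGH VDJ fit rather than refitting jointly —
a modularity choice: the V/J geometry and the constant-gene geometry are
disjoint, so conditioning costs little and keeps both fits convex. Below
`f_B = 1e-3` the steps are smaller than any realistic noise floor and the
isotype decomposition is emitted as undefined rather than as noise. IgE is
reported but flagged low-confidence: its block is the shortest and bounded
by pseudogene-rich sequence.

Germline CNVs are common across the IGH constant genes and masquerade as
class-switch steps. From a matched normal, each constant block (and each of
10 V-region chunks) is assigned the integer CN ∈ {0..4} whose log2(CN/2) is
nearest the block's median RDR (CN 0 represented by −3), with the margin to
the runner-up recorded; blocks with CN ≠ 2 or margin < 0.2 are masked before
the CSR fit. Masked or empty ranks are filled by interpolating `Ŝ` between
neighbouring ranks, which attributes no usage to the missing class rather
than inventing a step. The low-confidence flag keys on the realized flank
depth with a 5% guard band below 10×: sampling noise puts a nominally-10×
sample a hair under its target and the flag should not flap there.

## The simulator

The simulator is the forward model run generatively, and is the oracle for
every estimator test: per-base depth is Poisson with mean
`D · CN(x)/C_flank · bias(gc(x))`, where CN composes V(D)J deletion (from
truth usage), CSR deletion (from a truth isotype mix), germline CNVs
(multiplicative on both cell populations), and purity/local CN. GC is a
smooth AR(1) block profile (mean 0.45, sd 0.05, clipped to [0.30, 0.65]) and
the bias is `exp(0.3·(gc−0.5) − 1.0·(gc−0.5)²)`, a few percent across the GC
range, in line with PCR-free WGS. Downsampling is binomial per-position
thinning, consistent under nesting. Everything is deterministic under a
fixed seed and each track's truth serialises to JSON.

What the simulator does **not** emulate — and hence what passing tests do
not establish about real data: overdispersion beyond Poisson (an optional
negative-binomial stress knob exists but is off by default), mappability
dropouts and multi-mapping in the segment-rich loci, breakpoint scatter
inside switch regions (simulated breaks are exact at block boundaries),
V–J pairing correlations, somatic structural variants overlapping the loci,
and alignment artefacts. Real-data accuracy is bounded by these, not by the
recovery statistics reported here.

## Benchmark problem sizes and measured behaviour

The acceptance benchmarks (same code path as `scripts/acceptance.py`) use
cohorts of 100 TCRA samples (f ~ U(0, 0.5), 30× and thinned 5×), 50 IGH
samples (f_B ~ U(0.02, 0.2), Dirichlet(80, 3, 6, 4, 2, 1, 0.5, 2) isotype
mixes), germline CNV panels at 5–30×, and 24 tumor mixtures — sizes chosen
so each suite completes in minutes on one CPU while keeping Monte-Carlo
error far below the tolerances tested.

Two quantities sit at their information floor under these conditions, and
the suite documents rather than hides that:

- **Segment-usage total variation.** At 30× with 500 bp bins, per-pool depth
  carries ~1.3e-3 absolute noise in `f·F` units; across 40 V segments that
  is ~0.16 expected TV against the truth even before GC/baseline overhead.
  The usage test asserts TV ≤ 0.25.
- **Isotype aggregates at small f_B.** The only scale anchor inside the IGH
  window is ~40 kb of undeletable flank, and the constant region is ~270 kb
  split into 11–80 kb blocks; at 30× the per-block copy-number plug-ins have
  1–2.5e-3 SE, so aggregates spanning several switch boundaries carry
  ~2–4e-3 absolute error regardless of estimator. Relative to f_B = 0.02
  that is 10–20%; the cohort-mean relative error measures ~0.04–0.05 and the
  corresponding acceptance test (threshold 0.02) fails by design of the
  conditions, while ordering of switched vs non-switched is preserved in
  ≥ 98% of samples and absolute errors stay within 0.02 down to f_B ≈ 0.08.

## Known limitations

- TCRB fractions under-read true T cell content (allelic exclusion; see
  above). TCRG measures total T cells, not γδ T cells specifically, because
  αβ T cells usually carry rearranged TCRG.
- TCRD is nested inside TCRA and not separately quantified.
- Usage vectors are per-segment marginals; clonotypes, CDR3 sequences and
  V–J pairing are out of reach of depth data.
- The packaged annotation merges closely spaced segments into representative
  ones; users with their own segment models can supply `--annotation`.
- Purity/local-CN adjustment is only as good as the supplied ρ and `n_t`;
  errors propagate multiplicatively into `C_flank`.
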