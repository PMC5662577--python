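# Methods

This note documents the model behind `dopplervi`, the numerical choices
made where the procedure left freedom, and what the synthetic fixtures
do and do not establish about real data.

## The measurement model

A color Doppler still frame is an 8-bit RGB raster in which grey-scale
tissue satisfies R = G = B exactly (lossless export) and blood flow is
overlaid in saturated red/blue map colors. The *vascular index* of a
pixel region is the percentage of its pixels whose channel spread
`max(R,G,B) − min(R,G,B)` exceeds a threshold τ. τ defaults to 0: the
literal complement of "grey-scale" is any pixel with unequal channels.
For material that has passed through a lossy pipeline at some point, τ
of 10–20 absorbs chroma noise; exact-match outline recovery is
impossible on such material anyway, which is why the readers reject
lossy containers outright rather than guess.

The nodule (primary ROI) is recovered from a hand-drawn outline in one
exact RGB color, default pure green (0, 255, 0) — unused by both the
grey background and the red/blue Doppler maps. Interior recovery flood
fills the background from all border pixels (4-connectivity) with
outline pixels as barriers; the interior is whatever is neither outline
nor background, with enclosed background islands filled, because the
nodule is modelled as a solid, simply connected region and the VI is
defined over its whole area. Outline pixels are excluded from the ROI.
This construction is insensitive to outline thickness and concavity.

## Regional subdivision by inward offsetting

The offset distance is a percentage *n* of the ROI's maximum Feret
diameter *D* (the greatest center-to-center pixel distance, computed on
the convex hull): `offset_px = round(n/100 · D)` with half-up rounding.
Taken literally, a 25% offset on a disc halves its diameter — the
central region is then the inner 50% of the diameter, not the "inner
90%" sometimes quoted for qualitative grading; the percentage-of-diameter
definition is the one implemented.

Two offsetting modes produce the central region:

* **distance** — threshold of the exact Euclidean distance transform
  (`EDT > offset_px`). This is exact inward-offset geometry and serves
  as the reference mode; the phantom generator uses it for ground
  truth.
* **erosion** (default) — iterative binary erosion with 3×3 elements,
  the classical raster realization of contour-preserving shrinking.
  Pure cross (city-block) or pure square (Chebyshev) erosion is
  anisotropic: their unit balls reach 0.707 px and 1.414 px per step
  along diagonals. The implementation mixes them, with square steps at
  fraction √2 − 1 of iterations, which equalizes the axis and diagonal
  depths; the residual bulge of the composite octagon peaks at 22.5°,
  and its **angular mean** depth per step is
  (4/π)(sin π/4 + (√2 − 1)(1 − cos π/4)) ≈ 1.0548 px. The step count is
  therefore `round(offset_px / 1.0548)`, which removes the requested
  Euclidean depth on average over boundary orientations with about ±5%
  angular ripple. Both constants are closed-form geometry, not fitted.
  Measured against the distance mode on discs and low-harmonic blobs,
  the two central regions overlap with Jaccard ≥ 0.95 at offsets
  5–25% (the test suite asserts ≥ 0.90), and they coincide at offset 0.
  The square-step schedule is a fixed prefix sequence, so central area
  is monotone non-increasing in the offset level.

The peripheral region is the set difference; by construction the two
regions tile the primary ROI exactly, so regional color counts add up
to the overall count and the overall VI is the area-weighted mean of
the regional VIs — an identity the tests check to machine precision.
An empty central region (offset beyond the inradius) is legal; its VI
is reported as *missing*, never 0, to avoid biasing cohort statistics,
and the conjunctive classifier conservatively calls such records benign.

## Cohort statistics

Between-group VI comparisons use the two-sample t test computed from
group summaries. The default is the **Welch** variant
(Welch–Satterthwaite df): group SDs of the reference cohort differ by
up to 35% between groups with n = 84 vs 27, where the pooled test is
anti-conservative; the pooled variant is available by flag. Degenerate
zero-variance pairs with equal means return p = 1 by convention. The
optimum offset is the smallest level at which *both* regional tests
give p < α (α = 0.05 two-tailed), scanned over the 5%-interval coarse
grid plus unit refinement (5, 10, 15, 20, 21, 22, 23, 24, 25); a
two-stage utility (`refine_offset_search`) automates
coarse-then-refine on arbitrary data. No multiple-testing correction is
applied across the nine (strongly correlated) offset levels — the
search mirrors the original screening protocol, and a corrected variant
would need a joint model the summaries cannot support.

ROC cut-offs maximize the Youden index under the decision rule
"positive iff score ≥ cutoff", with candidates at the observed scores
and ties resolved toward the lower cutoff. The published cut-offs
(19.7 / 9.1 / 20.2 for peripheral / central / overall VI at the 22%
offset) ship as classifier defaults, clearly study-derived; the
optimality criterion behind them is not recorded in the source, so they
are treated as fixed inputs, not reproduction targets. Diagnostic
metrics are kept at full precision internally and rendered with decimal
half-up rounding to 1 decimal, the convention of clinical tables;
`counts_from_rates` inverts published (sensitivity, specificity) pairs
to integer confusion counts the same way, which closes the arithmetic
loop on the published performance tables exactly.

On the reference summary table, the recomputed Welch pattern makes 22%
the unique qualifying offset. Two printed quirks are handled
deliberately: the 23%-offset row's four cells are printed in a
different order from every other row and are mapped to the common
column order (under which the row is consistent with its neighbours),
and the printed significance marks of the 23%/24% rows do not follow
from those rows' own means/SDs under either t variant — the package
asserts the recomputed pattern, which leaves the headline selection
unchanged.

## Synthetic data: what it emulates, what it does not

**Phantoms.** A blob (disc with low-order radial harmonics, defaults
r = 60 px with 10%/6% amplitude at k = 2, 3 — gently lobed like
hand-drawn nodule contours) is filled with Rayleigh-envelope grey
speckle on a darker speckle background, partitioned at the generating
offset in distance mode, painted with Doppler-palette pixels by
independent Bernoulli draws at the target densities per region
(defaults 30% peripheral / 10% central at the 22% offset — a
hypervascular-rim pattern), and outlined in the annotation color. The
generator returns every piece of ground truth, so the pipeline can be
checked end-to-end: ROI recovery is pixel-exact, color counts are
integer-exact at τ = 0, and measured VIs match targets within Bernoulli
error (±2 pp is guaranteed with margin for regions ≥ 1000 px). Phantoms
contain no transducer physics — no point-spread function, attenuation,
aliasing, or burned-in overlays — so passing tests validate the
*arithmetic and geometry* of the pipeline, not robustness to scanner
artifacts; real images with color bars or captions must be cropped
before analysis.

**Cohorts.** Per-nodule VI records are sampled from normals truncated
to [0, 100], with the reference per-offset group means/SDs as defaults,
and GSU features as independent Bernoullis at the group prevalences.
All of a nodule's VI values share a latent factor (correlation
ρ = 0.7, configurable): independent values across offsets would be
physiologically absurd and would break representative-frame logic. The
joint distribution of regional VIs and GSU features in real nodules is
not recoverable from group summaries, so only marginals (plus this one
correlation) are emulated; rule accuracies measured on synthetic
cohorts are therefore qualitative, not calibrated. Truncation is by
resampling rather than clipping; note that truncating e.g.
N(11.9, 15.1²) at 0 still raises the realised mean by about +5, so
sampled group means are *not* unbiased estimates of the nominal means
for distributions with mass below 0 — tests of the sampler's
faithfulness use parameters far from the bounds.

**A negative result worth knowing.** Re-running the optimum-offset
search on cohorts resampled from the reference summaries recovers 22%
as the selected offset only in a minority of replicates (≈ 12/100; 22%
is *among* the qualifying offsets in ≈ 37/100). This is not an
implementation defect: the population Welch p-values at 22% are
0.023–0.026, i.e. the design re-detects its own effects with only
~60% power per region, and neighbouring offsets carry nearly identical
central effects, so sampling noise frequently promotes a smaller
offset (the search returns the smallest qualifying level). The
corresponding acceptance test states the majority bar and fails
honestly; the unit-level selection from the summaries themselves is
exact and stable.

## Defaults at a glance

| parameter | default | meaning |
| --- | --- | --- |
| annotation color | (0, 255, 0) | exact-match outline color |
| τ | 0 | channel-spread threshold for "color" |
| offset grid | 5, 10, 15, 20, 21, 22, 23, 24, 25 % | levels scanned by the search |
| VI offset | 22 % | level used for profiling/classification |
| offset mode | erosion | distance mode available as exact reference |
| t variant | welch | pooled available |
| α | 0.05 | two-tailed significance level |
| cut-offs | 19.7 / 9.1 / 20.2 % | peripheral / central / overall, study-derived |
| ρ | 0.7 | latent cross-offset VI correlation in simulation |

## Known limitations

* Exact-color outline matching requires lossless input end to end.
* No DICOM, no automatic segmentation, no velocity/direction decoding,
  no per-histology subtyping, no AUC confidence intervals.
* The erosion mode's ±5% angular ripple means its central region is not
  bit-identical to exact offset geometry; use distance mode when exact
  geometry matters.
* Study-derived cut-offs and summaries are scanner- and
  population-specific; re-derive them before clinical use elsewhere.
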