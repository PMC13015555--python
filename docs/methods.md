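# Methods

This note documents the models, estimators, numerical choices and known
limitations behind `mucosa`. It is written for users who want to know
*why* the package computes what it computes, and what the synthetic-data
tests do and do not establish about real data.

## Serology

**Thresholding.** Seropositivity cutoffs are set by ROC analysis of
background-corrected ODs with ulcerative colitis (UC) donors as the
positive class. The ROC sweeps every observed OD plus sentinels below
the minimum and above the maximum, under the rule *positive iff
OD >= threshold* (a sample on the dashed threshold line is positive).
AUC is the trapezoid area of this sweep, which equals the pairwise
probability that a UC OD exceeds a healthy-subject (HS) OD with ties
counted 1/2; the test suite asserts this equality exactly on random
cohorts. The working threshold maximises Youden's J = sensitivity +
specificity − 1; ties are broken toward the lowest threshold because a
screening biomarker should prefer sensitivity, and because it makes the
choice deterministic.

**Quantification.** Antibody levels in monoclonal-equivalent binding
units come from a four-parameter logistic (4PL) calibration,
`od = lower + (upper − lower) / (1 + (conc/inflection)^(−hill))`, fit by
least squares (`scipy.optimize.curve_fit`) to >= 5 standard
concentrations spanning >= 2 logs. The inverse 4PL interpolates unknown
ODs. The lower limit of quantification (LLOQ) is the lowest standard
whose fitted OD exceeds blank mean + 3 blank SD when blanks are
supplied, else the lowest standard; ODs below OD(LLOQ) are flagged
`below_lloq` and carry no concentration, and ODs above the calibrated
range are clamped to the highest standard with an `above_range` flag
rather than extrapolated, because the inverse 4PL is undefined beyond
the upper asymptote.

**Statistics plumbing.** Spearman correlation uses mid-ranks for ties;
its two-sided p-value is an exact permutation tail for n <= 10 (all n!
pairings, enumerated in chunks) and the t-approximation with n − 2 df
otherwise. Multiple-testing correction is the two-stage
Benjamini–Krieger–Yekutieli step-up (statsmodels `fdr_tsbky`),
cross-checked in the tests against an independent hand-coded
implementation of the two-stage procedure. Note a consequence of the
published procedure: with a single p-value and no rejection the
"adjusted" value is p·(1 + alpha), not p, because stage 1 runs at level
alpha/(1 + alpha).

**Rounding.** Reported percentages are rounded half-away-from-zero to
one decimal (173/194 → 89.2, 39/338 → 11.5).

## Adhesion and reporter assays

Wells are normalised per plate to the mean of that plate's untreated
wells. Percent inhibition of a serum is
`(1 − sample mean adherence / HS mean adherence) × 100`, where the HS
reference pools all HS serum wells *on the same plate* (same-plate
pooling controls batch effects; the replicate unit is the well, the
finest observable unit). Each serum is tested with a one-sided Welch t
test (Satterthwaite df) against the HS wells, alternative fixed as
*sample adherence below the HS mean* — blocking can only reduce
adherence. A serum is called inhibitory iff percent inhibition >= 30
and p <= 0.05, both boundaries inclusive. Reporter (SEAP OD620) assays
are summarised per sample as the ratio to the mean of per-sample HS
means, so HS ratios average to exactly 1. Dilution series report percent
inhibition per fold-dilution and flag (not reject) inhibition that
*increases* with dilution beyond 5 percentage points.

`exact_permutation_p` provides an exhaustive studentised permutation
companion to the Welch test: all C(n1+n2, n1) relabelings, Welch t as
the statistic, and a leave-observed-out mid-p (ties counted 1/2). With
3+3 replicates this distribution has only 20 atoms (granularity 0.05),
so agreement with a continuous parametric p to within 0.02 is only a
meaningful requirement where both tests sit in the far tail; the
package checks that agreement in the strong-separation regime
(adherence ratio 0.5, replicate CV 5%), and documents that at CV 10%
the small-df Welch approximation deviates from the exact tail by up to
~0.04 on unlucky variance draws — a property of the Welch
approximation at df ≈ 2, not of either implementation.

## Epithelial lineage signatures

Expression is a genes × samples matrix of log2(normalised counts + 1)
(pseudocount 1). Genes are Z-scored across samples with the sample SD
(n − 1 denominator; stated exactly so tests can be exact); zero-variance
genes become all-zero rows and are flagged. The signature score of a
marker set for a sample is the mean Z over the set's genes present in
the matrix; absent markers are dropped, never imputed, and the count
used is recorded. Group summaries are arithmetic means per treatment.
Default gene filter: expression > 1 (log2) in >= 20% of samples.

A rank-based scorer is provided as a clearly labelled stand-in for
published single-sample enrichment methods: genes are mid-ranked within
each sample and the set's mean rank is rescaled to [−1, 1]; it is
invariant to any within-sample monotone transform. It is *not* GSVA and
is not presented as such.

Because the gene-wise Z denominator absorbs between-arm variance, a
planted 1-SD shift appears as a score difference of roughly 0.6–0.8 Z
units, not 1.0; the direction-recovery tests therefore assert signs and
calibrated magnitudes, not raw effect equality.

## Digital unrolling of swiss rolls

**Model.** A swiss roll wound from a strip of near-constant thickness is
close to an Archimedean spiral, r = a + b·θ about the roll center; the
package fixes this family. θ is the total winding angle (monotone along
the strip), `b` the pitch per radian (layer-to-layer spacing 2πb), and
the tissue occupies a band of local half-thickness h(θ) about the
centerline.

**Fitting.** The fit must solve a joint assignment problem: each cell's
observed angle is only known mod 2π, and the turn number, center, and
pitch depend on each other.

1. *Candidate search.* For a candidate (center, pitch, chirality) the
   wrapped residuals u = r − b·φ (mod 2πb) of all cells collapse the
   turns onto one circle. Only near the true configuration do the
   layers align and expose the physical inter-layer gap as a *strictly
   empty* arc; the search therefore maximises the longest empty arc,
   measured in µm so pitches of different magnitude compare fairly.
   Because a ~100 µm center error (typical for a centroid start when
   the outer turn is partial) closes the gap entirely, the search is a
   joint coarse grid over center offsets (±200 µm), pitch, and both
   chiralities, evaluated on a fixed random subsample of cells.
   Among near-maximal pitches the smallest wins, since integer
   multiples of the true pitch reproduce the same absolute gap.
2. *Polish.* Nelder–Mead refines (center, pitch) on a graded density-
   deficit score (smooth where the strict gap is flat), followed by a
   pitch re-scan at the refined center.
3. *Assignment and least squares.* Turn numbers k = round((r − a −
   b·φ)/2πb) give each cell a monotone θ = φ + 2πk; (center, a, b) are
   refined by Levenberg–Marquardt with θ tracked continuously as the
   center moves, re-assigning k between passes.
4. *Band midline.* A least-squares line through cells tracks the
   *density* centroid, which tilts whenever cell-type composition
   across the crypt–lumen depth drifts along the colon (e.g. surface
   goblet cells confined to the distal colon). The centerline is
   therefore re-anchored on the geometric band midline: per 0.5-rad
   window, the midpoint of the 0.1–99.9% radial-residual spread, with
   (a, b) refit through those midpoints. Near-extreme quantiles track
   the band edges without re-importing interior density structure;
   outright min/max would be fragile to stray cells.

Half-thickness per window is half the 2.5–97.5% residual spread
(robust to outliers), floored at a tiny positive value so degenerate
zero-thickness input stays defined. Degeneracies raise errors: points
on a circle (no pitch), fewer than one full turn, or no detectable
inter-layer gap.

**Orientation.** The rolling protocol (distal end rolled first) puts
the distal colon at the inner terminus; `s` is reported 0 = proximal to
1 = distal, configurable. Which radial side is luminal is inferred from
a declared anchor cluster that is known to sit serosally (default:
smooth muscle — the lumen is the opposite side), overridable.

**Coordinates.** s is normalised arc length, integrated numerically on
a dense θ grid (trapezoid; agrees with the closed-form Archimedean arc
length to well under 0.1%). d = 0.5 + Δr·sign/(2h(θ)), clipped to
[0, 1]; cells outside the fitted angular range are flagged and excluded
from profiles, cells beyond the band are flagged but kept clipped.

**Composition and comparison.** Cluster frequencies are computed in
equal-width half-open bins of s per genotype (boundary cells go to the
upper bin; s = 1 to the last). Genotype comparison reports
log2((f_ko + ε)/(f_ctrl + ε)) with ε = 1/(cells in the bin pair), and a
percentile bootstrap CI that resamples cells with replacement within
each (genotype, bin) — implemented as a multinomial resample of cluster
counts, which is equivalent because cells are exchangeable given their
label, and seeded for bit-identical reruns. Multi-sample experiments
fit one spiral per section and normalise s per sample before pooling,
since section geometry is sample-specific.

## Synthetic data

The generators emulate the structure of each input kind with known
ground truth; they are declared stand-ins, with no claim that their
parameters match any real dataset's distributions. All are pure
functions of their spec, including the seed.

* **Serology**: log-normal OD mixtures (ODs are positive and
  right-skewed); cohort structure fixed at 338 HS / 194 UC with
  positive fractions 0.892 / 0.115. Default null median OD 0.08
  (log-SD 0.45), positive median 0.9 (log-SD 0.5).
* **Adhesion**: one plate per serum with 3 untreated wells, 3 HS serum
  wells at adherence 1 ± CV and 3 test wells at ratio ± CV;
  defaults 29 sera, 10 true inhibitors at ratio 0.5, CV 10%.
* **Expression**: baseline standard-normal log2 values; marker sets of
  disjoint genes shifted per treatment, defaults −1 SD
  (goblet/absorptive) under TGF-beta, +1 SD under integrin blockade,
  with stem markers moving oppositely at ±0.5 SD; 3 samples/arm.
* **Swiss roll**: spiral a = 400 µm, b = 110 µm/rad (pitch ≈ 691 µm),
  inner terminus at θ = 2π, half-thickness 250 µm (band 500 µm, gap
  ≈ 191 µm — a loosely wound roll), 60 mm colon at 400 cells/mm,
  2 sections per genotype. Cells are placed uniformly within their
  cluster's (s, d) rectangle, mapped onto the spiral and jittered
  radially (Gaussian, SD 20 µm) and tangentially (uniform ±0.002 rad).
  The layout plants: serosal smooth muscle (anchor), crypt-base
  proliferating cells, enterocytes spanning the depth, a *rare*
  (1% baseline) canonical goblet cluster confined to the mid third,
  non-canonical goblet cells, distal surface (intercrypt) goblet
  cells, and plasma cells. `knockout_expansion` (default 2) multiplies
  the planted cluster's density in the knockout genotype; because
  frequencies renormalise within bins, the true mid-bin log2 ratio at
  baseline weight 0.01 is ≈ 0.96, slightly below 1.
* **Standards**: forward-4PL ODs with optional Gaussian noise.

What passing these tests shows — and does not. The synthetic rolls have
Gaussian placement noise, strictly Archimedean geometry, and exhaustive
cluster labels; real sections fold, tear, compress unevenly, and carry
segmentation errors, so recovery bounds measured here (position rank
correlation > 0.99, depth error q95 < 0.1, pitch within ~1%) are
best-case calibrations of the estimator, not guarantees for tissue.
Likewise the expression generator has independent Gaussian genes; real
co-expression inflates signature-score variance relative to these
simulations.

## Problem sizes and determinism

Default test and acceptance problem sizes were chosen to exercise every
code path at meaningful statistical resolution on a single CPU:
ROC/Youden oracle sweeps over 200 cohorts of n <= 50; 1,000 simulated
sera for classifier recovery; 10 swiss-roll replicates of ~12,000 cells
for geometry recovery plus one full-scale (96,000 cell) planted-effect
experiment and 10 null replicates; 500 expression simulations for sign
recovery. Every stochastic routine takes an explicit seed and
reproduces bit-identical output; `scripts/acceptance.py` derives all
internal seeds from its single `--seed`.

## Known limitations

* The spiral intercept `a` is defined at θ = 0, one full turn inside
  the innermost tissue; recovering it means extrapolating the fitted
  pitch ~2π beyond the data, so its relative error runs ~2.5× the pitch
  error (typically ~3%, versus ~1% for the pitch itself). The
  inner-terminus radius, which is interpolated rather than
  extrapolated, recovers to ~1%.
* The intercept is also gauge-dependent: relabelling which turn is
  θ = 0 changes (a, θ-range) jointly without changing the curve;
  comparisons reduce a modulo whole turns (2πb).
* `compare_composition` treats cells as independent within (genotype,
  bin); it does not model section-level (mouse-level) variance, so its
  CIs describe counting noise, not biological replication.
* The half-thickness estimator assumes the band edges are populated in
  every angular window; a cluster layout with systematically empty
  depth extremes would bias d outward.
* Exact Spearman permutation p-values above n = 8 enumerate up to 3.6M
  pairings and take seconds; the t-approximation takes over from n = 11
  as designed.
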