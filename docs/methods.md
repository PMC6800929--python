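# Methods

This note records the models, numerical conventions, calibration procedure,
and design choices behind `noduletex`, in the spirit of a statistics
package's methods documentation. It states no empirical result that the
test suite or `scripts/acceptance.py` does not itself compute.

## Volumes and coordinates

A CT volume is an integer HU lattice indexed `[z, y, x]` with physical
spacing `(dx, dy, dz)` in mm; public coordinates (seed points, phantom
centres) are `(x, y, z)` with z the slice axis, 0-based. DICOM series are
read by sorting slices on the image-position coordinate projected onto the
slice normal — never on file names, which are unordered in the wild.
Stored pixel values map to HU through the rescale slope/intercept tags;
missing rescale tags, mixed series UIDs, and inter-slice spacing deviating
by more than 0.01 mm from uniform are hard errors (the tolerance allows for
floating-point metadata jitter). Intermediate fractional HU are rounded
half away from zero for cross-platform determinism; 12-bit quantisation
clamps to [−1024, 3071] (4096 levels) and is idempotent and
order-preserving. Protocol validation checks slice thickness against
[0.90, 1.25] mm (inclusive bounds) and the in-plane matrix against 512×512,
reporting *all* violations; the pipeline treats violations as warnings, not
failures. A lossless `.npz` + JSON-sidecar archive complements DICOM for
fast fixtures.

The reconstruction display window (width 1,500 HU, centre −700 HU) is
treated as display-only; no analysis step depends on it.

## Segmentation

Region growing admits voxels whose HU lies in a *closed* interval, default
[−450, +1500] — both endpoints included, since the interval is quoted as a
range without openness — and keeps the connected component containing the
seed. Connectivity defaults to 6-neighbour (face adjacency), the
conservative choice with fewer leak paths; 26-neighbour is available by
flag. An optional half-open slice range `[first, last)` restricts growth to
a block of slices and must contain the seed slice. The implementation
labels the thresholded lattice with `scipy.ndimage.label` and selects the
seed's component; the test suite checks it against an independent
breadth-first flood fill, exhaustively on random volumes up to 10×10×10.

Attached structures are removed by an explicit exclusion mask (the paper
trail for interactive vessel/bronchus editing), after which only the
seed-containing component is retained; excluding the seed voxel itself is
an error. Volume is `voxel_count × dx·dy·dz`. Volume doubling time uses
VDT = Δt·ln2/ln(V₂/V₁), reported as infinite when V₂ ≤ V₁; "stable" means
VDT > 2,000 days.

## Histogram and first-order statistics

Bin edges sit on half-integers so that unit-width bins are centred on
integer HU values (e.g. edges −450.5, −449.5, … for the default range).
This makes the histogram-path moments *bit-identical* to voxel-path moments
for integer HU input at unit width — including values at the inclusive
upper interval endpoint — which the suite asserts to 1e−10 over a thousand
random masks. Bins are half-open `[edge, edge+w)` except the last, which
includes its upper edge. Moments use the population (biased) form: the sum
runs over the entire voxel population of the nodule, not a sample.
Skewness and kurtosis are the standard third and fourth standardized
moments, kurtosis in excess form (−3, Gaussian = 0), matching the
leptokurtic/platykurtic reading of positive/negative values. Zero-variance
(single-HU) nodules raise an explicit "degenerate distribution" error
rather than returning NaN.

The published formulas normalise by `VAR³`/`VAR⁴` as printed; these
exponents are typographically corrupt standardized moments (they would not
be dimensionless), but the literal forms remain available behind
`literal_exponents=True` for auditing, and a `fisher=False` flag gives
non-excess kurtosis.

## Peak/plateau rule

The visual peak-vs-plateau dichotomy is replaced by an explicit rule.
Frequencies over the occupied range (first to last nonzero bin) are
smoothed with a centred moving average (default window 5 bins, reflection
padding so edge bins are not deflated), and

    peakedness = max(smoothed) / mean(smoothed over occupied bins)

where "occupied bins" are those with nonzero counts. The mean is taken
over occupied bins rather than over every bin in the span because nodule
histograms have sparse extreme-HU tails: a whole-span mean is diluted by
runs of empty bins and would label nearly every distribution a peak. A
histogram whose entire mass sits in a single HU level is the limit of
maximal concentration and scores infinite peakedness. An exactly uniform
histogram scores 1. The label is *peak* when peakedness ≥ 3.0; the
threshold was calibrated on the default phantom cohorts (see below) and is
exposed as a parameter, as are the window and a minimum-voxel floor (10).
An alternative rule (`kurtosis-sign`: peak iff excess KUR > 0) brackets the
moment-based interpretation of the dichotomy. PNG export pins the Agg
renderer and strips software metadata so identical inputs render
byte-identically.

## Diagnostics

AUC is the Mann–Whitney rank statistic with ties counted ½, which equals
the trapezoidal area under the empirical ROC curve whose diagonal segments
come from tied scores; ROC point geometry comes from scikit-learn with
`drop_intermediate=False`, and the trapezoid/rank identity is asserted over
1,000 random tied instances. The Youden cut-off maximizes
sensitivity + specificity − 1, breaking ties toward higher specificity (a
benign-sparing screen). 2×2-table statistics use exact rational arithmetic
(`fractions.Fraction`), so 42/50 is exactly 84%. The published patient-data
cut-offs (KUR > 6, SKW > 3.1) are stored as reference constants applied
only in an explicit published-cutoffs mode, never derived from phantoms.
Inter-reader reliability is ICC(2,1) — two-way random effects, absolute
agreement, single measures, the form appropriate when readers are a random
sample and systematic offsets should count against agreement — computed via
pingouin and cross-checked against a direct ANOVA variance-components
oracle; acceptability is ≥ 0.85.

## Synthetic phantoms

### What is emulated

Each phantom is an ellipsoidal nodule (radius 5.3–9.3 mm at default cohort
settings, mild axis anisotropy 0.92–1.08, ≈ 600–3,900 voxels at 1 mm
spacing on a 48³ lattice) on an aerated-lung background of −800 HU with
Gaussian noise (SD 30 HU) clipped to stay below the −450 HU inclusion
bound. Because the background can never enter the inclusion interval,
default segmentation recovers the ground-truth mask *exactly*, separating
segmentation correctness from subtraction correctness. An attached
cylindrical vessel (radius 1.0–1.6 mm, ≈ 60 HU, i.e. inside the interval)
is added to 35% of nodules to exercise structure subtraction. Nodule HU
values are clipped to the open interval (−450, 1500) and quantised, so the
ground-truth mask invariants hold after rounding.

### Texture family

Nodule voxels are i.i.d. draws from a standardized two-component Gaussian
mixture `(1−p)·body + p·N(d, τ²)`, with a *flat* body (uniform on
[−√3, √3]) for typical benign nodules and a *spike* body (standard normal)
for typical malignant ones; the secondary component models dispersed dense
material. All four moments are closed-form, so (p, d, τ) is solved by
least squares over a small grid of mixture weights to hit any feasible
per-nodule (SKW*, KUR*) target, and the analytic moments double as a
Monte-Carlo oracle in tests. This family was chosen over single-transform
families (Johnson-type sinh transforms of a Gaussian) because those cannot
reach the benign regime: at skewness 1.73 their minimum excess kurtosis is
≈ 5.8, far above the benign target of 3.37, whereas two-component mixtures
cover essentially the whole feasible region KUR ≥ SKW² − 2. The
standardized draw maps to HU via a location/scale pair; malignant defaults
(loc ≈ 50 HU, scale ≈ 22 HU) concentrate mass in the 0–100 HU soft-tissue
band, benign defaults (loc ≈ 35 HU, scale ≈ 55 HU) spread it.

The structural body also carries the class difference that the shape rule
detects. Given only (SKW, KUR), peakedness is class-independent, and the
class moment distributions overlap far too much for the published
peak/plateau operating point (≈ 84% sensitivity / 74% specificity) to be
reachable from moments alone; the flat-vs-spike body reproduces it
structurally. Each class contains an *atypical* fraction using the other
class's body (benign 12%, malignant 7%), mirroring the minority of benign
nodules with peaked histograms and malignant nodules with plateaus that
the reference cohorts report.

### Hyperdistributions and calibration

Per-nodule targets are drawn as SKW* from a truncated Gaussian on
[0.2, 4.5] and KUR* from a Gaussian truncated below at
SKW*² − 2 + 0.2 (the feasibility bound plus margin, nudged upward in 0.5
steps in the rare case the mixture solver still fails). Truncation and
finite-voxel moment bias shift realized cohort statistics away from the
proposal parameters — most strongly for kurtosis, where one-sided
truncation inflates the realized mean by 1.5–2 units. The proposal means
were therefore *calibrated*: iterated simulation of the full
generate → segment → histogram → statistics pipeline, adjusting proposals
by the residual to the reference cohort means (benign KUR 3.37 / SKW 1.73,
malignant KUR 5.88 / SKW 2.07) and then frozen as the package defaults
(benign μ_SKW = 1.60, μ_KUR = −2.5, SD 0.94/3.0; malignant μ_SKW = 1.96,
μ_KUR = 0.5, SD 1.01/4.0). With these defaults, 500-nodule cohorts
reproduce all four reference means within ±0.5 (KUR) and ±0.15 (SKW)
across master seeds; this is asserted by the acceptance suite and
recomputed by `scripts/acceptance.py`. The realized cohort SDs
(≈ 0.9 for SKW, ≈ 3–4 for KUR) are close to, but not exactly, the
reference cohort SDs — an unavoidable consequence of restricting the
hyperdistribution to the feasible moment region; the reference values do
not decompose within- vs between-nodule variation, so the truncated
Gaussian hyperdistribution is an explicit modelling assumption.

Seeding is counter-based: phantom i of a cohort uses
`SeedSequence(master_seed, spawn_key=(i,))`, so cohorts are reproducible
and order-independent, and distinct master seeds give voxelwise-different
cohorts.

### What is not emulated

No anatomy (airways, ribs, fissures), no scanner physics (beam hardening,
reconstruction kernels, noise correlation), no partial-volume effects
beyond voxelisation, and no spiculated or lobulated shapes (the reference
cohorts excluded them). Passing phantom tests therefore demonstrates
algorithmic correctness and calibrated statistical behaviour, not
performance on clinical images: in particular the real-data AUCs (≈ 0.71)
and reader ICCs (0.87, 0.91) depend on the patient images and are *not*
reproduced; the diagnostics are instead verified against independent
oracles, with a directional sanity check that phantom-cohort KUR separates
the classes (AUC > 0.5, malignant higher).

## Problem sizes

Default test and acceptance runs use 48³ lattices, 500 region-growing
oracle comparisons on volumes up to 10³, 1,000 random histograms for the
moment oracle, 1,000 tied instances for the ROC identity, and 500 phantoms
per class for calibration checks — sizes chosen so the full suite and the
acceptance script each complete in minutes on a single CPU while keeping
Monte-Carlo standard errors well inside the stated tolerances (cohort-mean
SE ≈ 0.15 for KUR, ≈ 0.04 for SKW at n = 500).

## Known limitations

- The peak/plateau rule is a calibrated surrogate for a visual judgement;
  its threshold is meaningful only relative to this peakedness definition.
- Histogram-path and voxel-path moments coincide exactly only at unit bin
  width on integer HU; wider bins introduce ordinary binning error.
- The growth-pair generator scales a single ellipsoid; it does not model
  shape change during growth, so VDT recovery is accurate only to
  voxelisation error (tested at 15%).
- `subtract_structures` requires the exclusion mask to be supplied
  (ground truth or a manual editor's output); no automatic vessel
  detection is attempted.
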