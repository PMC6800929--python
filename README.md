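# noduletex

CT texture analysis of solid pulmonary nodules.

A solitary pulmonary nodule (SPN) is a lung mass ≤ 3 cm surrounded by
normal tissue. Many SPNs found on CT are *indeterminate*: they lack both
clear benign features (calcification patterns) and clear malignant ones
(spiculation, growth). For such nodules, first-order statistics of the
Hounsfield-unit (HU) density histogram of the whole nodule volume — in
particular its **kurtosis** and **skewness** — carry diagnostic signal:
malignant nodules tend to concentrate their voxel density in the 0–100 HU
soft-tissue band, producing a sharp, heavy-tailed ("peak", leptokurtic)
histogram, while radiologically stable benign nodules spread their density
into a flat-topped ("plateau", platykurtic) histogram.

`noduletex` implements that analysis end to end, for researchers working on
nodule radiomics who need a tested, reproducible reference pipeline:

- **volume I/O** — DICOM series reading/writing with HU rescale handling,
  12-bit quantisation, and acquisition-protocol validation (slice thickness
  0.90–1.25 mm, 512×512 matrix);
- **segmentation** — seeded 3D region growing within a closed HU inclusion
  interval (default [−450, +1500]), subtraction of attached structures
  (vessels, bronchi, scars) via an explicit exclusion mask, nodule
  volumetry, and volume doubling time;
- **texture statistics** — the nodule-volume HU histogram with normalized
  frequencies H(i), and its first-order moments;
- **histogram shape** — a reproducible peak/plateau classification rule and
  annotated PNG export;
- **diagnostics** — ROC/AUC with tie handling, Youden cut-off selection,
  exact 2×2-table statistics, and two-reader ICC(2,1);
- **synthetic data** — a CT phantom generator whose benign and malignant
  cohorts are calibrated to reference cohort statistics, so every stage is
  testable without patient data;
- **pipeline/CLI** — a `noduletex` command with `simulate`, `segment`,
  `features`, `classify`, `roc`, `table`, and `run` subcommands.

## The statistics

For a segmented nodule with G histogram bins, bin representative values
c_i, and normalized frequencies H(i) (Σ H(i) = 1):

    MEN = Σᵢ cᵢ · H(i)
    VAR = Σᵢ (cᵢ − MEN)² · H(i)                      (population variance)
    SKW = Σᵢ (cᵢ − MEN)³ · H(i) / VAR^{3/2}          (third standardized moment)
    KUR = Σᵢ (cᵢ − MEN)⁴ · H(i) / VAR² − 3           (excess kurtosis)

KUR = 0 for a Gaussian; KUR > 0 is leptokurtic (peaked with heavy tails),
KUR < 0 platykurtic (flat-topped). With unit-width bins centred on integer
HU values these formulas agree *exactly* with the same moments computed
from the raw voxel list, and the package verifies that equivalence.

Volume doubling time follows VDT = Δt · ln 2 / ln(V₂/V₁); a nodule is
considered radiologically stable when VDT > 2,000 days.

## Worked example

```python
from noduletex import (PhantomSpec, TextureParams, VesselSpec, SeedPoint,
                       generate_phantom, region_grow_3d, subtract_structures,
                       build_histogram, stats_from_histogram, classify_shape,
                       volume_doubling_time)

spec = PhantomSpec(
    label="malignant", center=(24, 24, 24), radius_mm=8.0,
    texture=TextureParams(skew=2.07, kurt=5.88, loc_hu=50.0,
                          scale_hu=22.0, body="spike"),
    vessel=VesselSpec(direction=(1.0, 0.2, 0.1)),
    rng_seed=7)
truth = generate_phantom(spec)

seg = region_grow_3d(truth.volume, SeedPoint(24, 24, 24))   # HU in [-450, 1500]
seg = subtract_structures(seg, truth.vessel_mask)
print(f"voxels: {seg.voxel_count}   volume: {seg.volume_mm3:.0f} mm^3")

hist = build_histogram(truth.volume, seg)                   # unit-width HU bins
s = stats_from_histogram(hist)
print(f"MEN {s.MEN:.1f} HU   VAR {s.VAR:.0f}   SKW {s.SKW:.2f}   KUR {s.KUR:.2f}")

shape = classify_shape(hist)
print(f"histogram pattern: {shape.label} (peakedness {shape.peakedness:.2f})")

growth = volume_doubling_time(v1=500.0, v2=550.0, delta_t_days=365.0)
print(f"VDT {growth.vdt_days:.0f} days -> stable: {growth.stable}")
```

Output:

```
voxels: 2109   volume: 2109 mm^3
MEN 49.7 HU   VAR 491   SKW 2.01   KUR 5.55
histogram pattern: peak (peakedness 3.55)
VDT 2654 days -> stable: True
```

The phantom is an 8 mm malignant-profile nodule with an attached vessel:
region growing picks up nodule + vessel, subtraction of the vessel mask
recovers the nodule exactly, and its histogram is sharply peaked around
50 HU with positive skew and strongly positive excess kurtosis — the
malignant signature. The slow-growth example (500 → 550 mm³ over a year)
gives a doubling time of about 2,654 days, i.e. a stable nodule.

The same pipeline runs from the shell:

```
noduletex simulate --n-benign 50 --n-malignant 50 --seed 1 --out cohort
noduletex run --manifest cohort/manifest.csv --out results
```

which writes `features.csv` (one row per nodule: MEN, VAR, SKW, KUR, shape
label, peakedness), ROC point CSVs, `summary.json` (AUCs, Youden cut-offs,
the peak/plateau 2×2 table and its sensitivity/specificity/accuracy), and a
run log echoing the full configuration.

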