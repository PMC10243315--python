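# Methods

This note documents the models behind `scoutdose`, the parameters that
matter, what the synthetic-data generator does and does not emulate, and the
design choices made where the underlying physics or conventions were open.

## Size metrics

The water-equivalent area of an axial slice is computed in the ROI-mean
form `A_W = (mean CT/1000 + 1)·A_ROI` and the water-equivalent diameter as
`WED = 2·√(A_W/π)`.  Air pixels (−1000 HU) contribute exactly zero, so the
default ROI is the full reconstructed image; a `body` ROI policy
(threshold −300 HU, largest connected component) is available, and the two
agree to well under 0.5% on clean data.  When couch removal is active under
the full-image policy, pixels above threshold that are *not* part of the
body component are blanked to air before summing, so a couch inflates
neither A_W nor the geometric extents.  Geometric surrogates are the body
mask extents along image rows (AP) and columns (LAT), with
`ED = √(AP·LAT)`; holes (lungs) are filled first, since AP/LAT are outline
quantities.  The −300 HU default sits between lung (≈ −750 HU here) and
soft tissue; it is configurable.

On the localizer, the per-row profile value PPV̄ is the arithmetic mean of
the *full* row, air included — a constant detector offset then shifts every
PPV̄ equally and is absorbed by the calibration intercept.  Geometric width
from the localizer uses a threshold at 5% of the image dynamic range above
background, a divergent-beam demagnification SAD/SID (unity for parallel
geometry), and an AP/LAT aspect-ratio assumption (default 0.75) because a
single frontal view carries no AP information.  Objects touching the field
edge are flagged as truncated, not corrected.

## Calibration

Per (scanner model, localizer kV, axial kV), per-slice pairs
`(PPV̄ at the mapped row, R = A_W/FOV_X)` are pooled across phantoms and fit
by unweighted ordinary least squares.  Slice z maps to the localizer row
`round((top_z − z)/row_pitch)` with ties toward the smaller index — the
rounding convention is a package choice; the underlying tag arithmetic uses
SliceLocation (0020,1041), ImagePositionPatient (0020,0032) and
PixelSpacing (0028,0030).  A valid fit needs ≥ 3 points from ≥ 2 distinct
phantoms and non-degenerate PPV̄ spread.  The fitted PPV̄ range is stored;
application outside it is permitted but flagged as extrapolation, because
patients exceed phantom sizes.  Negative predicted areas (air-only rows)
clamp to zero with a warning record so batch runs survive.  Calibrations
are keyed per scanner and never transfer across scanners: localizer pixel
values are not absolute.

Against an affine pixel response the linear calibration is exact: the
intercept absorbs the offset and the slope scales as 1/gain, so at zero
noise the localizer-derived WED reproduces the axial WED to ray-sampling
tolerance (≪ 1%).  This identity — and its degradation under noise — is
what the acceptance sweep measures, against the 20% accuracy charge for
size-estimation methods.

The calibration store is JSON, keyed by (scanner, localizer kV, axial kV),
with coefficients round-tripped bit-exactly through `repr`.  Its metadata
records the package version rather than a wall-clock timestamp: all
pipeline outputs are byte-identical for deterministic runs, and a timestamp
would be the one field breaking that.

## Synthetic phantoms and renders

Phantoms are 2-D voxel cross-sections (constant along z) of relative water
attenuation: water 1.0, air 0.0, PMMA 1.15, lung 0.25 (≈ −750 HU, a
representative mid-inspiration value; configurable).  The standard
calibration family mirrors what a CT department owns: the ~1 cm acrylic
CTDI rod (anchoring the line near the origin), 16 cm and 32 cm PMMA
cylinders, and a 20 × 25 cm water oval.  Elliptical "patients" have
semi-axes AP/2 × LAT/2 and, for chest, two elliptical lung inserts scaled
so their combined area is a chosen fraction of the body area (default
layouts keep them inside the body wall; impossible fractions are rejected).
An optional PMMA half-pipe couch can be placed under the body, separated by
an air gap, to exercise couch removal.

Axial rendering maps attenuation to `HU = 1000·(μ − 1)`, adds optional
Gaussian HU noise, and rounds to integers as real reconstructions do.
Localizer rendering computes the water-equivalent path of each ray and
applies an affine per-kV response `pixel = gain·path + offset + noise`,
quantized to unsigned 16-bit.  The affine form is the minimal response a
linear calibration can invert, which is precisely the assumption the
calibration method makes about real scanners.  Defaults: gain 10 units/mm,
offset 50, SAD 600 mm, SID 1100 mm, 1 mm detector pitch.  The default beam
model is parallel — the idealization under which the profile–area relation
is exact; a fan-beam ray tracer is provided and agrees with the
laterally-magnified parallel render to 1% in the small-angle regime.  Noise
levels for the study conditions are expressed as gain-SNR (gain divided by
the per-pixel noise sigma): 50 for the "realistic" condition, 100 for the
"clean" one; row-averaging over ~600 columns makes the effective PPV̄ noise
~25× smaller still.

What the generator does **not** emulate: polyenergetic spectra, scatter,
bowtie filtration, beam hardening, anthropomorphic anatomy, tube-current
modulation, or detector non-linearity.  Passing tests therefore demonstrate
that the pipeline correctly inverts the response class it assumes (affine,
additive-Gaussian) and is robust to quantization and moderate noise — not
that a real scanner's response is affine.  On real equipment the residual
non-linearity is exactly what the per-kV calibration curves absorb
empirically.

## Dose and risk

NDC uses the 32 cm PMMA coefficients `a = 3.70469`, `b = 0.03671937 cm⁻¹`
(alternative pairs accepted via `NdcModel`); D is converted mm→cm only at
this boundary.  SSDE = NDC·CTDIvol.

Risk indices are *inputs*: the external organ-dose / lifetime-risk chain is
not reimplemented.  The synthetic cohort draws true WED uniformly over
80–400 mm (so NDC varies materially), CTDIvol uniformly over 4–30 mGy,
chest lung fractions over 0.15–0.40, and generates
`RI = α + β·SSDE_true + N(0, σ)` with defaults α = 0, β = 0.5 (risk-index
units per mGy), σ = 0.1 — scaled so cohort RI values fall in a plausible
0–30 per-1000-patients range.

RSI is the regression slope divided by mean(RI)/mean(metric), read so that
perfect proportionality gives RSI = 1 exactly; the reciprocal normalization
(slope × mean ratio) is available behind a flag since the verbal definition
admits both readings.  RDI = RMSE/|slope| (undefined and reported as NaN
for a zero slope).  RSI is invariant to rescaling the metric, RDI to
shifting the risk index; both invariances are property-tested.

## Numerical choices and problem sizes

Voxel pitch 1 mm everywhere; phantom grids 360 mm square, patient grids
560 mm square with a 600 mm localizer FOV; 30 mm z-extent at 5 mm slices
(6 slices/exam) — cross-sections are z-constant, so more slices add only
noise averaging.  The validation sweep uses 14 exams with true WED evenly
spaced over 80–400 mm, alternating all-water abdominopelvis and 30%-lung
chest bodies.  Fan-beam ray integration samples bilinearly at 0.5 mm steps.
Fit quality is reported as 1 − SS_res/SS_tot on the pooled points.
Duplicate SliceLocations are rejected; a missing SliceLocation falls back
to ImagePositionPatient[2] with a logged warning.

## Known limitations

Single-material bodies plus lungs only; no truncation compensation (flag
only); no gantry tilt or compressed transfer syntaxes; the AP/LAT aspect
ratio from a single frontal localizer is an assumption, not a measurement;
RSI/RDI values computed on synthetic cohorts characterize the estimator,
not any patient population.
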