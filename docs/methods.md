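# Methods

This note documents the models, the synthetic-data generator, the numerical
choices and the known limitations of `spacerstrat`, in the order the
pipeline applies them.

## Coordinate and axis conventions

All volumes are `(z, y, x)` arrays: `z` cranio-caudal (index increases
towards the head), `y` anterior→posterior, `x` right→left, with
`spacing_mm` and `origin_mm` in the same order and half-open index ranges.
Window sizes exposed to users (e.g. the network crop) are quoted `(X, Y, Z)`
following imaging convention; the two are converted at the module boundary.

## Synthetic pelvic phantoms

The generator emulates the *statistical structure* of a dose-escalated
prostate cohort, not any individual anatomy:

- **Prostate**: an ellipsoid with mildly jittered axis ratios; volume drawn
  per phantom from N(42.3, 15.7²) cc truncated at ±2.5 SD, matching the
  cohort statistics the package targets. Two superior-posterior ellipsoid
  lobes act as a seminal-vesicle proxy (the clinical CTV53 = prostate +
  vesicles); no published phantom geometry exists for them, so their shape
  is our choice (12 % of prostate volume, fixed ratios).
- **Rectum**: a tube posterior to the prostate (2 mm gap), length 105 mm at
  the default grid, with sinusoidal centreline wobble and ±10 % radius
  modulation; volume from N(69.3, 19.7²) cc truncated at ±2.5 SD.
- **Bladder**: an anterior-superior ellipsoid, N(180, 45²) cc. Bladder
  volume is not reported for the reference cohort; 180 cc is a typical
  comfortably-filled planning bladder.
- **Targets**: PTV60 = prostate ⊕ 5 mm, PTV53 = (prostate ∪ vesicles) ⊕
  9 mm, CTV68 = lesion ⊕ 3 mm cropped to the prostate, PTV68 = CTV68 ⊕
  2 mm. Dilations are physical-distance (EDT) based, so anisotropic voxels
  are handled exactly.
- **Boost lesions**: six per phantom, placed in posterior-weighted
  peripheral-zone sectors (default azimuths 30–150° measured from the
  left-right axis towards posterior, jittered ±8° per seed), at 0.60–0.78
  of the local prostate radius. Lesion volumes are log-normal with median
  6.0 cc clipped to [3, 13] cc; after the margin/crop chain this yields
  PTV68 volumes spanning ≈4–15 cc, inside the 3.0–31.7 cc clinical range.
  The lesion median is larger than the clinically reported 3.1 cc because
  the discrete 3 mm + 2 mm margins grow sub-voxel at the default 2.5–3 mm
  grid; the *PTV68* distribution is the quantity matched.

All stochastic choices derive from `PhantomSpec.seed`; identical specs give
voxel-identical phantoms.

### Analytic planned dose

A commercial optimiser is emulated by a closed-form surrogate:

```
dose = Σ_p  Δ_p · 2 / (1 + exp(d_eff,p / w_p)),    p ∈ {53, 60, 68}
d_eff,p = dist_outside(PTV_p) · (1 + s · R)
```

with plateaus Δ = 54/7/7 Gy (cumulative 54/61/68 Gy — ≈1 Gy headroom over
the 53/60 Gy prescriptions so coverage survives plan noise), fall-off
widths `w` of 11/7/4.5 mm, and `R` a Gaussian-smoothed rectum indicator:
inflating the effective distance inside the rectum steepens the fall-off
there and produces the concave rectal isodoses characteristic of optimised
plans, without touching target coverage (distances are zero inside each
target). A long-range scatter bath (18 Gy amplitude, 40 mm range,
max-composed so it never raises the plateaus) supplies the low-dose
envelope a real plan deposits along the rest of the rectum. Correlated
Gaussian noise (σ = 0.15 Gy, 8 mm correlation) models residual plan
texture, and each plan is renormalised so the PTV68 median is exactly
68 Gy, as clinical plans are.

Per-plan jitter (`FalloffConfig.sample`: widths ±20 %, sparing weight
0.5–1.6, bath ±20 %) emulates planner-to-planner variation. Every emitted
plan is verified against the coverage objectives (≥95 % of PTV60 ≥ 60 Gy,
≥95 % of PTV53 ≥ 53 Gy, PTV68 median 68 ± 0.3 Gy) and the simulator raises
if they cannot be met.

The fall-off and jitter defaults were fixed once, by sweeping until the
simulated ensembles reproduce the reference cohort's dose-structure:
roughly two-thirds of plans exceed optimal rectal tolerances and a quarter
exceed mandatory ones, violations concentrate at the highest-dose
constraint entries, and late-rectal-bleeding risks land in the reported
3.3–10.4 % band.

### What the phantoms do not model

No CT intensities (the method is mask-native), no femoral heads, no rectal
gas/filling variability, no inter-fraction motion, no beam/arc physics.
Plan "quality" variation is a smooth two-parameter family, far simpler than
a human planner's. Tests passing on phantoms therefore demonstrate that the
*method* — network, DVH, radiobiology, stratification accounting — works
end to end on data with the right statistical shape; they cannot certify
clinical accuracy on real plans.

## Preprocessing

Dose grids are resampled to the mask grid with a third-order spline
(negative overshoot clamped to 0). Crops are centred left-right on the
PTV53 centre of mass and cranio-caudally on the rectal centre of mass
(non-integer centres floored), with the anterior-posterior placement chosen
so the entire rectum lies inside the window; the window is shifted
minimally (and zero-padded past the grid edge, with a warning) when
needed, and every call hard-asserts that no rectum voxel was discarded.
Dose is normalized by the training-cohort maximum; the constant is stored
inside every checkpoint and always reused at prediction time, so a model's
outputs do not depend on which cohort it is later applied to.

## Network and training

The dose predictor is a hierarchically densely connected U-Net: dense
concatenative connections inside each resolution level, skip concatenation
of all same-resolution encoder features into the decoder, 2× max-pool
downsampling, trilinear-upsample + convolution upsampling, ReLU after every
3×3×3 convolution and a linear 1×1×1 output head. The engine is pure
NumPy: a minimal reverse-mode tape whose conv/pool/upsample gradients are
verified against finite differences in the test suite. Convolutions are
evaluated as 27 BLAS matrix products on contiguous offset slices of the
padded, flattened volume, which keeps CPU training practical.

Two presets are used:

| | levels | growth | input | bottleneck | optimiser |
|---|---|---|---|---|---|
| full scale | 5 | 16 | 128×128×64 | 8×8×4 | Adam, lr 1e-4, 200 epochs |
| desk scale | 3 | 4 | 32×32×16 | 8×8×4 | Adam, lr 1e-3, 50 epochs, batch 6 |

The cited architecture's exact per-level widths are not published; `growth`
(feature maps added per dense convolution) is configurable and the presets
are deliberately small. The desk-scale preset is the package's standard
experiment: 20 training phantoms × 6 boosts (120 plans), 14 held-out
phantoms, a problem size chosen so the full study (simulation → training →
evaluation) completes in minutes on one CPU core. The raised learning rate
compensates for the shorter schedule; no early stopping is used in either
preset. Training is exactly reproducible for a fixed seed (weight
initialisation and batch order are both generator-seeded; single-threaded
BLAS is deterministic).

Leave-one-out cross-validation is grouped by patient: all six boost plans
of the held-out patient leave the training fold together, and the fold
manifest records the split (19-of-20-patient folds train on 114 plans).

## DVH and radiobiology

Cumulative DVHs are direct voxel counts on fixed 0.1 Gy bins (v(0) = 100 %,
last bin 0); VdGy/Dv% queries interpolate linearly, Dmean/Dmax use raw
voxel statistics when the dose grid is available. EQD2 is applied per DVH
bin assuming each voxel receives its total dose in `n_fractions` equal
fractions; the default scheme is 20 fractions (the dose-escalation
protocol's hypofractionation) with α/β = 3 Gy, and results should always be
quoted with the scheme used. gEUD is evaluated in log space
(`exp(n·logsumexp(log v + (1/n)·log d))`) so the n = 0.085 (exponent ≈ 11.8)
and smaller volume parameters cannot overflow; the probit Φ uses the
double-precision error function. gEUD is bounded by [Dmean, Dmax] for
n ≤ 1, equals Dmean at n = 1 and approaches Dmax as n → 0⁺, all asserted in
tests against independent direct summation.

## Stratification conventions

- Positive class: "exceeds tolerance / high risk", everywhere.
- DVH constraints: a plan exactly on a tolerance *passes* (strict >).
  Risk thresholds: a risk exactly at the threshold is *high* (≥), matching
  the clinical phrasing "offer insertion to patients with risk ≥ t". The
  two conventions are deliberate and independently configurable by callers.
- The bundled constraint table (optimal/mandatory tolerances at 24.6, 32.4,
  40.8, 48.6, 57, 60 and 68 Gy, 0.2 % top-dose tolerance in place of 0 %)
  is an Onjukka-style *synthetic study table*: its numeric tolerances were
  co-calibrated with the simulator so the simulated cohorts reproduce the
  reference exceedance structure. It is not a clinical protocol; users
  supply their own table as YAML for any real analysis.
- Bland-Altman limits of agreement use the sample SD (n − 1); DVH-parameter
  errors are absolute percentage-point differences of V-values.
- Isodose Dice levels default to {24.6, 32.4, 40.8, 48.6, 60, 68} Gy;
  levels whose true isodose touches the crop boundary are excluded (logged),
  since their Dice would measure truncation rather than prediction quality.

## Numerical/degenerate-input policy

Validation errors are raised early: empty masks, misaligned grids, zero
fall-off widths, non-positive normalization constants, rectum extents
exceeding the crop window, indivisible network input shapes (the failing
axis is named). Both-empty isodose sets return DSC = 1 by convention
(logged). Undefined confusion metrics (empty class) are flagged `None`
rather than silently zero. NaN training loss aborts with the epoch/batch.

## Known limitations

- The analytic dose surrogate has smooth, radially monotone fall-off;
  real optimised plans contain streaks, hot spots and planner
  idiosyncrasies the network never sees here.
- The desk-scale network is far smaller than a clinical-resolution model;
  its accuracies quantify the pipeline, not achievable clinical accuracy.
- LKB parameters are fixed literature values; no fitting, no confidence
  intervals, and no tumour-control modelling.
- DICOM-RT ingestion (contour rasterisation, RT-DOSE grids) is an extension
  point: phantoms are mask-native, and NIfTI is the interchange format.
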