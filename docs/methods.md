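# Methods

## Model and assumptions

`leafwet` models a sessile water droplet on a two-tier leaf surface.
The microscale tier (papillose epidermal cells, bumps of order 8 µm high
and 25 µm wide in summer) is assumed fully wetted (Wenzel); the
nanoscale tier (epicuticular wax tubules, ~100 nm diameter, ~1 µm long)
is assumed to trap air so the droplet touches only tubule tips
(Cassie-Baxter). The nanoscale assumption is checked by a meniscus
penetration depth

```
h = d_wax · [ 1/sin(θ_Adv − 90°) − sqrt( (1/sin(θ_Adv − 90°))² − 1 ) ]
```

where `d_wax` is half the tubule spacing and `θ_Adv` the advancing angle
on the tubule wall (> 90° required; shallower walls cannot hold a
sagging meniscus and raise a domain error). The state is Cassie-Baxter
when `h` is less than the tubule height, Wenzel otherwise; the boundary
`h = height` classifies as Wenzel, the conservative choice. For the
dense summer tubule array (spacing 75 nm, wall angle 117°) this formula
gives `h ≈ 9 nm`, far below the ~1 µm tubule height, so the
Cassie-Baxter conclusion is robust to the exact depth value. Note the
depth is exposed as an explicit function of `d_wax` and `θ`: reported
depths in the literature for this system (25 nm green, 277 nm brown) are
not reproducible from the stated spacings and the 117° wall angle (25 nm
requires a wall angle near the leaf-scale advancing angle ≈ 157°), so
such values are treated as classification inputs only, never as targets
for the formula.

Combining the tiers and allowing a fraction `1 − α` of the surface to
have lost its wax entirely (eroded patches behave as plain Wenzel):

```
cos θ* = α·r_micro·(φ_nano·(cos θ + 1) − 1) + (1 − α)·r_micro·cos θ
```

Limits: `α = 0` → Wenzel; `α = 1` → the uniformly waxed form
`r φ cos θ − r(1 − φ)`; additionally `r = 1, α = 1` → plain
Cassie-Baxter. These reductions hold algebraically and are enforced to
1e-12 in tests. When parameters push `|cos θ*|` past 1 the package
raises a non-physical-regime error instead of clamping, so parameter
sweeps see the model breakdown explicitly.

### Hysteresis: two variants, deliberately

The published leaf-hysteresis relation is

```
Δθ*_leaf / sin θ*_leaf = r_micro (α(φ_nano − 1) + 1) · Δθ_flat / sin θ_flat
```

Differentiating the combined-angle expression with respect to `θ`,
however, yields the sine factors in the *reciprocal* position
(`sin θ* Δθ* = r(αφ + 1 − α) sin θ Δθ`). There is no numeric evidence in
the source material precise enough to adjudicate between them, so both
are implemented — `hysteresis_leaf` (as printed, the default) and
`hysteresis_leaf_derivative` — and prediction reports carry both values
labelled `as_printed` and `derivative`. Predicted advancing/receding
angles are reported as `θ* ± Δθ*/2`: the split of hysteresis around the
mean is not specified by the model, and a symmetric split is the only
choice that keeps the mean fixed.

### Droplet retention

Tilt mechanics use the retention force balance
`π a γ_LA (cos θ_Rec − cos θ_Adv) = V ρ g sin β` with spherical-cap
geometry evaluated at `θ̄ = (θ_Adv + θ_Rec)/2` (the mean-angle
convention; a measured "average" contact angle is exactly this mean).
The critical volume is the closed-form elimination of the contact radius
`a = R sin θ̄` with `V = (π/3) R³ (1 − cos θ̄)² (2 + cos θ̄)`; the
roll-off tilt is the inverse, returning the distinguished value `PINNED`
(serialized as the string `"PINNED"`) when no tilt up to 90° dislodges
the droplet — a first-class outcome, not an error. The two directions
are exact inverses; tests enforce a relative round-trip residual below
1e-9 (a 1e-12 tolerance on the arcsine argument absorbs float round-off
at the β = 90° boundary). Volume ratios between two leaves are
independent of `γ_LA`, `ρ`, `g` and `β`, which cancel; this invariance
is asserted, not assumed, in tests. Default fluid constants are
room-temperature water: `γ_LA = 0.072 N/m`, `ρ = 1000 kg/m³`,
`g = 9.81 m/s²`, overridable on `DropletSpec`.

All angles are degrees at every interface; conversion to radians happens
only inside formula bodies. Display tables round half-up to integer
degrees; machine-readable outputs keep full precision.

## Morphometry

**Roughness `r_micro`.** Cross-section images are globally thresholded
(automatic Otsu split by default, fixed threshold as an override; a
polarity flag says whether tissue is bright or dark), small objects are
removed, and the topmost foreground row per column becomes the surface
height, measured upward from the bottom image edge. Columns without
foreground are linearly interpolated when under 10% of the image,
otherwise extraction fails. The profile is boxcar-smoothed over 5
columns before the arc-length measurement: a raw pixel staircase biases
the arc length upward by several percent, while the smoothing bias for
bumps tens of pixels wide is below 0.1%. `r_micro` is the profile
arc-length/chord ratio taken directly as the area roughness — the 2-D
ratio is *not* squared for isotropy, matching how cross-section line
profiles are used in practice; a truly isotropic bumpy surface would
have a somewhat larger area ratio, a known limitation.

**Tip fraction `φ_nano`.** A 256-bin histogram of the top-view image is
smoothed with a moving average (window 5) and local maxima at least 20
bins apart are located (the histogram is zero-padded so edge-bin peaks
count); the two tallest are kept, ties broken toward the brighter bin.
`φ_nano` is the fraction of pixels strictly brighter than the upper
peak's bin center — the region where a droplet would meet solid wax.
Fewer than two qualifying peaks raises a unimodal-histogram error. The
bin count, smoothing window and separation are robustness choices
exposed in `MorphometryConfig`, not measured properties.

**Intact fraction `α`.** The image is split into intact (bright) vs
eroded (dark) classes by Otsu's threshold (polarity flag available;
inversion plus a flipped flag is an exact no-op by construction). Intact
connected components smaller than 5 µm² are reassigned to eroded, then
eroded components smaller than 22.5 µm² are reassigned to intact —
reassignment, not deletion, so the denominator is stable; the operation
is idempotent. Components use 4-connectivity so diagonally touching
speckles stay separate. Because the filters are physical areas, a pixel
size is mandatory. When Otsu's two classes are closer than 3 pooled
within-class standard deviations the image is treated as single-class
(an Otsu split of pure Gaussian noise yields a separation of ≈ 2.65
class standard deviations, so 3.0 cleanly separates noise splits from
genuine two-level images) and the lone class is labelled by which side
of the dtype midpoint its mean lies on — this makes a fully intact,
noisy image report `α = 1` rather than a meaningless noise split, at the
cost of requiring calibrated absolute brightness for such images.

**Pipeline.** Replicate images per role are averaged arithmetically with
the sample standard deviation reported; per-image failures become QA
flags carrying the image identity, and only a role with no valid image
aborts the run.

## Synthetic data

The generators stand in for the SEM experiments and define the study
conditions; every generator takes a single integer seed driving an
explicit per-call random state, and records its ground truth from the
emitted object itself (mask pixel counts, high-resolution arc length),
never from the requested parameters.

- **Cross sections** (`gen_bump_profile`): a periodic bump train
  (sin² by default; gaussian and semi-ellipse "hemisphere" templates
  available) with the measured summer-cell scale as defaults: height
  8 µm, width 25 µm, four bumps. True roughness is the numerical arc
  length at 10× the emitted sampling density. The raster rendering
  (0.1 µm/pixel, 16-bit, Gaussian intensity noise σ = 800 counts on a
  46 000-count contrast) draws solid tissue below the profile over a
  2 µm baseline. `bump_height_for_roughness` inverts the arc-length
  ratio so fixtures can target a specific `r_micro` (e.g. 6.73 µm for
  r = 1.16).
- **Wax-tip top views** (`gen_waxtip_image`): dark floor, a mid-gray
  correlated wax-blob texture covering 40% of the field, and
  non-overlapping bright discs (radius 6 px) placed by rejection
  sampling until the placed-mask fraction is within 0.005 of the target
  (default 0.25); an unsatisfiable packing raises an error. Tip level is
  set above the 16-bit ceiling so tips render as saturated highlights —
  as bright tubule tips do under SEM edge brightening — which gives the
  histogram a clean dominant peak in the top bin and makes the
  peak-threshold estimator unbiased for the tip fraction.
- **Erosion maps** (`gen_erosion_image`): a Gaussian random field
  smoothed to a 10 µm correlation length and thresholded at the quantile
  leaving the target intact fraction (default 0.46, the late-fall
  value). Ground truth is recorded *before* speckle injection: intact
  flecks (disc radius 2 px ≈ 3.25 µm² < 5 µm²) and eroded pinholes
  (radius 5 px ≈ 20.25 µm² < 22.5 µm²) are then placed strictly inside
  the opposite class, on separate random streams so the macro field is
  identical with speckles on or off — which is what lets tests assert
  the area filters remove speckle influence exactly.
- **Goniometer readings** (`gen_goniometer_readings`): Gaussian noise on
  a true advancing/receding pair, redrawn until 0 < rec ≤ adv < 180.

What the generators do **not** emulate: SEM charging, drift, focus and
shading gradients, stomata and vein structures, correlated (non-white)
detector noise, and partial wax degradation intermediate between intact
and eroded. Parameter-recovery results on these images therefore show
the estimators are correct and unbiased under clean two- or three-class
contrast; they do not show robustness to real-instrument artifacts.

## Problem sizes and numerical choices

Default synthetic images are 768² px (wax tips), 512² px (erosion) and
~1000×110 px (cross-sections); the recovery battery runs 20 seeded
replicates of each. These sizes hold estimator errors comfortably inside
the documented tolerances (r within 2%, φ within 0.03, α within 0.05)
while keeping the full suite fast. Spherical-cap radii come from the
closed-form cube root (verified against a bracketing root-finder in
tests). Degenerate inputs have defined behaviour throughout: zero
hysteresis gives zero critical volume; a zero-contrast cross-section or
top view raises; `α` estimates of exactly 0 or 1 carry an
empty-class QA flag.

## Leaf-state presets

The four built-in states carry the measured parameter values: `r_micro`
1.16 / 1.07 / 1.13 / 1.10 and `α` 1 / 0.46 / 0 / 1 for green, brown,
heat-treated and vacuum-dried leaves, with `φ_nano = 0.25` throughout,
flat-wax angles 101° (advancing/receding 117°/86°), and measured leaf
tilt angles 157°/137°, 151°/96°, 127°/86°, 162°/131°. Note the measured
mean for brown leaves, 123.5°, is quoted in the source material variously
as 123° or 124°; the package always uses the computed mean of advancing
and receding.

## Known limitations

- The hysteresis ambiguity above is unresolved by design; downstream
  users must choose a variant consciously.
- `r_micro` from a single line profile under-represents isotropic area
  roughness (not squared; see above).
- The single-class fallback for `α` relies on absolute brightness
  calibration of the micrograph.
- Evaporation, temperature dependence of surface tension, droplet
  impact dynamics and torque at the petiole are out of scope.
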