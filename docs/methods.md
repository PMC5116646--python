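# Methods

## Problem setting

A kVCT slice of anatomy containing a large metal implant is corrupted along
every ray that crosses the metal: the polychromatic beam hardens (low-energy
photons are absorbed preferentially, so the measured log-projection
underestimates the true line integral) and, behind several centimeters of
steel, the detector receives essentially no photons at all (photon
starvation), leaving the log-projection both biased and extremely noisy.
After filtered back projection these corrupted rays appear as dark streaks
along the implant's long axis, bright bands along its short axis, and loss
of internal metal structure. An MVCBCT scan of the same anatomy penetrates
the metal and is nearly artifact-free, but has 2–4× the noise and visibly
lower resolution. The correction replaces the corrupted sinogram data of
the kV scan with surrogate data projected from a kV/MV fused prior image.

## Pipeline

All processing is per 2D slice with parallel-beam geometry: views uniformly
spaced over 180°, one detector bin per pixel, detector spanning the grid
diagonal (the projector/FBP pair is scikit-image's `radon`/`iradon`).
Images are exchanged in HU; projections operate on the affine
water-equivalent scaling μ = μ_ref·(1 + HU/1000) with μ_ref = μ_water at
the reconstruction reference energy, so synthesized prior projections are
commensurate with the scanner's measured −ln(I/I₀) data. A consequence of
inverting this affine map is that an all-zero sinogram reconstructs to
uniform air (−1000 HU), and FBP linearity holds up to the −1000 HU offset.

1. **MV→kV calibration.** Mean CT numbers of density rods (lung-like 0.30
   to bone-like 1.60 g/cm³) in a 30 cm cylinder scanned at both energies
   define the knots of a monotone piecewise-linear curve. Beyond the
   outermost knots the end segments continue linearly — clamping would
   destroy the pseudo-kV value of metal, which lies far above the densest
   rod.
2. **Resampling and rigid registration.** Bilinear resampling in physical
   coordinates onto the kV grid, then an exhaustive coarse grid
   (±10 mm / ±10°, 2 mm / 2° steps) over (tx, ty, θ) refined by a
   deterministic pattern search down to 0.1 mm / 0.1°, minimizing
   mean-squared HU difference. Metal-valued pixels can be excluded from the
   metric since artifacts differ between modalities. On noiseless synthetic
   poses inside the bounds the recovered parameters are well within half a
   pixel / half a degree.
3. **Metal segmentation** by thresholding the (pseudo-kV) MV image at
   3000 HU, with optional small-component removal for noise spikes.
4. **Fusion.** `I_fused = w_d·[w·I_MV + (1−w)·I_KV] + (1−w_d)·I_KV`.
   The relative deviation R = |I_KV − I_MV| / |I_KV + I_MV| (denominator
   replaced by 1 where it vanishes) drives a clamped linear ramp
   w: 0 below R_lo = 0.05, 1 above R_hi = 0.40. The distance weight w_d is
   a Gaussian low-pass of the binary metal mask rescaled to 1 on the metal.
   R is computed on the calibrated pseudo-kV MV image, not raw MV HU.
5. **Prior.** The fused image with the metal region — the union of the MV
   metal mask and a 3000 HU threshold of the fused image itself — set to
   water (0 HU). The union guarantees the prior contains no metal-valued
   pixel even where detector blur makes the MV mask a little tight.
6. **Trace replacement.** The metal trace is the set of sinogram bins whose
   metal path length exceeds half a pixel diagonal (suppressing unstable
   grazing rays). Per-view runs of trace bins are replaced independently by
   the prior's projection plus a linear blend of the two boundary offsets,
   which makes the corrected sinogram exactly continuous with the measured
   data at both ends of every segment; bins outside the trace are
   bit-identical to the input. Segments touching a detector edge fall back
   to a one-sided constant offset.
7. **FBP and metal re-insertion.** Ramp filter by default (Shepp-Logan and
   Hann available); metal pixels take the registered MV image's values (a
   fixed HU can be configured instead — the alternative reading of "the
   segmented metal portion was added").

### Baselines

* **LIMAR**: linear interpolation across each trace segment of the kV
  sinogram (algebraically identical to trace replacement with a zero
  prior); metal re-inserted from the thresholded kV image.
* **NMAR**: the kV sinogram is divided by the (ε-floored, ε = 10⁻²)
  sinogram of a prior, the normalized trace is interpolated as in LIMAR,
  and the result is multiplied back. The classic prior is built from the
  LIMAR image by flattening air (< −500 HU) and soft tissue (−500…500 HU)
  to their class means, keeping denser pixels as-is. With a constant prior
  sinogram NMAR reduces exactly to LIMAR.
* **NMAR-MV**: NMAR with the registered pseudo-kV MV image as the prior
  and as the metal source. Because the MV prior carries the true metal
  structure, this is the only baseline that recovers internal metal detail.

## The scanner simulator

The simulator exists so that every stage is testable against ground truth
without scanner data. It emulates, per detector bin,
I = Σ_E S(E)·N₀·exp(−∫μ(E)dl), Gaussian detector blur along the bin axis,
Poisson counting noise (seeded, bit-reproducible), clamping of counts below
0.5 before the log (photon starvation), and FBP at the spectrum's effective
energy. Attenuation uses a two-term model
μ(E)/ρ = a·(E₀/E)³ + b·kn(E)/kn(E₀) (photoelectric-like plus
Klein–Nishina), with (a, b) solved from two anchor points per material so
water is ≈ 0.19 cm⁻¹ at 70 keV and steel's kV attenuation is ~17× its MV
attenuation.

The default phantom mirrors the verification experiment: a 24 cm water
body, a stainless-steel ellipse (4.97 × 3.58 cm, ρ = 7.8 g/cm³) with a
centered 1.81 cm air bore, and tissue rods on the center lines. Study
conditions (defaults):

| parameter | kV scan | MV scan |
|---|---|---|
| spectrum | 120 kVp: {45 keV: 0.25, 60: 0.45, 80: 0.25, 100: 0.05} | single 1.5 MeV line |
| photons/bin N₀ | 1×10⁵ | 8×10³ |
| detector blur | none | 1.5 mm σ |
| views | 180 over 180° | 180 over 180° |

These values were chosen so the simulation reproduces the qualitative
physics the method is designed for, and then frozen: the kV scan loses the
bore completely (hole-region mean ≈ 5100 HU, every hole pixel above the
3000 HU metal threshold), shows a > 100 HU mean deficit in a 1 cm band
along the long axis and a > 100 HU mean excess along the short axis, while
the MV scan resolves the bore at ≈ 2.3× the kV noise in uniform water.
The default working grid is 256² at 1.18 mm (same 30.2 cm field of view as
the 512² × 0.59 mm scans it mimics; 512² is supported but 256² keeps a
full study under a minute on one core). Unit tests use 64–128² grids.

What the simulator does **not** model: scatter, detector afterglow, bowtie
filtration, realistic tube spectra, fan/cone geometry, 3D effects. Passing
tests therefore demonstrate the algorithm's behavior under idealized
parallel-beam physics with beam hardening, starvation and Poisson noise —
not clinical performance.

## Numerical choices

* **Distance-weight reach.** `gaussian_sigma` defaults to 60 mm. The right
  scale for σ is the spatial extent of the artifacts, because the prior's
  surrogate quality depends on the fused image along the *entire* length of
  every metal-crossing ray, not just near the metal: with a short reach the
  kV streak content far from the implant re-enters the surrogate data and
  caps the achievable correction. Under the simulated study conditions the
  streaks span most of the body, and σ = 60 mm brings the artifact-band MAE
  reduction from ~25–40 % (σ = 10 mm) to ~55–65 %. For data whose artifacts
  are confined close to the metal a smaller σ preserves more kV detail;
  the parameter is exposed in `FusionConfig`.
* **Trace ε** = half a pixel diagonal of metal path; **NMAR ε** = 10⁻² on
  the prior sinogram; **count floor** = 0.5 counts.
* **Zero denominators** in the relative deviation and the
  percentage-difference map are replaced by 1 (keeps both finite; the
  percentage map is signed so bright and dark artifacts are
  distinguishable).
* **Even-grid centering.** The projector rotates about pixel n//2; on
  even-sized grids that is half a pixel off the phantom center, which is
  irrelevant for round trips (projector and FBP share the convention) but
  matters for rotational-symmetry checks, which use odd grids.
* **Degenerate inputs.** Empty metal mask ⇒ every MAR variant reduces to
  the plain FBP round trip of its input sinogram and the distance weight is
  identically zero (with a warning). Duplicate calibration abscissae raise
  a degenerate-fit error; < 2 rods cannot define a curve.

## Evaluation

Artifact regions are derived geometrically from the phantom: 1 cm-wide
bands along the metal's long and short axes (metal plus a 2 mm margin
excluded, bone/adipose rods included since errors are measured against
truth), the slightly eroded bore disk, the metal annulus, and a far-field
annulus. Region statistics are MAE / mean signed error / max |error| in HU.
The headline "artifact-band MAE" is measured on the union of the two axis
bands. Line profiles through the phantom center expose the bore plateau
and the steel span; percentage-difference maps are exported unclipped.

## Known limitations

* 2D parallel-beam only; no dose calculation (CT-number accuracy is the
  endpoint here).
* The fused prior inherits MV quantum noise inside the trace; the residual
  artifact-band error after correction is dominated by that noise floor.
* The MV→kV calibration is fitted on rods up to bone density and linearly
  extrapolated ~10× beyond for steel; pseudo-kV metal values are therefore
  approximate (they only steer segmentation and re-insertion, not the
  trace surrogate).
* Metal segmentation under MV detector blur biases the mask area a few
  percent low at thin metal tips.
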