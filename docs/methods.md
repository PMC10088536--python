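# Methods

`ebusdepot` quantifies how an intratumorally injected drug bolus appears,
grows and is retained in B-mode endobronchial ultrasound (EBUS) video, and
weighs two candidate physical mechanisms for how the tissue accommodates
the fluid. This note records the models, the defaults and why, the design
choices that were genuinely open, and what the synthetic benchmarks do and
do not demonstrate.

## Observables and screening

The injected drug is hyperechoic, so its arrival brightens the image. Two
scalar traces are computed:

* **ROI percent variation.** With `I_t` the mean intensity of a 1 cm x 1 cm
  region of interest centered on the manually annotated needle tip, and
  `I_0` that of the first frame,

      dI(t) = 100 (I_t - I_0) / I_0 .

  The trace is smoothed with a centered 1-s moving average, which strongly
  attenuates heartbeat modulation (at the 1.2 Hz default the residual
  amplitude is ~16% of the input). A video enters the analysis only when
  the smoothed trace rises *strictly above* 20%; ties at exactly 20% are
  excluded. When the needle tip is not visible in a recording, the tip and
  axis can be inherited from the previous injection of the same
  intervention (`inherit_needle_tip`, flagged as such).

* **Cone-mean uptake.** After subtracting the background — the pixel-wise
  mean over the 1 s immediately preceding injection onset `t0` — the mean
  intensity over the imaging cone is fit from onset with the
  exponential-plateau law

      mu(t) = c + a (1 - e^{-b t}) ,

  by constrained nonlinear least squares (`a >= 0`, `b > 0`;
  `scipy.optimize.curve_fit`, initialization `c0` = first sample, `a0` =
  last minus first, `b0 = ln 20 / (T/2)`, multi-start over `b0 x {0.2, 1, 5}`
  on failure). R^2 is reported on the raw (unsmoothed) trace. The
  injection duration is defined as the time for the model to reach 95% of
  its asymptote above the offset,

      dt = ln(20) / b ,

  which is the only offset-independent reading of "95% of plateau", and the
  constant-rate flow estimate is `Q = injected volume / dt`. Injected
  volumes are a required annotation input; they cannot be inferred from
  video.

If the annotation lacks `t0`, onset is detected as the first time the
smoothed ROI trace exceeds 5% and holds for 1 s, backtracked to the
preceding local minimum — an explicit, testable rule for what clinicians
mark implicitly.

## Segmentation

Per post-onset frame: (1) background subtraction with negative residuals
clamped to zero (the depot is brighter than tissue); (2) Perona-Malik
anisotropic diffusion (10 iterations, step 0.2, exponential conductance
with K set per image to the 90th percentile of gradient magnitudes) — an
edge-preserving speckle filter implemented in-package; (3) a two-class Otsu
split over within-cone intensities; (4) morphological closing with a
0.05 cm disk (about one speckle cell) followed by hole filling; (5)
retention of only the connected components that touch the 1 cm x 1 cm
needle-tip window, since the depot forms at the tip and distant bright
artifacts should not inflate its area.

**Noise floor.** Otsu always produces a split, even on unimodal noise, so a
frame is declared depot-free when the between-class variance at the chosen
threshold is below 1.2e-3 (normalized intensity squared). The value was
calibrated on the phantom's depot-free condition: at the default speckle
level (CV 0.3) noise-only frames reach ~9e-4 while frames holding a depot
of at least 0.05 cm^2 stay above ~1.5e-3 across the benchmark conditions,
so the floor sits inside that gap. It is a recorded, overridable parameter;
at substantially different noise levels it should be re-calibrated the same
way.

## Shape and retention

Geometry is expressed in a needle-centered frame: origin at the tip, X-axis
along the insertion direction, Y-axis 90 degrees counterclockwise from X in
image coordinates (right-handed with the row axis pointing down — the sign
convention is fixed so signed lateral centroid paths are reproducible).
Per frame the area centroid, the minimum/maximum Feret (caliper) diameters
(convex hull of pixel centers; max = hull diameter, min = smallest width
over hull-edge normals; no half-pixel boundary correction, a documented
sub-pixel bias), and the area are reported; empty masks yield missing
values rather than zeros, because zero is a legitimate centroid coordinate.

Retained volume is the solid of revolution of the final-frame depot about
the needle axis, computed by **two-sided Pappus**: the y > 0 and y < 0
parts each contribute `2 pi |y_centroid| A`, summed per pixel. This stays
well defined for depots deflected off the needle axis and reproduces closed
forms for axis-adjacent shapes (a half-disk of radius r on the axis gives
the full sphere `4/3 pi r^3`). A column-run washer integration serves as an
independent numerical oracle in the tests. Retention percent is
`100 x rotation volume / injected volume`; the complement is the volume
estimated to have escaped the imaged plane.

## Physical mechanisms

* **Darcy porous flow.** With constant volumetric rate Q and spherical
  symmetry about the tip, Darcy's law gives `P(r) = Q / (4 pi K r)`.
  Requiring `P(R) = P_i` at the depot radius R (beyond which flow ceases)
  yields `K = Q / (4 pi R P_i)`. Defaults: Q = 0.4 mL/s (the lower limit of
  the fitted flow rates), P_i = 10 mmHg, R in 0.1-1 cm from the observed
  Feret diameters, giving K in 3.2e-3 to 3.2e-2 cm^2.mmHg^-1.s^-1. The
  literature comparison value defaults to 3.1831e-7 cm^2.mmHg^-1.s^-1 — a
  representative tumor-interstitium conductivity consistent with the 4-5
  orders-of-magnitude excess this estimate produces — and is always
  user-overridable. Porous flow is ruled implausible when the *minimum*
  excess is at least 3 orders of magnitude (conservative relative to the
  observed 4-5; configurable).

* **Tissue fracture.** The needle track seeds a crack that injection
  pressure can propagate. The steady-state tunneling threshold for a crack
  of width h in a material of modulus E and mode I toughness Gamma is taken
  as

      sigma_th = sqrt(pi E Gamma / (2 h)) .

  The prefactor (pi/2 under the root) and an optional plane-strain
  correction `E/(1-nu^2)` are exposed as configuration, since the exact
  constant of the tunneling analysis depends on geometry assumptions that
  cannot be pinned down; the default reproduces ~127 kPa for the
  micro-crack regime (E = 25 kPa midpoint, Gamma = 330 J/m^2, h = 800 um)
  and ~114 kPa for the macro-crack regime (Gamma = 3.3 kJ/m^2 midpoint,
  h = 1 cm). Injection stress is obtained by linear pressure-flow scaling
  of two published reference measurements (30 kPa at 0.05 mL/s; 300 kPa at
  0.4 mL/s), giving 240-300 kPa at 0.4 mL/s. Fracture is deemed plausible
  when the minimum injection stress exceeds the larger regime threshold.
  Darcy quantities are kept in cm/mmHg/s units and fracture quantities in
  SI/kPa; conversions are centralized (`ebusdepot.units`) so the two
  systems never mix implicitly.

The per-injection report (`pipeline.analyze_video`) drives the Darcy
estimate with the injection's own fitted Q (floored at 0.4 mL/s) and its
observed Feret range; the two mechanisms are *not* differentiated further
(macro-crack vs. micro-crack percolation cannot be resolved at EBUS
resolution).

## The phantom generator

`simulate.simulate_video` renders what the analysis needs to see, not
acoustics: no RF/point-spread simulation, no 3-D. A fan-shaped cone
(apex at the transducer, 70 degrees, radius 5.5 cm) holds a uniform tissue
level (0.25) plus a bright needle line; inside the cone each frame is
multiplied by unit-mean gamma speckle whose CV is `speckle_scale` (0.3
default — a first-order model of log-compressed B-mode speckle) and by a
sinusoidal heartbeat factor (1.2 Hz, 5% default, chosen to exercise the 1-s
smoothing). Frames are kept in [0, 1] internally and only quantized to
8-bit on export, so tests are free of quantization effects. The default
frame rate is 30 frames/s, a typical clinical video rate; acquisition
parameters of real scanners vary and are read from the annotation/sidecar
instead of being assumed.

The depot is an ellipse (aspect 2:1) anchored at the needle tip and
elongating along the needle axis; an optional deflection angle tilts its
axis to reproduce off-axis spreading phenotypes. Its size is driven so
that:

* the final-frame ellipse, revolved about the needle axis, has exactly
  `true_retention x injected_volume` — the scale is solved from a
  continuous-geometry quadrature independent of the analysis code;
* earlier frames scale as the square root of the kinetic curve, so the
  noiseless cone-mean trace follows `c + a (1 - e^{-b(t-t0)})`; a per-frame
  brightness correction (target area over realized pixel count) removes
  pixel-discretization error, making the noiseless trace exact to float
  precision.

Ground truth (per-frame masks, noiseless trace, `dt = ln 20 / b`, retention
fraction) is returned alongside the video. Configurations that demand a
depot larger than the cone, or brighter than the displayable headroom, fail
loudly naming the conflicting parameters.

**What the phantom does not emulate:** depth-dependent attenuation and
focus, anisotropic speckle correlation, reverberation/shadowing artifacts,
tissue motion other than a global heartbeat factor, irregular (non-elliptic)
depot shapes, and out-of-plane depot growth. Passing the benchmarks
therefore shows the pipeline recovers known truth under controlled,
idealized imaging — not that it meets the same accuracy on clinical video.

## Benchmark problem sizes

Chosen as compact standard conditions for single-CPU runs and recorded here
as package choices:

* **Kinetics recovery:** 200 replicate traces per rate constant
  `b in {0.06, 0.15, 0.6} /s` (durations `ln20/b` ~ 50, 20, 5 s, spanning
  the observed range), 60 s at 30 frames/s, Gaussian noise with SD 5% of
  the amplitude. Pass: >= 95% of replicates recover the duration within
  10%.
* **Segmentation:** 20 videos, 160 x 160 px at 40 px/cm, 10 frames/s,
  10 s, mixed deflections (0, +-10, +-20 degrees) and kinetics; median
  per-frame Dice vs. truth >= 0.8 at default noise (>= 0.95 noiseless),
  scored only on frames whose true depot area is at least 0.05 cm^2 (below
  that, a mask of a few dozen pixels makes Dice numerically meaningless).
* **Retention recovery:** full pipeline on phantoms with true retention
  5, 10, 15% of 8 mL; estimate within +-5 percentage points and below 20%.

## Numerical choices and degenerate inputs

* Even-sized ROIs put the tip at index `floor(side/2)` (tie toward
  top-left); all pixel geometry is 0-based (row, col), origin top-left.
* Moving averages use shrinking windows at the edges, so constants are
  preserved exactly.
* Otsu thresholds come from `skimage.filters.threshold_otsu` (256-bin
  histogram); an exhaustive cut-point search is kept as a test oracle.
* `fit_uptake` flags fits that end on the `b > 0` constraint boundary;
  non-convergence after the multi-start raises with diagnostics rather than
  returning a silent default.
* Degenerate inputs fail with named errors: zero-mean reference frame in
  dI(t), empty cone mask, onset at the last frame, background window longer
  than the pre-onset lead-in, empty final mask in retention.
* Cone masks for clinical-style inputs are estimated by thresholding the
  temporal maximum image at 2/255 and keeping the largest connected
  component; synthetic videos carry their exact cone in the sidecar.

## Known limitations

Single-plane rotation volume assumes approximate axial symmetry of the
depot; no uncertainty is attached to the retention estimate. The uptake
model is the single inverted exponential — no bi-exponential or sigmoidal
alternatives, and no model selection. Segmentation is classical (filter +
threshold + morphology); no learned models. The mechanism layer is
order-of-magnitude reasoning with ranged inputs, not a poroelastic or
fracture simulation.
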