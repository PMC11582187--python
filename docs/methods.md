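# Methods

`gelstrain` couples two computational pieces of cardiac-patch engineering: a
linear-viscoelasticity and formulation-design toolkit for dynamic-bond
hydrogel patches, and a segmental circumferential-strain analysis for
short-axis left-ventricular (LV) wall contours. This note records the models,
the numerical choices, and what the synthetic generators do and do not
emulate.

## Viscoelastic model

The patch material is a generalized Maxwell solid with no equilibrium mode:
a set of modes `(G_i, tau_i)`, each a stiffness in Pa and a relaxation time
in seconds, giving

    G(t)   = sum_i G_i exp(-t/tau_i)
    G'(w)  = sum_i G_i (w tau_i)^2 / (1 + (w tau_i)^2)
    G''(w) = sum_i G_i (w tau_i)   / (1 + (w tau_i)^2),   w = 2*pi*f.

All dynamic-covalent crosslinks exchange, so stress relaxes toward zero; an
infinite-time mode would model a permanent network and is deliberately
absent. Frequencies are hertz everywhere in the API; angular frequency is
internal. Spectra keep their modes sorted slowest-first and refuse
relaxation times equal to within relative 1e-9, which would be an
unidentifiable reparametrization of a single mode.

**Gel point.** The gel point `(f_GP, G_GP)` is the crossover `G' = G''`:
below it the network flows on the deformation time scale, above it it
responds elastically. `find_gel_point` locates the single sign change of
`log(G'/G'')` across a sampled sweep and interpolates linearly in
`log f`-`log G` between the bracketing samples. For a single mode
`G'/G'' = w*tau` exactly, so the frequency is recovered to machine precision
at any sampling density; the modulus converges quadratically with grid
spacing (about `h^2/8` in relative terms for log-spacing `h`), which is why
the 1e-6-level checks in the test suite sample sweeps at 4000 points over a
+/-1.3-decade window. Multiple sign changes raise an error carrying every
bracketing pair rather than silently picking one: a measured gel in this
family shows a single crossover, so multiplicity signals a bad measurement
or a pathological spectrum.

**Relaxation fitting.** `fit_relaxation` fits a Prony series by
`scipy.optimize.least_squares` on log-parameters (positivity and scale
freedom for free), initialized with times log-spaced across the observed
window and weights `G(0)/n_modes`. Residuals are relative,
`(model - data)/data`, because rheometer error is multiplicative — this is
the matched estimator for the lognormal noise the generator produces and it
keeps the small fast-mode tail from being swamped by the initial modulus.
Data whose late-time mean is at least 99 % of the early-time mean are
rejected as non-decaying. The *characteristic relaxation time* reported is
the stiffness-weighted mean `sum(G_i tau_i)/sum(G_i)`; the literature for
two-mode fits does not fix a convention, and the weighted mean is the
zero-shear-viscosity-consistent choice (`eta_0 = G_0 * tau_char`).

Identifiability sets a real floor here: for the reference pair
(800 Pa, 10 s) + (200 Pa, 0.5 s) sampled at 10 Hz over 50 s with 1 %
multiplicative noise, the fast time carries ~4.6 % relative standard error
at the information limit, independent of estimator. The recovery studies
therefore sample at 50 Hz (2500 points over 50 s), emulating an instrument
recording continuously through the relaxation window; there the fast time is
recovered within 5 % in ~97 % of replicates.

**Stress simulation.** `simulate_stress` evaluates the Boltzmann
superposition integral `sigma(t) = int G(t-s) de/ds ds` for strain histories
piecewise linear between samples. On each interval the integral is closed
form per mode, so the update is an exact exponential integrator: no
quadrature error, exact degree-1 homogeneity in strain, and a step strain
reproduces `eps0 * G(t)` identically. `cycles_to_convergence` reduces a
cyclic stress record to per-cycle peak magnitudes and returns the first
(1-based) cycle from which successive peaks change by less than a relative
tolerance, flagging non-convergence instead of guessing.

## Formulation calibration and design

The hydrogel has two independent experimental handles. The ratio of the two
boronate chemistries — FPBA (slow exchange) versus PBA (fast exchange)
crosslinking to dopamine catechols — sets the gel-point frequency between
the pure-component crossovers, 0.3 Hz (pure FPBA-DA) and ~6 Hz (pure
PBA-DA, treated as exactly 6.0 with the tilde recorded in metadata). The
gelatin weight fraction sets the gel-point modulus (1.3 kPa at 15 wt%,
2.5 kPa at 20 wt%) without moving the frequency. `default_calibration`
stores exactly these published design-point knots; no molecular model is
invented to go beyond them.

`predict_gel_point` interpolates frequency with a monotone piecewise-cubic
(PCHIP) on `(fraction, log f)` — it passes through every knot, cannot
overshoot, and preserves strict monotonicity, which with only four printed
points is everything one can defend — and modulus linearly between its two
knots. The interpolation hull is `fraction in [0, 1]` by
`wt% in [15, 20]`; outside it the estimate is clamped and a warning issued
(or an error in strict mode). The gelatin fraction producing the advertised
0.5 kPa lower bound is not published, so the modulus hull stops at 15 wt%.

`formulation_to_modes` realizes a recipe as an explicit two-mode spectrum —
one mode per bond population — whose numeric crossover lands on the
calibrated gel point. Mode times start at the pure-component values
`tau = 1/(2*pi*f)` and only the weight split is solved (Brent root finding
on the crossover condition, which is scale-free in total stiffness); the
total stiffness is then scaled to put the crossover modulus on target. Two
modes separated by the full factor-20 time ratio, however, cannot present a
*unique* crossover at targets near the geometric middle of the range (about
1-2 Hz): the loss hump of the fast mode re-crosses the storage plateau of
the slow one and three crossings appear, which no measured gel in this
family shows. Where that happens the construction compresses both mode
times geometrically toward `1/(2*pi*f_GP)`, taking the largest time spread
that still yields a unique crossover (bisection with a 2 % margin off the
tangency). Physically this encodes that bond exchange in the mixed network
narrows the relaxation spectrum relative to the pure components. At
fractions 0 and 1 the construction collapses exactly to the single
pure-component mode.

`match_formulation` selects a recipe for a heart specification (myocardial
modulus, wall and graft thickness, heart-rate band, species). The
theoretical model linking wall mechanics to an optimal patch modulus is not
published alongside the design points, so the matcher refuses to invent it:
the target modulus comes from a species-keyed table of the two published
design points (rat and pig), with nearest-band-midpoint fallback for
unlisted species and support for explicit candidate recipes. Bands that
miss the calibrated 0.3-6.0 Hz range, or targets outside the tunable
0.5-2.5 kPa window, raise typed errors.

## Strain mapping

The LV wall contour of each cine frame is reduced to 24 per-segment
circumferential strains: the classic 6-segment short-axis scheme, each
segment split in four. Design choices, in order of consequence:

* **Eulerian angular bins.** Segments are fixed equal-angle sectors about
  the reference-frame centroid, not material-tracked wall patches. The
  analysis needs no speckle tracking, and the synthetic ground truth is
  analytic in this frame. Published segmental analyses that track tissue
  will differ in the transition zones.
* **Reference frame and centroid.** The reference is end-diastole (maximal
  polygon area, ties to the earliest frame); the centroid is the area
  centroid of the reference contour and is reused for every frame, so a
  rigid translation of the whole cine moves the bins with it and strains
  are unchanged.
* **Mid-wall line.** With paired endo- and epicardial contours the analyzed
  curve is the point-wise mid-wall line (ray-cast at equal angles about the
  endocardial centroid). Which surface published echo analyses trace is
  usually unstated; mid-wall is the least-committal default, and a single
  supplied contour is used as-is.
* **Resampling.** Contours are resampled to 360 equal arc-length points
  before cutting; this stabilizes the ray geometry without smoothing.

`segment_arc_lengths` walks the contour once, splitting every edge exactly
where it crosses a sector-boundary ray (true ray-segment intersections), so
the 24 lengths sum to the polygon perimeter to machine precision on every
frame — conservation is structural, not approximate. A contour that crosses
some boundary ray more than once is not star-shaped about the centroid; in
strict mode (the default for the bare function) this raises `NonStarShaped`.
The cine pipeline runs tolerant instead: echocardiographic point noise
produces small local zigzags that are physically still wall, and every piece
of contour is credited to the sector it traverses. A centroid not enclosed
exactly once by the contour (winding number != 1) is always an error.

Strain is the published arc-length ratio per segment,
`(l_current - l_reference)/l_reference * 100` (negative = contraction,
positive = passive stretch); the boundary differential is the circular
absolute difference of adjacent segments; the headline scalar is its
maximum over all non-reference frames. Per-frame strain is reported for the
whole cycle, with end-systole (minimal area) exposed as the peak-strain
convenience.

## Synthetic generators

All generators are pure functions of `(parameters, seed)`; moduli get
unit-mean multiplicative lognormal noise of prescribed coefficient of
variation (positivity, signal-proportional error), contour points get
additive isotropic Gaussian noise.

The LV phantom is a mid-wall ring, radius `r(theta, t) =
R (1 + eps(theta) s(t)/100)`, with `s(t)` a raised-cosine pulse (0 at
end-diastole, 1 at end-systole — hit exactly when the frame count is even)
and `eps(theta)` the peak-strain profile: healthy peak strain (default
-20 %) outside the infarct arc, infarct strain (default 0) inside, cosine
blend over an optional transition rim. The infarct arc is open at its
edges, so for a sharp-edged phantom the radial step wall belongs to the
infarct-side sector and the peak strain differential lands exactly on the
border boundary. Defaults are rat scale (R = 3.5 mm, 4 Hz, 20 frames, 240
points); `pig_phantom` rescales to 25 mm at 1.3 Hz.

The ground truth records the bin average of `eps(theta)` per segment —
exact wherever the profile is locally flat, because imposed radial scaling
equals circumferential scaling there. Where the profile varies with angle
(transition rims, sharp edges) the real arc length acquires a
`sqrt(r^2 + (dr/dtheta)^2)` contribution that pure radial scaling ignores;
the measured strain in those segments is systematically above the bin
average (about +9 percentage points for a 30-degree rim at -20 % strain),
and the sharp-edge step adds a finite wall length at the border. The test
suite checks transition segments against an independent arc-length
quadrature of the analytic profile rather than against the bin average.

What the phantom does not emulate: B-mode speckle, out-of-plane motion,
3-D ventricular geometry, twist, and material (tracked-tissue) strain.
Passing the recovery suites demonstrates the analysis pipeline is correct
for star-shaped, radially deforming walls with point noise — not that it
reproduces clinical speckle-tracking output.

## Study conditions used by the acceptance checks

Design points are evaluated straight from the calibration (exact
arithmetic); endpoint frequencies are cross-checked through the
spectrum-construction + crossover-search route at 4000 sweep points.
Randomized crossover checks use 100 single-mode spectra with times spanning
1e-3 to 10 s. Relaxation recovery runs 100 seeded replicates of the
reference two-mode pair at 1 % noise on the 50 Hz grid. Border
localization runs 100 seeded replicates of the 90-degree rat-scale infarct
phantom at 0.035 mm point noise (1 % of radius), scoring a hit when the
argmax differential boundary is within one boundary of a true border. The
full suite runs in well under a minute on one core.

## Known limitations

* The calibration is an interpolation of four frequency knots and two
  modulus knots; between knots it is a smoothness assumption, not a
  measurement, and extrapolation beyond the hull is refused rather than
  modelled.
* The two-mode spectrum construction reproduces the calibrated crossover
  but is not fitted to full measured sweeps; its off-crossover shape is a
  model choice.
* Strain segments are angular bins about a fixed centroid; strongly
  translated or non-star-shaped ventricles (severe aneurysm) violate the
  geometry and are reported as errors rather than analyzed.
* The quantification formulas (TUNEL fraction, circumferential infarct
  percentage, minimum wall thickness) consume counts and traced contours;
  image segmentation upstream of them is out of scope.
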