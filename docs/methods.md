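# Methods

## Scope and shape of the package

The package is organised as an analysis project: every computation lives in
`src/dropwet/` (importable, unit-tested), while the numbered scripts under
`analysis/` are thin narrative drivers that run the study on synthetic data
and write tables under `results/`. No instrument data ships with the
package; the synthetic module generates every input with exact ground
truth, which is what makes the whole chain testable by round-trip.

## Young–Laplace shapes (`drop_shape`)

The axisymmetric sessile-drop profile is integrated in arc length from the
apex with the singular term handled by its series limit (dφ/ds → b at
s = 0; the integration starts at a reduced offset of 1e−8 with the
corresponding series values). Internally the system is non-dimensionalised
by the apex curvature, so gravity enters only through C = c/b², which keeps
the integrator well conditioned for every drop size. Drop volume and
cross-section area are carried as extra quadrature states, so metrics need
no post-hoc integration. Depth below the apex is the internal vertical
coordinate; conversion to height above the substrate happens at the module
boundary. Gravity is fixed at 9.81 m/s² (all experiments are at 1 g, no
tilting); passing `gravity=0` gives the spherical-cap limit, which the
tests use as a closed-form oracle (agreement ≤ 1e−4 relative).

A physical note: at *equal apex curvature* hydrostatic pressure makes the
tangent angle turn faster, so the drop truncated at a given contact angle
is *smaller* than the zero-gravity cap; "gravity flattens the drop" is a
statement at *equal volume*, where the solved shape is wider and lower.
Both signs are asserted by brute-force integration in the tests.

The inverse problem (`solve_for`: find b for a target volume and contact
angle) brackets b around the spherical-cap inverse and refines with Brent's
method to 0.1% in volume.

## Synthetic scenes (`synthetic`)

The generator renders dark drops (dye-stained, intensity 25) on a light
background (230) above a darker substrate band (80), origin top-left, with
the substrate surface on the boundary between the last air row and the
first substrate row. Silhouettes are rasterised by an analytic scanline
fill with 4× row supersampling, so edge pixels carry fractional coverage
and the true boundary is recoverable to subpixel precision; the rendered
cross-section area matches the analytic one to well under one pixel per
boundary pixel. Noise is additive Gaussian on intensity, clipped to 0–255;
no speckle — the simplest model that exercises subpixel edge detection.
Identical seeds give bit-identical frames (all randomness flows through
`numpy` generators keyed on the scene seed and frame index).

Study conditions baked into the defaults: 35 µL drops at 40° static
contact angle; evaporation sampled every 300 s with exactly affine
volume decay (pinned mode holds the contact radius and lets the angle
fall; depinning mode pins until the angle reaches a threshold, default
25°, then holds the angle and shrinks the length); rotation ramps of
1 rpm/s to 100 rpm with one frame per rpm, advancing plateau 53° reached
at 40 rpm, receding plateau 15°, sliding at 50 rpm (or a permanently
pinned rear). No particular camera resolution is assumed — the pixel scale
is a free scene parameter; the default is 0.015 mm/px with finer scales
used for shallow drops so flank fits retain enough near-baseline samples.

Asymmetric drops and ramp frames are rendered as a two-arc composition:
each flank is a circular arc sharing the apex height, with the height
fixed in closed form by the footprint length, h = L/(cot(θ_l/2) +
cot(θ_r/2)). A gravity-corrected asymmetric Laplace shape would require
the tilted-drop equation, which is outside this package's scope; the ramp
analysis consumes only angles, edges and lengths, for which the arc
composition is exact ground truth. Frame-to-frame volume along a ramp is
therefore a derived quantity of the kinematic targets, not a conserved
one; the frame-0 volume is the configured drop volume. The default ramp
edge-advance rate is 0.25 mm/rpm, an elongation of a few millimetres over
the spreading phase, comparable to the measured length curves.

Cell fields place 3:1 ellipses ("rod-shaped" cells without flagella)
uniformly at random per channel with a 2 px exclusion margin; drawn pixel
areas are rejection-sampled into the configured 10–30 px² range so
ground-truth counts are exact by construction. What the generator does
*not* emulate: optical blur, uneven illumination, out-of-focus z-content,
overlapping/clustered cells beyond simple contact, reflections and
meniscus optics, motion blur. Passing tests therefore demonstrate
correctness of the estimators on well-posed inputs, not robustness to
every artefact of real microscopy or goniometry.

## Image measurement (`imaging`)

The baseline is the row maximising the horizontally integrated absolute
vertical intensity step (mean |row-to-row difference| per column, ties to
the bottom-most row, failure below a 10-intensity-unit prominence). The
row-mean gradient was deliberately avoided: a wide drop can make its own
apex the strongest row-mean step, while a substrate edge always dominates
the per-column integrated magnitude.

The droplet is the largest dark connected component touching the baseline
after Otsu thresholding of the above-baseline region. Flanks are traced
one subpixel crossing per row by linear interpolation of the intensity
through the threshold (for an antialiased edge the coverage profile is an
S-curve whose mid-level crossing sits on the true boundary, so
interpolating at the Otsu level — close to mid-grey — is nearly unbiased);
the apex region is completed by per-column crossings restricted to
z > 0.5 h, where column-wise interpolation is the accurate family. Mixing
both families everywhere was measured to bias the flank fit by several
degrees; the split keeps the round-trip angle error at ~0.05° noiseless
and ~0.2° at noise_sd = 5/255.

Contact angles use the conventional polynomial-goniometry estimator: a
quadratic r(z) fit per flank over points with z ≤ 0.15 h (configurable),
tangent evaluated at z = 0, measured through the liquid; at least 10
points per flank are required, otherwise the estimator refuses rather than
extrapolate (choose a finer pixel scale or a larger height fraction for
very shallow drops). Contact points, edges and length come from the same
fit at z = 0. Top-view footprints are closed marching-squares contours at
the Otsu level, smoothed by a 5-point circular moving average to suppress
grid zigzag (which otherwise inflates the perimeter by ~2.5%); area is by
the shoelace formula. Units are mm and degrees at every interface; pixels
are internal.

## Volume fitting (`profile_fit`)

The measured profile is symmetrized (left/right radii averaged on a common
height grid about the endpoint midpoint) before fitting, which is the
declared reconciliation of the axisymmetric model with sometimes
asymmetric drops; the RMS misfit is reported and the result is flagged
non-axisymmetric above 5% of the drop height. The objective is the RMS
*horizontal* distance at matched heights — well defined for single-valued
flanks, which covers all angles in this study (≤ ~55°). The apex curvature
is searched by a coarse geometric scan bracketing the spherical-cap
estimate followed by golden-section refinement; everything is
deterministic. The contact angle is not pinned: it is implied by the
truncation at the measured height and reported as `theta_implied_deg` for
comparison with the goniometric value. Round-trip accuracy: 0.03%
noiseless, ≤ 0.5% at noise_sd 5/255 — far inside the 1%/5% contract.

## Evaporation kinetics (`evaporation`)

Volume-vs-time is summarised by OLS; the default fit window is 0–3000 s
because at longer times the measured volume flattens and the linear law no
longer applies; the window is configurable. Zero-variance volumes return
slope 0 with R² = 0 by convention. Depinning is declared when either edge
has retracted inward by more than 2% of the initial length for at least 2
consecutive frames — the threshold sits above the ≤ 2 px round-trip noise
of the edge measurement, and the persistence rule rejects single-frame
jitter. The detector is invariant to uniform translation of all edges.

## Forced wetting (`forced_wetting`)

a_T = (2π·RS/60)²·r exactly; at 100 rpm and r = 0.25 m this is 27.4 m/s².
The tangential Bond number is implemented as Bo_T = ρL²a_T/σ with the
characteristic length defaulting to 1 mm: with L¹ the group is not
dimensionless, so L² is the only defensible reading. Onsets use the same
2%-of-initial-length, 2-frame persistence rule as the depinning detector;
plateaus are frames where the 5-frame sliding-window slope of angle versus
speed is below 0.1°/rpm, and the advancing/receding angles are means over
the post-onset plateau frames. A rear edge that never depins yields
`rs_slide = None` with the receding angle taken from the trailing rear
plateau (the pinned-rear regime of long-evaporated drops; a drop that
disappears from view is treated by the caller as sliding at its
disappearance speed). The retention force is F_s = ρV·a_T with V the drop
volume at the start of the ramp (post-evaporation, configurable) — the
physically meaningful mass at test time. k₁ and k₂ divide the same F_s by
R σ (cos θ_r − cos θ_a) with R the initial and the sliding length, so
k₁L₁ = k₂L₂ holds to machine precision.

## Rheology (`rheology`)

η = K·γ̇ⁿ⁻¹ is fitted by OLS of ln η on ln γ̇ (slope n − 1, intercept
ln K), the field convention and exact on noiseless power laws; at least 4
points spanning ≥ 0.5 decades are required. `classify_newtonian` accepts
|n − 1| ≤ 0.1 by default.

## Viability (`viability`)

Per channel: Otsu threshold → 4-connected components → components above
the upper size bound are split by a watershed seeded from
distance-transform maxima (min seed distance 3 px, seeds ordered
lexicographically by (row, col) so segmentation is deterministic);
objects within 10–30 px² are kept. Components already inside the size
range are never subdivided, which makes counts on non-overlapping fields
exact; oversized blobs the watershed cannot split are filtered out. The
default pixel scale (0.566 µm/px edge) back-derives from 10 px² = 3.2 µm².
Condition comparison is the pooled-variance one-tailed unpaired Student
t-test, significant at p < 0.005 (Welch available behind a flag);
degenerate zero-variance inputs return t = 0, p = 0.5. Under the null the
rejection rate calibrates to ~0.5% over 10⁴ simulated triplicate
experiments.

## Problem sizes and numerical choices

Integration tolerance 1e−9 relative (convergence verified by halving);
inverse solves to 0.1% in volume; volume-fit golden section to 1e−6 in
reduced curvature. Test and acceptance runs use desk-scale problems — 11
frame evaporation series, 101-frame ramps (ground-truth geometry frames
where images add nothing), 10–20 noise seeds, 10⁴ simulated t-tests —
chosen so the full suite completes in well under a minute of CPU per heavy
test while leaving the statistical checks well resolved.

## Known limitations

Single-valued-flank assumptions limit profile extraction and volume
fitting to contact angles up to ~90°; pendant drops, tilted-substrate
asymmetric Laplace shapes and flow-coupled dynamics are out of scope.
The ramp generator's two-arc frames do not conserve volume along the ramp.
Real-image robustness (illumination gradients, reflections, debris) is
untested by construction — the estimator defaults are declared choices,
not reconstructions of the original (unpublished) analysis code.
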