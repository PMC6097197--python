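# Methods

## The perfusion model

The central retina is supplied by terminal arteriolar branches that
point toward the fovea and drained by venules staggered between them.
All flow entering (and leaving) a 2.5 mm diameter circle centered on
the fovea must cross that circle through these vessels, so the macular
supply can be accounted vessel by vessel at the circle:

* per crossing, flow is modeled as plug flow through a circular lumen,
  `Q = k |v| π (d/2)²` with `v` the measured velocity (mm/s) and `d`
  the caliber (µm); in consistent units `Q` is mm³/s, reported ×1000 as
  nl/s. The instrument does not document whether `v` is a
  cross-sectional mean or a centerline speed; `k` (the
  `profile_correction` parameter, default 1.0 = plug flow) exposes the
  choice — `k = 0.5` is the parabolic-centerline interpretation. The
  default is documented, not guessed from data.
* arteriolar flows and venular flows are summed separately; macular
  flow is the arithmetic mean of the two totals. Inflow and outflow are
  physiologically near-equal, and the relative imbalance
  `|A − V| / mean(A, V)` is reported as a per-eye quality diagnostic.
  If one side has no measurable vessel, the other side's total is used
  and the result flagged one-sided (a warning, not an error).
* a vessel whose centerline intersects the circle more than once (a
  chord) contributes exactly once: the intersection nearest the
  centerline endpoint farther from the fovea ("outermost") is retained,
  so a vessel cannot be double-counted as both supply and drain.

The tissue receiving this flow is the inner retina — RNFL, GCIPL, INL
and OPL, the layers containing the retinal capillary plexuses —
integrated over the matching 2.5 mm disc. Perfusion is the quotient:

    perfusion (nl/s/mm³) = macular flow (nl/s) / inner-retina volume (mm³)

## Caliber by FWHM

At each retained crossing the image is sampled along the line
perpendicular to the centerline tangent, at the native pixel pitch with
bilinear interpolation (window half-length 150 µm by default).
Background is the median of the outer 25% of samples on each side —
robust to a neighboring vessel's shoulder entering one tail. Depth is
background minus the profile minimum; the caliper reads the width at
half depth. Two modes:

* `interpolate` (default): the two half-level crossings bracketing the
  minimum are located by linear interpolation between samples
  (sub-pixel). On noiseless Gaussian cross-sections of 20–120 µm at
  pixel scales of 3–15 µm the bias, averaged over sub-pixel alignment,
  stays below half a pixel (the closed form is FWHM = 2√(2 ln 2) σ).
* `pixel_count`: the number of samples below the half level times the
  pitch — the integer-pixel procedure historical tools used; accurate
  to ±1 sample by construction.

Degenerate profiles raise typed errors rather than returning numbers: a
dip shallower than 3× the robust noise SD of the background tails (or a
flat profile) raises `NoVesselError`; a second dip deeper than 60% of
the main depth raises `AmbiguousProfileError`; a half level that is not
bracketed inside the window also counts as ambiguous. The 3× and 60%
thresholds are conventional detection margins, configurable at the call.

## Field-of-view conversion

Velocities measured at the 35° setting (7.3 × 7.3 mm²) are multiplied
by 0.95 (arterioles) or 0.92 (venules) to express them in the 20°
(4.3 × 4.3 mm²) frame; 20° input passes through unchanged and signs are
preserved. Diameters are never converted — they are measured in the
native image and scaled to µm by that image's own mm/px.

## Disc volumetrics

Boundary surfaces arrive as seven depth maps (mm) on the 6 × 6 mm,
128 × 512 raster; layer thickness is the difference of consecutive
boundaries, validated non-negative at every node (violations name the
offending layers). Cells are anisotropic, area (6/128) × (6/512) mm²,
cell-centered, fovea at the grid center by default. The disc mask
subdivides each cell 4 × 4 and weights it by the fraction of subcell
centers inside the circle: on this coarse raster an all-or-nothing mask
mis-estimates the disc area by up to a few tenths of a percent in an
alignment-dependent way, and the fractional mask converges to
π·1.25² mm² as the subdivision grows. Volumes are
`Σ weight · cell_area · thickness` per layer; the inner-retina
composite is the exact sum of its four layer volumes (same mask, same
summation order), the total the sum of all six.

## The synthetic scene generator

The generator provides ground truth for every stage; its defaults are
the study conditions the analysis assumes.

* **Vessel networks.** Arterioles and venules alternate angularly
  around the fovea (staggered), each centerline starting 1.7–2.0 mm
  out, spiraling gently inward with monotonically decreasing radius and
  stopping 0.05–0.25 mm outside a 0.4 mm avascular center — so every
  vessel crosses the 2.5 mm circle exactly once. Calibers are uniform
  30–90 µm (constant along a vessel), velocities −(3.0–4.5) mm/s for
  arterioles and +(2.2–3.5) mm/s for venules before calibration,
  contrasts 0.45–0.7.
* **Rendering.** A vessel is a dark ridge whose cross-section is a
  Gaussian dip with FWHM equal to the true diameter — making the FWHM
  caliper unbiased by construction, which is the point of an oracle.
  Overlaps combine by maximum dip; optional white Gaussian noise is
  added last. Default raster 1024 × 1024 px (≈4.2 µm/px at 20°; the
  source instrument's pixel count is not documented, so the default is
  declared, chosen to resolve 20 µm vessels). The 90 µm default caliber
  ceiling keeps Gaussian tails inside the 150 µm profile window; wider
  vessels need a longer window, which the caliper tests use.
* **Layer surfaces.** Six smooth thickness maps with a Gaussian foveal
  pit (inner layers thinned by 85% at the center, pit radius 0.35 mm;
  the ONL thickens at the fovea as real retinas do), stacked by
  cumulative sum into ordered boundaries.
* **Cohorts.** Per arm, flow, inner-retina volume and GCIPL volume are
  drawn from normal distributions truncated at zero (physical
  quantities are non-negative); perfusion is the drawn flow/volume
  quotient. Default arm parameters are the published group statistics
  (case: flow 2.82 ± 0.92 nl/s, GCIPL 0.47 ± 0.04 mm³, n = 24;
  control: 4.09 ± 0.46 nl/s, 0.50 ± 0.05 mm³, n = 19), with
  demographics (age, sex split 11M/13F vs 10M/9F, MMSE, duration, risk
  flags) matching the published table; categorical counts are exact,
  shuffled by seed. The inner-retina volume distribution is not
  published; its mean is derived as flow mean / perfusion mean
  (1.0930 mm³ case, 1.1298 mm³ control) and its SD set to 0.09 mm³
  (~8% CV, matching the published GCIPL CV).
* **Scene calibration.** Each subject's scene is calibrated so the
  pipeline's ground truth equals the drawn values: velocities (not
  diameters) are scaled per side so the analytic flow through the
  retained crossings equals the drawn flow — velocity is the linear
  knob that leaves geometry untouched — and inner-layer thickness maps
  are scaled so GCIPL and composite inner-retina disc volumes equal
  their draws exactly (volume is linear in thickness).

What the generator does **not** emulate: velocimetry itself (no
stroboscopic frames or red-blood-cell motion — velocities are inputs),
OCT speckle or B-scan texture (surfaces are generated directly), vessel
branching inside the circle, pathology-specific vessel morphology, or
non-Gaussian vessel profiles (real calibers read through red-cell
columns can bias FWHM). Passing tests therefore validate the
measurement chain — geometry, caliper, unit accounting, integration,
statistics — not the upstream instruments.

## Statistics

Group contrasts use the two-sided Student t-test with pooled variance
(`welch` available by flag), means and SDs with the n−1 denominator;
monotone association uses Spearman rank correlation (mid-ranks, the
t-approximation p); 2 × 2 categorical tables use the uncorrected
Pearson χ² (df 1, zero margins rejected). No multiple-testing
correction is applied by default, mirroring the analysis design the
package reproduces. Percent differences are reported relative to the
control mean and rounded half-away-from-zero for display alongside full
precision. These routines wrap scipy.stats; the test suite cross-checks
them against hand-computed formulas.

## Orchestration and reproducibility

`run_pipeline` executes simulate → render → flow → volume → perfusion →
group statistics. A master seed spawns per-subject seeds through
`numpy.random.SeedSequence` (recorded in the run manifest together with
package and numpy versions and the full configuration), so a run is a
pure function of its configuration. Stage failures are re-raised naming
the stage and subject. Arms smaller than five subjects trigger a
low-power warning in the log.

## Problem sizes and tolerances in the shipped checks

The test suite exercises full image-based recovery with 10 subjects per
arm (noiseless, 1024 px renders): per-subject macular flow within 2% of
the injected value and group mean perfusion within 5%. Replicate-level
significance uses 1,000 drawn cohorts at the published perfusion
distributions. Geometry oracles compare exact segment–circle
intersection with dense polyline resampling on 1,000 random networks,
and disc-mask area against the analytic disc to 0.1% on a fine grid.
The acceptance script reproduces these quantities at the published
cohort sizes (24/19).

## Known limitations

* Flow accuracy degrades below ~6 µm/px rendering because the FWHM
  half-level interpolation error grows; the default raster stays finer.
* The plug-flow constant `k` is a model choice; absolute flows scale
  linearly with it, perfusion group *contrasts* do not depend on it.
* Truncated-normal cohort draws shift the realized mean slightly above
  the nominal mean when SD/mean is large; at the shipped parameters the
  shift is ≪1%.
* The generator's inner-volume distribution is an assumption (see
  above); only its mean is pinned by published quantities.
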