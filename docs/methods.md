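# Methods

## The coupled isomer decay model

Mercury-197 exists as a metastable state (197mHg, half-life 23.8 h) and a
ground state (197gHg, half-life 64.14 h). The metastable state decays by
isomeric transition into the ground state with branching fraction
b = 0.914, so the partial transition constant is λ_IT = b·λ_m with
λ = ln 2 / t½. The metastable activity is a pure exponential,

    A_m(t) = A_m(0) · e^(−λ_m t),

and the ground-state activity combines its own decay with grow-in from
the metastable parent. The default (`model="published"`) grow-in term is

    A_g(t) = [λ_IT / (λ_g − λ_IT)] · (λ_g / λ_m) · A_m(0)
             · (e^(−λ_IT t) − e^(−λ_g t)) + A_g(0) · e^(−λ_g t),

the form used for all decay corrections in the imaging and counting
workflow this package reimplements. Note that this expression carries
the *partial* constant λ_IT in both the grow-in exponent and the
denominator. The strict branched Bateman chain — in which the parent
population decays with its *total* constant λ_m and only the branch
fraction feeds the daughter — is available as `model="chain"`:

    A_g(t) = [λ_IT / (λ_g − λ_m)] · (λ_g / λ_m) · A_m(0)
             · (e^(−λ_m t) − e^(−λ_g t)) + A_g(0) · e^(−λ_g t).

The two conventions differ by less than 3% of the metastable
contribution over a 120 h window with the default constants (e.g. for a
pure metastable source of 1 MBq the grow-in at 23.8 h is 0.1515 vs
0.1473 MBq). Two measurable consequences of the published form, both
covered by tests: (1) the integrated ground-state production from a
pure metastable source equals 100% of the parent inventory rather than
the branching fraction 91.4% (which the chain form reproduces exactly);
(2) the pair (A_m, A_g) is not an autonomous flow — evolving forward
and then backward by the same interval does not return the initial
state (the chain form does). The exact inverse of the forward solution
is `decay_correct`, which both models satisfy to ≤1e−10 relative.

**Degenerate quotient.** When λ_g approaches the feed constant the
grow-in quotient is singular; at |λ_g − λ_feed|/λ_g < 1e−9 the code
switches to the analytic limit A_m(0)·b·λ_g·t·e^(−λ_g t). The default
constants never approach this branch, but a general tool must not
divide by ~0; the limit branch is verified against an RK4 oracle to
≤1e−6.

**Inconsistent measurements.** Inverting the ground-state solution can
imply a negative initial ground activity when the measured A_g is
smaller than the grow-in from the corrected metastable activity alone.
Deficits within 1e−9 relative are treated as exactly zero (roundoff);
anything larger raises an error naming the deficit rather than clamping,
because a silent clamp would mask energy-window cross-talk or timestamp
errors — precisely the artifact the metastable channel is prone to in
high-uptake tissues.

**Units.** Hours and MBq internally; seconds and becquerels appear only
inside atom-count conversions (N = A/λ), which feed the metal:ligand
mole ratio used to characterize radiolabeling efficiency.

## Mono-exponential fitting

`fit_monoexp` fits A₀·e^(−λt) by unweighted least squares on the linear
scale (per-point sigmas switch it to weighted), initialized from a
log-linear regression when all values are positive and from a coarse
grid over decay constants otherwise. The half-life uncertainty comes
from the parameter covariance by the delta method. On noiseless
exponential input the generating half-life is recovered to well below
0.01% relative; with 5% multiplicative Gaussian noise at the ten-point
uniformity schedule the median fitted half-life over 100 seeds stays
within 5% of truth for both isomers. Weighting by ROI SD is not applied
by default since the reference workflow does not state it.

## Digital phantoms

The generator emulates the three phantom experiments used to
characterize quantitative dual-isotope SPECT, with the study's own
fill parameters as defaults:

| phantom | geometry | default concentrations (g / m, MBq/mL) |
|---|---|---|
| point source | 0.052 mL sphere | 66.0 / 15.7 |
| uniformity | cylinder (7 mm radius used in tests) | 3.58 / 0.832 |
| resolution | micro-Jaszczak hot rods | 15.1 / 3.57 |

The uniformity schedule is the ten printed acquisition times
t = 0, 2.0, 3.7, 23.3, 26.3, 31.7, 47.0, 70.1, 95.4, 118.5 h.

**Micro-Jaszczak layout.** Rod diameters default to {0.85, 0.95, 1.1,
1.3, 1.5, 1.7} mm — chosen to bracket the ~1.1 mm resolvability limit —
with center-to-center spacing twice the diameter and hexagonal packing
in six 60° sectors (the standard hot-rod convention). The exact sector
layout of the physical phantom is not published, so rod counts per
sector emerge from the configurable bore radius (13 mm default), with a
1 mm clearance margin at the bore wall and sector boundaries. Every
sector holds at least two rods so that per-diameter variability (and
hence CNR) is defined.

**Rasterization.** Voxel values are concentration × occupied volume
fraction. In-plane occupancy of the z-aligned shapes uses 3×3 stratified
supersampling; the axial fraction is a 1-D interval overlap and is
computed exactly (point-sampling the flat rod/cylinder ends is the one
place where supersampling has a systematic alignment bias, and the
exact overlap removes it). Spheres are supersampled in full 3-D.
Rasterized totals match concentration × analytic volume to well under
1% at ≤0.4 mm voxels for all three geometries. Individual boundary
voxels are quantized to ninths of occupancy, so a single grazing voxel
can deviate from a 21³-supersampled reference by up to ~1/7 of the
concentration (mean boundary deviation ~1%); raising `subs` to 7 brings
the worst voxel under 5%. The default favors speed; totals and ROI
means — the quantities the metrics consume — are insensitive to it.

**Imaging model.** The collimator/reconstruction chain is out of scope;
its effective result is modeled as an isotropic Gaussian PSF
(σ = FWHM/2.3548) applied post-hoc, a global sensitivity
(counts·s⁻¹·MBq⁻¹), a scan duration, and optional Poisson noise with an
explicit seed. The blur conserves the grid total exactly by kernel
renormalization at the boundary: with W = blur(1), blur(I/W)
redistributes every count inside the grid. What this model does *not*
emulate: depth-dependent resolution, attenuation, scatter tails,
septal penetration, reconstruction non-negativity bias and correlated
noise. Passing tests therefore validate the analysis pipeline
(calibration, ROI statistics, decay fitting), not scanner physics;
the printed real-scanner image-quality curves and effective half-lives
(60.7 ± 5.9 h, 22.4 ± 1.1 h) are not reproduction targets.

## Image quantification

**VOIs** select voxels by center inclusion (a voxel belongs iff its
center is inside the shape) — simple, unambiguous, and testable by
direct enumeration. **Calibration factors** are known concentration /
mean VOI intensity on a point-source image, exact by construction on
the deriving VOI. **Rod ROIs** are circles eroded by one voxel to
limit edge partial volume (disable with `erode_one_voxel=False`; at
0.4 mm voxels the erosion would swallow the sub-millimeter rods, so
hot-rod analysis is run at 0.16–0.2 mm grids, matching the resampled
resolution of the reference workflow). Interstitial ROIs of the same
size sit at midpoints between adjacent rod pairs.

Metric definitions (the reference work defers them to its citations;
these are the conventional forms, swappable):

- inter-rod contrast C = 100·(M_rod − M_btw)/(M_rod + M_btw), with
  resolvability flagged at C > 20%. On a noiseless truth image C = 100%;
  under heavy blur C can dip a few points below zero because the eroded
  rod ROIs sit in a locally depleted region — it is reported as
  computed, not clamped.
- CNR = (C/100) / CV of per-rod means; with zero variability (exactly
  identical rods) it is reported as absent rather than infinite.
- recovery coefficient RC = M_rod / true concentration, which is ≤1
  under blur and rises toward 1 with rod diameter.

**Uniformity analysis** places a 6 mm circular ROI on five evenly
spaced, non-consecutive transaxial slices within the central 60% of the
axial extent, averages the per-slice means per time point, and fits the
mono-exponential stage. Noiseless end-to-end runs recover 23.8 h for
the metastable channel and 64.1 h (3 s.f.) for a pure ground-state
channel; with both isomers present the apparent ground-state half-life
exceeds 64.14 h because of grow-in — the package's coupled correction
exists precisely to handle this.

## Biodistribution

Window count rates (55–93 keV ground, 110–160 keV metastable) divide by
per-window counter efficiencies to give activities, which are decay-
corrected to injection time and normalized by the injected activity:
%IA/organ and %IA/g (measured mass, or standardized fraction of body
weight for blood 0.07, bone 0.107, muscle 0.40 — editable configuration,
since the standard-weight tables are cited, not printed). SUV (g/mL) is
tissue concentration over injected activity per gram body weight, per
isomer. Decay during the counting interval is neglected (count times of
~minutes against half-lives of days).

No cross-talk correction between the windows is applied by default:
the workflow being reimplemented identifies the resulting metastable
overestimation in high-uptake organs but defines no correction. A
user-supplied 2×2 cross-talk matrix (applied by inversion before
efficiency conversion) is the hook for modeling it; the synthetic
cohort tests show that injecting spillover reproduces the m > g bias
qualitatively while the identical-isomer null otherwise holds.

The synthetic cohort generator assigns each organ the same biological
fraction of both isomers (isomers of one element are chemically
identical), applies physical decay from injection to measurement, and
converts to counts with multiplicative lognormal noise of configurable
CV (seeded, unit mean). It does not emulate inter-animal biological
variability beyond that noise, organ-specific kinetics, or excretion
between injection and measurement.

Isomer comparison uses Student's pooled-variance unpaired two-sided
t-test (the captioned convention of the reference analysis;
`pooled=False` switches to Welch) with stars at p < 0.05/0.01/0.001.

## Problem sizes and numerical choices

Tests run phantoms at 0.5 mm voxels (uniformity, ~56×44×44) and 0.2 mm
(hot rods, 55×140×140); these grids put boundary effects well below the
tolerances asserted while keeping the full suite around ten seconds.
The RK4 oracle in the tests uses 10⁴ fixed steps, giving agreement with
the analytic solution at the 1e−10 level, comfortably inside the 1e−8
assertion. Ties and degenerate inputs: flat series refuse to fit;
empty VOIs, overlapping windows, non-positive dimensions, and unknown
config keys raise immediately with named locations.

## Known limitations

- The published grow-in convention is not the strict branched-chain
  solution (see above); both are provided, the published one is the
  default because it is the correction actually applied by the workflow
  this package reproduces.
- The imaging model is an effective post-reconstruction blur; no
  projection-domain physics, attenuation, or scatter.
- Real-scanner image-quality values and in vivo uptake tables depend on
  unavailable scanner/animal data and are out of scope; the property
  suites substitute.
- The cross-talk matrix is a user hook, not a calibrated model of the
  spectral overlap.
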