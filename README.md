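# hgpair

Quantification toolkit for the mercury-197 isomer pair in preclinical
dual-isotope SPECT.

197mHg (t½ = 23.8 h) and 197gHg (t½ = 64.14 h) are a chemically matched
theranostic pair: both image well on SPECT (134 keV and 77 keV
photopeaks) and both emit therapeutically potent Meitner-Auger and
conversion electrons. They are co-produced on medical cyclotrons via
197Au(p,n), so every preparation contains both — and because the
metastable state feeds the ground state by isomeric transition with
91.4% branching (λ_IT = 0.914·λ_m), their activities form a coupled
parent–daughter system:

    A_m(t) = A_m(0) · e^(−λ_m t)
    A_g(t) = [λ_IT/(λ_g − λ_IT)] · (λ_g/λ_m) · A_m(0) · (e^(−λ_IT t) − e^(−λ_g t))
             + A_g(0) · e^(−λ_g t)

Any quantitative statement about either isomer — a calibration factor,
a phantom decay curve, a %IA/g table — requires solving and *inverting*
this system at arbitrary time points. `hgpair` provides that decay
engine plus the full analysis pipeline around it, for physicists and
radiochemists validating dual-isotope imaging workflows:

- **`hgpair.decay`** — analytic forward solution and exact decay
  correction (with an error, not a clamp, when a measured ground-state
  activity is below the unavoidable grow-in), atom/mole conversions and
  metal:ligand ratios, mono-exponential fitting.
- **`hgpair.phantom`** — synthetic digital phantoms (point source,
  uniform syringe, micro-Jaszczak hot rods) evolved over an imaging
  schedule and degraded by a Gaussian PSF + Poisson counting model, so
  the entire pipeline is testable without scanner data. NIfTI-1 I/O.
- **`hgpair.quantify`** — VOI statistics, point-source calibration
  factors, inter-rod contrast / CNR / recovery coefficients, and
  uniformity time-series decay analysis.
- **`hgpair.biodist`** — dual-energy-window gamma-counter analysis:
  %IA/g and %IA/organ decay-corrected to injection, SUV, per-organ
  isomer comparison, and a synthetic cohort generator.
- **`hgpair` CLI** — `decay`, `simulate`, `calibrate`, `iq-metrics`,
  `uniformity`, `biodist` subcommands.

See `docs/methods.md` for the model conventions (including the
distinction between the published grow-in form and the strict branched
Bateman chain), phantom geometry defaults, and known limitations.

## Worked example

Evolve a pure metastable source one half-life and correct it back:

```
$ hgpair decay forward --am 1 --ag 0 --t-hours 23.8
t = 23.8 h
a_m = 0.5 MBq
a_g = 0.151481 MBq
```

Half the metastable activity remains, and 0.151 MBq of ground-state
activity has grown in from the 91.4% isomeric-transition branch.
Correcting a measurement back to time zero inverts this exactly, and
refuses measurements the physics cannot explain:

```
$ hgpair decay correct --am 0.5 --ag 0.07 --t-hours 23.8
Error: measured ground-state activity 0.07 MBq at t=23.8 h is 0.08148 MBq
below the unavoidable grow-in 0.151481 MBq from the metastable state;
check energy-window cross-talk and timestamps
```

From the library, the radiolabeling metal:ligand ratio — 1 MBq of
activity split evenly between the isomers contains
A_m/λ_m + A_g/λ_g ≈ 2.28×10¹¹ mercury atoms, so against 10⁻¹⁰ mol of
ligand:

```python
>>> from hgpair import IsomerConstants, metal_ligand_ratio
>>> metal_ligand_ratio(1.0, 0.5, 1.0e-10, IsomerConstants())
263.7044126506157        # i.e. a 1:264 metal:ligand ratio
```

And a complete synthetic uniformity study — rasterize a uniform
cylinder (3.58 MBq/mL ground state, 0.832 MBq/mL metastable), image it
at ten time points over 120 h through the PSF/sensitivity chain,
calibrate, place 6 mm ROIs on five non-consecutive slices, and fit:

```python
>>> from hgpair import *
>>> spec = PhantomSpec(UniformCylinder(7.0, 22.0), ActivityPair(a_m=0.832, a_g=3.58))
>>> model = ImagingModel(psf_fwhm=0.8)
>>> frames = decay_series(spec, [0, 2.0, 3.7, 23.3, 26.3, 31.7, 47.0, 70.1, 95.4, 118.5],
...                       model, IsomerConstants(), grid_shape=(56, 44, 44), voxel_size=0.5)
>>> cf = CalibrationFactor(1.0 / ((0.5**3/1000) * model.counts_per_mbq_s * model.scan_time))
>>> series = [(t, apply_calibration(ch["m"], cf)) for t, ch in frames]
>>> uniformity_analysis(series)["fit"].half_life
23.800000000000004
```

The metastable channel recovers its physical 23.8 h half-life through
the whole image pipeline; a pure ground-state channel recovers 64.1 h,
while a mixed ground-state series fits *slower* than 64.14 h — the
grow-in signature that makes the coupled correction necessary.

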