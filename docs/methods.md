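# Methods

## Physical model

Pulsed proton energy deposition acts as a thermoacoustic monopole source:
the initial pressure is P0(r) = Γ(r) ρ(r) Dose(r) with Grüneisen
coefficient Γ = c²β/Cp, and the time-dependent source separates into a
spatial amplitude map and a shared temporal pulse, P0(r, t) = P0(r) ⊗ G(t).
Studies may bypass the dose pathway and specify source amplitudes directly
in pascals; the study source configuration is a 12 mPa Bragg-peak voxel,
optionally accompanied by 2 mPa sources at every voxel of the proton
entrance path, all driven by the same pulse (see the study-protocol
section for when the entrance sources are included).  Propagation obeys the first-order linear acoustic
equations with spatially varying sound speed and density and frequency
power-law absorption α(ω) = α₀ωᵈ.  Nonlinear acoustics, shear waves and
medium dispersion as an independent property are out of scope.

## Pulse convention and the arrival offset

The proton pulse is a unit-peak Gaussian of "total width" w = 10 µs read
as the 6σ support: σ = w/6 ≈ 1.67 µs, peak at w/2, truncated to [0, w].
For a monopole injected with this profile the detected far-field waveform
in 3-D follows the pulse derivative, so the global maximum lags the
geometric arrival d/c by approximately w/2 − σ ≈ 3.3 µs (slightly more in
2-D, where the Green's function has an afterglow tail).  This offset is a
property of the pulse parameterization, not of the medium: it is common
to all media simulated with the same pulse and cancels in every
between-media difference the studies report.  Absolute arrival times
therefore carry the offset, and published absolute arrivals can only be
matched to within the uncertainty of the (unstated) pulse
parameterization; the pulse width and σ convention are configurable.

## Material models

* **Water vs. temperature.**  Speed of sound follows the five-degree
  Marczak polynomial and density the Kell formula, each shifted by a
  constant so that 25 °C maps exactly to the study baseline (1498 m/s,
  997 kg/m³).  Valid input range (0, 100) °C; phantom generation may
  evaluate the polynomials outside it (smooth extrapolation) when
  sampling wide Gaussian tails.
* **CT numbers.**  All interfaces use the offset CT-number scale
  (air ≈ 0, water ≈ 1000); a helper converts from the conventional scale.
  Properties interpolate piecewise-linearly through anchor points (air,
  lung, water, soft tissue, cortical bone), exactly reproducing the
  tissue-table means, with clamped extrapolation outside [0, 1850].
* **Thermoacoustic constants.**  β and Cp per tissue are not acoustically
  observable in these studies and default to water-like values
  (β = 2.3·10⁻⁴ 1/K, Cp = 4178 J/(K·kg), giving Γ ≈ 0.12 and ≈1.2 Pa for
  a 1 cGy Bragg-peak dose); they are configurable through the YAML
  constants table.  Per-tissue α₀ values are likewise configurable and
  default to zero (lossless), since arrival times, the quantity of
  interest, are insensitive to weak absorption.

## Phantom statistics

Heterogeneity is i.i.d. per voxel with no spatial correlation: the study
conditions prescribe only per-tissue means and standard deviations, so
the voxel size (1 mm) is the correlation length of the disorder and is
treated as part of the study conditions.

* **Thermal water.**  Voxel temperatures ~ Normal(25, sd²) with
  sd ∈ {0, 5, 10, 15} °C.  By default temperatures convert to properties
  through the tangent line at 25 °C (slopes dc/dT ≈ +2.67 m/s/K,
  dρ/dT ≈ −0.26 kg/m³/K from the anchored polynomials).  The linear map
  keeps the perturbation exactly zero-mean — the bulk medium is unchanged
  and only intra-medium heterogeneity remains, which is precisely the
  effect this study arm isolates.  The full polynomials are concave at
  25 °C, so converting a wide symmetric temperature field through them
  would *lower the bulk mean speed* (≈8.6 m/s at sd = 15 °C) and
  contribute a bulk delay an order of magnitude larger than the
  heterogeneity effect; that variant remains available as
  `conversion="polynomial"`.
* **Tissue phantoms.**  Non-uniform tissue volumes perturb CT number,
  speed and density coherently with a single standard-normal draw per
  voxel, scaled by the measured per-tissue SDs — a local linearization of
  the CT-to-property conversion calibrated to the measured property
  statistics.  This reproduces the printed per-tissue property SDs
  exactly and keeps uniform and non-uniform phantoms matched in
  expectation.  (Pushing HU draws through the global piecewise-linear
  anchor map instead would roughly double the lung speed SD and shift the
  soft-tissue mean across an anchor kink, breaking the matched-means
  construction.)  Properties are floored at 1% of the lung means to guard
  against non-physical Gaussian tails; clamp events are logged except for
  CT volumes, where air voxels are expected.
* **Bimaterial phantoms.**  Two tissues split half/half across the
  midplane perpendicular to the source–detector axis; with a 100 mm
  separation centred on the midplane the straight path crosses 50 mm of
  each material, so the uniform path-averaged speed equals the arithmetic
  mean of the two tissue speeds.
* **CT-like volumes.**  Synthetic labeled anatomy (elliptical soft-tissue
  body, optional bone shell, lung region, spherical air pocket, thin air
  slab) generated through the same CT-number mapping a real volume would
  use.  A thin wide air slab is the configuration that reproduces large
  clinical overestimates: the wavefront detours around the slab edge
  (large delay) while the straight-path average speed barely drops.
  Real CT volumes load from NIfTI or raw `.npz` with an explicitly
  declared CT-number scale.

## Wave solver

Default scheme: k-space pseudospectral on staggered grids — spectral
derivatives with half-voxel shifts and the sinc(c_ref k Δt/2) k-space
correction (c_ref = max c), density components split per axis.  A
second-order staggered finite-difference fallback (`scheme="fdtd"`) is
available.  Power-law absorption with non-integer d uses
fractional-Laplacian loss and dispersion operators in the spectral
scheme; the fallback applies a per-voxel exponential decay matched to the
power law at 1 MHz and flags the approximation in the run metadata.

Boundaries are split-field PMLs appended *outside* the user grid (edge
replication), with a quartic profile of peak strength
pml_absorption · c_ref/Δx over 20 points; with the default strength 2.0 a
normally incident traversal is attenuated by ≈8 Np, and the measured
residual against an oversized-domain control is below 1% of the direct
peak.  Sources inject into the density components with a mass-rate
scaling (2cΔt/Δx per unit source pressure), preserving exact linearity in
amplitude.  Stability requires Δt·max(c)/Δx ≤ 0.3 (checked, with the
limiting voxel reported); arithmetic is single precision by default with
double available for oracle tests.  Numerical tie-breaks: the global
maximum of a trace takes the earliest sample; path sampling uses
ceil(L/Δx) midpoint samples with nearest-voxel lookup, boundary samples
assigned to the lower voxel index (endpoint-swap invariant, and exact for
midplane interfaces).

## Path-averaged speed

The straight Bragg-peak-to-detector segment is sampled at midpoints of
equal sub-segments no longer than one voxel; per-sample speeds are
averaged arithmetically.  Converting each sample before averaging (rather
than averaging CT numbers and converting once) is the order that makes
the two-material benchmark paths equal the arithmetic mean of the two
tissue speeds; the CT-number-first variant, which matches the clinical
processing description, is available as `mode="hu"`.

## Study protocol and problem sizes

The full-size geometry is a 200 mm cube at 1 mm voxels with source and
detector 100 mm apart and the beam entering perpendicular to the
source–detector axis (entrance path from the volume edge to the Bragg
peak).  The package's desk-scale protocol — the default and what the
test suite and acceptance script run — keeps the in-plane geometry and
the 1 mm disorder scale but drops to a single 2-D section for the
stochastic studies, and uses a coarse 3-D volume (2–2.5 mm voxels, CFL-
scaled Δt) for the absolute water-baseline arrival.  Desk-scale runs
drive the Bragg-peak source alone: the global maximum of a superposition
of many weak entrance-path contributions is a max-statistic whose
expectation shifts late under per-path jitter, which at 2-D desk scale
inflates every heterogeneity-induced delay by tens of percent (measured
≈40% on the thermal arm).  The full source configuration (12 mPa Bragg
plus 2 mPa entrance voxels) remains available via
``StudyConfig(entrance_path=True)`` and is the appropriate choice for
full-scale 3-D runs.  Arrival-time
*differences* are insensitive to these reductions; absolute amplitudes
and the absolute arrival offset are not, and 2-D amplitudes decay as
1/√r rather than 1/r.  Time steps are 10 ns for the thermal study (whose
effect is tens of ns) and 100 ns for the tissue studies (whose effects
are several µs); stochastic arms run 5 independent seeds by default
(8 for the thermal delay in the acceptance script) with mean ± SD
reported.  Complete 3-D full-scale runs are supported behind
`scale="full"` with a runtime warning.

## What the synthetic data does and does not emulate

The generators reproduce the studies' *statistical* media: correct means
and SDs, matched expectations between uniform and non-uniform variants,
and clean half-space interfaces.  They do not emulate spatially
correlated anatomy, organ boundaries, CT noise texture, beam-spot
structure, detector frequency response, or per-tissue absorption values;
passing tests therefore demonstrate the heterogeneity mechanisms (variance-
driven delay, interface scattering, air-cavity detours) rather than
patient-specific error magnitudes.

## Known limitations

* Absolute arrival times carry the pulse-parameterization offset
  discussed above (≈3.3 µs in 3-D with the default pulse); published
  absolute arrivals quoting a different offset cannot be matched exactly
  without knowing the original pulse convention.
* 2-D desk-scale amplitudes are not calibrated to 3-D; the 0.2 mPa
  validity gate is applied to whatever amplitude scale a run produces.
* The fractional-Laplacian absorption operators assume a single global
  exponent d; spatially varying d is not supported.
* Subsampling in the refinement probe is only meaningful for uniform
  media (coarsening a disorder realization changes its statistics).
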