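# Methods

## Model

`winghum` treats each flapping wing as a single moving point force. The
wing's net aerodynamic force — lift perpendicular to the local wing
velocity, drag antiparallel to it — is applied to the air at the wing's
third moment of area radius R₃ (default 55 % of wing length), the spanwise
station at which a point force reproduces the net aerodynamic torque about
the shoulder.  The acoustic pressure at an earth-fixed observer follows the
moving point-force (dipole loading-noise) equation: a nearfield term
proportional to the force itself, decaying as 1/r², and a farfield term
proportional to the force's time derivative (plus a convective correction),
decaying as 1/r, both evaluated at the retarded time and amplified by
Doppler factors (1−Mr)⁻².  The model is valid for subsonic source motion
(|M| < 1; hummingbird-scale wings reach |M| ≈ 0.03) and for acoustically
compact wings, R/λ₁ ≪ 1, which holds from mosquitoes (0.006) to
hummingbirds (0.007) and beyond, because wing length and wingbeat frequency
are inversely related across fliers.

Two reduced forms accompany the full equation.  A pivot-fixed
simplification drops the per-sample source motion from the geometry,
keeping a convective term 4Φ₀Rf_w²/a₀·(r·F); its harmonic band levels agree
with the full equation within ~1 dB over the first four harmonics at
hummingbird scale.  A distributed variant superposes point sources at the
centers of n equal-width span strips, with a linear spanwise weighting
solved so that total force and pivot torque match the single-point model;
at hummingbird scale the 1- and 10-source models differ by well under
0.1 dB per harmonic band, confirming compactness.

What is deliberately *not* modeled: scattering by the body and wings (a
compact wing is effectively acoustically transparent), atmospheric
absorption, reflections, quadrupole turbulence noise, feather
sonations/flutter, and any first-principles aerodynamics — forces are
inputs, never computed from blade-element or CFD models.

## Conventions

Right-handed frame fixed to the body pivot: x anterior, y toward the
animal's left, z up.  The stroke plane is horizontal; the stroke angle φ is
measured in that plane from the y-axis (wing abeam at mid-stroke), the
deviation angle θ is the elevation out of it.  Wingbeat phase τ ∈ [0, 1)
starts the downstroke at τ = 0, with the wing at its posterior reversal
sweeping anterior during τ < 1/2.  These conventions (zero reference, sign,
phase origin) are a documented package choice — there is no community
standard, and measured tables fitted on load inherit whatever convention
they were digitized in.  With the downstroke defined as the forward sweep and
weight support biased toward it, drag opposes the forward motion and the
first-harmonic dipole tilts aft in the sagittal plane, matching the
qualitative in vivo observation.

Lift sign follows the hovering convention: the lift direction is
v̂ × ŝ (ŝ the outboard spanwise unit vector, mirrored for the right wing),
which flips with the stroke direction; the signed lift is therefore
negative during the upstroke while the resulting vertical force stays
supportive in both half-strokes.

## Inputs and the synthetic presets

A run needs (i) morphology and wingbeat parameters (m, R, R₃/R, f_w, Φ₀),
(ii) kinematic series φ(τ), θ(τ) as truncated Fourier series (default cap:
harmonic 5; in vivo tables may carry more), and (iii) a per-wing force
specification: either lift/drag phase series or a *weight support profile*
— vertical force in bodyweights vs. τ, normalized so its wingbeat mean is
exactly one bodyweight — plus a lift/drag ratio (default: constant 2.0, a
stand-in for published quasi-steady hummingbird lift/drag data;
a phase-resolved table can be supplied).

Five paradigm presets cover the major groups of flapping fliers.  Their
weight-support waveforms are parameterized synthetic stand-ins of the form
|sin 2πτ|^s·(1 + a·sin 2πτ) (plus a downstroke-only half-sine for the
generalist bird), chosen so force vanishes at stroke reversals and the
documented harmonic signatures hold: flies concentrate profile energy in
harmonic 2 with substantial content through harmonic 6 (sharp mid-stroke
force peaks, s = 3–4), hummingbirds and hawkmoths pair harmonics 1 and 2
(s ≈ 1, strong downstroke bias), and the generalist bird's half-sine puts
> 4× more power in harmonic 1 than 2.  Morphology defaults are
literature-scale round numbers per paradigm animal (e.g. hummingbird:
m = 5 g, R = 5.8 cm, f_w = 44.2 Hz, Φ₀ = 2 rad; mosquito: R = 3.5 mm,
f_w = 600 Hz, shallow Φ₀ = 0.8 rad).  Externally digitized profiles can be
loaded through the CSV schema and replace the stand-ins without code
changes.

What the synthetic presets do **not** emulate: measured wingbeat-to-wingbeat
variability, ambient and instrumentation noise floors, non-harmonic tonal
contaminants, wing flexibility, and the exact published waveform shapes.
Tests passing on these presets therefore validate the *machinery*
(propagation, spectra, directivity, power, scaling) and the qualitative
harmonic signatures — not agreement with any specific measured spectrum,
which requires ingesting the measured tables.

After force assembly the package rescales the total force by a single
scalar so the wingbeat-mean vertical force of both wings equals m·g
exactly (to 1e-10 relative); the small correction absorbs the lift tilt
induced by the deviation angle and the drag's vertical component.

## Numerics

* **Periodicity everywhere.**  Kinematics and forces are exactly periodic,
  so all time derivatives (wing velocity, ∂F/∂t, ∂Mr/∂t) use spectral
  (FFT) differentiation on the one-period grid — no stencil error, no
  endpoint artifacts.  The Nyquist bin's derivative is zeroed.
* **Forward (source-time) propagation.**  Pressures are evaluated on the
  uniform emission grid and mapped to arrival times t + |r(t)|/a₀, which
  are strictly increasing for |M| < 1 (checked; a non-monotone map or
  |1−Mr| < 10⁻⁶ raises).  Because the emission-time pressure is exactly
  periodic, the one-period series is tiled cyclically and cubic-spline
  interpolated onto a uniform observer grid; the returned trace is the
  exact periodic steady state, so no startup transient needs discarding.
  The observer grid origin depends only on the observer's pivot distance,
  so microphones at equal radius share a time grid and can be summed
  coherently.
* **Resolution.**  Default 1024 samples per wingbeat (≥ 100× oversampling
  of harmonic 10) and 4 simulated wingbeats.  Harmonic band accounting
  (±2.5 Hz around each of harmonics 1–10) requires spectral resolution
  ≤ 2.5 Hz, i.e. trace duration ≥ 0.4 s; band analyses therefore simulate
  18 wingbeats at 44.2 Hz.  Band SPLs are stable to < 0.05 dB under
  doubling of the sampling rate.
* **Spectra.**  Default window is rectangular over an exact integer number
  of wingbeats — every harmonic falls exactly on a bin and Parseval's
  identity holds to rounding error.  Welch/Hann is available for measured
  data.  SPL reference is 20 µPa and configurable; relative
  (inter-harmonic) levels are reference-free.  Total acoustic power
  excludes the steady (DC) pressure offset that the mean force induces in
  the nearfield, since it does not radiate; the power-concentration
  fraction uses this fluctuating total as its denominator (the harmonic
  band sum is also reported, making the alternative denominator available).
* **Directivity.**  Spherical sampling uses Fibonacci (equal-area)
  lattices — 512 nodes for power quadrature (converged to < 0.5 % under
  node doubling), 360 angles per ring for sections.  The principal axis of
  a lobed section is found on a 3-point circularly smoothed curve: the two
  deepest, roughly opposite local minima define the waistline chord; the
  axis is its in-plane perpendicular, folded into [0°, 180°); ties break
  toward the smaller angle.  Axisymmetric patterns raise with a
  diagnostic.  Radiated power integrates p²_rms/(ρ₀a₀) over a sphere and
  is radius-invariant to ≈ (λ₁/2πr)² — use r ≳ 1.3 λ₁ for ≤ 2 %.
* **Reversal singularities.**  The lift/drag directions are undefined where
  |v| < 10⁻⁶ of its peak; directions there are carried over from the
  nearest moving sample.  Decomposing a net force into per-wing lift/drag
  reconstructs each wing's force from its observable x/z half-force by
  constraining it to the wing's instantaneous lift-drag plane (the lateral
  components cancel bilaterally and are otherwise unobservable); samples
  where that 2×2 system is near-singular fall back to direct projection.

## Allometric sweeps

Species records (name, group, m, R, f_w, optional Φ₀) get their group's
paradigm profile normalized to their own body weight, a pure
first-harmonic stroke at their amplitude (default Φ₀ = 2 rad — order one
in radians across fliers — with a shallow 0.8 rad default for elongated
flies), and a far-field power integration at two first-harmonic
wavelengths.  Sweeps use 256 samples per wingbeat and 128 quadrature nodes
(power changes < 0.5 % versus the full resolution).  Log-log OLS slopes of
simulated power against body mass or against the scaling-law predictor are
fit pooled and per group (≥ 3 species), with t-based 95 % confidence
intervals.  On a synthetic isometric grid (R ∝ m^⅓, f_w ∝ m^⁻⅓) the fitted
slope against the predictor is 1.00 within ±0.05, validating the machinery;
empirical cross-species exponents depend on external species compilations,
which are not bundled — a documented CSV schema accepts user tables.

## Known limitations

* Absolute SPLs against published tables carry an unknown reference offset
  (the reference pressure of the published decibels is unstated); relative
  inter-harmonic levels are the robust comparison.
* The synthetic paradigm waveforms are qualitative stand-ins; per-harmonic
  absolute levels for a specific species require its measured profile.
* The constant lift/drag ratio ignores phase/angle-of-attack dependence;
  supply a tabulated rule where it matters.
* Nearfield validity ends at the source region (observers must sit outside
  the wing sweep); no evanescent reconstruction toward the body is
  attempted.
* The per-wing decomposition of a measured net force assumes bilateral
  symmetry and recovers lateral force components only up to the lift-drag
  plane constraint.
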