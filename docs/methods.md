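# Methods

`berryflux` models the oxygen budget of a millimeter-scale photosynthetic
aggregate — a dense, gel-bound consortium of unicellular cyanobacteria,
diatoms and heterotrophic bacteria — and estimates its respiration,
photosynthesis and carbon-fixation rates from Clark-type oxygen-microsensor
data. This note documents the models, the numerical choices, and what the
synthetic-data generator does and does not emulate.

## Steady-state sphere model

The aggregate is idealized as a sphere of radius R (half the equivalent
spherical diameter, ESD) reacting at a uniform net volumetric rate Q
(production positive, respiration negative) in a diffusive medium.  O₂ moves
with apparent diffusivity θ·D_w inside the gel matrix and D_w in the water.
The steady field is

    C(r) = C_R + q_in/(6 θ D) (R² − r²)                      r ≤ R
    C(r) = C_∞ + Q_tot/(4π D) (1/r − 1/(R+δ))                R ≤ r ≤ R+δ
    C(r) = C_∞                                               r > R+δ

with continuity of concentration and flux at the surface.  δ is the
diffusive-boundary-layer thickness; δ → ∞ (the default) is the stagnant
infinite medium with the familiar Q_tot/(4πDr) far-field tail, and finite δ
pins C = C_∞ at the outer edge of the layer, approximating stirred water.

Setting C(0) = 0 gives the **critical respiration** — the diffusion-limitation
(anoxia) threshold:

    Q_crit = C_∞ / ( R² [ (1/(3D))(1 − R/(R+δ)) + 1/(6 θ D) ] ).

For ESD 1.7 mm, θ = 0.95, D_w = 2.175×10⁻⁵ cm² s⁻¹ (24 °C) this evaluates to
4.59 μmol cm⁻³ h⁻¹ with seawater solubility (S = 35) and 5.49 with brackish
solubility (S = 3.5) — the two legitimate readings of the study salinity (see
*Parameters*).  Respiration above this threshold makes the core anoxic
regardless of bulk oxygenation; the measured dark respiration (6.8) exceeds
both.

**Volume override.**  Published per-aggregate budgets pair an ESD of 1.7 mm
with a working volume of 2.8 mm³, slightly larger than the ESD-implied
2.57 mm³ (plausibly a different individual).  `AggregateGeometry` therefore
carries the volume as an independently settable field.  Q is always referred
to the working volume (total reaction Q·V_aggregate); the internal uniform
source is rescaled by V_aggregate/V_sphere(R) so the surface flux stays
consistent.  With the default volume this reduces exactly to the textbook
closed form.

**What the model does not capture.**  Light attenuation inside the aggregate
is not modeled — the source is uniform — so measured core supersaturation
values (which reflect depth-dependent production and a stirred boundary
layer) are matched only in order of magnitude, not fitted.  The aggregate
rests on agar during measurements; since O₂ diffusion in dilute agar matches
water, it is treated as a full sphere in uniform medium.

## Transient solver

Light–dark dynamics obey

    ∂C/∂t = (1/r²) ∂/∂r ( r² D(r) ∂C/∂r ) + q(r, t),

with symmetry at r = 0 and Dirichlet C = C_∞ at the far edge (10 aggregate
radii by default, or R+δ when a boundary layer is configured; a reflecting
option exists for mass-balance checks).  The source is uniform inside the
aggregate and piecewise constant in time (a light schedule).

Discretization is a conservative finite volume on uniform spherical shells:
the r = 0 singularity is handled naturally by the zero-area inner face, and
face diffusivities are harmonic means so the θ·D_w/D_w jump at the surface
is conservative.  Time integration is method of lines with LSODA
(tridiagonal Jacobian bandwidth), one schedule segment at a time so source
switches land exactly on segment boundaries.  Defaults: 40 shells across the
radius, rtol 1e-6, atol 1e-3 μmol L⁻¹.  Consumption is multiplied by a ramp
clip(C/1 μmol L⁻¹, 0, 1) so no O₂ is consumed where none remains — a smooth
stand-in for a hard cutoff that keeps the ODE system well behaved; the state
is clipped at zero on output.

Verification: the long-time solution matches the analytic steady state
within 1 μmol L⁻¹ when both use the same Dirichlet edge (the infinite-medium
closed form differs from any finite domain by its truncated 1/r tail, ~15
μmol L⁻¹ at 11 R, which is why the comparison must use the finite-δ analytic
variant); halving the grid spacing changes the time-to-anoxia by < 0.1%;
closed-domain mass balance closes within 1%.  Darkening a core initialized
at the observed 520 μmol L⁻¹ supersaturation under the measured 6.8
μmol cm⁻³ h⁻¹ respiration yields core anoxia (< 1 μmol L⁻¹) in ≈ 6.6 min,
inside the observed 5–8 min window.

## Flux estimators

**Radial (default).**  Depths above the aggregate surface map to radial
distance r = R + (surface_depth − depth), assuming the profile passes
through the center.  The external field is linear in 1/r, so (C_∞, k) are
fit by ordinary least squares to C = C_∞ + k/r and the whole-aggregate
exchange is 4π D_w k (efflux positive).  Points closer than 50 μm to the
surface (sensor-contact artifacts) or farther than one ESD are excluded by
default; both cutoffs are arguments.

**Planar (alternate).**  Fick's first law across the boundary layer:
J = −D_w dC/dz fit over a configurable height window (default 50–250 μm),
scaled by the sphere surface π·ESD².  It ignores spherical spreading and is
biased relative to the radial estimator; it is provided because planar flux
fits are the common field practice for flat sediment profiles.

**Light–dark shift.**  At a lighted steady state, local gross production is
balanced by respiration plus diffusion; in the first seconds after
darkening both are unchanged, so the initial decline rate −dC/dt at the
sensor equals the local gross photosynthesis.  The slope is fit over a
window 2–12 s after the dark onset (the sensor's 90% response is < 1 s, so
the first 2 s are skipped); the window is configurable.  Longer windows are
biased low by diffusive relaxation — the same bias that makes core-point
shift measurements read lower than profile-derived volumetric gross rates.

**Rate-table arithmetic.**  Gross = net + |dark respiration|; volumetric =
per-aggregate / working volume; carbon fixation = gross O₂ / PQ × 12.011
(ng C h⁻¹).  Full precision is carried throughout; rounding (integers for
per-aggregate and carbon columns, one decimal for volumetric) happens only
in the presentation view.

## Incubation rates

Acetylene reduction (nitrogenase proxy): rate = ethylene / (dry mass ×
active hours).  Unicellular diazotrophic cyanobacteria confine
oxygen-sensitive N₂ fixation to the dark, so the default convention counts
only dark hours (10 h per 14L:10D cycle).  Spans are assumed to start at
light onset; a partial final cycle contributes dark hours only after its
light phase has elapsed.  Molar C:N = (m_C/12.011)/(m_N/14.007).

## Parameters

| parameter | default | units | rationale |
|---|---|---|---|
| D_w | linear through 2.175e-5 @ 24 °C, 2.3535e-5 @ 27 °C | cm² s⁻¹ | the two calibration anchors for ~3.5% saline water |
| θ | 0.95 | – | apparent diffusivity ratio for gel-like aggregates |
| PQ | 1.2 | mol O₂ / mol C | standard photosynthetic quotient |
| C_sat | Garcia–Gordon (1992) Benson–Krause volumetric fit | μmol L⁻¹ | published seawater O₂ solubility parameterization; overridable |
| salinity | 35 | – | the study reports "3.5 psu" water but calibrated in 3.5% NaCl; 35 is the seawater reading. Both options are legitimate and C_sat differs ~20% between them, so salinity is an explicit config knob, never silently resolved |
| δ (DBL) | ∞ (stagnant) | μm | best reproduces the published anoxia threshold; finite values model stirred water |
| anoxia threshold | 1 | μmol L⁻¹ | "full anoxia" is not numerically defined in the source observations |
| ESD / volume | 1.7 mm / 2.8 mm³ | | the study aggregate; see *Volume override* |

## Synthetic data

The generator emulates the acquisition described for the study: steady-state
depth profiles on a 50 μm grid through the aggregate center, 1 Hz
center-point traces, and bottle tables, each from the corresponding forward
model plus i.i.d. additive Gaussian sensor noise (default σ = 2 μmol L⁻¹ on
concentration; multiplicative 5% on ethylene).  A single seed fixes all
randomness; identical seeds give byte-identical files.

It deliberately does **not** emulate: depth-registration error, sensor
drift or calibration offsets, stirring artifacts, response-time smearing,
lateral profile offsets, or non-uniform (light-attenuated) internal
production.  Passing round-trip tests therefore show that the estimators
invert the stated physical model under sensor-like noise — not that they are
robust to every artifact of real recordings.

The default scenario uses the study's rates (dark respiration 6.8, net
production 4.8 and 11.0 μmol cm⁻³ h⁻¹ at 170 and 320 μE m⁻² s⁻¹): noise-free
profiles analyzed by the radial estimator recover per-aggregate totals of
19.0, 13.4 and 30.8 nmol h⁻¹, which round to the published 19, 13 and 31.

## Problem sizes

All computations are desk scale: analytic profiles on ≤ 500-point grids,
transient solves with 40 shells over ≤ 4 simulated hours (well under a
second each), and 30-replicate noise studies.  The entire test suite runs in
a few seconds on one CPU.

## Known limitations

- The uniform-source model cannot reproduce measured core supersaturation
  quantitatively (it overpredicts: +516 μmol L⁻¹ above ambient at Q = 11
  versus an observed total of 520 μmol L⁻¹ that includes ambient).
- The exact configuration behind the published 5.0 μmol cm⁻³ h⁻¹ threshold
  (bulk O₂, boundary-layer treatment) is unreported; the closed form brackets
  it (4.59–5.49) across the two salinity readings but no configuration is
  claimed to reproduce it exactly.
- Published acetylene-reduction rates (11 and 20 nmol mg⁻¹ h⁻¹) cannot be
  recomputed from raw data (ethylene amounts and dry masses unreported); the
  arithmetic convention is implemented and exercised on constructed and
  synthetic bottles only.
- Bulk O₂ during the published light–dark time course is unreported, so
  re-illumination overshoot dynamics are not matched quantitatively.
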