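# Methods

This note documents the models, numerical choices and limitations of
`quakeloss`: what each stage computes, which knobs matter, what the
synthetic generators emulate, and what the passing tests do and do not
demonstrate about real-world use.

## 1. Empirical fatality model

### Model

Expected fatalities for one event are

    E = Σ_{I=5}^{11} r(I) · (HDI_my / HDI_ey) · Pe(region, I)

- `r(I) = 10^(β + θ·I)`, clamped to ≤ 1: the fatality ratio, deaths per
  exposed person at macroseismic intensity class `I`.  Classes V–XI span
  the observed range of damaging shaking in the catalog domain; anything
  below V contributes no fatalities and is reported separately.
- `(β, θ)` are fitted per sub-region (codes a–e: Xinjiang, Qinghai-Tibet
  Plateau, Northeast, North China, South China).  Region boundaries are
  not re-derived here; the region code is an input per event or scenario.
- The HDI factor `HDI(max_year)/HDI(event_year)` scales historical
  events' ratios up, normalizing for building resilience and social
  development across eras.  HDI years between table entries are linearly
  interpolated; extrapolating outside the table is an error.  The factor
  is applied both during fitting and during prediction: the alternative
  (fitting without it) would make fitted ratios era-dependent, defeating
  the correction's purpose.
- The log base of the ratio law is 10 (the convention for order-of-
  magnitude fatality models); it is a keyword argument where it matters.
- The clamp `r ≤ 1` enforces that a ratio of persons cannot exceed one.
  It only binds for extreme `(β, θ)` during grid search, not at fitted
  optima.

### Fitting

The objective

    ε = ln[(1/N) Σ (E_i − O_i)²] + (1/N) Σ [ln(E_i/O_i)]²

balances absolute squared error (dominated by the largest events) against
relative log error (weighting small events equally).  Events with zero
recorded fatalities are excluded — the log term is undefined there and the
catalog is by construction a *damaging*-earthquake catalog; the count of
excluded events is recorded in the fit diagnostics.  A perfect fit drives
the first term's argument to zero; the implementation returns `-inf` as a
documented sentinel, the objective's true infimum.

The optimizer is deterministic: a coarse grid search over
β ∈ [−20, 0], θ ∈ [0, 3] at 0.1 resolution, then Nelder–Mead refinement
from the best cell (tolerances 1e-6 in parameters, 1e-10 in objective).
No random restarts are needed: at fixed θ the objective is smooth in β,
and the grid is fine enough to land in the global basin.

The objective has a flat valley along the identified combination
`β + θ·Ī` (with `Ī` near the exposure-weighted mean intensity): the slope
θ is sharply identified when exposure profiles vary across events, while
β trades off against θ at roughly eight-to-one.  The tests therefore
verify optimizer correctness by *dominance* over an exhaustive
0.01-resolution grid (the fitted objective is at least as low as every
grid point's, with slope agreement to one cell) rather than by naive
parameter equality, which the valley makes ill-posed for noisy
small-N catalogs.  If the usable events expose only a single intensity
class, only `β + θ·I0` is identified; the fit flags this in its
diagnostics and warns.

The log residual `ζ = RMS(ln(E_i/O_i))` is pooled across regions: a single
spread parameter for the lognormal range model, matching the single
residual the range probabilities use; per-region overrides are possible by
calling `log_residual` on a region's diagnostics.

### Range probabilities and response levels

Fatalities are modeled as lognormal with median `E` and log-scale `ζ`:

    P(a < deaths ≤ b) = Φ((ln b − ln E)/ζ) − Φ((ln a − ln E)/ζ)

evaluated over the four NEEP ranges (0,10], (10,50], (50,300], (300,∞).
The ranges partition the support, so the probabilities sum to one (a
property test enforces 1e-9); the recommended level is the argmax range,
ties resolved toward the milder level.  `P(0 < x ≤ E) = 0.5` exactly —
`E` is the distribution's median.  A reference residual of
ζ ≈ 1.774 reproduces a 65.2% probability of the (0,10] range at E = 5;
E = 104 at the same residual puts the (50,300] range on top, a Level II
response.  At `E = 0` (no exposed population in damaging classes) the
lognormal is undefined; the pipeline reports P(0,10] = 1 and Level IV by
convention — a zero-exposure event is trivially a General Earthquake
Disaster Event.

Rounding of `E` for reports is half-up; the continuous value is always
retained alongside.

## 2. Wave solver

A collocated-grid velocity–stress formulation of linear elastodynamics:

    ρ ∂t v_i = ∂j σ_ij + f_i
    ∂t σ_ij = λ δ_ij ∂k v_k + μ (∂i v_j + ∂j v_i)

marched with classical RK4.  Spatial derivatives use 5-node one-sided
biased operators (offsets −1..3); the default coefficient set
[−1/4, −5/6, 3/2, −1/2, 1/12] is the standard 4th-order-exact biased
first derivative.  Alternative (e.g. dispersion-optimized) coefficient
sets can be supplied; construction validates the exactness invariants
Σaₙ = 0 and Σn·aₙ = 1.

**Alternation schedule.** One-sided operators on a collocated grid are
individually unstable but stable in the MacCormack construction: within a
stage all derivatives along an axis share one bias direction, and the
direction alternates across RK stages and cycles per axis per step
(forward iff stage + step + axis is even).  In characteristic variables
the elastic system decouples into advections, for which this alternation
is the classical stable pairing; applying opposite biases to the velocity
and stress derivatives within a stage, by contrast, mixes the
characteristics destructively and diverges (verified empirically during
development).

**Boundaries.** The free surface uses the traction-image method: the
traction components σzz, σxz, σyz are zeroed on the surface node and
mirrored antisymmetrically into three ghost layers; the remaining
components are mirrored symmetrically.  Side and bottom boundaries use a
Cerjan-style exponential sponge (default width 12 cells, damping factor
exp(−(0.025·(W−d))²) per step).  A periodic mode (all axes wrapped, no
free surface) exists for verification runs — plane-wave dispersion and
energy-conservation measurements need a lossless, boundary-free domain.

**Sources.** Point sources carry a moment tensor (added to the stress
rates, scaled by the cell volume and the source-time function) and/or a
body force (added to the velocity rates).  The default source-time
function is a unit-integral Gaussian moment-rate pulse of corner
frequency f0, so the stress glut integrates to the full moment tensor; a
zero-integral Ricker wavelet is available for band-limited tests.  Finite
faults are lists of subfault point sources with onsets, read from a
plain-text table (either explicit moments or slip × area × rigidity);
strike/dip/rake convert to moment tensors in the x=north, y=east, z=down
convention.  A single-subfault fault is bit-identical to the equivalent
point source.

**Terrain.** An optional vertically terrain-following stretch scales
z-derivatives per column by the ratio of the flat computational depth to
the local physical column thickness.  This is a gentle-slope
approximation: horizontal metric cross-terms of a full curvilinear
mapping are neglected.  Steep-topography scattering is therefore only
qualitatively represented; runs in this package default to flat.

**Stability and units.** dt defaults to CFL·dx/max(vp) with CFL 0.4
(conservative for the RK4/biased-operator pair; the plane-wave benchmark
measured 0.007% phase-speed error and ~1e-8 relative energy drift at 20
points per wavelength).  Everything is SI; georeferencing uses a local
flat-earth degree↔metre conversion (111.32 km/degree), acceptable at
scenario extents ≤ 200 km.

**Verification suite** (`quakeloss.wavesim.verification`): plane-wave P
and S phase speeds in a periodic box; first-arrival times against ray
theory on homogeneous and two-layer 100³ models; and the double-couple
radiation pattern of a shallow vertical strike-slip source.  Travel times
are measured as cross-correlation lags between two receivers on the same
ray — absolute single-trace picks are contaminated by the source-time
function's phase and by near-field terms, which the two-receiver lag
cancels.  The radiation check measures transverse-component PGV on a
surface ring: a pure Mxy double couple radiates SH as cos 2φ, giving the
four-lobed butterfly with nodes on the diagonals; nodal amplitudes
measure below 1% of the lobe maximum against a 10% criterion.

## 3. Intensity law

`I = clamp(c0 + c1·log10(PGV), 1, 12)` cellwise, with PGV in m/s and
PGV = 0 mapping to the lower clamp.  The shipped defaults c0 = 9.77,
c1 = 3.00 approximate the PGV branch of the China Seismic Intensity Scale
(GB/T 17742-2020); they are configuration values to be replaced from the
standard for operational use, and are validated here only for
monotonicity and round-trip identity inside the clamp.  PGV itself is the
time-maximum of the horizontal velocity magnitude √(vx²+vy²) per surface
cell by default; three-component and per-component-max conventions are
options, since intensity standards differ on the component rule.

## 4. Exposure overlay

Population cells are the unit of accumulation: the intensity field is
sampled by nearest neighbor at each population cell center, the sampled
value is binned (round half up; < 4.5 is below the damaging range; > 11.5
clamps to XI with a warning), and the cell's persons are added to that
class.  Population mass is never resampled, so

    Σ_I Pe(I) + below_V + unassessed = total population

holds to floating-point precision (tested to 1e-6 relative over a
thousand random raster pairs).  Persons whose cell centers fall outside
the intensity grid go to an `unassessed` bucket, reported in diagnostics
rather than dropped.  Nearest-neighbor (not bilinear) sampling keeps
ordinal class boundaries sharp.  NODATA population cells are treated as
zero persons with a logged count.

## 5. Synthetic data

The generators define the study conditions for all tests:

- **Catalogs** — per-intensity exposure is log-uniform per class with an
  upper range shrinking by 0.4 decades per class above V (high-intensity
  zones are geographically small, so fewer people are exposed there) and
  an 85% chance a class is present at all; this profile variation across
  events is what identifies the slope θ.  Recorded fatalities are
  `O = max(1, round(E(β*, θ*) · exp(ζ*·z)))` with standard-normal `z` —
  multiplicative lognormal noise, matching the range model's
  normal-in-log assumption.  The `max(1, ·)` floor keeps every generated
  event usable under the O ≥ 1 fitting rule and is flagged in event
  metadata.  Defaults (20 events/region, β* = −9, θ* = 0.9) give
  single-event fatality counts from ones to thousands, the realistic
  span of a damaging-earthquake catalog.
- **Population** — Gaussian-blob clusters on a 5% uniform background,
  scaled to a target total and rounded to whole persons (LandScan-style
  clustering); zero clusters gives a uniform raster.
- **HDI** — linear from 0.22 (1950) to 0.76 (2021), a monotone stand-in
  for a national development trajectory.
- **Intensity fields** — `I = I0 − decay·log10(max(r, r0)/r0) +
  lobe·|sin 2(φ − strike)|`, clamped to [1, 12]: radially decaying with an
  optional four-lobed azimuthal modulation mimicking a strike-slip
  butterfly pattern.

What passing tests show — and what they do not: the generators are
internally consistent with the model (lognormal noise, log-linear ratio),
so recovery tests validate the *estimator*, not the model's adequacy for
real catalogs.  Real exposure tables have correlated errors, intensity
mis-assignment and reporting biases that these fixtures deliberately
omit; fitting a real catalog remains the only test of the model itself.

## 6. Problem sizes and determinism

All solver benchmarks run on desk-scale grids (thin 240-cell boxes for
plane waves; 100³ for travel times; 110×110×30 for the radiation
pattern), chosen so the full physics suite completes in a few minutes on
one CPU while keeping 12+ points per wavelength everywhere.  The solver
has no random state; catalog/population generators take explicit seeds
and are byte-reproducible.  Pipeline reports embed an input digest
instead of timestamps, so identical configs give byte-identical JSON.

## 7. Known limitations

- The solver is purely elastic: no viscoelastic attenuation, no dynamic
  rupture, no full curvilinear metrics; single-threaded desk scale only.
- The flat-earth georeferencing distorts at continental extents.
- The intensity-law coefficients and PGV component convention must be
  supplied from the governing standard for operational use.
- The fatality model is a two-parameter empirical regression: its
  estimates are order-of-magnitude guidance for response triage, not
  casualty predictions, and the lognormal range probabilities inherit the
  fitted residual's assumption of normal log errors.
- GeoTIFF I/O is not provided; rasters are ESRI ASCII grids.
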