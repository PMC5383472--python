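# Methods

## Model overview

`exposim` is an agent-based exposure model. A cohort of agents is seeded
from a gridded density surface (cells drawn with probability proportional to
density × area, position uniform within the cell), advanced through time
with a directed random walk, exposed to a depth-independent sound field with
a duty cycle, and scored against threshold-shift criteria. All coordinates
are local planar x, y in kilometres with the source at the origin; grids for
real sites are assumed pre-projected, which keeps the model free of any map
projection logic.

## Sound field and exposure bookkeeping

Received level follows geometric spreading, `RL = SL − k log10(r/r_ref) −
α r`, evaluated on horizontal range only. The reference range is 1 m and
ranges below it are clamped, so RL never exceeds SL. Absorption defaults to
α = 0; the 15 log R intermediate-spreading default matches shallow-water
far-field behaviour between cylindrical and spherical limits.

The duty cycle is realized as a deterministic energy fraction: each step of
length dt contributes `d · dt` active seconds at the current weighted level.
For any dt much longer than a ping period this is identical in cumulative
energy to an explicit on/off schedule, and it makes the final SEL exactly
invariant to the choice of dt for a stationary agent (a property the test
suite checks to 1e-6 dB). SEL is accumulated on the linear intensity scale
with zero as the "no exposure yet" sentinel; dB values are only formed on
output, so there is no −∞ arithmetic.

The sound field is depth-independent. The idealized scenarios use a flat
50-m sea and a far-field geometric model, so vertical structure would be
spurious precision; diving therefore affects behavioural realism but not
accumulated SEL, and users of the dive machinery should know that.

A `FieldLibrary` (precomputed RL grid with bilinear interpolation) is
provided for file-driven workflows; the engine itself evaluates the closed
form directly, which is both faster and exact.

## Movement

Headings are wrapped-normal: `θ_new = wrap(μ + σ z)`, `z ~ N(0,1)`. For
natural movement μ is the previous heading (a correlated random walk with
persistence `ρ = exp(−σ²/2)` per step); for aversive movement μ is the exact
away-from-source bearing recomputed every step, making the walk a directed
flight whose net radial speed is ρ·v. Aversion is always on while a
responsive scenario runs — no received-level trigger is modelled, because
none of the behavioural dose–response data needed to calibrate one is
packaged. σ is in radians at the 60-s default step; σ = 10 gives
ρ ≈ 2·10⁻²², i.e. headings indistinguishable from uniform.

A draw is consumed even when σ = 0 so that comparison arms sharing a seed
stay aligned on the random stream (paired seeds). Paired seeding is the
package's main variance-reduction device: arms of a comparison share
seeding, initial headings, dive phases and the heading noise sequence, so
between-arm dB differences are estimated far more precisely than either
arm's absolute level.

Constraints: a proposal beyond the hard boundary radius is reflected
specularly about the boundary circle (range 2R − r at the same bearing);
a proposal on land (bathymetry ≤ 0) triggers up to 8 heading redraws, after
which the agent reverses heading and stays put for the step. Bathymetry
queries outside the gridded extent take the nearest edge value, which lets
a small flat grid stand for an unbounded idealized sea.

The dive cycle is triangular: descend and ascend over the species' typical
dive duration to a per-dive peak depth (a uniform 0.5–1.0 fraction of the
smaller of maximum dive depth and local seafloor depth), then a surface
interval at 0 m. Cycle length is dive duration + surface time by
construction.

## Hearing, weighting and criteria

Two weighting schemes are supported at the (single) source frequency:

* **M-weighting** per functional hearing group, the standard band-pass form
  `W(f) = K + 20 log10[f_h² f² / ((f² + f_l²)(f² + f_h²))]` with K
  normalizing the maximum to 0 dB; band edges per group are packaged as
  data (Southall et al. 2007 values). At 1 kHz the weighting is −0.03 dB
  for pinnipeds in water and −0.32 dB for high-frequency cetaceans —
  effectively zero.
* **A-weighting (audiogram)**: `W_A(f) = −H(f)`, hearing threshold
  subtracted, so the weighted level is a sensation level on the SEL scale.
  H is interpolated linearly in log10 frequency between audiogram nodes,
  with no extrapolation. This normalization is the package's design choice:
  it is the only one consistent with both the tens-of-dB separation between
  M- and A-weighted exposure curves and an audiogram-appropriate criterion
  written as H(f) + 95 dB.

PTS criteria: scheme M uses the functional-group constants for nonpulsed
sound (203 dB re 1 μPa²·s pinnipeds in water, 215 dB cetaceans); scheme A
uses H(f) + 95 dB. The packaged TTS dose–response is logistic with slope
s = 4 dB and midpoint solved so P(195 dB) = 0.185 (μ ≈ 200.93 dB): the
195-dB anchor reflects the level where significant TTS onset is reported in
captive odontocete/pinniped studies, while the 4-dB slope is a documented
free choice — only the anchor is empirically pinned. The PTS curve used for
"probability any agent experiences PTS" (1 − Π(1 − pᵢ)) shares the 4-dB
slope with its midpoint at the PTS threshold; the threshold-exceedance
fraction remains the default, regulator-facing output, and exceedance is
closed (ties count, conservatively).

The packaged audiograms are synthetic fixtures (flagged in their filenames):
pinned to H(1 kHz) = 71 dB (gray seal) and 80 dB (harbor porpoise) so the
audiogram-appropriate criteria evaluate to 166 and 175 dB at 1 kHz, with the
remaining nodes following literature-shaped curves (best sensitivity near
10–20 kHz for the seal, near 100 kHz for the porpoise). They are not
measured data and should be replaced for real assessments via
`load_species_table`.

Species movement parameters are likewise fixture values chosen once from
typical literature ranges: gray seal 1.5 m/s typical swim speed (3 max),
300-m maximum dive, 300-s dives, 120-s surfacings; harbor porpoise 1.4 m/s
(4 max), 200 m, 120 s, 60 s. Natural (non-responsive) movement uses a
heading SD of 0.5 rad per 60-s step for both species — moderate persistence
typical of travelling/foraging movement at this resolution.

## Uncertainty

Density cells carry a coefficient of variation. Resampling draws each cell
independently from a mean-preserving lognormal (`σ² = ln(1+cv²),
μ = ln D − σ²/2`); lognormal is the standard error model for density
estimates and guarantees nonnegativity. `risk_with_uncertainty` repeats
seed → simulate → summarize across resampled surfaces with fresh seeds and
reports 2.5/97.5 percentile intervals. Only density and seeding
stochasticity are resampled; movement and hearing parameters are held fixed
(resample the profile externally to extend this).

## The idealized stage and what it does (not) show

The default environment is a uniform-density disc of radius 100 km
(0.05 animals/km², CV 0.3, 5-km cells) centred on the source over a flat
50-m sea, with 10,000 agents by default (2,000 in the quicker acceptance
runs), 60-s steps and durations of 1 hour to 10 days. This emulates an
idealized exposure study, not any real site: real density surfaces are
patchy, extend asymmetrically and interact with coastlines. Consequences
worth being explicit about:

* Absolute SEL curves and M-weighted exceedance percentages depend strongly
  on how much of the population sits close to the source, i.e. on the
  density surface; on the dense uniform disc they are much higher than any
  field case with a realistic, wide, patchy distribution.
* Between-arm dB differences (aversion sweeps, weighting scheme offsets)
  are far more transferable, which is why the package reports comparisons
  with paired seeds.
* Hard-boundary effects are driven by how many agents reach the boundary.
  A directionless cohort (σ = 10) diffuses only ~10 km RMS in 10 days at
  1.5 m/s, so with both arms seeded inside the same 100-km disc a 100-km
  boundary changes mean SEL by well under 1 dB; with a wider or differently
  shaped seeding surface the same boundary can matter by several dB. For
  fleeing cohorts (σ = 0.5) the constrained arm piles up against the
  boundary ring and integrates its received level for the rest of the run,
  so the boundary effect is large (~10 dB at 10 days against the 75-km
  ring) but still bounded by where the unconstrained cohort would have
  escaped to.

Mean SEL curves average per-agent SELs in the dB domain (with empirical
2.5/97.5 percentile bands); a linear-domain mean would be dominated by the
handful of closest agents and shift curve levels by 1–2 dB without changing
between-arm differences appreciably.

## Numerical choices and limitations

* dt = 60 s default: resolves dive cycles and keeps 10-day × 10⁴-agent
  runs at around a minute each; the duty-fraction convention makes exposure
  totals insensitive to dt.
* History thinning stores every step up to 48 h and every 10th step beyond
  (the final SEL always comes from the unthinned accumulator); the
  experiment drivers record hourly.
* Wrapped-normal sampling wraps in-range values bit-exactly, so σ = 0 is
  literally deterministic.
* Single source, single frequency, stationary source; no multi-band
  accumulation, no behavioural dose–response beyond the generic logistic,
  no population-consequence modelling. Density estimation itself (survey or
  habitat-suitability modelling) is out of scope: the density grid is an
  input.
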