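# Methods

This note documents the models and procedures implemented in
`mirounga`, the parameter choices that matter, what the synthetic-data
generator does and does not emulate, and the package's known
limitations.

## Track processing and geometry

Raw location fixes are reduced to one position per 24 h by linear
interpolation at integer days from the first fix (`regularize_daily`).
Longitudes follow a single [−180, 180) convention and interpolation
crosses the antimeridian the short way. Days falling inside a fix gap
longer than 5 days are kept on the daily grid but flagged, and every
downstream statistic skips flagged days. A state-space filter for
satellite-location error is deliberately out of scope: the analyses
consume only daily positions, and the linear rule is documented as a
choice, not claimed as a reconstruction of any particular filter.

Distances are haversine great circles on a sphere of radius 6371.0 km
(111.195 km per degree of latitude). Raster lookups (bathymetry, ice,
distance-to-coast) are nearest-cell with ties to the lower index, for
both grids, so habitat-mask membership is bit-reproducible at cell
boundaries; bilinear interpolation would make the 20-m benthic rule
and the mask edges float with the query point.

## Habitat masks and stages

The four habitats are rule-based masks evaluated in precedence order
Antarctic shelf → Kerguelen Plateau → Oceanic East → Oceanic West,
with depth bands half-open ((0, 2000], (0, 1000], (1000, ∞)), the
60°S parallel assigned to the northern rule set and the 70°E meridian
to the east. Precedence resolves the overlap where water 1000–2000 m
deep south of 60°S satisfies both a shelf and an oceanic definition:
the shelf wins, preserving the shelf/oceanic dichotomy the analysis
is built on. Land (depth ≤ 0) and missing bathymetry classify as
OTHER — classification is total and never raises.

Stage windows are fixed day-since-departure intervals, 67 inclusive
days each (printed as "66 days" when measured as consecutive
differences). Dominant habitat is the argmax of per-label percentages
over classified days in the window; exact ties are broken by the fixed
label order and flagged. Days without a bathymetry value are excluded
from the stage denominator. Size matching retains individuals of both
sexes inside the 1st–99th percentile band (linear-interpolation
percentile definition) of the female length distribution.

## Haul-out detection

A mid-year haul-out is a maximal run of > 4 consecutive daily
positions within 4 km of the nearest land cell, starting ≥ 30 days
after departure and ≥ 30 days after the previous event ended ("a
month" is fixed at 30 days; the same gap also separates successive
events so that one stay interrupted by a single-day offshore
excursion — location noise — is merged rather than split). The
distance-to-coast grid is computed once from the bathymetry land mask
by brute-force nearest-land-cell great-circle search; the grids used
here are small enough that nothing cleverer is warranted. Phenology
summaries are restricted to seals tracked ≥ 150 days.

## Move persistence

Persistence γ_t ∈ (0, 1) is estimated from daily displacement
vectors (in local-km coordinates, longitude scaled by cos lat to
avoid metric distortion near −65°) under the first-difference
autoregression d_t = γ_t·d_{t−1} + ε_t, with γ random-walking on the
logit scale. The estimator minimizes

    Σ_t ‖d_t − γ_t d_{t−1}‖² + λ Σ_t (logit γ_{t+1} − logit γ_t)²

with displacements pre-scaled to unit root-mean-square so the data
term is dimensionless: λ then has the same meaning for fast and slow
animals, and the estimate is invariant to global rotation,
translation and rescaling of the track. λ defaults to 10 for daily
data; larger values smooth harder, and λ → ∞ forces a constant γ.

The optimization is coordinate descent on the logit parameters (γ
initialized at 0.5, clamped to [0.001, 0.999], iterated to a relative
objective tolerance of 1e-8). Two numerical accelerations leave the
fixed point unchanged: a damped Newton phase with the exact
tridiagonal Hessian (banded solve, backtracking line search) brings
the iterate near the optimum first, and the coordinate sweeps use
red–black ordering so each half-sweep vectorizes. Zero-displacement
runs (haul-outs) and gap-flagged days carry no data term and are
flagged missing in the output; a nominal 95% half-width per day is
derived from the local curvature.

No claim of numerical equivalence with any published state-space
persistence estimator is made; calibration is qualitative (directed
transit ≈ 0.9, area-restricted search < 0.5) and is verified by
parameter recovery against the generator's latent γ.

## Dives and drift rate

Benthic classification compares a dive's maximum depth with the
gridded seafloor: benthic within ±20 m of the floor. The lower band
is the behavioural rule; the symmetric upper tolerance is an artifact
decision absorbing bathymetry grid error for dives nominally deeper
than the cell value.

Drift dives are detected from the 4-point abstracted profile (plus
implicit surface endpoints) by four explicit filters on the five
inter-point segments: relative duration ≥ 35% of the dive, vertical
rate |r| ≤ 0.6 m/s, segment start deeper than 100 m, and uniqueness
(two qualifying segments = ambiguous = rejected). Rates are signed
with depth increase negative (a negatively buoyant seal sinks). These
thresholds are package defaults standing in for the multi-stage
filtering of dedicated drift-dive software; they are transparent,
testable, and adequate for using drift rate as a *relative* condition
index, which is all the analysis requires. The daily series is the
per-day median of detected rates (robust to single outliers),
linearly interpolated across days without drift dives (flagged), then
smoothed with a centred 5-day rolling median.

## Model comparison

Candidate models over sex, habitat and stage are compared with
AICc = −2ℓ + 2k + 2k(k+1)/(n−k−1), ΔAICc, Akaike weights, and the
rule of parsimony (fewest parameters among candidates with Δ < 2.0,
ties on k to the smaller AICc). The fitting machinery is a
contract-level stand-in for REML mixed models: every candidate is
fitted on the same rows with per-seal intercepts shrunk by an
identical ridge penalty (prior variance 1/τ, τ = 1 on the logit /
standardized-response scale), binary responses by penalized IRLS and
continuous responses by penalized least squares on a standardized
response. The reported log-likelihood is the joint likelihood (data
term minus the shrinkage term), so a candidate that buries a
between-seal covariate effect in its seal intercepts pays for it and
the comparison remains informative; k counts fixed effects plus
variance terms. AR1 residual structure is not modelled. The
comparative contract — identical machinery and rows across a
candidate set — is what the selection procedure needs; equality with
any specific mixed-model implementation's likelihood values is not
claimed, and recovery is verified generatively (a seeded sex×stage
interaction is selected; with no effects the null wins the parsimony
rule in ≥ 80% of replicates). For very large dive tables a seeded
random subsample (default 10⁵ rows) is drawn once and shared by all
candidates.

Report percentages are rounded half-up to integers; where published
counts are rounded differently (floor in one place, half-up in
another), the discrepancy is logged rather than silently matched.

## Synthetic-data generator

The generator produces the four inputs the pipeline consumes plus the
latent truth, deterministically per seed (per-seal seed streams are
spawned from one root, so a seal's data do not change when the cohort
grows).

* **Bathymetry** — an analytic grid (40–110°E, 72–44°S, 0.5°): deep
  basins (~3800 m), a 600-m plateau around the colony north of 60°S,
  a 600-m circum-Antarctic shelf band south of 65.5°S, a continental
  land edge and a colony island. All four habitat labels are
  realizable by construction and the colony cell is land.
* **Ice season** — concentration ~0.8 south of a sinusoidal edge
  latitude (northernmost, −56°, at day-of-year 258; southernmost,
  −69.5°, in late summer), ramping to 0 over 1.5° of latitude. One
  season, no interannual variability: sufficient for membership
  classification and for a seasonal sex×stage occupancy contrast.
* **Population** — 102 females and 85 males by default (the cohort
  size the defaults emulate), standard lengths ~N(2.33, 0.18) and
  N(2.37, 0.18) m, male departures centred mid-January and female
  departures three weeks later, trips ~240 d (females) / ~300 d
  (males).
* **Movement** — each seal draws a preferred habitat from its sex's
  preference vector (defaults mirror the observed stage-1 dominant
  proportions: males 55/29/14/2% across Antarctic shelf / plateau /
  east / west, females 4/10/50/36%). Daily displacements follow
  d_t = γ_t·d_{t−1} + ε_t with isotropic Gaussian innovations
  (sd 16 km); during transit legs the innovation mean steers toward
  the target at ~90 km/day and γ = 0.9; inside the habitat γ drops to
  the foraging value (0.35 shelf, 0.75 oceanic) with a weak pull that
  keeps the seal within ~150 km of its patch. Haul-out episodes
  (probability 0.83 males, 0.09 females) return the seal to the
  colony coast for 5–20 zero-displacement days; start times are drawn
  per preferred habitat (plateau users ~45 days earlier than
  Antarctic-shelf users) with a 25-day spread, chosen so the cohort
  hauls out asynchronously — most seals haul out but only ~15–25% are
  ashore on the peak day, as observed.
* **Dives** — ~15 transmitted dives per at-sea day. Over shelf cells
  a dive is benthic with a sex-and-habitat probability (defaults 0.40
  and 0.30 for males on the Antarctic shelf and plateau, 0.10 and
  0.05 for females), with maximum depth within 20 m of the floor;
  otherwise pelagic at least 21 m above the floor. A fraction (0.2)
  are drift dives whose long middle segment moves at the seal's
  latent drift rate plus N(0, 0.02) noise; the latent trajectory
  starts at −0.25 m/s (lean, post-molt), rises 0.0025 m/s per day to
  day 90 and plateaus below −0.03 m/s, mirroring an early-trip
  recovery of condition.

What the generator does **not** emulate: Argos location error and
irregular fix schedules (tracks are born daily and clean), eddy
fields and prey patchiness, bathymetric slopes and canyons,
interannual ice variability, tag failure as a process (trip length
variation is a crude proxy), and any absolute lipid-mass scale for
drift rate. Passing recovery tests therefore demonstrates the
pipeline's correctness and internal consistency under the stated
generative assumptions — not robustness to real-data pathologies,
which enter upstream of this package's scope.

## Problem sizes used in validation

The test suite and acceptance script size their simulations to what
each check needs: persistence recovery uses 30 seals × 200 days
(two-regime latent truth), drift-rate recovery 4 seals × 61 days with
≥ 3 drift dives/day, habitat recovery 40 seals with concentrated
(0.92) preferences, the shelf-dominance gap the full 187-seal cohort
averaged over three replicate studies, and model-selection recovery
50 replicates of a 20-seal × 60-day occupancy table. The end-to-end
CLI example runs the full default cohort.

## Known limitations

* The ridge-penalized seal intercepts use a fixed prior variance
  rather than an estimated variance component; AICc differences are
  meaningful within a candidate set but the absolute likelihood scale
  differs from an REML fit, and k for variance terms is a convention.
* The persistence estimator's uncertainty band is curvature-based and
  nominal; it ignores smoothing-parameter uncertainty.
* Drift-dive thresholds are not calibrated against any labelled dive
  set; they are constructive defaults the generator and detector
  share, which is what makes closed-loop validation possible.
* The daily regularizer interpolates linearly; with real, noisy,
  irregular Argos data a proper state-space filter should be applied
  before this package's pipeline.
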