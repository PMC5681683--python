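# Methods

## Scope and data model

The package operates on three inputs in one shared planar metric CRS
(metres; UTM expected — geographic coordinates must be projected
upstream): a per-individual GPS fix table (id, timestamp, x, y, HDOP,
satellite count), a landscape GeoJSON (river centerline LineString, water
Polygon, territory Polygons keyed by `territory_id`), and a deployment
table (status dominant/subordinate, minimum age, season spring/autumn,
capture night). Timestamps are zone-aware; the activity window
[19:00, 07:00) is evaluated on the local wall clock (default Europe/Oslo).
An individual tracked under both statuses is tracked in different seasons,
so a deployment's fixes are the individual's fixes in its season window.

## Quality screen

Three removal rules: (a) every fix in the capture night's activity window
(19:00 on the capture date to 07:00 next morning — one night; the data
model has no habituation period), (b) HDOP > 5, (c) fewer than 4
satellites. Thresholds are strict, so HDOP = 5.0 with 4 satellites
survives. A fix failing both a quality rule and the capture-night rule is
tallied once, under the quality rule, so counts partition the input. The
screen is idempotent. Report percentages round half-up to one decimal.

## Territory delineation and bank length

The home range is the percentage MCP: the ⌊f·n⌋ fixes nearest the
arithmetic centroid (f = 0.95 by default), ties broken by input order
(stable sort), hulled. Centroid peeling is one of several MCP variants;
it is this package's documented choice. Territory size is **bank length**:
max − min centerline chainage of the MCP-retained fixes, in km. This is a
single-bank measure (chainage span), invariant to reversing the
centerline's vertex order; it does not sum the two banks.

Foray fixes must be excluded from the MCP, yet the foray definition needs
a territory border. When field-confirmed territory polygons are supplied
in the landscape, classification uses them directly (the field-study
approach) and the MCP is only used for the size covariate. Otherwise
`refine_with_forays` iterates: delineate from current intra fixes →
classify all fixes → relabel, until labels are unchanged (counting the
final verifying pass) or `max_iter = 10`, returning the last iterate with
a non-convergence flag. On data where the foray fixes fit inside the 5%
peel allowance — the typical deployment, given field-typical foray lengths
of a few fixes — the loop stabilises in ≤3 passes; deployments whose foray
fixes exceed ~5% of all fixes shrink the hull stepwise and can need 4+
passes. Exclusion itself has been robust in every simulated scenario
exercised; only the pass count grows.

## Foray detection and metrics

A fix is a foray fix iff it is outside the focal polygon, **strictly**
more than `buffer_m = 100` m from the polygon's exterior ring (unsigned
Euclidean distance — not an along-river distance), and inside ≥1 non-focal
territory (boundary points count as inside everywhere; containment
tolerance 1e-9 m). Fixes outside the MCP but within the buffer, or in
unclaimed space, stay intra-territorial.

Segmentation takes maximal runs of consecutive foray fixes with no
intervening intra fix. Because no fixes are scheduled 07:00–19:00, a run
ending at the last fix of one night and resuming at the first fix of the
next merges automatically into one multi-night foray whose full duration
includes the unobserved daytime; an active-time-only duration (elapsed
minus daytime portions) is carried alongside, and both are floored at one
sampling interval so a single-fix foray counts 0.25 h. Foray distance is
the sum of straight-line distances between consecutive member fixes plus
the distance from the territory border to the first and to the last fix;
it therefore always exceeds 2×buffer. Intrusion extent is the number of
distinct non-focal territories containing ≥1 member fix.

Per deployment: forays per week divides the count by tracking nights / 7
(nights with ≥1 retained fix, not calendar days); percent of active time
on forays uses active-time foray minutes over scheduled active time
(720 min × tracking nights) by default, with a realized-coverage variant
(retained fixes × interval) available.

## Movement metrics

Medium is water iff the fix is covered by the water polygon (shoreline
counts as water). Hourly travel speed: consecutive fix pairs with gap ≤
`max_gap_min = 20` (excluding steps across dropped fixes) are assigned to
the clock hour of their first fix; each hour's summed step distance is
rescaled by its covered minutes to m/hr. A per-step instantaneous variant
(distance/gap) is available behind a flag; the hourly aggregation is the
package's documented realization of "distance per hour". Intra-territorial
speed can be restricted to water–water pairs (conservative, since the
animals travel faster in water and are more aquatic on forays); foray
speed always uses all pairs. Distance from shore is the unsigned distance
from a land fix to the water polygon's boundary; water fixes are a
precondition error.

## Count models, AICc and model averaging

Families: Gaussian-identity (OLS), Bernoulli-logit, Poisson-log, NB2-log,
and ZINB (log-link NB2 count part, intercept-only logit zero part — the
zero mechanism is not covariate-dependent). Fits are maximum likelihood
via statsmodels; the parameter count k includes the residual variance
(Gaussian), the NB dispersion, and the zero-inflation intercept.
Categorical covariates are treatment-coded with reference levels autumn,
dominant and foray, so reported effects are "(spring)", "(subordinate)"
and "(intra-territorial)".

ZINB optimisation falls back to Nelder–Mead plus a gradient polish when
BFGS diverges (the zero part is weakly identified when the data carry
little zero inflation). When the dispersion sits on its boundary
(α → 0, the ZIP limit) the full observed-information matrix is singular;
regression SEs are then taken from the information sub-block with the
dispersion held at its estimate, and the dispersion's own SE is reported
as missing. Fits that still lack finite SEs are flagged non-converged and
drop out of averaging.

The candidate set is all 2^p covariate subsets (p ≤ 8, no interactions),
including the intercept-only model. AICc = −2logL + 2k + 2k(k+1)/(n−k−1);
models with ΔAICc strictly < 4 are retained (the best model always is).
Averaging is *full* (zero-substitution): a model lacking a term
contributes β = 0; unconditional SE = Σ wᵢ·√(seᵢ² + (βᵢ − β̄)²); CIs are
Wald ±1.96·SE, rounded half-up to 3 decimals in tables; a CI containing
zero marks the term uninformative. Conditional averaging and
profile-likelihood CIs are deliberately not offered. The collinearity
screen flags covariate pairs with |r| ≥ 0.6 (strict threshold).

**Random effects are not implemented.** Repeated deployments of one
individual violate independence; the package documents this and offers
`one_per_individual` subsampling of the covariate table as a crude
alternative. Fixed-effects estimates remain consistent for the planted
parameters in the simulations shipped here, but SEs on real repeated
measures would be optimistic.

## The synthetic-data generator

The generator emulates the study design, not beaver kinematics: what is
controlled is exactly what the pipeline measures.

* **Landscape** — a random-walk-bearing centerline (50 m steps, bearing
  SD 0.06 rad, gently sinuous), water = centerline buffered to a 40 m wide
  river, territories = consecutive chainage intervals (default drawn
  uniform 1–5 km of bank each) buffered 60 m beyond the shore with flat
  caps: adjacent, sharing borders, overlapping <10%.
* **Population** — 46 dominant + 10 subordinate deployments over 54
  individuals by default (two animals under both statuses, in opposite
  seasons); tracking nights per deployment from a clipped normal
  (mean 10.3, SD 3.9, range 4–22); capture dates drawn inside spring
  (Apr–Jun) and autumn (Aug–Oct) windows chosen away from DST changes.
* **Within-territory movement** — a patrol-like persistent walk in river
  coordinates (chainage, lateral offset): water fixes (p = 0.75) move at
  600 m/hr mid-channel, land fixes at 250 m/hr with exponential
  shore-attraction (mean 12 m beyond the bank); direction flips are rare
  (0.03/step) and each border arrival triggers a 1–3-fix scent-marking
  dwell before turning. Border dwell matters: a lazily diffusive walk
  under-visits the territory ends, and the 95% peel then clips several
  hundred metres off the recovered bank length, contradicting the
  recovery contract the pipeline is tested against.
* **Forays** — per-deployment propensity mixes a structural never-forayer
  class (p = 0.25) with gamma rate multipliers (shape 1.5, mean 1) on a
  per-night rate of 0.12, making population counts genuinely zero-heavy
  and overdispersed (zero inflation and heterogeneity are what the ZINB
  is for). A foray travels along the river at 1400 m/hr into 1–5
  consecutive neighbours (weights 0.60/0.25/0.08/0.04/0.03, truncated to
  availability), penetrating at least 300 m past the border and typically
  10–50% into its deepest territory, dwells 1–6 fixes, and returns — or,
  with probability 0.08, lays up through the day and returns the next
  night. These rates were chosen to reproduce field-scale summaries
  (roughly 45% of individuals foraying, ~0.6 forays/week, median foray
  ~1 h and ~1.3 km, mostly into the adjacent territory).
* **Degradation** — Gaussian noise (σ = 5 m) is added *after* truth
  labelling; 5% of fixes are dropped; 10.1% are given disqualifying
  HDOP/satellite values. Truth labels (movement type, medium, foray id,
  occupied territory) are computed geometrically from the pre-noise
  positions against the planted polygons, so they satisfy the same
  definitions the pipeline applies.

What the generator does **not** emulate: realistic autocorrelated speeds,
home-site (lodge) fidelity within the night, seasonal behavioural change,
floods/ice, map error in the water polygon, and non-riparian excursions.
Passing recovery tests therefore demonstrates that the pipeline's rules
and estimators are implemented correctly and are robust to GPS-scale
noise — not that they would be unbiased on field data with unmodelled
errors (the field study needed scent-mound-confirmed borders for good
reason).

## Numerical choices

Boundary points count as inside polygons (tolerance 1e-9 m); the foray
buffer comparison is strict (>100 m). MCP ties break by input order;
retained count uses floor. GeoJSON output rounds coordinates to 1e-6 m
and sorts keys so identical landscapes are byte-identical. Percent values
round half-up to one decimal; table coefficients to three. Seeds live in
configs, never in global state; every output of the simulator and the
pipeline is a pure function of (inputs, config), audited by a manifest of
SHA-256 hashes.

## Problem sizes used in validation

The test-suite recovery experiments use 20 individuals × 10 nights for
foray precision/recall (σ = 5 m, 30% foray nights, ≥300 m penetration), a
single 3 km territory with 300 fixes at σ = 10 m for bank-length
recovery, 100 replicates of n = 500 for ZINB parameter recovery
(β_size = −0.4, π = 0.3, θ = 2), and 1,000 random cases per geometry
oracle. These sizes make each check statistically meaningful while the
whole suite and the acceptance script each run in well under a few
minutes on one CPU.

## Known limitations

* No random effects (above); no kernel or autocorrelation-aware home
  ranges; convex MCPs can include water/land the animal never used.
* Bank length is a single-bank chainage span; studies summing both banks
  will report ~2× larger sizes.
* Fixed-point refinement can need extra passes (and in principle could
  overshoot) when forays contribute more fixes than the MCP peel can
  absorb; supplying field-confirmed borders avoids the issue entirely.
* Wald CIs on the ZINB are slightly anti-conservative at n = 500
  (empirical coverage ≈ 93–95% in the shipped experiment), as expected
  for observed-information intervals on a mixture model.
* Multi-ring (holed) polygons and geodesic coordinates are unsupported;
  all geometry is planar and single-ring.
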