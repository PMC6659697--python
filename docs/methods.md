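# Methods

## Scope

`stepselect` implements an integrated step selection analysis (iSSA) that
competes three functional-connectivity hypotheses — corridors, least-cost
paths, stepping stones — on GPS movement tracks over a raster landscape,
together with a synthetic landscape generator and a movement simulator so
every stage is testable without field data. The statistical core is a
from-scratch matched-stratum conditional logistic regression.

## Coordinate and raster conventions

All geometry is planar metres; no geodesy. The raster origin is the
lower-left corner; cell (row, col) of an R-row grid has its centre at
(x0 + (col + 0.5)·res, y0 + (R − row − 0.5)·res), i.e. row 0 is the top row,
matching the ESRI ASCII grid layout used for I/O. Rasters are written as
ASCII grids with a JSON legend (class code order, linear-feature list,
schema); this keeps every artifact plain text.

## Synthetic landscape

The default schema has 15 feature classes: eight natural polygonal (bare,
deciduous, coniferous, mixed, wetlands, grasslands, lakes, shrubs), streams
(linear), three anthropogenic polygonal (development, crops, forage), rail
lines and roads (linear), and a protected-area (PA) overlay. Polygonal
classes tile the grid; linear features and PAs are independent overlays, so
a PA can contain development, crops or roads, as real multi-use reserves do.

* **Polygonal cover** — one Gaussian random field per class, smoothed with a
  4-cell kernel; cells are assigned greedily (scarcest class first) to the
  unassigned cells where the class's field is highest, until its target
  count is met. Realised fractions match targets to rounding; smoothing
  yields contiguous patches so corridor structure exists to be selected for.
* **Linear features** — correlated random-walk polylines entering from a
  random edge, rasterised one cell wide at 0.5-cell sampling (connected),
  added until the class's target length density (km/km²) is met. Defaults:
  streams 0.5, roads 1.2, rail 0.1 km/km².
* **Protected areas** — discs/rectangles with log-normal areas
  (sdlog 0.35) around `pa_mean_area_m2`, placed to avoid overlap while a
  placement budget lasts. Default: 12 patches of 2 km² mean on a 15 × 9 km,
  30-m landscape (≈18 % coverage). The default extent is 15 × 9 km because
  the grid must be an integer number of 30-m cells.
* Default cover fractions describe an aspen-parkland working landscape
  (deciduous-dominant natural cover interspersed with cropland and forage).

Generation is bit-reproducible given (config, schema).

## Covariates

Two families per class, evaluated at arbitrary points:

* `dist_<class>` — Euclidean distance (m) from the point to the nearest
  *cell centre* of the class, truncated at 1000 m (animals are not expected
  to respond to features further away). A point inside a class cell reads 0;
  a class absent from the landscape reads the cap.
* `dens_<class>` — number of class cell centres within a 106-m buffer (the
  mean step length) divided by the buffer area clipped to the raster extent,
  in pixels/m². The clipped area is measured discretely, as (cell centres in
  buffer ∩ extent) × res²; this makes the saturated-buffer identity
  (dens = 1/res²) exact and removes edge bias by construction. Distances use
  a per-class KD-tree; densities use per-row cumulative sums, so both are
  exact (they equal an exhaustive scan, which the tests assert) yet fast.

Before regression, all dist/dens columns — current and lagged — are
standardised per individual with the sample (n−1) standard deviation;
zero-variance columns are set to 0 and flagged rather than erroring. The
movement-kernel terms lnStepLength and cosTurnAngle enter models raw.

## Movement simulator

At each step the mover draws K = 20 candidate (length, turn) pairs — length
log-normal(meanlog, sdlog), turn wrapped-normal(0.08, 1.0) — and picks one
with probability ∝ exp(utility). Because the choice is a softmax over
candidates, the simulator is the exact generative dual of the
conditional-logit likelihood: utilities linear in model terms are
recoverable by the matching iSSA fit, which is what makes hypothesis
recovery a well-posed estimation problem.

Calibration: sdlog defaults to 1.0 and meanlog = ln(105.47) − sdlog²/2, so
the marginal mean step is 105.47 m on a 300-s fix schedule. The turn
standard deviation defaults to 1.0 rad: the field calibration target is the
*mean* turn (0.08 rad, weak forward bias) and no spread is prescribed, and
at 1.0 rad the wrap-around bias of the signed mean (the tail mass folded
from beyond ±π) stays below 0.003 rad, an order of magnitude inside
Monte-Carlo error for the calibration runs.

Framework rules (α = selection strength; α = 0 reduces every framework to
the same uniform-choice null, bit-identically):

* **corridor** — u = α Σ_poly (dens·res²)(lag dens·res²)
  + α Σ_lin (dist/cap)(lag dist/cap) over the corridor classes (default: the
  three forest classes and the three linear classes, i.e. exactly the
  classes the corridor candidate model watches; configurable). The product
  form rewards consistency of habitat composition between consecutive steps
  and is linear in the corridor model's interaction terms. An
  absolute-difference similarity (−α Σ|Δdens|) was considered and rejected:
  because candidates cluster around the step start, whose covariates equal
  the lagged values, it produces a preference *peaked at the availability
  centre* that no linear term can represent — it degenerates into a
  short-step preference absorbed by other models' movement terms, making
  corridor recovery impossible by construction.
* **least-cost path** — u = −α Σ_f cost_f·dens_f(end) (avoidance of dense
  costly features; default unit costs on the three forest classes), plus
  kernel modulation by the local normalised cost density ρ = Σ cost·dens·res²
  at the current fix: proposal lengths × (1 + 0.6ρ), turn sd ÷ (1 + 0.6ρ).
  The modulation, not the utility, carries the framework's signature
  prediction — density positively correlated with speed and negatively with
  tortuosity — which the LCP candidate model's dens × movement interactions
  estimate. Without it the utility induces only density main effects, which
  the core model already contains, and the LCP model could never win.
* **stepping stone** — u = α·1[end inside a PA], plus residency modulation
  while inside a PA: lengths × 0.5, turn sd × 2 (short, tortuous steps).
* **null** — u = 0.

Candidates leaving the extent are redrawn (up to 100 times) and finally
pulled back along the step direction to the boundary with a logged warning.

Reference ("moderate") strengths, chosen so the utility spread across a
candidate set is of order one — selection comparable in strength to the
movement kernel, given each utility's natural scale: corridor α = 10
(products of buffer fractions ≤ 1), lcp α = 1500 (densities are O(10⁻³)
pixels/m²), stepping stone α = 1.5 (0/1 indicator).

## Step sampling and the case-control design

Steps are straight segments between consecutive fixes; heading =
atan2(Δy, Δx); turn = wrapped heading difference in (−π, π]. Gaps longer
than 1.5× the nominal interval split bursts; the first step of each burst
has no previous heading and never enters a stratum. Zero-length steps are
dropped with a warning (log-length undefined; a moving-fix collar should
not produce them). Per-individual step-length distributions are log-normal
MLEs on used steps (sample-sd convention, ≥10 positive steps required).

Each usable used step is matched with k = 10 available steps: length from
the fitted log-normal, turn uniform on (−π, π] applied to the previous
*used* heading (the same reference as the used turn). Out-of-extent
endpoints are redrawn then clamped, preserving the fixed 1:10 design.
Covariates are attached at every candidate end point; lagged covariates are
evaluated once per stratum at the shared start point (the previous used
step's end), so they are constant within a stratum by construction.

## Conditional logistic regression

The partial likelihood conditions on one chosen row per stratum. Newton–
Raphson with step-halving; converged when |Δℓ| < 1e−8 and max |score| <
1e−6, at most 100 iterations. The observed information supplies Wald SEs,
z and p per term (the per-parameter surface typically reported for iSSA
coefficients); AIC = 2k − 2ℓ̂ with k the estimated (non-dropped) term
count; concordance is the within-stratum c-index (ties 0.5).

Numerical/structural choices:

* Columns constant within every stratum (e.g. lagged main effects) are
  structurally inestimable under exact conditioning and are dropped with a
  warning; likewise columns exactly collinear within strata (Gram–Schmidt
  on within-stratum-centred columns, keeping earlier terms).
* Separation is an error, not a penalised fit: raised when a standardised
  coefficient exceeds 15 during iteration, when the information matrix
  conditioning exceeds 1e12, or when — after numerical convergence — the
  likelihood is still non-decreasing along 1.5·β̂ with a standardised
  coefficient above 2 (complete separation flattens the likelihood before
  the in-loop threshold is reached).
* The likelihood is concave, so multi-start agreement to 1e−6 is asserted
  as a test invariant rather than handled at runtime.

The engine is validated against closed forms (ℓ(0) = −S ln 11 for 1:10
strata), a derivative-free optimiser on tiny designs, coefficient-recovery
coverage (β̂ ± 2 SE covering truth ≈95 % of replicates) and statsmodels'
`ConditionalLogit` (reference in tests only, never at runtime).

## Candidate models

Core: cosTurnAngle + lnStepLength + dist/dens of deciduous, coniferous and
mixed forest + dist to wetlands — the habitat-plus-movement baseline for a
forest mustelid. Corridor adds dens_f × lag_dens_f (forest classes) and
dist_f × lag_dist_f (linear classes); LCP adds dens_f × lnStepLength and
dens_f × cosTurnAngle (forest classes); stepping stone adds dist/dens of
PAs, dens_PA × movement interactions and dens_PA × lag_dens_PA; global is
the union screened for pairwise collinearity (|r| ≥ 0.7, later term
dropped). "Previous step" effects appear only as current × lagged
interactions because a lagged main effect is constant within a stratum and
hence inestimable under exact conditioning — a pure lagged main effect
reported for a strict clogit cannot be reproduced; the interaction is the
estimable surrogate and the discrepancy is deliberate.

Per individual, all five models are fitted and ranked by AIC (ties broken
toward fewer terms, then name); Akaike weights w_i = exp(−Δ_i/2)/Σ exp(−Δ_j/2);
tallies count rank-1 and rank-2 finishes per hypothesis. Individuals with
failed or non-converged fits are excluded from tallies and reported.

Within-PA residency: for steps ending inside a PA, Pearson correlations
(two-sided t, df = n−2) between step length / cos turn angle and forest
density at the step end.

## Validation experiments and problem sizes

* Movement calibration: 20 null tracks × 1000 fixes on a 30 × 30 km, 100-m
  calibration domain (a 1000-step walk's RMS displacement is a few km, so
  the boundary-redraw rule cannot bias the kernel statistics; under the null
  the landscape content is never consulted). Grand mean step within 3 MC SE
  of 105.47 m; grand mean turn within 3 MC SE of 0.08 rad.
* Clogit recovery: 200 replicates of 500 strata × 11 with β = (0.5, −1.0).
* Framework recovery: per framework, 10 replicate individuals of 2000 fixes
  on the 15 × 9 km reference landscape, full pipeline, majority rank-1
  required; under α = 0 no hypothesis may beat core by ΔAIC > 2 in most
  replicates. These sizes keep the full suite under a few minutes while
  leaving the statistical checks well-powered.

## What the synthetic data do and do not show

The generator emulates: log-normal step lengths with a 105.47-m mean, weak
forward directional bias, a 15-class patchy landscape with linear features
and a PA network, softmax habitat selection, and (optionally) fix dropouts.
It does not emulate home ranges, inter-individual interactions, stationary
bouts (the collar's speed trigger), GPS positional error, habitat-dependent
fix loss, or real landscape composition. Passing the recovery experiments
therefore shows the *estimator* identifies the generating selection rules
under the model's own assumptions — not that real telemetry from any
particular system would single out one framework.

## Known limitations

* No mixed-effects/frailty clogit, robust SEs, penalised (Firth) fits or
  model averaging; separation is surfaced, not corrected.
* Distances are point-to-cell-centre; densities are unweighted counts (no
  kernel weighting); no geodesic support.
* The collinearity screen is pairwise-greedy, not a full VIF analysis.
* Available-step generation redraws (rather than rejects) out-of-extent
  candidates; near hard boundaries the available kernel is slightly
  truncated relative to the fitted log-normal.
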