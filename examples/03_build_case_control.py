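"""From a track to the iSSA case-control table.

Each observed ("used") step is matched with 10 random "available" steps that
share its start point: lengths redrawn from the individual's fitted
log-normal, headings uniform around the previous bearing. Distance-to and
buffer-density covariates for all 15 feature classes are attached at every
candidate end point, together with the lagged covariates at the stratum's
start, then standardised per individual.
"""

import stepselect as ss

stack = ss.generate_landscape(ss.LandscapeConfig(seed=7))
track = ss.simulate_track(
    stack, ss.MovementParams(), ss.SelectionParams(), n_fixes=500, seed=9,
    individual_id="demo",
)
steps = ss.derive_steps(track)
dist = ss.fit_step_distribution(steps)
print(f"fitted step-length distribution: meanlog={dist.meanlog:.3f}, "
      f"sdlog={dist.sdlog:.3f}")

geometry = ss.generate_available(steps, dist, k=10, seed=10, stack=stack)
table = ss.attach_covariates(geometry, stack)
ss.validate_case_control(table, k=10)
table = ss.scale_covariates(table)

n_strata = table["stratum_id"].nunique()
print(f"{len(steps)} steps -> {n_strata} strata x 11 rows = {len(table)} rows")
cov_cols = [c for c in table.columns if c.startswith(("dist_", "dens_", "lag_"))]
print(f"{len(cov_cols)} covariate columns "
      f"(15 classes x dist/dens x current/lagged)")
print(f"zero-variance columns flagged: {len(table.attrs['zero_variance'])}")
# Every stratum holds exactly one used row (case=1); lagged covariates are
# constant within a stratum by construction, which is why 'previous step'
# effects can only enter models as current x lagged interactions.
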