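"""Step derivation, step-length fitting and the case-control construction."""

import numpy as np
import pandas as pd
import pytest

import stepselect as ss
from stepselect.errors import ConfigurationError, DesignError, InsufficientDataError


def _track(coords, individual_id="t", interval=300.0):
    coords = np.asarray(coords, dtype=float)
    return ss.Track(
        individual_id=individual_id,
        t=np.arange(len(coords)) * interval,
        x=coords[:, 0],
        y=coords[:, 1],
    )


class TestDeriveSteps:
    def test_collinear_motion(self):
        steps = ss.derive_steps(_track([(0, 0), (3, 4), (6, 8)]))
        assert np.allclose(steps["length_m"], [5.0, 5.0])
        assert steps["turn_rad"].iloc[1] == pytest.approx(0.0)
        assert steps["cos_turn"].iloc[1] == pytest.approx(1.0)

    def test_right_angle_left_turn(self):
        steps = ss.derive_steps(_track([(0, 0), (1, 0), (1, 1)]))
        assert steps["turn_rad"].iloc[1] == pytest.approx(np.pi / 2)
        assert steps["cos_turn"].iloc[1] == pytest.approx(0.0, abs=1e-12)

    def test_rotation_leaves_turns_unchanged(self):
        """Turn angles are intrinsic: rotating the whole track preserves them."""
        rng = np.random.default_rng(8)
        pts = np.cumsum(rng.normal(0, 50, size=(40, 2)), axis=0) + 5000
        theta = 0.77
        R = np.array([[np.cos(theta), -np.sin(theta)], [np.sin(theta), np.cos(theta)]])
        a = ss.derive_steps(_track(pts))
        b = ss.derive_steps(_track(pts @ R.T))
        assert np.allclose(a["turn_rad"].dropna(), b["turn_rad"].dropna(), atol=1e-9)
        assert np.allclose(a["length_m"], b["length_m"])

    def test_gap_starts_new_burst(self):
        t = np.array([0.0, 300.0, 600.0, 1800.0, 2100.0, 2400.0])
        track = ss.Track("g", t, np.arange(6.0) * 10, np.zeros(6))
        steps = ss.derive_steps(track, nominal_interval_s=300.0)
        assert set(steps["burst_id"]) == {0, 1}
        # one turn-less first step per burst
        assert steps["turn_rad"].isna().sum() == 2

    def test_zero_length_step_dropped_with_warning(self):
        with pytest.warns(UserWarning, match="zero-length"):
            steps = ss.derive_steps(_track([(0, 0), (0, 0), (1, 0), (2, 0)]))
        assert (steps["length_m"] > 0).all()

    def test_too_few_fixes(self):
        with pytest.raises(InsufficientDataError):
            ss.derive_steps(_track([(0, 0), (1, 1)]))


class TestFitStepDistribution:
    def test_monte_carlo_recovery(self):
        rng = np.random.default_rng(9)
        lengths = rng.lognormal(4.2, 0.5, 5000)
        steps = pd.DataFrame({"length_m": lengths})
        dist = ss.fit_step_distribution(steps)
        assert dist.meanlog == pytest.approx(4.2, abs=0.05)
        assert dist.sdlog == pytest.approx(0.5, abs=0.05)

    def test_scale_invariance(self):
        rng = np.random.default_rng(10)
        lengths = rng.lognormal(3.0, 0.7, 200)
        d1 = ss.fit_step_distribution(pd.DataFrame({"length_m": lengths}))
        d2 = ss.fit_step_distribution(pd.DataFrame({"length_m": lengths * 7.0}))
        assert d2.meanlog == pytest.approx(d1.meanlog + np.log(7.0))
        assert d2.sdlog == pytest.approx(d1.sdlog)

    def test_degenerate_and_short_inputs(self):
        with pytest.raises(InsufficientDataError):
            ss.fit_step_distribution(pd.DataFrame({"length_m": [np.e] * 12}))
        with pytest.raises(InsufficientDataError):
            ss.fit_step_distribution(pd.DataFrame({"length_m": [1.0] * 5}))


@pytest.fixture(scope="module")
def geometry(null_steps, default_stack):
    dist = ss.fit_step_distribution(null_steps)
    return (
        ss.generate_available(null_steps, dist, k=10, seed=77, stack=default_stack),
        dist,
    )


class TestGenerateAvailable:
    def test_stratum_shape(self, geometry):
        table, _ = geometry
        sizes = table.groupby("stratum_id").size()
        assert (sizes == 11).all()
        assert (table.groupby("stratum_id")["case"].sum() == 1).all()

    def test_available_turns_uniform(self, geometry):
        from scipy import stats

        table, _ = geometry
        turns = table.loc[table["case"] == 0, "turn_rad"].to_numpy()
        assert turns.min() >= -np.pi and turns.max() <= np.pi
        p = stats.kstest(turns, "uniform", args=(-np.pi, 2 * np.pi)).pvalue
        assert p > 0.01

    def test_available_lengths_match_fitted_lognormal(self, geometry):
        table, dist = geometry
        lnL = np.log(table.loc[table["case"] == 0, "length_m"].to_numpy())
        se = lnL.std(ddof=1) / np.sqrt(len(lnL))
        assert abs(lnL.mean() - dist.meanlog) < 3 * se

    def test_deterministic_given_seed(self, null_steps, default_stack):
        dist = ss.fit_step_distribution(null_steps)
        few = null_steps.iloc[:50]
        a = ss.generate_available(few, dist, k=5, seed=3, stack=default_stack)
        b = ss.generate_available(few, dist, k=5, seed=3, stack=default_stack)
        pd.testing.assert_frame_equal(a, b)

    def test_k_must_be_positive(self, null_steps, default_stack):
        dist = ss.fit_step_distribution(null_steps)
        with pytest.raises(ConfigurationError):
            ss.generate_available(null_steps, dist, k=0, seed=1, stack=default_stack)


class TestAttachCovariates:
    def test_lag_columns_constant_within_stratum(self, small_table):
        lag_cols = [c for c in small_table.columns if c.startswith("lag_")]
        spread = small_table.groupby("stratum_id")[lag_cols].agg(
            lambda s: s.max() - s.min()
        )
        assert (spread.to_numpy() == 0).all()

    def test_spot_check_against_direct_call(self, small_stack, small_table):
        """An attached density equals density_in_buffer at the same endpoint."""
        # use the unscaled geometry: rebuild covariates for one row
        row = small_table.iloc[3]
        pt = [(row["end_x"], row["end_y"])]
        direct = ss.density_in_buffer(small_stack, "deciduous", pt)[0]
        # undo the per-individual scaling
        raw = ss.attach_covariates(
            small_table[["stratum_id", "case", "individual_id", "start_x", "start_y",
                         "end_x", "end_y"]].iloc[[3]],
            small_stack,
        )
        assert raw["dens_deciduous"].iloc[0] == pytest.approx(direct, abs=1e-15)

    def test_uniform_landscape_flags_zero_variance(self):
        cfg = ss.LandscapeConfig(
            extent_m=(3000.0, 3000.0), resolution_m=30.0, seed=1,
            cover_fractions={"crops": 1.0}, pa_count=0,
            linear_density={"streams": 0.0, "roads": 0.0, "rail_lines": 0.0},
        )
        stack = ss.generate_landscape(cfg)
        track = ss.simulate_track(
            stack, ss.MovementParams(), ss.SelectionParams(), 60, seed=2
        )
        steps = ss.derive_steps(track)
        dist = ss.fit_step_distribution(steps)
        geom = ss.generate_available(steps, dist, k=5, seed=3, stack=stack)
        table = ss.scale_covariates(ss.attach_covariates(geom, stack))
        flagged = {c for _, c in table.attrs["zero_variance"]}
        assert "dens_crops" in flagged
        assert (table["dens_crops"] == 0).all()

    def test_validate_rejects_broken_strata(self, small_table):
        broken = small_table.copy()
        broken.loc[broken.index[1], "case"] = 1  # two cases in stratum 0
        with pytest.raises(DesignError):
            ss.validate_case_control(broken)
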