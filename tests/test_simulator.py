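"""Movement simulator: calibration, determinism, framework behaviour."""

import math

import numpy as np
import pytest

import stepselect as ss
from stepselect.errors import ConfigurationError, DomainError
from stepselect.simulate import MEAN_STEP_M, wrap_angle


def test_default_movement_calibration():
    move = ss.MovementParams()
    assert move.mean_step_m == pytest.approx(MEAN_STEP_M)
    assert move.turn_mean_rad == 0.08
    assert move.fix_interval_s == 300.0


def test_wrap_angle_range():
    theta = np.linspace(-10, 10, 1001)
    w = wrap_angle(theta)
    assert np.all(w > -np.pi) and np.all(w <= np.pi)
    # wrapping preserves the angle modulo 2π
    assert np.allclose(np.cos(w), np.cos(theta), atol=1e-12)


def test_seed_determinism(default_stack):
    kw = dict(n_fixes=200, seed=13)
    a = ss.simulate_track(default_stack, ss.MovementParams(), ss.SelectionParams(), **kw)
    b = ss.simulate_track(default_stack, ss.MovementParams(), ss.SelectionParams(), **kw)
    assert np.array_equal(a.x, b.x) and np.array_equal(a.y, b.y)


def test_zero_strength_reduces_every_framework_to_null(default_stack):
    tracks = [
        ss.simulate_track(
            default_stack,
            ss.MovementParams(),
            ss.SelectionParams(framework=fw, strength=0.0),
            n_fixes=300,
            seed=21,
        )
        for fw in ("null", "corridor", "lcp", "stepping_stone")
    ]
    for tr in tracks[1:]:
        assert np.array_equal(tr.x, tracks[0].x)
        assert np.array_equal(tr.y, tracks[0].y)


def test_null_step_lengths_match_lognormal_moment(null_steps):
    """Sample mean step within 3 SE of exp(meanlog + sdlog²/2)."""
    lengths = null_steps["length_m"].to_numpy()
    se = lengths.std(ddof=1) / math.sqrt(len(lengths))
    assert abs(lengths.mean() - MEAN_STEP_M) < 3 * se


def test_null_mean_cos_turn_matches_wrapped_normal(null_steps):
    """E[cos θ] = exp(−σ²/2)·cos μ for the wrapped normal."""
    move = ss.MovementParams()
    expected = math.exp(-move.turn_sd_rad**2 / 2) * math.cos(move.turn_mean_rad)
    cos = null_steps["cos_turn"].dropna().to_numpy()
    se = cos.std(ddof=1) / math.sqrt(len(cos))
    assert abs(cos.mean() - expected) < 4 * se


def test_stepping_stone_concentrates_in_pas(default_stack):
    """PA occupancy under strong stepping-stone selection exceeds availability
    in every replicate."""
    avail = default_stack.pa_mask.mean()
    for seed in range(1, 6):
        tr = ss.simulate_track(
            default_stack,
            ss.MovementParams(),
            ss.SelectionParams(framework="stepping_stone", strength=1.5),
            n_fixes=800,
            seed=seed,
        )
        steps = ss.derive_steps(tr)
        occ = default_stack.in_pa(
            steps["end_x"].to_numpy(), steps["end_y"].to_numpy()
        ).mean()
        assert occ > avail, (occ, avail)


def test_dropout_creates_bursts(default_stack):
    tr = ss.simulate_track(
        default_stack,
        ss.MovementParams(dropout_rate=0.2),
        ss.SelectionParams(),
        n_fixes=400,
        seed=3,
    )
    assert len(tr) < 400
    steps = ss.derive_steps(tr)
    assert steps["burst_id"].nunique() > 1  # gaps split the track into bursts
    # steps across a dropout gap are never derived
    assert steps["length_m"].count() == len(steps)


def test_fixes_stay_inside_extent(default_stack):
    w, h = default_stack.extent_m
    tr = ss.simulate_track(
        default_stack,
        ss.MovementParams(meanlog=np.log(2000.0)),  # huge steps force clamping
        ss.SelectionParams(),
        n_fixes=300,
        seed=2,
    )
    assert np.all((tr.x >= 0) & (tr.x <= w) & (tr.y >= 0) & (tr.y <= h))


def test_invalid_inputs(default_stack):
    with pytest.raises(DomainError):
        ss.simulate_track(
            default_stack, ss.MovementParams(), ss.SelectionParams(),
            n_fixes=10, seed=1, start=(-100.0, 0.0),
        )
    with pytest.raises(ConfigurationError):
        ss.simulate_track(
            default_stack, ss.MovementParams(), ss.SelectionParams(), n_fixes=2, seed=1
        )
    with pytest.raises(ConfigurationError):
        ss.SelectionParams(framework="teleport")
    with pytest.raises(ConfigurationError):
        ss.SelectionParams(strength=-1.0)


class TestCandidateUtility:
    def _vec(self, dens, dist):
        return ss.CovariateVector(dist=dist, dens=dens)

    def test_zero_strength_is_uniform(self):
        cur = self._vec({"deciduous": 1e-3}, {"streams": 10.0})
        prev = self._vec({"deciduous": 5e-4}, {"streams": 500.0})
        for fw in ("corridor", "lcp", "stepping_stone", "null"):
            u = ss.candidate_utility(fw, cur, prev, (50.0, 0.1),
                                     ss.SelectionParams(framework=fw, strength=0.0))
            assert u == 0.0

    def test_lcp_softmax_ratio(self):
        """dens 0.001 vs 0.0005, cost 1, α=1000 → Δu = −0.5, odds e^0.5."""
        params = ss.SelectionParams(framework="lcp", strength=1000.0,
                                    class_costs={"conif": 1.0})
        prev = self._vec({}, {})
        u1 = ss.candidate_utility("lcp", self._vec({"conif": 0.001}, {}), prev,
                                  (50.0, 0.0), params)
        u2 = ss.candidate_utility("lcp", self._vec({"conif": 0.0005}, {}), prev,
                                  (50.0, 0.0), params)
        assert u1 - u2 == pytest.approx(-0.5)
        assert math.exp(u2 - u1) == pytest.approx(1.6487, abs=1e-3)

    def test_stepping_stone_indicator(self):
        params = ss.SelectionParams(framework="stepping_stone", strength=2.0)
        inside = self._vec({"protected_areas": 1e-3}, {"protected_areas": 0.0})
        outside = self._vec({"protected_areas": 0.0}, {"protected_areas": 250.0})
        prev = self._vec({}, {})
        assert ss.candidate_utility("stepping_stone", inside, prev, (1, 0), params) == 2.0
        assert ss.candidate_utility("stepping_stone", outside, prev, (1, 0), params) == 0.0

    def test_corridor_linear_in_products(self):
        """Corridor utility is linear in dens(end)·dens(prev): doubling the
        previous density doubles the utility (the generative-dual property)."""
        params = ss.SelectionParams(framework="corridor", strength=10.0,
                                    corridor_polygonal=("mixed",),
                                    corridor_linear=())
        cur = self._vec({"mixed": 8e-4}, {})
        u1 = ss.candidate_utility("corridor", cur, self._vec({"mixed": 4e-4}, {}),
                                  (1, 0), params)
        u2 = ss.candidate_utility("corridor", cur, self._vec({"mixed": 8e-4}, {}),
                                  (1, 0), params)
        assert u2 == pytest.approx(2 * u1)
        assert u1 > 0

    def test_unknown_framework(self):
        with pytest.raises(ConfigurationError):
            ss.candidate_utility("warp", self._vec({}, {}), self._vec({}, {}),
                                 (1, 0), ss.SelectionParams(strength=1.0))
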