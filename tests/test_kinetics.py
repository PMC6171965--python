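"""Motor binding, walking, release, turnover and boundary kinetics on
hand-built miniature states."""

import numpy as np
import pytest
from scipy.stats import chisquare

from astersim import HexagonDomain, SimulationConfig
from astersim.dynamics import (
    diffuse_free_motors,
    enforce_boundary,
    filament_turnover,
    motor_release,
    motor_search_and_bind,
    motor_walk,
)
from astersim.state import NO_FILAMENT

from .conftest import make_state


def cfg_small(**over):
    base = dict(n_filaments=1, n_motors=1, hexagon_circumradius=2.5)
    base.update(over)
    return SimulationConfig(**base)


class TestSearchAndBind:
    def test_no_filament_in_reach_no_binding(self, rng):
        cfg = cfg_small(motor_attach_rate=1000.0)
        state = make_state(fil=[(2.0, 2.0, 0.0)], motors=[dict(pos=(0.0, 0.0))])
        motor_search_and_bind(state, cfg, rng, step=1)
        assert not state.mot_bound.any()

    def test_binds_at_foot_of_perpendicular(self, rng):
        # filament along x through the origin; motor 0.1 um above x=0.2:
        # the closest point is the perpendicular foot, walk coord = +0.2
        cfg = cfg_small(motor_attach_rate=1000.0, free_attach_deterministic=False)
        state = make_state(fil=[(0.0, 0.0, 0.0)], motors=[dict(pos=(0.2, 0.1))])
        motor_search_and_bind(state, cfg, rng, step=1)
        assert state.mot_bound.sum() == 1  # one head only: a single filament
        h = int(np.nonzero(state.mot_bound[0])[0][0])
        assert state.mot_len[0, h] == pytest.approx(0.2)
        assert state.mot_fil[0, h] == 0

    def test_zero_attach_rate_never_binds(self, rng):
        cfg = cfg_small(motor_attach_rate=0.0, free_attach_deterministic=False)
        state = make_state(fil=[(0.0, 0.0, 0.0)], motors=[dict(pos=(0.0, 0.1))])
        for step in range(50):
            motor_search_and_bind(state, cfg, rng, step=step)
        assert not state.mot_bound.any()

    def test_free_motor_grabs_deterministically_when_enabled(self, rng):
        cfg = cfg_small(motor_attach_rate=0.0, free_attach_deterministic=True)
        state = make_state(fil=[(0.0, 0.0, 0.0)], motors=[dict(pos=(0.0, 0.1))])
        motor_search_and_bind(state, cfg, rng, step=1)
        assert state.mot_bound.sum() == 1

    def test_two_heads_take_two_distinct_filaments(self, rng):
        cfg = cfg_small(n_filaments=2, motor_attach_rate=1000.0)
        state = make_state(
            fil=[(0.0, 0.05, 0.0), (0.0, -0.05, 0.0)],
            motors=[dict(pos=(0.0, 0.0))],
        )
        motor_search_and_bind(state, cfg, rng, step=1)
        assert state.mot_bound.all()
        assert state.mot_fil[0, 0] != state.mot_fil[0, 1]

    def test_partner_filament_ineligible(self, rng):
        # one-bound motor with a single filament around: second head never
        # binds the same rod
        cfg = cfg_small(motor_attach_rate=1000.0)
        state = make_state(
            fil=[(0.0, 0.0, 0.0)],
            motors=[dict(bound=(0, None), lens=(0.1, 0.0))],
        )
        for step in range(50):
            motor_search_and_bind(state, cfg, rng, step=step)
        assert not state.mot_bound[0, 1]

    def test_binding_only_within_reach(self, rng):
        # perpendicular distance 0.31 > r = 0.3: not a candidate
        cfg = cfg_small(motor_attach_rate=1000.0)
        state = make_state(fil=[(0.0, 0.0, 0.0)], motors=[dict(pos=(0.0, 0.31))])
        motor_search_and_bind(state, cfg, rng, step=1)
        assert not state.mot_bound.any()


class TestWalk:
    def test_single_step_advance(self):
        cfg = cfg_small()
        state = make_state(fil=[(0, 0, 0)], motors=[dict(bound=(0, None), lens=(0.0, 0))])
        flags = motor_walk(state, cfg)
        assert state.mot_len[0, 0] == pytest.approx(0.01)
        assert not flags.any()

    def test_plus_end_arrival_flagged_and_capped(self):
        cfg = cfg_small()
        state = make_state(fil=[(0, 0, 0)], motors=[dict(bound=(0, None), lens=(0.495, 0))])
        flags = motor_walk(state, cfg)
        assert flags[0, 0]
        assert state.mot_len[0, 0] == pytest.approx(0.5)  # capped at the tip

    def test_frozen_motor_acts_as_crosslink(self):
        cfg = cfg_small(motor_velocity=0.0)
        state = make_state(fil=[(0, 0, 0)], motors=[dict(bound=(0, None), lens=(0.2, 0))])
        flags = motor_walk(state, cfg)
        assert state.mot_len[0, 0] == 0.2
        assert not flags.any()

    def test_walk_monotone_nondecreasing(self):
        cfg = cfg_small()
        state = make_state(fil=[(0, 0, 0)], motors=[dict(bound=(0, None), lens=(-0.3, 0))])
        prev = -0.3
        for _ in range(60):
            motor_walk(state, cfg)
            assert state.mot_len[0, 0] >= prev
            prev = state.mot_len[0, 0]


class TestRelease:
    def test_certain_stochastic_release(self, rng):
        cfg = cfg_small(motor_detach_rate=1000.0)
        state = make_state(
            fil=[(0, 0, 0), (0, 0.1, 0)], motors=[dict(bound=(0, 1), lens=(0.1, 0.1))]
        )
        motor_release(state, cfg, rng)
        assert not state.mot_bound.any()
        assert (state.mot_fil == NO_FILAMENT).all()

    def test_overstretch_releases_most_recent_head(self, rng):
        cfg = cfg_small(n_filaments=2, motor_detach_rate=0.0)
        state = make_state(
            fil=[(0.0, 0.0, 0.0), (0.0, 0.31, 0.0)],
            motors=[dict(bound=(0, 1), lens=(0.0, 0.0), bind_steps=(3, 7))],
        )
        motor_release(state, cfg, rng)  # extension 0.31 > r = 0.3
        assert state.mot_bound[0, 0]
        assert not state.mot_bound[0, 1]  # head B bound later -> released

    def test_no_trigger_no_release(self, rng):
        cfg = cfg_small(n_filaments=2, motor_detach_rate=0.0)
        state = make_state(
            fil=[(0.0, 0.0, 0.0), (0.0, 0.2, 0.0)],
            motors=[dict(bound=(0, 1), lens=(0.1, 0.1))],
        )
        motor_release(state, cfg, rng)
        assert state.mot_bound.all()

    def test_plus_end_flag_releases_after_force(self, rng):
        cfg = cfg_small()
        state = make_state(fil=[(0, 0, 0)], motors=[dict(bound=(0, None), lens=(0.49, 0))])
        flags = motor_walk(state, cfg)
        motor_release(state, cfg, rng, flags)
        assert not state.mot_bound.any()

    def test_fully_released_motor_rejoins_pool_at_midpoint(self, rng):
        cfg = cfg_small(n_filaments=2, motor_detach_rate=1000.0)
        state = make_state(
            fil=[(0.0, 0.0, 0.0), (0.0, 0.2, 0.0)],
            motors=[dict(bound=(0, 1), lens=(0.0, 0.0))],
        )
        motor_release(state, cfg, rng)
        np.testing.assert_allclose(state.mot_pos[0], [0.0, 0.1])


class TestTurnover:
    def test_zero_rate_changes_nothing(self, rng, domain):
        cfg = cfg_small(filament_turnover_rate=0.0)
        state = make_state(fil=[(0.5, 0.5, 1.0)], motors=[dict(pos=(0, 0))])
        n = filament_turnover(state, cfg, domain, rng, step=1)
        assert n == 0
        np.testing.assert_array_equal(state.fil_center[0], [0.5, 0.5])

    def test_replacement_count_near_binomial_mean(self, domain):
        # p2*dt = 0.05 per filament: 1000 filaments over 40 draws -> mean 50/step
        cfg = SimulationConfig(n_filaments=1000, n_motors=0, filament_turnover_rate=5.0)
        rng = np.random.default_rng(0)
        state = make_state(fil=[(0, 0, 0)] * 1000)
        total = sum(
            filament_turnover(state, cfg, domain, rng, step=s) for s in range(40)
        )
        assert total == pytest.approx(40 * 1000 * 0.05, rel=0.15)

    def test_bound_heads_released_on_turnover(self, rng, domain):
        cfg = cfg_small(n_filaments=1, n_motors=3, filament_turnover_rate=1e6)
        motors = [dict(bound=(0, None), lens=(0.1, 0)) for _ in range(3)]
        state = make_state(fil=[(0, 0, 0)], motors=motors)
        filament_turnover(state, cfg, domain, rng, step=5)
        assert not state.mot_bound.any()
        assert (state.fil_birth == 5).all()

    def test_exempt_filament_survives(self, rng, domain):
        cfg = cfg_small(filament_turnover_rate=1e6)
        state = make_state(fil=[(0.5, 0.5, 1.0)])
        state.fil_turnover_exempt[0] = True
        assert filament_turnover(state, cfg, domain, rng, step=1) == 0
        np.testing.assert_array_equal(state.fil_center[0], [0.5, 0.5])


class TestBoundary:
    def test_agents_inside_untouched(self, rng, domain):
        cfg = cfg_small()
        state = make_state(fil=[(0.5, 0.5, 1.0)], motors=[dict(pos=(0.1, 0.1))])
        enforce_boundary(state, cfg, domain, rng)
        np.testing.assert_array_equal(state.fil_center[0], [0.5, 0.5])
        np.testing.assert_array_equal(state.mot_pos[0], [0.1, 0.1])

    def test_escaped_filament_reinserted_with_orientation_kept(self, rng, domain):
        cfg = cfg_small(n_motors=1)
        state = make_state(
            fil=[(3.0, 0.0, 1.234)], motors=[dict(bound=(0, None), lens=(0.1, 0))]
        )
        enforce_boundary(state, cfg, domain, rng)
        assert domain.contains(state.fil_center[0])
        assert state.fil_angle[0] == 1.234
        assert not state.mot_bound.any()  # heads severed on teleport

    def test_escaped_free_motor_reinserted(self, rng, domain):
        cfg = cfg_small()
        state = make_state(fil=[(0, 0, 0)], motors=[dict(pos=(9.0, 9.0))])
        enforce_boundary(state, cfg, domain, rng)
        assert domain.contains(state.mot_pos[0])

    def test_reinsertion_uniform_over_hexagon(self, domain):
        # 10^4 escaped filaments land uniformly (chi-square over 6 triangles)
        n = 10_000
        cfg = SimulationConfig(n_filaments=n, n_motors=0, hexagon_circumradius=2.5)
        state = make_state(fil=[(50.0, 0.0, 0.0)] * n)
        enforce_boundary(state, cfg, domain, np.random.default_rng(3))
        pts = state.fil_center
        assert domain.contains(pts).all()
        sector = (np.floor(np.arctan2(pts[:, 1], pts[:, 0]) / (np.pi / 3))).astype(int) % 6
        assert chisquare(np.bincount(sector, minlength=6)).pvalue > 0.01


class TestDiffusion:
    def test_step_length_fixed(self, rng):
        cfg = cfg_small(free_motor_diffusion_step=0.05)
        state = make_state(fil=[(2, 2, 0)], motors=[dict(pos=(0.0, 0.0))])
        diffuse_free_motors(state, cfg, rng)
        assert np.linalg.norm(state.mot_pos[0]) == pytest.approx(0.05)

    def test_bound_and_tethered_motors_do_not_diffuse(self, rng):
        cfg = cfg_small(n_motors=2)
        state = make_state(
            fil=[(0, 0, 0)],
            motors=[
                dict(bound=(0, None), lens=(0.1, 0)),
                dict(pos=(1.0, 1.0), anchor=(1.0, 1.0)),
            ],
        )
        before = state.motor_head_positions().copy()
        diffuse_free_motors(state, cfg, rng)
        np.testing.assert_array_equal(state.motor_head_positions(), before)
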