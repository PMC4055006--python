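"""Capture simulator: flow profile, trajectory fates, oracles, reproducibility."""

import numpy as np
import pandas as pd
import pytest
from scipy.integrate import quad

from magtarget import (CellPopulation, CellSpec, FlowSpec, LinearBmagField,
                       MagnetSpec, TubeGeometry, capture_efficiency,
                       ce_velocity_curve, default_magnet, integrate_trajectory,
                       place_magnet, poiseuille_velocity, simulate_capture,
                       slab_capture_fraction)
from magtarget.cell_magnetics import saturated_moment

TUBE = TubeGeometry()


class TestPoiseuille:
    def test_centerline_and_wall(self):
        flow = FlowSpec(mean_velocity_m_per_s=4e-3)
        assert poiseuille_velocity(0.0, flow, TUBE) == pytest.approx(8e-3)
        assert poiseuille_velocity(TUBE.inner_radius_m, flow, TUBE) == 0.0

    def test_flux_average_is_mean_velocity(self):
        flow = FlowSpec(mean_velocity_m_per_s=7e-3)
        R = TUBE.inner_radius_m
        integral, _ = quad(
            lambda r: poiseuille_velocity(r, flow, TUBE) * 2 * np.pi * r, 0, R)
        assert integral / (np.pi * R ** 2) == pytest.approx(7e-3, abs=1e-12)

    def test_plug_profile(self):
        flow = FlowSpec(mean_velocity_m_per_s=4e-3, profile="plug")
        assert poiseuille_velocity(1e-3, flow, TUBE) == 4e-3

    def test_outside_lumen_rejected(self):
        with pytest.raises(ValueError):
            poiseuille_velocity(2e-3, FlowSpec(), TUBE)


class TestCaptureEfficiency:
    @pytest.mark.parametrize("q1,q2,expected", [(85, 15, 85.0), (0, 100, 0.0),
                                                (1, 0, 100.0)])
    def test_formula(self, q1, q2, expected):
        assert capture_efficiency(q1, q2) == expected

    def test_zero_total_rejected(self):
        with pytest.raises(ValueError):
            capture_efficiency(0, 0)


class TestTrajectories:
    def test_zero_moment_cell_exits(self, study_magnet):
        cell = CellSpec(iron_mass_kg=0.0)
        res = integrate_trajectory(cell, (0.0, 0.4e-3, -0.2e-3), FlowSpec(),
                                   TUBE, place_magnet(study_magnet, TUBE))
        assert res.fate == "exited"
        assert res.end_point_m[0] >= TUBE.length_m

    def test_cell_on_wall_under_magnet_captured_immediately(self, study_magnet):
        cell = CellSpec()
        y_wall = -(TUBE.inner_radius_m - 0.5 * cell.diameter_m)
        res = integrate_trajectory(cell,
                                   (TUBE.magnet_axial_position_m, y_wall, 0.0),
                                   FlowSpec(), TUBE,
                                   place_magnet(study_magnet, TUBE))
        assert res.fate == "captured"
        assert res.t_s == 0.0

    def test_inlet_outside_lumen_rejected(self, study_magnet):
        with pytest.raises(ValueError, match="inlet"):
            integrate_trajectory(CellSpec(), (0.0, 1.15e-3, 0.0), FlowSpec(),
                                 TUBE, place_magnet(study_magnet, TUBE))

    @pytest.mark.parametrize("v_bar,slope", [(4e-3, 10.0), (8e-3, 30.0),
                                             (20e-3, 80.0)])
    def test_uniform_force_threshold_matches_slab_oracle(self, v_bar, slope):
        """With uniform force and plug flow, the inlet height separating
        capture from exit has the closed form y* = u L / v - R_eff."""
        cell = CellSpec()
        u = saturated_moment(cell.iron_mass_kg) * slope / (
            3 * np.pi * 1e-3 * cell.diameter_m)
        r_eff = TUBE.inner_radius_m - 0.5 * cell.diameter_m
        y_star = u * TUBE.length_m / v_bar - r_eff
        assert -r_eff < y_star < r_eff, "parameter set must straddle the lumen"
        stub = LinearBmagField((0.0, -1.0, 0.0), slope)
        flow = FlowSpec(mean_velocity_m_per_s=v_bar, profile="plug")

        def fate_at(y0):
            res = integrate_trajectory(cell, (0.0, y0, 0.0), flow, TUBE, stub,
                                       mode="2d",
                                       capture_window_halfwidth_m=np.inf)
            return res.fate == "captured"

        # endpoints nudged off the walls: a cell released touching a wall is
        # a contact at t = 0, not a transport outcome
        lo, hi = -r_eff * (1 - 1e-6), r_eff * (1 - 1e-6)
        assert fate_at(lo) and not fate_at(hi)
        for _ in range(30):
            mid = 0.5 * (lo + hi)
            if fate_at(mid):
                lo = mid
            else:
                hi = mid
        assert abs(0.5 * (lo + hi) - y_star) < 0.01 * 2 * r_eff


class TestSimulateCapture:
    def test_zero_moment_population_ce_zero(self, study_magnet):
        pop = CellPopulation([CellSpec(iron_mass_kg=0.0)] * 40)
        res = simulate_capture(n_cells=40, population=pop,
                               magnet=study_magnet, seed=3)
        assert res.q1 == 0
        assert res.ce_pct == 0.0
        assert set(res.outcomes["fate"]) == {"exited"}

    def test_dominant_force_limit_captures_everything(self, study_magnet):
        strong = MagnetSpec(remanence_t=100 * study_magnet.remanence_t)
        res = simulate_capture(n_cells=40, magnet=strong,
                               flow=FlowSpec(mean_velocity_m_per_s=4e-3),
                               seed=5)
        assert res.ce_pct == 100.0

    def test_conservation_and_se(self, study_magnet):
        res = simulate_capture(n_cells=120, magnet=study_magnet,
                               flow=FlowSpec(mean_velocity_m_per_s=20e-3),
                               seed=11)
        assert res.q1 + res.q2 + res.flagged == res.n
        assert res.flagged == 0
        ce = res.ce_pct
        assert res.se_pct == pytest.approx(
            np.sqrt(ce * (100 - ce) / (res.q1 + res.q2)))

    def test_seed_reproducibility_bit_identical(self, study_magnet):
        kwargs = dict(n_cells=60, magnet=study_magnet,
                      flow=FlowSpec(mean_velocity_m_per_s=50e-3), seed=21)
        a = simulate_capture(**kwargs)
        b = simulate_capture(**kwargs)
        assert (a.q1, a.q2, a.flagged) == (b.q1, b.q2, b.flagged)
        pd.testing.assert_frame_equal(a.outcomes, b.outcomes)

    def test_ce_monotone_in_remanence(self, study_magnet):
        flow = FlowSpec(mean_velocity_m_per_s=50e-3)
        weak = simulate_capture(n_cells=150, magnet=study_magnet, flow=flow,
                                seed=9)
        strong = simulate_capture(
            n_cells=150, magnet=MagnetSpec(remanence_t=1.8), flow=flow, seed=9)
        assert strong.ce_pct >= weak.ce_pct

    def test_ce_monotone_in_iron_load(self, study_magnet):
        from magtarget import PopulationParams
        flow = FlowSpec(mean_velocity_m_per_s=50e-3)
        lo = simulate_capture(n_cells=150, magnet=study_magnet, flow=flow,
                              population_params=PopulationParams(
                                  iron_mean_kg=10e-15, iron_sd_kg=1e-15),
                              seed=13)
        hi = simulate_capture(n_cells=150, magnet=study_magnet, flow=flow,
                              population_params=PopulationParams(
                                  iron_mean_kg=40e-15, iron_sd_kg=1e-15),
                              seed=13)
        assert hi.ce_pct >= lo.ce_pct


class TestCeCurve:
    def test_single_velocity_single_row(self, study_magnet):
        table = ce_velocity_curve([20e-3], n_cells=40, seed=2,
                                  magnet=study_magnet)
        assert len(table) == 1
        assert table.loc[0, "velocity_m_per_s"] == 20e-3

    def test_identical_velocities_identical_ce(self, study_magnet):
        table = ce_velocity_curve([50e-3, 50e-3], n_cells=40, seed=2,
                                  magnet=study_magnet)
        assert table.loc[0, "ce_pct"] == table.loc[1, "ce_pct"]

    def test_requires_a_velocity(self):
        with pytest.raises(ValueError):
            ce_velocity_curve([])


class TestSlabFormula:
    def test_closed_form(self):
        assert slab_capture_fraction(1e-3, 4e-3, 2e-3, 20e-3) == 1.0
        assert slab_capture_fraction(1e-4, 0.1, 2e-3, 20e-3) == pytest.approx(
            0.01)
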