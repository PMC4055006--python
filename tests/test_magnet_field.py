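"""Magnetostatics of the cylinder magnet: closed form vs oracle, symmetries."""

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

from magtarget import (EDGE_MARGIN_M, MagnetSpec, UniformField,
                       calibrate_remanence, default_magnet, field_at,
                       field_map, gradient_at, on_axis_field)
from magtarget.magnet_field import b_field


class TestOnAxisField:
    def test_far_field_decays(self, study_magnet):
        assert abs(on_axis_field(1.0, study_magnet)) < 1e-4

    def test_calibration_identity_at_face(self, study_magnet):
        assert on_axis_field(0.0, study_magnet) == pytest.approx(0.600)

    def test_value_at_working_distance(self, study_magnet):
        # closed form at z = 1 mm, cross-checked against the disk-charge oracle
        assert on_axis_field(1e-3, study_magnet) == pytest.approx(0.450, abs=1e-3)

    def test_rejects_points_behind_face(self, study_magnet):
        with pytest.raises(ValueError):
            on_axis_field(-1e-3, study_magnet)

    @given(z1=st.floats(0.0, 0.05), dz=st.floats(1e-6, 0.05))
    @settings(max_examples=50, deadline=None, derandomize=True)
    def test_strictly_decreasing(self, z1, dz):
        magnet = MagnetSpec(remanence_t=1.3)
        assert on_axis_field(z1, magnet) > on_axis_field(z1 + dz, magnet)


class TestCalibration:
    def test_remanence_for_600mT(self):
        assert calibrate_remanence(0.600, 4e-3, 8e-3) == pytest.approx(
            1.3417, abs=1e-3)

    def test_zero_target(self):
        assert calibrate_remanence(0.0) == 0.0

    def test_round_trip_exact(self):
        magnet = default_magnet(0.600)
        assert on_axis_field(0.0, magnet) == pytest.approx(0.600, rel=1e-12)

    def test_nonphysical_target_warns(self):
        with pytest.warns(UserWarning, match="2 T"):
            calibrate_remanence(1.5, 4e-3, 8e-3)

    def test_flank_calibration_selectable(self):
        magnet = default_magnet(0.600, where="flank")
        fs = field_at((4e-3 + 0.0, 0.0, EDGE_MARGIN_M), magnet)
        assert fs.b_mag_t == pytest.approx(0.600, rel=1e-6)
        # the flank maximum exceeds the face-center field, so the flank
        # calibration needs a weaker remanence
        assert magnet.remanence_t < default_magnet(0.600).remanence_t


class TestFieldAt:
    def test_axis_consistency_with_closed_form(self, study_magnet):
        for z in (0.5e-3, 1e-3, 5e-3, 20e-3):
            fs = field_at((0.0, 0.0, z), study_magnet)
            assert abs(fs.b_t[2] - on_axis_field(z, study_magnet)) < 1e-6
            assert abs(fs.b_t[0]) < 1e-12 and abs(fs.b_t[1]) < 1e-12

    def test_matches_brute_force_oracle(self, study_magnet, field_oracle):
        rng = np.random.default_rng(42)
        checked = 0
        while checked < 50:
            rho = rng.uniform(0.0, 15e-3)
            z = rng.uniform(0.3e-3, 15e-3)
            if np.hypot(rho - 4e-3, z) < 3 * EDGE_MARGIN_M:
                continue
            fs = field_at((rho, 0.0, z), study_magnet)
            br_o, bz_o = field_oracle(rho, z, study_magnet)
            err = np.hypot(fs.b_t[0] - br_o, fs.b_t[2] - bz_o)
            assert err < 1e-3 * np.hypot(br_o, bz_o)
            checked += 1

    def test_axisymmetry(self, study_magnet):
        # same (rho, z), different azimuth: |B| identical, B rotates with theta
        ref = field_at((3e-3, 0.0, 2e-3), study_magnet)
        for theta in (0.7, 2.0, 4.5):
            pt = (3e-3 * np.cos(theta), 3e-3 * np.sin(theta), 2e-3)
            fs = field_at(pt, study_magnet)
            assert fs.b_mag_t == pytest.approx(ref.b_mag_t, rel=1e-12)

    def test_interior_rejected(self, study_magnet):
        with pytest.raises(ValueError, match="inside"):
            field_at((0.0, 0.0, -4e-3), study_magnet)

    def test_edge_margin_clamped_and_flagged(self, study_magnet):
        with pytest.warns(UserWarning, match="edge"):
            fs = field_at((4e-3, 0.0, 1e-5), study_magnet)
        assert fs.clamped
        assert np.isfinite(fs.b_mag_t)


class TestGradientAt:
    def test_uniform_stub_has_zero_gradient(self):
        stub = UniformField((0.0, 0.0, 0.3))
        fs = gradient_at((1e-3, 2e-3, 3e-3), stub)
        assert np.allclose(fs.grad, 0.0)
        assert np.allclose(fs.grad_bmag, 0.0)

    def test_on_axis_axial_derivative_matches_analytic(self, study_magnet):
        z = 1e-3
        R, L, Br = (study_magnet.radius_m, study_magnet.length_m,
                    study_magnet.remanence_t)
        analytic = 0.5 * Br * (R ** 2 / ((z + L) ** 2 + R ** 2) ** 1.5
                               - R ** 2 / (z ** 2 + R ** 2) ** 1.5)
        fs = gradient_at((0.0, 0.0, z), study_magnet)
        assert fs.grad[2, 2] == pytest.approx(analytic, rel=5e-3)

    def test_divergence_free(self, study_magnet):
        rng = np.random.default_rng(7)
        checked = 0
        while checked < 20:
            rho = rng.uniform(0.0, 12e-3)
            z = rng.uniform(0.5e-3, 12e-3)
            if np.hypot(rho - 4e-3, z) < 5e-4:
                continue
            theta = rng.uniform(0, 2 * np.pi)
            fs = gradient_at((rho * np.cos(theta), rho * np.sin(theta), z),
                             study_magnet)
            div = np.trace(fs.grad)
            assert abs(div) < 1e-3 * np.linalg.norm(fs.grad)
            checked += 1

    def test_radial_bmag_derivative_antisymmetric(self, study_magnet):
        table = field_map([-3e-3, 3e-3], [1e-3], study_magnet)
        db = table.sort_values("r_m")["dB_dr"].values
        assert db[0] == pytest.approx(-db[1], rel=1e-6)

    def test_stencil_crossing_surface_raises(self, study_magnet):
        with pytest.raises(ValueError, match="stencil"):
            gradient_at((0.0, 0.0, 5e-7), study_magnet)


class TestFieldMap:
    def test_profile_decays_beyond_flank(self, study_magnet):
        r = np.linspace(4.5e-3, 15e-3, 40)
        table = field_map(r, [1e-3], study_magnet)
        assert np.all(np.diff(table["Bmag"].values) < 0)

    def test_profile_decays_with_z(self, study_magnet):
        z = np.linspace(0.5e-3, 20e-3, 40)
        table = field_map([0.0], z, study_magnet)
        assert np.all(np.diff(table.sort_values("z_m")["Bmag"].values) < 0)

    def test_empty_grid(self, study_magnet):
        assert field_map([], [1e-3], study_magnet).empty

    def test_interior_grid_rejected(self, study_magnet):
        with pytest.raises(ValueError):
            field_map([0.0], [-4e-3], study_magnet)


class TestPose:
    def test_rigid_transform_preserves_magnitude(self, study_magnet):
        posed = study_magnet.with_pose((0.01, -0.002, 0.0), (0.0, 1.0, 0.0))
        # point 1 mm in front of the pole face along the new axis
        b_posed = b_field([(0.01, -0.001, 0.0)], posed)[0]
        assert np.linalg.norm(b_posed) == pytest.approx(
            on_axis_field(1e-3, study_magnet), rel=1e-12)
        # field points along the magnet axis there
        assert b_posed[1] == pytest.approx(np.linalg.norm(b_posed), rel=1e-9)
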