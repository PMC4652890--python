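"""Nearness inversion, COMANV, steering sigmoid and saccade command."""

import numpy as np
import pytest

from comanav.control import (SquaredFlowAccumulator, cad_can, comanv,
                             control_from_integrated, nearness_from_integrated,
                             saccade_command, vertical_average, weight,
                             wrap_deg)
from comanav.retina import RetinaGeometry


@pytest.fixture(scope="module")
def g():
    return RetinaGeometry()


class TestAccumulator:
    def test_constant_field_squares(self, g):
        acc = SquaredFlowAccumulator("geometric")
        f = np.full(g.shape, 0.3), np.full(g.shape, 0.4)
        for _ in range(5):
            acc.add_geometric(*f)
        isf = acc.result()
        assert np.allclose(isf.s_phi, 0.09) and np.allclose(isf.s_eps, 0.16)

    def test_alternating_sign_equals_constant(self, g):
        a, b = SquaredFlowAccumulator("geometric"), SquaredFlowAccumulator("geometric")
        f_phi = np.full(g.shape, 0.2)
        f_eps = np.full(g.shape, 0.1)
        for k in range(4):
            a.add_geometric(f_phi, f_eps)
            s = -1.0 if k % 2 else 1.0
            b.add_geometric(s * f_phi, s * f_eps)
        assert np.allclose(a.result().s_phi, b.result().s_phi)

    def test_empty_window_rejected(self):
        with pytest.raises(ValueError):
            SquaredFlowAccumulator("geometric").result()

    def test_emd_regridding_shapes_and_average(self, g):
        acc = SquaredFlowAccumulator("emd")
        h = np.zeros((91, 180))
        v = np.zeros((90, 181))
        h[:, 10] = 2.0   # detector between receptor columns 10 and 11
        acc.add_emd(h, v)
        isf = acc.result()
        assert isf.s_phi.shape == (91, 181)
        # flanking average: receptors 10 and 11 each get half the square
        assert np.allclose(isf.s_phi[:, 10], 2.0)
        assert np.allclose(isf.s_phi[:, 11], 2.0)
        assert np.allclose(isf.s_phi[:, 12], 0.0)

    def test_source_validation(self):
        with pytest.raises(ValueError):
            SquaredFlowAccumulator("other")


class TestNearnessInversion:
    def test_direct_arithmetic(self, g):
        """Single tick, OF_phi=0.3, OF_eps=0.2 at 30 deg elevation."""
        acc = SquaredFlowAccumulator("geometric")
        f_phi = np.zeros(g.shape)
        f_eps = np.zeros(g.shape)
        row = 60  # eps = +30 deg
        f_phi[row], f_eps[row] = 0.3, 0.2
        acc.add_geometric(f_phi, f_eps)
        nm = nearness_from_integrated(acc.result(), g)
        assert nm.values[row, 50] == pytest.approx(
            np.sqrt(0.09 + 0.04 / 0.25))

    def test_sphere_recovery_with_mixed_directions(self, g):
        """Constant-nearness surround: v*mu recovered everywhere, FOE removed."""
        v, mu = 0.1, 5.0
        rng = np.random.default_rng(3)
        acc = SquaredFlowAccumulator("geometric")
        phi = g.phi_rad[None, :]
        sin_eps = np.sin(g.eps_rad)[:, None]
        ones = np.ones(g.shape)
        for _ in range(50):
            d = np.deg2rad(rng.normal(0.0, 18.0))
            acc.add_geometric(v * mu * np.sin(phi - d) * ones,
                              v * mu * sin_eps * np.cos(phi - d) * ones)
        nm = nearness_from_integrated(acc.result(), g)
        vals = nm.values[nm.valid_rows]
        assert np.max(np.abs(vals - v * mu)) / (v * mu) < 0.01

    def test_single_direction_flow_null_at_foe_foc(self, g):
        """With one translation direction both flow components vanish at the
        FOE/FOC singular directions, independent of the nearness; the mixed-
        direction integration removes the singularity."""
        v, mu = 0.1, 5.0
        phi = g.phi_rad[None, :]
        sin_eps = np.sin(g.eps_rad)[:, None]
        ones = np.ones(g.shape)
        single = SquaredFlowAccumulator("geometric")
        single.add_geometric(v * mu * np.sin(phi) * ones,
                             v * mu * sin_eps * np.cos(phi) * ones)
        isf = single.result()
        for col in (90, 0, 180):  # FOE at phi=0; FOC at +/-180
            assert isf.s_phi[45, col] == pytest.approx(0.0, abs=1e-24)
            assert isf.s_eps[45, col] == pytest.approx(0.0, abs=1e-24)
        mixed = SquaredFlowAccumulator("geometric")
        for d_deg in (-18.0, 18.0):
            d = np.deg2rad(d_deg)
            mixed.add_geometric(v * mu * np.sin(phi - d) * ones,
                                v * mu * sin_eps * np.cos(phi - d) * ones)
        nm = nearness_from_integrated(mixed.result(), g)
        assert nm.values[45, 90] == pytest.approx(v * mu, rel=1e-9)

    def test_pole_rows_masked(self, g):
        acc = SquaredFlowAccumulator("geometric")
        acc.add_geometric(np.ones(g.shape), np.ones(g.shape))
        nm = nearness_from_integrated(acc.result(), g)
        assert not nm.valid_rows[0] and not nm.valid_rows[-1]

    def test_equator_interpolated_vs_excluded(self, g):
        acc = SquaredFlowAccumulator("geometric")
        acc.add_geometric(np.ones(g.shape), np.zeros(g.shape))
        nm_i = nearness_from_integrated(acc.result(), g)
        assert nm_i.values[45, 7] == pytest.approx(1.0)
        nm_e = nearness_from_integrated(acc.result(), g, equator="exclude")
        assert not nm_e.valid_rows[45]

    def test_emd_band_masked_and_gain_applied(self, g):
        acc = SquaredFlowAccumulator("emd")
        acc.add_emd(np.full((91, 180), 1e-3), np.zeros((90, 181)))
        nm = nearness_from_integrated(acc.result(), g, emd_gain=10.0,
                                      emd_band_deg=20.0)
        assert not nm.valid_rows[45] and not nm.valid_rows[50]  # 0, 10 deg
        assert nm.valid_rows[55]                                 # 20 deg
        assert nm.values[55, 30] == pytest.approx(1e-2)


class TestVerticalAverageAndComanv:
    def test_constant_map(self, g):
        acc = SquaredFlowAccumulator("geometric")
        acc.add_geometric(np.full(g.shape, 0.5), np.zeros(g.shape))
        nm = nearness_from_integrated(acc.result(), g)
        prof = vertical_average(nm)
        assert prof.shape == (180,)
        assert np.allclose(prof, 0.5)

    def test_masked_rows_do_not_contribute(self, g):
        acc = SquaredFlowAccumulator("geometric")
        acc.add_geometric(np.ones(g.shape), np.zeros(g.shape))
        nm = nearness_from_integrated(acc.result(), g)
        nm.values[0, :] = 99.0  # masked pole row: must change nothing
        assert np.allclose(vertical_average(nm), 1.0)

    def test_single_column_profile(self, g):
        acc = SquaredFlowAccumulator("geometric")
        f = np.zeros(g.shape)
        f[:, 30] = 1.0
        acc.add_geometric(f, np.zeros(g.shape))
        prof = vertical_average(nearness_from_integrated(acc.result(), g))
        assert prof[30] > 0 and np.allclose(np.delete(prof, 30), 0.0)

    def test_uniform_profile_zero_comanv(self, g):
        vec = comanv(np.full(180, 1.0), g)
        assert np.hypot(*vec) < 1e-12

    def test_single_bin_direction(self, g):
        prof = np.zeros(180)
        prof[np.argmin(np.abs(g.phi_deg[:-1] - 90.0))] = 1.0
        vec = comanv(prof, g)
        assert np.degrees(np.arctan2(vec[1], vec[0])) == pytest.approx(90.0)

    def test_mirror_bins_cancel_to_forward(self, g):
        prof = np.zeros(180)
        prof[np.argmin(np.abs(g.phi_deg[:-1] - 60.0))] = 1.0
        prof[np.argmin(np.abs(g.phi_deg[:-1] + 60.0))] = 1.0
        vec = comanv(prof, g)
        assert np.degrees(np.arctan2(vec[1], vec[0])) == pytest.approx(0.0)

    def test_resolution_independent_scale(self, g):
        """The azimuthal integral: a uniform half-profile of value 1 gives
        norm 2 (integral of cos over a half-circle) regardless of binning."""
        prof = np.where(np.abs(g.phi_deg[:-1]) <= 90.0, 1.0, 0.0)
        vec = comanv(prof, g)
        assert np.hypot(*vec) == pytest.approx(2.0, rel=0.02)


class TestSteering:
    def test_cad_opposite_comanv(self):
        cad, can = cad_can(np.array([0.0, 1.0]))
        assert cad == pytest.approx(-90.0)

    def test_can_is_norm(self):
        _, can = cad_can(np.array([0.3, 0.4]))
        assert can == pytest.approx(0.5)

    def test_zero_vector_convention(self):
        cad, can = cad_can(np.zeros(2))
        assert cad == 0.0 and can == 0.0
        assert weight(0.0, 2.0, 4.0) == 0.0

    def test_weight_at_threshold_is_half(self):
        assert weight(4.0, 2.0, 4.0) == pytest.approx(0.5)

    def test_weight_example_gain2(self):
        assert weight(8.0, 2.0, 4.0) == pytest.approx(0.8)

    def test_weight_monotone_to_one(self):
        ws = [weight(c, 2.0, 4.0) for c in (0.5, 1, 2, 4, 8, 100)]
        assert all(b > a for a, b in zip(ws, ws[1:]))
        assert ws[-1] > 0.99

    def test_invalid_gain_threshold(self):
        with pytest.raises(ValueError):
            weight(1.0, 0.0, 4.0)

    @pytest.mark.parametrize("w,cad,alpha,expected", [
        (1.0, 55.0, -30.0, 55.0),
        (0.0, 55.0, -30.0, -30.0),
        (0.8, 90.0, -30.0, 66.0),
    ])
    def test_saccade_command_blend(self, w, cad, alpha, expected):
        assert saccade_command(cad, w, alpha) == pytest.approx(expected)

    def test_goal_noise_seeded(self):
        rng1 = np.random.default_rng(5)
        rng2 = np.random.default_rng(5)
        a = saccade_command(0.0, 0.0, 10.0, sigma_deg=5.0, rng=rng1)
        b = saccade_command(0.0, 0.0, 10.0, sigma_deg=5.0, rng=rng2)
        assert a == b and a != 10.0

    def test_wrap_deg(self):
        assert wrap_deg(190.0) == pytest.approx(-170.0)
        assert wrap_deg(-190.0) == pytest.approx(170.0)
        assert wrap_deg(180.0) == pytest.approx(180.0)


def test_full_decision_chain_points_away_from_single_wall(g):
    """A nearness excess on the left drives a rightward avoidance saccade."""
    acc = SquaredFlowAccumulator("geometric")
    phi = g.phi_rad[None, :]
    sin_eps = np.sin(g.eps_rad)[:, None]
    rng = np.random.default_rng(0)
    mu = 1.0 + 4.0 * np.exp(-0.5 * ((g.phi_deg[None, :] - 90.0) / 30.0) ** 2)
    ones = np.ones(g.shape)
    for _ in range(50):
        d = np.deg2rad(rng.normal(0.0, 18.0))
        acc.add_geometric(0.1 * mu * np.sin(phi - d) * ones,
                          0.1 * mu * sin_eps * np.cos(phi - d) * ones)
    ctrl = control_from_integrated(acc.result(), g=2.0, n0=0.05)
    assert -135.0 < ctrl.cad_deg < -45.0   # away from the excess at +90
    assert ctrl.w > 0.5
    assert ctrl.gamma_deg < 0.0
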