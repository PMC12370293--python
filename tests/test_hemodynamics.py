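import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from endoflow import hemodynamics as hemo

import fd_oracle

UL_MIN = 1e-9 / 60.0  # m^3/s per uL/min


@pytest.fixture(scope="module")
def ctrl():
    return hemo.SeriesControl()


class TestMeanVelocity:
    @pytest.mark.parametrize(
        "q_ul_min, expected",
        [(0.0, 0.0), (13.0, 2.1667e-3), (1.3, 2.1667e-4)],
    )
    def test_chip_values(self, chip_geometry, q_ul_min, expected):
        um = hemo.mean_velocity(chip_geometry, q_ul_min * UL_MIN)
        assert um == pytest.approx(expected, rel=1e-4)

    def test_negative_flow_rejected(self, chip_geometry):
        with pytest.raises(hemo.InvalidParameterError):
            hemo.mean_velocity(chip_geometry, -1e-9)

    def test_bad_geometry_rejected(self):
        with pytest.raises(hemo.InvalidParameterError):
            hemo.ChannelGeometry(-1e-3, 50e-6, 17e-3)


class TestSeriesC1:
    def test_bracket_value_wide_channel(self, chip_geometry, ctrl):
        # W/H = 10: the normalisation bracket is small but positive
        bracket, n_used = hemo.c1_bracket(chip_geometry, ctrl)
        assert bracket == pytest.approx(9.37e-3, rel=5e-3)
        assert 1 <= n_used <= ctrl.n_terms

    def test_zero_velocity(self, chip_geometry, ctrl):
        assert hemo.series_c1(chip_geometry, 0.0, ctrl) == 0.0

    def test_linear_in_um(self, chip_geometry, ctrl):
        c1 = hemo.series_c1(chip_geometry, 1e-3, ctrl)
        assert hemo.series_c1(chip_geometry, 3e-3, ctrl) == pytest.approx(3 * c1)

    def test_extreme_aspect_ratio_raises(self, ctrl):
        geom = hemo.ChannelGeometry(1.0, 1e-9, 1.0)
        with pytest.raises(hemo.IllConditionedGeometryError):
            hemo.series_c1(geom, 1e-3, ctrl)


class TestVelocityField:
    def test_no_slip_and_symmetry(self, chip_geometry, ctrl):
        W, H = chip_geometry.half_width, chip_geometry.half_height
        c1 = hemo.series_c1(chip_geometry, 2.1667e-3, ctrl)
        ys = np.linspace(-H, H, 7)
        assert np.allclose(hemo.velocity_at(chip_geometry, c1, W, ys, ctrl), 0, atol=1e-12)
        assert np.allclose(hemo.velocity_at(chip_geometry, c1, -W, ys, ctrl), 0, atol=1e-12)
        x, y = 0.3 * W, 0.4 * H
        u = hemo.velocity_at(chip_geometry, c1, x, y, ctrl)
        assert hemo.velocity_at(chip_geometry, c1, -x, y, ctrl) == pytest.approx(u)
        assert hemo.velocity_at(chip_geometry, c1, x, -y, ctrl) == pytest.approx(u)
        assert u > 0

    def test_outside_cross_section_rejected(self, chip_geometry, ctrl):
        with pytest.raises(hemo.DomainError):
            hemo.velocity_at(chip_geometry, -1e3, 2 * chip_geometry.half_width, 0.0, ctrl)

    def test_matches_fd_oracle_pointwise(self, chip_geometry, pinned_fluid, ctrl):
        Q = 13.0 * UL_MIN
        xs, ys, U = fd_oracle.solve_duct(
            chip_geometry.half_width, chip_geometry.half_height, Q, 201, 41
        )
        c1 = hemo.series_c1(chip_geometry, hemo.mean_velocity(chip_geometry, Q), ctrl)
        series = hemo.velocity_at(chip_geometry, c1, xs[:, None], ys[None, :], ctrl)
        core = series > 0.1 * series.max()
        rel = np.abs(U[core] - series[core]) / series.max()
        assert rel.max() < 0.01

    def test_mass_conservation(self, chip_geometry, ctrl):
        # quadrature of the series field recovers Q to < 0.5%
        Q = 13.0 * UL_MIN
        W, H = chip_geometry.half_width, chip_geometry.half_height
        xs = np.linspace(-W, W, 201)
        ys = np.linspace(-H, H, 201)
        c1 = hemo.series_c1(chip_geometry, hemo.mean_velocity(chip_geometry, Q), ctrl)
        U = hemo.velocity_at(chip_geometry, c1, xs[:, None], ys[None, :], ctrl)
        q_num = np.trapezoid(np.trapezoid(U, ys, axis=1), xs)
        assert q_num == pytest.approx(Q, rel=5e-3)


class TestWallShear:
    def test_vanishes_at_corners_and_even(self, chip_geometry, pinned_fluid, ctrl):
        W = chip_geometry.half_width
        c1 = hemo.series_c1(chip_geometry, 2.1667e-3, ctrl)
        assert hemo.wss_bottom(chip_geometry, pinned_fluid, c1, W, ctrl) == pytest.approx(0, abs=1e-9)
        x = 0.37 * W
        assert hemo.wss_bottom(chip_geometry, pinned_fluid, c1, x, ctrl) == pytest.approx(
            hemo.wss_bottom(chip_geometry, pinned_fluid, c1, -x, ctrl)
        )

    @pytest.mark.parametrize("q_ul_min, peak", [(13.0, 0.14), (1.3, 0.014)])
    def test_table_peaks(self, chip_geometry, pinned_fluid, ctrl, q_ul_min, peak):
        _, _, p = hemo.wss_profile(chip_geometry, pinned_fluid, q_ul_min * UL_MIN, 201, ctrl)
        # two significant figures, as tabulated
        assert float(f"{p:.2g}") == peak

    def test_profile_peak_at_center_and_linear_in_q(self, chip_geometry, pinned_fluid, ctrl):
        x, tau, p1 = hemo.wss_profile(chip_geometry, pinned_fluid, 13 * UL_MIN, 201, ctrl)
        # centerline value equals the max up to series-truncation ripple
        assert tau[len(x) // 2] == pytest.approx(p1, rel=1e-4)
        assert abs(x[tau.argmax()]) <= 0.02 * chip_geometry.half_width
        _, _, p2 = hemo.wss_profile(chip_geometry, pinned_fluid, 26 * UL_MIN, 201, ctrl)
        assert p2 == pytest.approx(2 * p1)

    def test_matches_fd_oracle(self, chip_geometry, pinned_fluid, ctrl):
        Q = 13.0 * UL_MIN
        xs, ys, U = fd_oracle.solve_duct(
            chip_geometry.half_width, chip_geometry.half_height, Q, 401, 41
        )
        tau_fd = fd_oracle.wall_shear_centerline(U, ys, pinned_fluid.dynamic_viscosity)
        c1 = hemo.series_c1(chip_geometry, hemo.mean_velocity(chip_geometry, Q), ctrl)
        tau = hemo.wss_bottom(chip_geometry, pinned_fluid, c1, 0.0, ctrl)
        assert tau_fd == pytest.approx(tau, rel=0.02)

    def test_convergence_in_terms(self, chip_geometry, pinned_fluid):
        base = hemo.SeriesControl(n_terms=500, convergence_tol=0.0)
        fine = hemo.SeriesControl(n_terms=1000, convergence_tol=0.0)
        um = hemo.mean_velocity(chip_geometry, 13 * UL_MIN)
        t1 = hemo.wss_bottom(
            chip_geometry, pinned_fluid, hemo.series_c1(chip_geometry, um, base), 0.0, base
        )
        t2 = hemo.wss_bottom(
            chip_geometry, pinned_fluid, hemo.series_c1(chip_geometry, um, fine), 0.0, fine
        )
        assert abs(t2 / t1 - 1) < 1e-4

    @settings(max_examples=20, deadline=None, derandomize=True)
    @given(
        q=st.floats(0.5, 50.0),
        mu=st.floats(5e-4, 5e-3),
    )
    def test_homogeneous_in_q_and_mu(self, q, mu):
        # WSS and pressure drop are degree-1 homogeneous in Q and in mu
        geom = hemo.ChannelGeometry.from_full_dimensions(1.0e-3, 100e-6, 17e-3)
        fl = hemo.Fluid(density=1000.0, dynamic_viscosity=mu)
        fl2 = hemo.Fluid(density=1000.0, dynamic_viscosity=2 * mu)
        ctrl = hemo.SeriesControl(n_terms=100)
        _, _, p = hemo.wss_profile(geom, fl, q * UL_MIN, 11, ctrl)
        _, _, p_q = hemo.wss_profile(geom, fl, 2 * q * UL_MIN, 11, ctrl)
        _, _, p_mu = hemo.wss_profile(geom, fl2, q * UL_MIN, 11, ctrl)
        assert p_q == pytest.approx(2 * p, rel=1e-9)
        assert p_mu == pytest.approx(2 * p, rel=1e-9)
        assert hemo.channel_delta_p(geom, fl, 2 * q * UL_MIN) == pytest.approx(
            2 * hemo.channel_delta_p(geom, fl, q * UL_MIN), rel=1e-9
        )
        assert hemo.channel_delta_p(geom, fl2, q * UL_MIN) == pytest.approx(
            2 * hemo.channel_delta_p(geom, fl, q * UL_MIN), rel=1e-9
        )


class TestFrictionModel:
    def test_hydraulic_diameter(self, chip_geometry):
        assert hemo.hydraulic_diameter(chip_geometry) == pytest.approx(1.818e-4, rel=1e-3)
        square = hemo.ChannelGeometry.from_full_dimensions(2e-4, 2e-4, 1e-2)
        assert hemo.hydraulic_diameter(square) == pytest.approx(2e-4)
        swapped = hemo.ChannelGeometry(chip_geometry.half_height, chip_geometry.half_width, 1.0)
        assert hemo.hydraulic_diameter(swapped) == pytest.approx(
            hemo.hydraulic_diameter(chip_geometry)
        )

    def test_friction_factor_values(self):
        assert hemo.friction_factor(10.0, 1.0) == pytest.approx(84.70, abs=0.01)
        # parallel-plate limit
        assert hemo.friction_factor(1e9, 1.0) == pytest.approx(96.0, rel=1e-6)
        assert hemo.friction_factor(10.0, 2.0) == pytest.approx(84.70 / 2, abs=0.01)
        with pytest.raises(hemo.InvalidParameterError):
            hemo.friction_factor(0.5, 100.0)

    def test_pressure_gradient(self, chip_geometry, pinned_fluid):
        assert hemo.pressure_gradient(chip_geometry, pinned_fluid, 0.0) == 0.0
        dpdz = hemo.pressure_gradient(chip_geometry, pinned_fluid, 13 * UL_MIN)
        assert dpdz == pytest.approx(2.78e3, rel=5e-3)
        assert hemo.pressure_gradient(
            chip_geometry, pinned_fluid, 26 * UL_MIN
        ) == pytest.approx(2 * dpdz)

    @pytest.mark.parametrize("q_ul_min, dp", [(13.0, 47.1), (1.3, 4.71)])
    def test_channel_delta_p(self, chip_geometry, pinned_fluid, q_ul_min, dp):
        val = hemo.channel_delta_p(chip_geometry, pinned_fluid, q_ul_min * UL_MIN)
        assert val == pytest.approx(dp, rel=5e-3)

    def test_delta_p_exact_scaling(self, chip_geometry, pinned_fluid):
        assert hemo.channel_delta_p(
            chip_geometry, pinned_fluid, 13 * UL_MIN
        ) == pytest.approx(10 * hemo.channel_delta_p(chip_geometry, pinned_fluid, 1.3 * UL_MIN))


class TestPressures:
    def test_hydrostatic_head(self):
        fl = hemo.Fluid(density=1000.0, dynamic_viscosity=0.00072)
        cond = hemo.FlowCondition(flow_rate=0.0, outlet_head=0.40, gravity=9.81)
        out = hemo.outlet_gauge_pressure(fl, cond)
        assert out.total == pytest.approx(3924.0)
        assert out.hydrostatic == pytest.approx(3924.0)

    def test_zero_head_no_friction(self):
        fl = hemo.Fluid()
        cond = hemo.FlowCondition(flow_rate=13 * UL_MIN, outlet_head=0.0)
        assert hemo.outlet_gauge_pressure(fl, cond).total == 0.0

    def test_tube_friction_term_subpascal(self):
        # stated-viscosity medium in a 0.5 m, 1 mm tube at the high flow rate
        fl = hemo.Fluid(density=1000.0, dynamic_viscosity=7.2e-4)
        cond = hemo.FlowCondition(
            flow_rate=13 * UL_MIN, outlet_head=0.40,
            tube_inner_diameter=1e-3, tube_length=0.5, include_tube_friction=True,
        )
        out = hemo.outlet_gauge_pressure(fl, cond)
        assert 0 < out.tube_friction < 1.0
        assert out.total == pytest.approx(out.hydrostatic + out.tube_friction)

    def test_pressure_profile_affine(self, chip_geometry, pinned_fluid):
        cond = hemo.FlowCondition(flow_rate=13 * UL_MIN, outlet_head=0.40)
        z, p = hemo.pressure_profile(chip_geometry, pinned_fluid, cond, 41)
        dpdz = hemo.pressure_gradient(chip_geometry, pinned_fluid, cond.flow_rate)
        assert np.allclose(p[0] - p, z * dpdz, rtol=1e-9)
        assert np.all(np.diff(p) <= 0)
        assert p[0] == pytest.approx(3971.1, rel=5e-3)

    def test_no_head_outlet_is_zero_gauge(self, chip_geometry, pinned_fluid):
        cond = hemo.FlowCondition(flow_rate=1.3 * UL_MIN, outlet_head=0.0)
        _, p = hemo.pressure_profile(chip_geometry, pinned_fluid, cond, 11)
        assert p[-1] == 0.0


class TestConditionTable:
    def test_four_condition_summary(self, chip_geometry, pinned_fluid):
        conds = [
            hemo.FlowCondition.from_lab_units(13.0, 0.0, label="SS high only"),
            hemo.FlowCondition.from_lab_units(1.3, 0.0, label="SS low only"),
            hemo.FlowCondition.from_lab_units(13.0, 40.0, label="SS high+HP"),
            hemo.FlowCondition.from_lab_units(1.3, 40.0, label="SS low+HP"),
        ]
        df = hemo.summarize_conditions(chip_geometry, pinned_fluid, conds).set_index("condition")
        assert len(df) == 4
        assert df.loc["SS high only", "inlet_gauge_pa"] == pytest.approx(47.1, rel=5e-3)
        assert df.loc["SS low only", "inlet_gauge_pa"] == pytest.approx(4.71, rel=5e-3)
        assert df.loc["SS high+HP", "inlet_gauge_pa"] == pytest.approx(3971.1, rel=5e-3)
        assert df.loc["SS low+HP", "inlet_gauge_pa"] == pytest.approx(3928.7, rel=5e-3)
        np.testing.assert_allclose(
            df["inlet_gauge_pa"], df["outlet_gauge_pa"] + df["delta_p_pa"], rtol=1e-12
        )

    def test_empty_conditions_rejected(self, chip_geometry, pinned_fluid):
        with pytest.raises(hemo.InvalidParameterError):
            hemo.summarize_conditions(chip_geometry, pinned_fluid, [])

    def test_force_balance(self, chip_geometry, pinned_fluid):
        # delta_p * A consistent with L * integral of wall shear around the
        # perimeter (series solution); the friction correlation is approximate
        Q = 13 * UL_MIN
        ctrl = hemo.SeriesControl()
        W, H = chip_geometry.half_width, chip_geometry.half_height
        c1 = hemo.series_c1(chip_geometry, hemo.mean_velocity(chip_geometry, Q), ctrl)
        xs = np.linspace(-W, W, 401)
        tau_b = hemo.wss_bottom(chip_geometry, pinned_fluid, c1, xs, ctrl)
        bottom = np.trapezoid(tau_b, xs)
        # side walls: mu du/dx at x = W via central difference of the series
        ys = np.linspace(-H, H, 101)
        eps = W * 1e-6
        du = (
            hemo.velocity_at(chip_geometry, c1, W - eps, ys, ctrl)
            - hemo.velocity_at(chip_geometry, c1, W - 2 * eps, ys, ctrl)
        ) / eps
        side = np.trapezoid(pinned_fluid.dynamic_viscosity * np.abs(du), ys)
        shear_force = chip_geometry.length * (2 * bottom + 2 * side)
        dp_force = hemo.channel_delta_p(chip_geometry, pinned_fluid, Q) * (4 * W * H)
        assert shear_force == pytest.approx(dp_force, rel=0.05)
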