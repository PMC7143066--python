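"""Desk-scale mixing simulator: geometry, properties, solvers, metrics."""

import numpy as np
import pandas as pd
import pytest

from pdmix.mixing import (
    MixingProfile,
    MixingUndefinedError,
    PropertyModel,
    build_geometry,
    discretize,
    distance_to_threshold,
    evolve_diffusion,
    fit_property_polynomial,
    inlet_speeds,
    load_property_table,
    mixing_profile,
    solve_flow,
    solve_transport,
    transverse_nonuniformity,
)
from pdmix.mixing.transport import TransportField


class TestGeometry:
    def test_device_defaults(self):
        geom = build_geometry()
        assert geom.path_length_mm == pytest.approx(47.5)
        assert geom.narrowest_gap_um == pytest.approx(40.0)
        assert geom.n_obstacles == 90
        # path length consistent with count x pitch within 5%
        assert geom.n_obstacles * geom.pitch_um == pytest.approx(
            geom.length_um, rel=0.05
        )

    def test_zero_obstacles_is_a_straight_channel(self):
        geom = build_geometry(n_obstacles=0)
        grid = discretize(geom, cells_across=30)
        assert grid.fluid.all()

    def test_obstacles_alternate_walls(self):
        centers = build_geometry().obstacle_centers()
        ys = [c[1] for c in centers[:4]]
        assert ys == [0.0, 300.0, 0.0, 300.0]

    def test_oversized_radius_rejected(self):
        with pytest.raises(ValueError):
            build_geometry(obstacle_radius_um=300.0)

    def test_resolution_must_resolve_the_gap(self):
        with pytest.raises(ValueError):
            discretize(build_geometry(), cells_across=10)

    def test_gap_retains_at_least_four_cells(self):
        grid = discretize(build_geometry().truncated(2), cells_across=30)
        xc = grid.geom.obstacle_centers()[0][0] * 1e-6
        col = int(xc / grid.h)
        assert grid.fluid[col].sum() >= 4


class TestProperties:
    def test_packaged_fits_match_pure_component_entries(self):
        props = PropertyModel.from_packaged()
        table = load_property_table()
        assert props.rho(0.0) == pytest.approx(997.05, rel=0.01)
        assert props.rho(1.0) == pytest.approx(785.22, rel=0.01)
        assert props.mu(0.0) == pytest.approx(0.890e-3, rel=0.01)
        assert props.D(0.4) == pytest.approx(0.40e-9, rel=0.05)
        assert len(table) == 11

    def test_exactly_order_plus_one_points_interpolate(self):
        c = np.linspace(0, 1, 6)
        v = 1.0 + c + c**3
        poly, resid = fit_property_polynomial(c, v, order=5)
        assert np.allclose(resid, 0.0, atol=1e-10)

    def test_constant_table_gives_constant_polynomial(self):
        c = np.linspace(0, 1, 8)
        poly, _ = fit_property_polynomial(c, np.full(8, 2.5), order=5)
        assert np.allclose(poly(np.linspace(0, 1, 20)), 2.5)

    def test_too_few_points_rejected(self):
        with pytest.raises(ValueError):
            fit_property_polynomial([0.0, 0.5, 1.0], [1.0, 2.0, 3.0], order=5)

    def test_non_positive_property_rejected(self):
        from numpy.polynomial import Polynomial

        with pytest.raises(ValueError):
            PropertyModel(
                rho=Polynomial([1000.0]),
                mu=Polynomial([1e-3, -2e-3]),  # goes negative on [0, 1]
                D=Polynomial([1e-9]),
            )


class TestFlow:
    def test_straight_channel_matches_plane_poiseuille(self, straight_flow):
        grid = straight_flow.grid
        u = straight_flow.u[grid.nx // 2]
        y, W = grid.y, grid.width
        parabola = 6.0 * u.mean() * (y / W) * (1.0 - y / W)
        assert np.max(np.abs(u - parabola)) / parabola.max() < 0.02

    def test_mass_conservation_to_solver_tolerance(self, straight_flow, frr_sweep):
        assert straight_flow.mass_imbalance < 1e-6
        for result in frr_sweep.values():
            assert result.flow.mass_imbalance < 1e-6

    def test_velocity_scales_linearly_with_tfr_in_stokes_limit(self, straight_flow):
        grid = straight_flow.grid
        doubled = solve_flow(grid, 36.0, 1.0, mu=1.0e-3, rho=1000.0)
        assert np.allclose(doubled.u, 2.0 * straight_flow.u, atol=1e-9)

    def test_inlet_arm_speeds_follow_flow_split(self):
        geom = build_geometry()
        u_org, u_aq = inlet_speeds(18.0, 2.0, geom)
        assert u_aq / u_org == pytest.approx(2.0)
        area = (geom.width_um * 1e-6 / 2) * (geom.depth_um * 1e-6)
        total = (u_org + u_aq) * area
        assert total == pytest.approx(18.0 * 1e-6 / 3600.0)

    def test_picard_convection_converges_on_straight_channel(self, straight_flow):
        grid = straight_flow.grid
        fl = solve_flow(grid, 18.0, 1.0, mu=1.0e-3, advection=True)
        assert fl.meta["converged"]
        assert fl.mass_imbalance < 1e-6
        # Re ~ 17: convection perturbs but does not overturn the profile
        rel = np.max(np.abs(fl.u - straight_flow.u)) / np.max(straight_flow.u)
        assert rel < 0.5


class TestTransport:
    def test_pure_diffusion_matches_two_stream_series(self):
        geom = build_geometry(n_obstacles=0, entrance_um=0.0, exit_um=200.0)
        grid = discretize(geom, cells_across=40)
        W = grid.width
        c0 = np.where(grid.y[None, :] < W / 2, 1.0, 0.0) * np.ones((grid.nx, 1))
        D, t = 1e-9, 4.0
        ct = evolve_diffusion(grid, c0, D, t, n_steps=400)
        y = grid.y
        series = 0.5 * np.ones_like(y)
        for k in range(1, 200):
            series += (
                (2.0 / (k * np.pi))
                * np.sin(k * np.pi * 0.5)
                * np.cos(k * np.pi * y / W)
                * np.exp(-D * (k * np.pi / W) ** 2 * t)
            )
        assert np.max(np.abs(ct[grid.nx // 2] - series)) < 0.02

    def test_species_conservation(self, straight_flow, frr_sweep):
        tr = solve_transport(straight_flow, D=1e-9)
        assert tr.species_imbalance < 1e-6
        for result in frr_sweep.values():
            assert result.transport.species_imbalance < 1e-6

    def test_vanishing_diffusivity_keeps_outlet_segregated(self, straight_flow):
        tr = solve_transport(straight_flow, D=1e-15)
        me = mixing_profile(tr).me
        assert me[-1] < 5.0

    def test_concentration_bounded_by_inlet_values(self, frr_sweep):
        for result in frr_sweep.values():
            c = result.transport.c
            assert np.nanmin(c) > -1e-4
            assert np.nanmax(c) < 1.0 + 1e-4


class TestMixingMetrics:
    def _uniform_field(self, value, frr=1.0):
        geom = build_geometry(n_obstacles=0, entrance_um=0.0, exit_um=100.0)
        grid = discretize(geom, cells_across=10)
        c = np.full((grid.nx, grid.ny), value)
        return TransportField(grid=grid, c=c, frr=frr, flux_in=1.0, flux_out=1.0)

    def _segregated_field(self, frr):
        geom = build_geometry(n_obstacles=0, entrance_um=0.0, exit_um=100.0)
        grid = discretize(geom, cells_across=40)
        frac = 1.0 / (1.0 + frr)
        c = np.where(grid.y[None, :] < frac * grid.width, 1.0, 0.0) * np.ones(
            (grid.nx, 1)
        )
        return TransportField(grid=grid, c=c, frr=frr, flux_in=1.0, flux_out=1.0)

    def test_uniform_section_is_fully_mixed(self):
        profile = mixing_profile(self._uniform_field(0.5))
        assert np.allclose(profile.me, 100.0)

    def test_segregated_section_has_zero_efficiency(self):
        profile = mixing_profile(self._segregated_field(1.0), n_samples=40)
        assert np.allclose(profile.me, 0.0, atol=1.0)

    def test_segregated_reference_variance_at_frr_3(self):
        """A 0/1 section with organic fraction 1/(1+FRR) = 1/4: brute-force
        variance of the sampled indicator equals 0.1875."""
        profile = mixing_profile(self._segregated_field(3.0), n_samples=40)
        brute = np.var(np.r_[np.ones(10), np.zeros(30)])
        assert brute == 0.1875
        assert profile.table["sigma0_sq"].iloc[-1] == pytest.approx(0.1875, abs=0.01)

    def test_undefined_for_single_stream_inlet(self):
        field = self._uniform_field(1.0, frr=0.0)
        field.frr = 0.0
        with pytest.raises(MixingUndefinedError):
            mixing_profile(field)

    def test_me_profile_bounded_and_non_decreasing(self, frr_sweep):
        for result in frr_sweep.values():
            me = result.profile.me
            assert np.all(me >= 0.0) and np.all(me <= 100.0)
            assert np.all(np.diff(me) >= -1.0)  # 1 pp numerical slack

    def test_distance_to_90_non_increasing_in_frr(self, frr_sweep):
        """Narrower organic stream (higher FRR) homogenizes sooner."""
        distances = []
        for frr in (1, 3, 5, 9):
            crossing = distance_to_threshold(frr_sweep[frr].profile, 90.0)
            assert not crossing.censored
            distances.append(crossing.distance_mm)
        assert all(a >= b - 1e-9 for a, b in zip(distances, distances[1:]))

    def test_outlet_efficiency_stable_under_grid_refinement(self, straight_flow):
        coarse = mixing_profile(solve_transport(straight_flow, D=1e-9)).me[-1]
        geom = straight_flow.grid.geom
        fine_grid = discretize(geom, cells_across=60)
        fine_flow = solve_flow(fine_grid, 18.0, 1.0, mu=1.0e-3)
        fine = mixing_profile(solve_transport(fine_flow, D=1e-9)).me[-1]
        assert abs(coarse - fine) < 3.0

    def test_step_profile_crossing_interpolates_between_stations(self):
        table = pd.DataFrame(
            {
                "station": range(1, 11),
                "x_mm": np.arange(1.0, 11.0),
                "mean_c": 0.5,
                "sigma2": 0.0,
                "sigma0_sq": 0.25,
                "me_percent": [0.0] * 4 + [100.0] * 6,
            }
        )
        profile = MixingProfile(table=table, n_samples=50, frr=1.0)
        crossing = distance_to_threshold(profile, 90.0)
        assert not crossing.censored
        assert 4.0 < crossing.distance_mm <= 5.0

    def test_monotone_profile_matches_hand_interpolation(self):
        table = pd.DataFrame(
            {
                "station": [1, 2, 3],
                "x_mm": [1.0, 2.0, 3.0],
                "mean_c": 0.5,
                "sigma2": 0.0,
                "sigma0_sq": 0.25,
                "me_percent": [40.0, 80.0, 96.0],
            }
        )
        profile = MixingProfile(table=table, n_samples=50, frr=1.0)
        crossing = distance_to_threshold(profile, 90.0)
        assert crossing.distance_mm == pytest.approx(2.0 + (90 - 80) / (96 - 80))

    def test_unreached_threshold_is_censored_not_an_error(self):
        table = pd.DataFrame(
            {
                "station": [1, 2],
                "x_mm": [1.0, 2.0],
                "mean_c": 0.5,
                "sigma2": 0.2,
                "sigma0_sq": 0.25,
                "me_percent": [10.0, 20.0],
            }
        )
        crossing = distance_to_threshold(
            MixingProfile(table=table, n_samples=50, frr=1.0), 90.0
        )
        assert crossing.censored

    def test_transverse_nonuniformity_larger_at_frr_3_than_1(self, frr_sweep):
        """Off-centre interface at FRR = 3 leaves a more skewed transverse
        profile than the symmetric FRR = 1 case at matched early stations."""
        for station in (0, 1):
            x = frr_sweep[1].profile.x_mm[station]
            cv1 = transverse_nonuniformity(frr_sweep[1].transport, x)
            cv3 = transverse_nonuniformity(frr_sweep[3].transport, x)
            assert cv3 > cv1
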