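import numpy as np
import pytest
from hypothesis import given
from hypothesis import strategies as st

import pgpdyn as pg
from pgpdyn.grid import quadrature_weights
from pgpdyn.kinetics import (
    birth_operator,
    equilibrium_density,
    mean_proliferation_rate,
    transfer_amplitude,
)


@pytest.fixture(scope="module")
def g():
    return pg.ActivityGrid(0.0, 1.0, 100)


class TestTherapyRate:
    def test_no_drug_no_selection(self, params, g):
        assert np.all(pg.therapy_rate(g.centers, 0.0, params) == 0.0)

    def test_high_pgp_cells_escape_killing(self, params, g):
        # protection sigmoid -> 0 at the top of the grid with a mid-grid midpoint
        top = float(pg.therapy_rate(g.x_max, 100.0, params))
        assert top < 1e-3 * params.delta_max

    def test_closed_form_at_half_maximal_point(self):
        # delta_max * Hill(C50) * sigmoid(0) = 0.1 * 0.5 * 0.5
        p = pg.ProcessParameters(delta_max=0.1, C50=50.0, h_drug=1.0, x_half=0.5)
        assert pg.therapy_rate(0.5, 50.0, p) == pytest.approx(0.025, rel=1e-12)

    @given(
        x=st.lists(st.floats(0.0, 1.0), min_size=2, max_size=6),
        c=st.lists(st.floats(0.0, 500.0), min_size=2, max_size=6),
    )
    def test_monotone_in_activity_and_dose(self, params, x, c):
        xs, cs = np.sort(x), np.sort(c)
        for dose in cs:
            rates = pg.therapy_rate(xs, float(dose), params)
            assert np.all(np.diff(rates) <= 1e-15)
        for xx in xs:
            ladder = [float(pg.therapy_rate(float(xx), float(d), params)) for d in cs]
            assert np.all(np.diff(ladder) >= -1e-15)


class TestVelocities:
    def test_induction_requires_drug(self, params, g):
        assert np.all(pg.induction_velocity(g.centers, 0.0, params, g) == 0.0)

    def test_velocities_vanish_at_upper_boundary(self, params, g):
        assert pg.induction_velocity(g.x_max, 100.0, params, g) == 0.0
        assert pg.transfer_velocity(g.x_max, 5.0, 50.0, params, g) == 0.0

    def test_induction_closed_form_at_midpoint(self, g):
        p = pg.ProcessParameters(alpha_I=0.02, C50=1e-6, h_drug=1.0)
        v = float(pg.induction_velocity(0.5, 1e6, p, g))  # C >> C50: Hill ~ 1
        assert v == pytest.approx(0.01, rel=1e-4)

    def test_transfer_requires_mvs(self, params, g):
        assert np.all(pg.transfer_velocity(g.centers, 0.0, 0.0, params, g) == 0.0)

    def test_transfer_closed_form(self, g):
        p = pg.ProcessParameters(kappa0=0.001)
        assert pg.transfer_velocity(0.5, 5.0, 0.0, p, g) == pytest.approx(0.0025)

    def test_tenfold_amplitude_ratio_uniform_in_x_and_M(self, params, g):
        for M in (0.5, 2.0, 7.0):
            with_drug = pg.transfer_velocity(g.centers[:-1], M, 50.0, params, g)
            without = pg.transfer_velocity(g.centers[:-1], M, 0.0, params, g)
            ratio = with_drug / without
            np.testing.assert_allclose(ratio, params.kappaD / params.kappa0, rtol=1e-12)
        assert transfer_amplitude(50.0, params) / transfer_amplitude(0.0, params) == 10.0


class TestProliferation:
    def test_no_cost_is_flat(self, g):
        p = pg.ProcessParameters(c_cost=0.0)
        r = pg.proliferation_rate(g.centers, 1, p, g)
        np.testing.assert_allclose(r, p.r_max_1)

    def test_rate_at_lower_boundary_and_midpoint(self, g):
        p = pg.ProcessParameters(r_max_1=0.035, c_cost=0.5)
        assert pg.proliferation_rate(g.x_min, 1, p, g) == pytest.approx(0.035)
        assert pg.proliferation_rate(0.5, 1, p, g) == pytest.approx(0.02625)

    def test_kernel_birth_mass_equals_rate(self, params, g):
        # integral over daughters of W(x, x') equals r(x') for every parent
        w = quadrature_weights(g)
        for index in (1, 2):
            A = birth_operator(g, index, params)
            col_mass = w @ (A / (w[None, :]))  # strip the parent weight
            r = pg.proliferation_rate(g.centers, index, params, g)
            np.testing.assert_allclose(col_mass, r, atol=1e-10)

    def test_full_reversion_centers_daughters_at_basal(self, params, g):
        # daughter mean equals b1 regardless of the parent, up to the small
        # upward shift from truncating the Gaussian tail at the boundary
        p = params.replace(lambda_rev=1.0)
        w = quadrature_weights(g)
        for x_parent in (0.1, 0.5, 0.9):
            ker = pg.proliferation_kernel(g.centers, x_parent, 1, p, g)
            mean = float(w @ (g.centers * ker) / (w @ ker))
            assert mean == pytest.approx(p.b1, abs=1e-4)

    def test_partial_reversion_daughter_mean(self, g):
        p = pg.ProcessParameters(lambda_rev=0.3, b1=0.2, sigma_div=0.02)
        w = quadrature_weights(g)
        ker = pg.proliferation_kernel(g.centers, 0.7, 1, p, g)
        mean = float(w @ (g.centers * ker) / (w @ ker))
        assert mean == pytest.approx(0.7 + 0.3 * (0.2 - 0.7), abs=1e-4)

    @given(lam=st.floats(0.05, 1.0), sig=st.floats(0.02, 0.2))
    def test_kernel_normalization_for_random_shapes(self, g, lam, sig):
        p = pg.ProcessParameters(lambda_rev=lam, sigma_div=sig)
        w = quadrature_weights(g)
        ker = pg.proliferation_kernel(g.centers, 0.83, 2, p, g)
        r = float(pg.proliferation_rate(0.83, 2, p, g))
        assert float(w @ ker) == pytest.approx(r, abs=1e-10)


class TestCrowdingAndMVs:
    def test_empty_population_no_decay(self, params, grid):
        state = pg.SystemState.from_arrays(
            grid, np.zeros(grid.n_bins), np.zeros(grid.n_bins)
        )
        assert pg.crowding_decay(state, params) == (0.0, 0.0)

    def test_logistic_fixed_point_at_capacity(self, grid):
        # uniform r: at N = K the decay equals the mean rate (zero net growth),
        # at N = K/2 it equals half of it
        p = pg.ProcessParameters(c_cost=0.0, r_max_1=0.03, r_max_2=0.03, K_cap=1e4)
        u = np.full(grid.n_bins, 1e4 / grid.span / 2.0)
        state = pg.SystemState.from_arrays(grid, u, u)
        g1, g2 = pg.crowding_decay(state, p)
        assert g1 == g2 == pytest.approx(0.03, rel=1e-9)
        half = pg.SystemState.from_arrays(grid, u / 2.0, u / 2.0)
        assert pg.crowding_decay(half, p)[0] == pytest.approx(0.015, rel=1e-9)

    def test_mv_flux_signs_and_magnitude(self, params, grid):
        zero = np.zeros(grid.n_bins)
        empty = pg.SystemState.from_arrays(grid, zero, zero, M=0.0)
        assert pg.mv_flux(empty, params) == 0.0
        # donors only: pure accumulation
        u2 = 1e4 * pg.equilibrium_density(grid, 2, params)
        donors = pg.SystemState.from_arrays(grid, zero, u2, M=3.0)
        assert pg.mv_flux(donors, params) > 0.0
        # 1e4 donor cells concentrated at relative activity 0.8
        p = params.replace(gamma_shed=1e-5, gamma_up=0.0)
        k = int(np.argmin(np.abs(grid.rel(grid.centers) - 0.8)))
        u2 = np.zeros(grid.n_bins)
        u2[k] = 1e4 / grid.dx
        conc = pg.SystemState.from_arrays(grid, zero, u2, M=0.0)
        expected = 1e-5 * 1e4 * grid.rel(grid.centers[k])
        assert pg.mv_flux(conc, p) == pytest.approx(expected, rel=1e-12)


class TestBasalProfiles:
    def test_equilibrium_profile_is_stationary_shape(self, params, g):
        # one application of the birth operator rescales the profile without
        # deforming it (Perron eigenvector)
        u = equilibrium_density(g, 2, params)
        Au = birth_operator(g, 2, params) @ u
        lam = float(Au @ u / (u @ u))
        np.testing.assert_allclose(Au, lam * u, atol=1e-12 * np.max(Au))
        assert lam == pytest.approx(pg.equilibrium_growth_rate(g, 2, params), rel=1e-9)

    def test_equilibrium_mean_near_basal_center(self, params, g):
        w = quadrature_weights(g)
        for index, b in ((1, params.b1), (2, params.b2)):
            u = equilibrium_density(g, index, params)
            mean = float(w @ (g.centers * u))
            assert mean == pytest.approx(b, abs=0.01)

    def test_gaussian_seed_mass_and_mode(self, params, g):
        w = quadrature_weights(g)
        u = pg.basal_gaussian_density(g, 1, params)
        assert float(w @ u) == pytest.approx(1.0, abs=1e-12)
        assert abs(g.centers[np.argmax(u)] - params.b1) <= g.dx
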