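"""Transport, growth and full-run behaviour of the dispersal solver."""

import numpy as np
import pytest

from paleodisp import (
    DispersalModel,
    DispersalParams,
    HepStack,
    LandMask,
    ScalarField,
    VectorField,
    advect_diffuse,
    build_grid,
    diffusivity,
    grow,
    gradient,
    initialize,
    normalize_isotope,
    update_velocity,
)
from paleodisp.exceptions import ConfigurationError, StabilityError


@pytest.fixture
def basin():
    grid = build_grid((0.0, 10.0), (40.0, 50.0), 0.5)
    return grid, LandMask(grid, np.ones(grid.shape, dtype=bool))


def _uniform_stack(grid, value_gs, value_gi):
    f = {
        (p, r): np.full(grid.shape, value_gs if r == "GS" else value_gi)
        for p in ("P1", "P2")
        for r in ("GS", "GI")
    }
    return HepStack(grid, f)


def _gi_series(start_ka=45.0, n=2000):
    age = start_ka - 0.02 * np.arange(n)
    val = np.full(n, -36.0)
    val[-1] = -44.0  # anchor the normalisation; simulation never reaches it
    return normalize_isotope(age, val)


class TestParams:
    def test_defaults_are_positive_and_stable(self, basin):
        grid, _ = basin
        DispersalParams().check_stability(grid)

    def test_bad_values_rejected(self):
        with pytest.raises(ConfigurationError):
            DispersalParams(rho_c_max=-1.0)
        with pytest.raises(ConfigurationError):
            DispersalParams(d_min=50.0, d_max=10.0)
        with pytest.raises(ConfigurationError):
            DispersalParams(eta=0.9)

    def test_alpha_from_drift_scales(self):
        p = DispersalParams.with_drift_scales(V=2.0, G=0.01, tau=10.0)
        assert p.alpha == pytest.approx(20.0)

    def test_stability_check_rejects_fine_grid_with_large_dt(self):
        grid = build_grid((0.0, 0.5), (0.0, 0.25), 0.05)  # ~5.5 km cells
        with pytest.raises(StabilityError):
            DispersalParams(dt_days=100.0).check_stability(grid)


class TestInitialize:
    def test_total_population_matches(self, basin):
        grid, mask = basin
        state = initialize(grid, mask, center=(5.0, 45.0), spread_km=150.0,
                           total_population=5000.0)
        persons = (state.rho.values * grid.cell_areas()).sum() / 100.0
        assert persons == pytest.approx(5000.0, abs=1.0)
        assert np.all(state.v.u == 0.0)

    def test_zero_population_is_empty(self, basin):
        grid, mask = basin
        state = initialize(grid, mask, center=(5.0, 45.0), total_population=0.0)
        assert np.all(state.rho.values == 0.0)

    def test_linearity_in_total(self, basin):
        grid, mask = basin
        s1 = initialize(grid, mask, center=(5.0, 45.0), total_population=1000.0)
        s2 = initialize(grid, mask, center=(5.0, 45.0), total_population=2000.0)
        assert np.allclose(s2.rho.values, 2.0 * s1.rho.values)

    def test_water_center_rejected(self, basin):
        grid, _ = basin
        land = np.ones(grid.shape, dtype=bool)
        i, j = grid.locate(5.0, 45.0)
        land[i, j] = False
        with pytest.raises(ConfigurationError):
            initialize(grid, LandMask(grid, land), center=(5.0, 45.0))


class TestVelocity:
    def test_free_decay(self, basin):
        grid, _ = basin
        p = DispersalParams()
        zero = VectorField(grid, np.zeros(grid.shape), np.zeros(grid.shape))
        u = np.full(grid.shape, 3.0)
        v = np.full(grid.shape, -1.0)
        t = 7.0
        un, vn = update_velocity(u, v, zero, p, t)
        assert np.allclose(un, 3.0 * np.exp(-p.gamma * t))
        assert np.allclose(vn, -1.0 * np.exp(-p.gamma * t))

    def test_fixed_point_under_constant_forcing(self, basin):
        grid, _ = basin
        p = DispersalParams()
        g = VectorField(grid, np.full(grid.shape, 0.02), np.zeros(grid.shape))
        u = np.zeros(grid.shape)
        v = np.zeros(grid.shape)
        for _ in range(200):
            u, v = update_velocity(u, v, g, p, 1.0)
        assert np.allclose(u, p.alpha * 0.02 / p.gamma, rtol=1e-6)

    def test_zero_alpha_keeps_rest(self, basin):
        grid, _ = basin
        p = DispersalParams(alpha=1e-300)
        g = VectorField(grid, np.ones(grid.shape), np.ones(grid.shape))
        u, v = update_velocity(np.zeros(grid.shape), np.zeros(grid.shape), g, p, 1.0)
        assert np.allclose(u, 0.0, atol=1e-290)


class TestDiffusivity:
    def test_rest_velocity_clips_to_minimum(self, basin):
        grid, _ = basin
        D = diffusivity(np.zeros(grid.shape), np.zeros(grid.shape), grid,
                        DispersalParams())
        assert np.all(D == 10.0)

    def test_direct_product_value(self):
        # |v| = 20, sqrt(dx dy) = 50 km, kappa = kappa_l = 1, kappa_sigma = 0.1
        # gives raw D = 100 exactly at the clip ceiling
        grid = build_grid((0.0, 1.0), (0.0, 0.5), 0.5)
        p = DispersalParams()
        scale = np.sqrt(grid.dx[0] * grid.dy)
        v = 100.0 / (p.kappa * p.kappa_l * p.kappa_sigma * scale)
        D = diffusivity(np.full(grid.shape, v), np.zeros(grid.shape), grid, p)
        assert np.allclose(D, 100.0)

    def test_large_velocity_caps_at_maximum(self, basin):
        grid, _ = basin
        D = diffusivity(np.full(grid.shape, 1e6), np.zeros(grid.shape), grid,
                        DispersalParams())
        assert np.all(D == 100.0)


class TestTransport:
    def test_no_motion_is_bitwise_identity(self, basin, rng):
        grid, mask = basin
        rho = rng.uniform(0, 5, grid.shape)
        out = advect_diffuse(rho, np.zeros(grid.shape), np.zeros(grid.shape),
                             np.zeros(grid.shape), grid, mask, 0.1)
        assert np.array_equal(out, rho)

    def test_closed_basin_conserves_population(self, basin, rng):
        grid, mask = basin
        areas = grid.cell_areas()
        rho = rng.uniform(0, 5, grid.shape)
        u = 10.0 * np.sin(np.linspace(0, 3, grid.shape[1]))[None, :] * np.ones(grid.shape)
        v = 10.0 * np.cos(np.linspace(0, 3, grid.shape[0]))[:, None] * np.ones(grid.shape)
        D = rng.uniform(10, 100, grid.shape)
        lam0 = (rho * areas).sum()
        for _ in range(1000):
            rho = advect_diffuse(rho, u, v, D, grid, mask, 0.01)
        lam1 = (rho * areas).sum()
        assert abs(lam1 - lam0) / lam0 <= 1e-6
        assert rho.min() >= 0.0

    def test_mask_blocks_all_exchange(self, basin, rng):
        grid, _ = basin
        land = np.ones(grid.shape, dtype=bool)
        land[:, 10] = False  # wall splits the basin
        mask = LandMask(grid, land)
        rho = np.zeros(grid.shape)
        rho[:, :10] = 2.0
        out = rho.copy()
        for _ in range(50):
            out = advect_diffuse(out, np.full(grid.shape, 5.0), np.zeros(grid.shape),
                                 np.full(grid.shape, 50.0), grid, mask, 0.05)
        assert np.all(out[:, 10:] == 0.0)

    def test_cfl_violation_raises_with_cell(self, basin):
        grid, mask = basin
        rho = np.ones(grid.shape)
        u = np.full(grid.shape, 1e4)
        with pytest.raises(StabilityError, match="advective"):
            advect_diffuse(rho, u, np.zeros(grid.shape), np.zeros(grid.shape),
                           grid, mask, 0.05)
        with pytest.raises(StabilityError, match="diffusive"):
            advect_diffuse(rho, np.zeros(grid.shape), np.zeros(grid.shape),
                           np.full(grid.shape, 1e5), grid, mask, 0.05)


class TestGrowth:
    def test_at_capacity_is_stationary(self):
        p = DispersalParams()
        rho_c = np.full(4, 2.0)
        out = grow(rho_c.copy(), rho_c, np.full(4, 1.0), p, 5.0)
        assert np.allclose(out, rho_c, rtol=1e-14)

    def test_matches_closed_form_logistic(self):
        p = DispersalParams()
        rho_c = np.array([3.0])
        phi_av = np.array([2.0])
        r = p.r_max * phi_av / p.rho_c_max
        rho = np.array([0.3])
        dt = p.dt_yr
        out = rho.copy()
        n = 1000
        for _ in range(n):
            out = grow(out, rho_c, phi_av, p, dt)
        t = n * dt
        exact = rho_c * rho * np.exp(r * t) / (rho_c + rho * (np.exp(r * t) - 1.0))
        assert out[0] == pytest.approx(exact[0], rel=1e-12)

    def test_overcrowded_cell_relaxes_downward(self):
        p = DispersalParams()
        out = grow(np.array([5.0]), np.array([2.0]), np.array([4.0]), p, 50.0)
        assert 2.0 < out[0] < 5.0

    def test_zero_capacity_decays_at_r_max(self):
        p = DispersalParams()
        out = grow(np.array([2.0]), np.array([0.0]), np.array([0.0]), p, 10.0)
        assert out[0] == pytest.approx(2.0 * np.exp(-p.r_max * 10.0))


class TestRun:
    def _model(self, grid, mask, stack, **kw):
        return DispersalModel(grid, mask, stack, _gi_series(), DispersalParams(**kw))

    def test_zero_potential_everywhere_decays_monotonically(self, basin):
        grid, mask = basin
        model = self._model(grid, mask, _uniform_stack(grid, 0.0, 0.0))
        init = initialize(grid, mask, center=(5.0, 45.0), total_population=5000.0)
        res = model.run(init, 44.8)
        assert np.all(np.diff(res.lam) < 0)

    def test_homogeneous_growth_approaches_capacity_ceiling(self, basin):
        grid, mask = basin
        model = self._model(grid, mask, _uniform_stack(grid, 0.8, 0.8))
        init = initialize(grid, mask, center=(5.0, 45.0), spread_km=400.0,
                          total_population=2000.0)
        res = model.run(init, 44.5)
        ceiling = (0.8 * 5.0 * grid.cell_areas()).sum() / 100.0
        assert res.lam[-1] > res.lam[0]
        assert res.lam[-1] < ceiling

    def test_bit_identical_reruns(self, basin):
        grid, mask = basin
        model = self._model(grid, mask, _uniform_stack(grid, 0.2, 0.9))
        init = initialize(grid, mask, center=(5.0, 45.0), total_population=3000.0)
        a = model.run(init, 44.9)
        b = model.run(init, 44.9)
        assert np.array_equal(a.rho, b.rho)
        assert np.array_equal(a.lam, b.lam)
        assert np.array_equal(a.mob, b.mob)

    def test_scaling_up_potential_never_reduces_population(self, basin):
        grid, mask = basin
        init = initialize(grid, mask, center=(5.0, 45.0), total_population=3000.0)
        lo = self._model(grid, mask, _uniform_stack(grid, 0.5, 0.5)).run(init, 44.7)
        hi = self._model(grid, mask, _uniform_stack(grid, 0.55, 0.55)).run(init, 44.7)
        assert hi.lam[-1] >= lo.lam[-1]

    def test_water_cells_stay_empty(self, basin):
        grid, _ = basin
        land = np.ones(grid.shape, dtype=bool)
        land[:, :3] = False
        mask = LandMask(grid, land)
        model = DispersalModel(grid, mask, _uniform_stack(grid, 0.9, 0.9),
                               _gi_series(), DispersalParams())
        init = initialize(grid, mask, center=(5.0, 45.0), total_population=3000.0)
        res = model.run(init, 44.8)
        assert np.all(res.rho[:, :, :3] == 0.0)

    def test_backward_run_rejected(self, basin):
        grid, mask = basin
        model = self._model(grid, mask, _uniform_stack(grid, 0.5, 0.5))
        init = initialize(grid, mask, center=(5.0, 45.0))
        with pytest.raises(ConfigurationError):
            model.run(init, 46.0)

    def test_snapshot_spacing(self, basin):
        grid, mask = basin
        model = self._model(grid, mask, _uniform_stack(grid, 0.5, 0.5))
        init = initialize(grid, mask, center=(5.0, 45.0))
        res = model.run(init, 44.9)  # 100 years
        assert res.n_snapshots == 11
        spacing = -np.diff(res.times_ka) * 1000.0
        assert np.all(np.abs(spacing - 10.0) < 0.1)
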