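"""BMP-2 balance: closed-form kinetics, conservation, and homeostasis."""

import numpy as np
import pytest

import osteosim as o
from osteosim.bmp2 import (BMPParams, BMPState, background_consumption_rate,
                           degradation_rate, differentiation_sink,
                           gel_diffusivity, gel_pool_step, production_rate,
                           step_bmp2)
from osteosim.fv import ImplicitDiffusion
from osteosim.grid import Grid

P = BMPParams()


class TestPointKinetics:
    def test_consumption_zero_and_half_saturation(self):
        assert background_consumption_rate(0.0, 1e5, 0.0) == 0.0
        n = 2e5
        half = background_consumption_rate(P.Kma, n / 2, n / 2)
        assert half == pytest.approx(n * P.v_max_per_cell / 2, rel=1e-12)

    def test_consumption_saturates_at_vmax(self):
        n = 3e5
        sat = background_consumption_rate(1e6, n, 0.0)
        assert sat == pytest.approx(n * P.v_max_per_cell, rel=1e-3)
        assert sat < n * P.v_max_per_cell   # strictly below the asymptote

    def test_production_at_depletion(self):
        # alpha / gamma0 per cell when the medium is empty
        assert production_rate(0.0, 1.0, 0.0) == pytest.approx(2e-7)
        assert production_rate(5.0, 0.0, 0.0) == 0.0

    def test_production_strictly_decreasing_in_g(self):
        g = np.linspace(0.0, 50.0, 200)
        rates = production_rate(g, 1e5, 1e5)
        assert np.all(np.diff(rates) < 0)

    def test_degradation_halves_in_half_life(self):
        # integrate dg/dt = -rate(g) with fine Euler steps
        g, dt = 1.0, 1e-5
        for _ in range(int(P.t_half_free / dt)):
            g -= dt * degradation_rate(g)
        assert g == pytest.approx(0.5, rel=1e-3)

    def test_degradation_quarter_after_two_half_lives(self):
        lam = np.log(2) / P.t_half_free
        assert np.exp(-lam * 0.84) == pytest.approx(0.25, rel=1e-3)

    def test_validation(self):
        with pytest.raises(ValueError):
            background_consumption_rate(-1.0, 1.0, 1.0)
        with pytest.raises(ValueError):
            production_rate(1.0, -1.0, 0.0)
        with pytest.raises(ValueError):
            BMPParams(t_half_free=5.0)     # slower than the in-gel pool
        with pytest.raises(ValueError):
            BMPParams(D_gel=10.0)          # gel must hinder diffusion


class TestDifferentiationSink:
    def test_sink_resets_to_floor(self):
        g = np.array([P.g_min, 50.0, 50.0, 0.001])
        mask = np.array([True, True, False, True])
        out = differentiation_sink(g, mask)
        assert out.tolist() == [P.g_min, P.g_min, 50.0, 0.001]


class TestGelPool:
    def test_intact_gel_half_life(self):
        g_gel, released = gel_pool_step(np.array([1.0]), np.array([1.0]),
                                        P.t_half_gel)
        assert g_gel[0] == pytest.approx(0.5, rel=1e-12)
        assert released[0] == 0.0

    def test_empty_pool_stays_empty(self):
        g_gel, released = gel_pool_step(np.zeros(3), np.full(3, 0.5), 1.0)
        assert np.all(g_gel == 0) and np.all(released == 0)

    def test_step_splitting_consistency(self):
        """One step equals two half steps exactly for frozen alginate."""
        a = np.array([0.5])
        g1, r1 = gel_pool_step(np.array([2.0]), a, 1.0)
        gh, rh1 = gel_pool_step(np.array([2.0]), a, 0.5)
        g2, rh2 = gel_pool_step(gh, a, 0.5)
        assert g1[0] == pytest.approx(g2[0], rel=1e-12)
        assert r1[0] == pytest.approx(rh1[0] + rh2[0], rel=1e-12)

    def test_mass_bookkeeping(self):
        """Released + destroyed equals the decrease of the encapsulated pool."""
        g0 = np.array([3.0])
        a = np.array([0.3])
        g1, released = gel_pool_step(g0, a, 2.0)
        lam_rel = o.release_rate(a)
        lam_tot = P.lambda_gel + lam_rel
        destroyed = (P.lambda_gel / lam_tot) * (g0 - g1)
        assert destroyed[0] + released[0] == pytest.approx(g0[0] - g1[0],
                                                           rel=1e-12)

    def test_diffusivity_blend(self):
        assert gel_diffusivity(1.0) == pytest.approx(P.D_gel)
        assert gel_diffusivity(0.0) == pytest.approx(P.D_vivo)
        assert gel_diffusivity(0.5) == pytest.approx((P.D_gel + P.D_vivo) / 2)


def _quiet_params():
    """Parameters with all reaction channels effectively disabled."""
    return BMPParams(t_half_free=1e12, t_half_gel=1e13,
                     v_max_per_cell=1e-30, alpha_prod=1e-30)


class TestFieldStep:
    def test_diffusion_conserves_mass(self, small_grid):
        params = _quiet_params()
        rng = np.random.default_rng(7)
        g = rng.uniform(0.0, 5.0, small_grid.shape)
        state = BMPState(g, np.zeros(small_grid.shape))
        zeros = small_grid.zeros()
        mask = np.zeros(small_grid.shape, dtype=bool)
        total0 = small_grid.integrate(state.g)
        for _ in range(5):
            state = step_bmp2(state, zeros, zeros, zeros, mask, 1.0,
                              small_grid, params)
        assert small_grid.integrate(state.g) == pytest.approx(total0,
                                                              rel=1e-10)

    def test_decay_only_follows_exponential(self, small_grid):
        """No cells, no gel: the spatial mean follows exp(-lambda t)."""
        g0 = 2.5
        state = BMPState(small_grid.full(g0), small_grid.zeros())
        zeros = small_grid.zeros()
        mask = np.zeros(small_grid.shape, dtype=bool)
        days = 3
        for _ in range(days * 20):
            state = step_bmp2(state, zeros, zeros, zeros, mask, 0.05,
                              small_grid, dt_react=0.002)
        expected = g0 * np.exp(-P.lambda_free * days)
        # first-order reaction sub-steps: ~1% bias at this resolution
        assert state.g.mean() == pytest.approx(expected, rel=1e-2)

    def test_point_source_matches_fine_difference_oracle(self):
        """Implicit diffusion agrees with a brute-force explicit scheme."""
        grid = Grid(np.linspace(0, 2.0, 11), np.linspace(0, 2.0, 11))
        g0 = grid.zeros()
        g0[5, 5] = 100.0
        D = grid.full(1.0)

        # oracle: explicit FTCS with a tiny step
        dt_fine = 2e-4
        g_ref = g0.copy()
        from osteosim.fv import transmissibilities, divergence
        Tx, Ty = transmissibilities(grid, D)
        for _ in range(int(0.5 / dt_fine)):
            g_ref = g_ref + dt_fine * divergence(grid, Tx, Ty, g_ref)

        g_imp = g0.copy()
        n = 200
        solver = ImplicitDiffusion(grid, D, 0.5 / n)
        for _ in range(n):
            g_imp = solver.step(g_imp)
        scale = np.abs(g_ref).max()
        assert np.abs(g_imp - g_ref).max() < 0.01 * scale

    def test_homeostasis_band_84_days(self, small_grid):
        """With tissue-density cells and no gel, g stays physiological."""
        cells = small_grid.full(1e6)
        zeros = small_grid.zeros()
        mask = np.zeros(small_grid.shape, dtype=bool)
        for g0 in (0.008, 0.05):
            state = BMPState(small_grid.full(g0), small_grid.zeros())
            for _ in range(84):
                state = step_bmp2(state, zeros, cells, zeros, mask, 1.0,
                                  small_grid)
                assert state.g.min() >= 0.008 - 1e-9
                assert state.g.max() <= 0.05 + 1e-9

    def test_nonnegativity_under_stress(self, small_grid):
        """Strong consumption and decay never drive g negative."""
        rng = np.random.default_rng(11)
        state = BMPState(rng.uniform(0, 1e-3, small_grid.shape),
                         rng.uniform(0, 10.0, small_grid.shape))
        a = rng.uniform(0, 1, small_grid.shape)
        cells = small_grid.full(5e6)
        mask = rng.uniform(size=small_grid.shape) > 0.5
        for _ in range(10):
            state = step_bmp2(state, a, cells, cells, mask, 1.0, small_grid)
            assert state.g.min() >= 0
            assert state.g_gel.min() >= 0

    def test_invalid_dt_rejected(self, small_grid):
        state = BMPState(small_grid.zeros(), small_grid.zeros())
        z = small_grid.zeros()
        with pytest.raises(ValueError):
            step_bmp2(state, z, z, z, z.astype(bool), -1.0, small_grid)
        with pytest.raises(ValueError):
            gel_pool_step(z, z, 0.0)
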