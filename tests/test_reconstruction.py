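"""Per-pixel loss, CMA-ES solving, and the mean-field outer loop."""

import numpy as np
import pytest

import quasispec as q
from quasispec.discontinuity import EdgeState, GradientField, build_couplings
from quasispec.reconstruction import (SolverConfig, initialize_field,
                                      pixel_loss, run_reconstruction,
                                      solve_pixel)
from quasispec.spectra import PixelSpectrum, TransparencyField

from conftest import fast_config


def _free_couplings(shape, t_ed=1.0):
    st = EdgeState(np.zeros(shape, dtype=bool),
                   GradientField(np.zeros(shape)))
    return build_couplings(shape, st, t_ed=t_ed)


class TestPixelLoss:
    def test_perfect_match_gives_zero(self, grid, light):
        rng = np.random.default_rng(0)
        t = rng.uniform(0, 1, grid.w)
        field = TransparencyField(grid, np.tile(t, (3, 3, 1)))
        obs = (light.values * grid.simpson_weights) @ t
        cw = _free_couplings((3, 3))
        val = pixel_loss((1, 1), PixelSpectrum(grid, t), field, light,
                         obs, cw)
        assert val == pytest.approx(0.0, abs=1e-10)

    def test_single_neighbor_delta_squared(self, grid, light):
        """Fidelity-perfect t, one neighbour off by delta at one wavelength."""
        rng = np.random.default_rng(1)
        t = rng.uniform(0.1, 0.9, grid.w)
        delta = 0.07
        data = np.tile(t, (1, 2, 1))
        data[0, 1, 5] += delta
        field = TransparencyField(grid, data)
        obs = (light.values * grid.simpson_weights) @ t
        cw = _free_couplings((1, 2))
        val = pixel_loss((0, 0), PixelSpectrum(grid, t), field, light,
                         obs, cw)
        assert val == pytest.approx(delta ** 2, rel=1e-9)

    def test_matches_independent_scalar_transcription(self, grid, light):
        """Vectorized loss equals a direct scalar evaluation, 100 cases."""
        rng = np.random.default_rng(2)
        wts = grid.simpson_weights
        h, w = 3, 3
        for _ in range(100):
            data = rng.uniform(0, 1, (h, w, grid.w))
            field = TransparencyField(grid, data)
            t = rng.uniform(0, 1, grid.w)
            obs = rng.uniform(0, 300, 3)
            m = (int(rng.integers(0, h)), int(rng.integers(0, w)))
            cw = _free_couplings((h, w))
            got = pixel_loss(m, PixelSpectrum(grid, t), field, light,
                             obs, cw)
            # scalar transcription of the loss
            fid = sum(np.exp(abs(
                sum(light.values[c][i] * wts[i] * t[i]
                    for i in range(grid.w)) - obs[c])) for c in range(3)) - 3
            nbrs = [(m[0] + dr, m[1] + dc)
                    for dr, dc in ((1, 0), (-1, 0), (0, 1), (0, -1))
                    if 0 <= m[0] + dr < h and 0 <= m[1] + dc < w]
            smooth = sum(
                1.0 * sum((t[i] - data[n[0], n[1], i]) ** 2
                          for i in range(grid.w))
                for n in nbrs) / len(nbrs)
            assert got == pytest.approx(fid + smooth, rel=1e-9)


class TestSolvePixel:
    @staticmethod
    def _problem(grid, light, seed=0):
        rng = np.random.default_rng(seed)
        kernel = light.values * grid.simpson_weights
        t_star = rng.uniform(0.1, 0.9, grid.w)
        obs = kernel @ t_star
        nbr = np.tile(t_star, (2, 1))
        return kernel, obs, nbr, np.ones(2), t_star

    def test_reaches_tolerance_on_reachable_toy_problem(self):
        """w=4 toy: observed = forward(t*), neighbours = t*; the optimum
        t* has zero loss, so the solver must reach loss(t*) + tol."""
        grid4 = q.WavelengthGrid(np.linspace(500.0, 600.0, 4))
        light4 = q.EffectiveLight(grid4, np.ones((2, 4)) * 0.01,
                                  ("a", "b"))
        kernel, obs, nbr, gw, t_star = self._problem(grid4, light4)
        init = PixelSpectrum(grid4, np.full(4, 0.5))
        cfg = SolverConfig(budget=2000)
        x, f, evals, reached = solve_pixel(init, kernel, obs, nbr, gw,
                                           tolerance=0.05, config=cfg, seed=1)
        assert reached and f <= 0.05  # loss(t*) = 0
        assert x.min() >= 0 and x.max() <= 1

    def test_infinite_tolerance_returns_init_with_zero_evals(self, grid,
                                                             light):
        kernel, obs, nbr, gw, _ = self._problem(grid, light)
        init = PixelSpectrum(grid, np.full(grid.w, 0.3))
        cfg = SolverConfig()
        x, f, evals, reached = solve_pixel(init, kernel, obs, nbr, gw,
                                           tolerance=np.inf, config=cfg,
                                           seed=1)
        assert evals == 0 and reached
        assert np.array_equal(x, init.values)

    def test_deterministic_given_seed(self, grid, light):
        kernel, obs, nbr, gw, _ = self._problem(grid, light, seed=3)
        init = PixelSpectrum(grid, np.full(grid.w, 0.5))
        cfg = SolverConfig(budget=300)
        out1 = solve_pixel(init, kernel, obs, nbr, gw, 1e-9, cfg, seed=7)
        out2 = solve_pixel(init, kernel, obs, nbr, gw, 1e-9, cfg, seed=7)
        assert np.array_equal(out1[0], out2[0])
        assert out1[1] == out2[1]

    def test_never_worse_than_warm_start(self, grid, light):
        kernel, obs, nbr, gw, t_star = self._problem(grid, light, seed=4)
        init = PixelSpectrum(grid, t_star)  # already optimal-ish
        cfg = SolverConfig(budget=60)
        from quasispec.reconstruction import _batch_loss
        f0 = float(_batch_loss(t_star[None], kernel, obs, nbr, gw)[0])
        _, f, _, _ = solve_pixel(init, kernel, obs, nbr, gw,
                                 tolerance=0.0, config=cfg, seed=2)
        assert f <= f0 + 1e-12


class TestInitializeField:
    def test_white_background_pixel_starts_near_one(self, grid, light):
        white = light.integrals()
        img = q.ChannelImage(np.tile(white, (2, 2, 1)), bit_depth=1)
        f = initialize_field(img, light)
        assert np.allclose(f.data, 1.0, atol=1e-6)

    def test_black_pixel_starts_at_zero(self, grid, light):
        img = q.ChannelImage(np.zeros((2, 2, 3)), bit_depth=1)
        f = initialize_field(img, light)
        assert np.all(f.data == 0)

    def test_half_background_gray_starts_at_half(self, grid, light):
        white = light.integrals()
        img = q.ChannelImage(np.tile(0.5 * white, (2, 2, 1)), bit_depth=1)
        f = initialize_field(img, light)
        assert np.allclose(f.data, 0.5, atol=1e-9)


class TestToleranceSchedule:
    def test_linear_then_constant(self):
        cfg = SolverConfig(tol_initial=0.5, tol_final=0.05, tol_horizon=10)
        tols = [cfg.tolerance(i) for i in range(1, 15)]
        assert tols[0] == pytest.approx(0.5)
        assert tols[9] == pytest.approx(0.05)
        assert all(t == pytest.approx(0.05) for t in tols[9:])
        diffs = np.diff(tols[:10])
        assert np.allclose(diffs, diffs[0])  # linear decrease


class TestRunReconstruction:
    def test_uniform_background_converges_fast_and_uniform(self, grid, light):
        """All pixels share the same subproblem -> uniform field, few sweeps."""
        white = light.integrals()
        img = q.ChannelImage(np.tile(0.8 * white / white.max(), (6, 6, 1)),
                             bit_depth=1)
        cfg = fast_config(white_level=white / white.max(),
                          tol_horizon=2, tol_initial=0.1, tol_final=0.05,
                          max_iterations=5)
        field, trace, costs, edges = run_reconstruction(img, light, cfg)
        assert trace.n_iterations <= 3
        spread = field.data.std(axis=(0, 1)).max()
        assert spread < 0.05
        assert trace.converged

    def test_trace_contract(self, tiny_scene):
        sc = tiny_scene
        cfg = fast_config(sc["white_level"], max_iterations=4, seed=2)
        _, trace, _, _ = run_reconstruction(sc["image"], sc["light"], cfg)
        assert trace.n_iterations <= 4
        assert len(trace.mean_cost) == len(trace.variation_coefficient)
        assert len(trace.tolerance) == trace.n_iterations
        assert all(c >= 0 for c in trace.mean_cost)
        # ran out of iterations before the constant-tolerance phase
        assert not trace.converged

    def test_saturated_pixels_excluded_and_flagged(self, grid, light):
        white = light.integrals()
        data = np.tile(0.6 * white / white.max(), (5, 5, 1)) * 255
        data[2, 2] = 255.0
        img = q.ChannelImage(data, bit_depth=8,
                             saturated=(data.max(axis=2) >= 255))
        cfg = fast_config(white_level=white / white.max() * 0.9,
                          max_iterations=2)
        field, trace, costs, _ = run_reconstruction(img, light, cfg)
        assert not field.valid[2, 2]
        assert np.isnan(costs[2, 2])

    def test_reprojection_residual_decreases_on_phantom(self, tiny_scene):
        """Mean |forward(field) - observed| shrinks over the sweeps."""
        sc = tiny_scene
        light = sc["light"].scaled_to_white(sc["white_level"])
        obs = sc["image"].normalized()
        kernel = light.values * light.grid.simpson_weights

        def mean_resid(field):
            pred = np.einsum("hwl,cl->hwc", field.data, kernel)
            return float(np.abs(pred - obs).mean())

        cfg1 = fast_config(sc["white_level"], max_iterations=1, seed=3)
        cfg8 = fast_config(sc["white_level"], max_iterations=8, seed=3)
        f1, *_ = run_reconstruction(sc["image"], sc["light"], cfg1)
        f8, *_ = run_reconstruction(sc["image"], sc["light"], cfg8)
        assert mean_resid(f8) < mean_resid(f1)


class TestCMAES:
    def test_converges_on_quadratic(self):
        from quasispec import cmaes
        rng = np.random.default_rng(0)
        target = rng.uniform(0.3, 0.7, 12)

        def f(X):
            return np.sum((X - target) ** 2, axis=1)

        res = cmaes.minimize(f, np.full(12, 0.5), 0.2, budget=4000,
                             target=1e-8, seed=5)
        assert res.fun < 1e-6

    def test_respects_box_bounds(self):
        from quasispec import cmaes

        seen = []

        def f(X):
            seen.append(X.copy())
            return np.sum(X ** 2, axis=1)

        cmaes.minimize(f, np.full(6, 0.9), 0.5, budget=600, seed=0)
        allx = np.vstack(seen)
        assert allx.min() >= 0.0 and allx.max() <= 1.0

    def test_deterministic_per_seed(self):
        from quasispec import cmaes

        def f(X):
            return np.sum((X - 0.3) ** 2, axis=1)

        r1 = cmaes.minimize(f, np.full(8, 0.6), 0.2, budget=500, seed=11)
        r2 = cmaes.minimize(f, np.full(8, 0.6), 0.2, budget=500, seed=11)
        assert np.array_equal(r1.x, r2.x) and r1.fun == r2.fun
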