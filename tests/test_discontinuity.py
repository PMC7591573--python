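"""Edge state, Bresenham rasterization, and coupling weights."""

import numpy as np
import pytest

import quasispec as q
from quasispec.discontinuity import (EdgeState, GradientField, bresenham_line,
                                     build_couplings, coupling_weight,
                                     detect_edges, grayscale_first_pc,
                                     image_gradient, neighbor_offsets,
                                     spectral_gradient)


def _edge_state(edges, grad=None):
    e = np.asarray(edges, dtype=bool)
    g = GradientField(grad if grad is not None else np.zeros(e.shape))
    return EdgeState(e, g)


class TestGrayscalePC:
    def test_equal_channels_project_to_common_channel(self):
        rng = np.random.default_rng(0)
        ch = rng.uniform(0, 1, (6, 6))
        img = q.ChannelImage(np.stack([ch, ch, ch], axis=2), bit_depth=1)
        gray = grayscale_first_pc(img)
        # rank-1 data: output is a monotone affine map of the channel
        flat_in = ch.ravel()
        flat_out = gray.ravel()
        corr = np.corrcoef(flat_in, flat_out)[0, 1]
        assert corr == pytest.approx(1.0, abs=1e-10)
        assert gray.min() == pytest.approx(0.0) and gray.max() == pytest.approx(1.0)

    def test_anticorrelated_channels_capture_difference_axis(self):
        """First PC of 2-channel anti-correlated data is the difference axis."""
        rng = np.random.default_rng(1)
        a = rng.uniform(0, 1, (8, 8))
        img = q.ChannelImage(np.stack([a, 1 - a], axis=2), bit_depth=1,
                             channels=("x", "y"))
        x = img.data.reshape(-1, 2)
        cov = np.cov(x.T)
        evals, evecs = np.linalg.eigh(cov)  # eigendecomposition oracle
        axis = evecs[:, -1]
        scores = (x - x.mean(0)) @ axis
        gray = grayscale_first_pc(img).ravel()
        corr = abs(np.corrcoef(scores, gray)[0, 1])
        assert corr == pytest.approx(1.0, abs=1e-10)
        assert scores.var() >= np.var(x[:, 0]) - 1e-12

    def test_constant_image_warns_and_returns_zero(self):
        img = q.ChannelImage(np.full((4, 4, 3), 0.5), bit_depth=1)
        with pytest.warns(UserWarning):
            gray = grayscale_first_pc(img)
        assert np.all(gray == 0)


class TestImageGradient:
    def test_constant_image_zero_gradient(self):
        assert np.all(image_gradient(np.full((5, 5), 3.0)).values == 0)

    def test_step_edge_maximal_on_step(self):
        img = np.zeros((5, 8))
        img[:, 4:] = 1.0
        g = image_gradient(img).values
        assert np.all(g[:, [3, 4]] > 0.99)
        assert np.all(g[:, [0, 7]] < 1e-12)

    def test_linear_ramp_uniform_interior_gradient(self):
        """Central differences recover the analytic slope of a ramp."""
        s = 0.25
        cols = np.arange(10)
        img = np.tile(s * cols, (6, 1))
        gy, gx = np.gradient(img)
        raw = np.hypot(gx, gy)
        assert np.allclose(raw[:, 1:-1], s)  # pre-normalization oracle
        g = image_gradient(img).values
        assert np.allclose(g[:, 1:-1], g[0, 1])  # uniform after scaling


class TestSpectralGradient:
    def test_uniform_field_zero(self, grid):
        field = q.TransparencyField(grid, np.full((5, 5, grid.w), 0.4))
        assert np.all(spectral_gradient(field).values == 0)

    def test_orthogonal_regions_maximal_on_boundary(self, grid):
        w = grid.w
        a = np.zeros(w)
        a[:w // 2] = 0.8
        b = np.zeros(w)
        b[w // 2:] = 0.8
        data = np.empty((5, 6, w))
        data[:, :3] = a
        data[:, 3:] = b
        field = q.TransparencyField(grid, data)
        g = spectral_gradient(field).values
        assert g[2, 2] == pytest.approx(1.0) or g[2, 3] == pytest.approx(1.0)
        assert g[2, 0] == 0.0 and g[2, 5] == 0.0

    def test_three_pixel_row_matches_hand_correlation(self, grid):
        """Centre dissimilarity equals the hand-computed (1 - rho)/2."""
        rng = np.random.default_rng(5)
        s1 = rng.uniform(0.1, 1, grid.w)
        s3 = rng.uniform(0.1, 1, grid.w)
        data = np.stack([s1, np.full(grid.w, 0.5), s3])[None, :, :]
        field = q.TransparencyField(grid, data)
        g = spectral_gradient(field, axis=1)
        rho = float(s1 @ s3 / (np.linalg.norm(s1) * np.linalg.norm(s3)))
        expected = (1 - rho) / 2
        # only one nonzero entry -> max-normalized to 1; check pre-norm ratio
        raw = q.discontinuity._flank_dissimilarity(data, 1)
        assert raw[0, 1] == pytest.approx(expected, rel=1e-12)
        assert g.values[0, 1] == pytest.approx(1.0)

    def test_zero_norm_spectrum_counts_as_similar(self, grid):
        data = np.zeros((1, 3, grid.w))
        data[0, 1] = 0.5
        field = q.TransparencyField(grid, data)
        assert np.all(spectral_gradient(field, axis=1).values == 0)


class TestDetectEdges:
    def test_zero_gradient_no_edges(self):
        st = detect_edges(GradientField(np.zeros((6, 6))))
        assert not st.edges.any()

    def test_clean_step_gives_single_thin_line(self):
        """One clean step -> one connected ~1-px line, like a reference run."""
        from skimage import measure
        img = np.zeros((16, 16))
        img[:, 8:] = 1.0
        grad = image_gradient(img)
        st = detect_edges(grad)
        assert st.edges.any()
        labels = measure.label(st.edges, connectivity=2)
        assert labels.max() == 1
        cols = np.where(st.edges.any(axis=0))[0]
        assert len(cols) <= 2  # thin, at the step

    def test_edge_count_monotone_in_high_threshold(self):
        """Hysteresis mask shrinks as the high threshold rises."""
        rng = np.random.default_rng(7)
        img = rng.uniform(0, 1, (24, 24))
        grad = image_gradient(img)
        counts = [detect_edges(grad, high_quantile=hq).mask.sum()
                  for hq in (0.5, 0.7, 0.9, 0.97)]
        assert all(b <= a for a, b in zip(counts, counts[1:]))


class TestBresenham:
    def test_adjacent_pixels_empty_set(self):
        assert bresenham_line((0, 0), (1, 1)) == []
        assert bresenham_line((0, 0), (0, 1)) == []

    def test_collinear_integer_points(self):
        assert bresenham_line((0, 0), (2, 0)) == [(1, 0)]
        assert bresenham_line((0, 0), (0, 4)) == [(0, 1), (0, 2), (0, 3)]

    def test_symmetric_under_endpoint_swap(self):
        rng = np.random.default_rng(8)
        for _ in range(50):
            m = tuple(rng.integers(-6, 7, 2))
            n = tuple(rng.integers(-6, 7, 2))
            if m == n:
                continue
            assert bresenham_line(m, n) == bresenham_line(n, m)

    def test_identical_endpoints_raise(self):
        with pytest.raises(ValueError):
            bresenham_line((2, 3), (2, 3))

    def test_matches_bruteforce_rasterization_in_7x7_window(self):
        """All segments in a 7x7 window against a nearest-raster oracle.

        The oracle steps the line one unit along its major axis: a correct
        rasterization has exactly one intermediate point per step, and each
        point lies within half a pixel of the true line position (equality
        allowed only at exact rounding ties).
        """

        def oracle_positions(m, n):
            a, b = sorted((m, n))
            dr, dc = b[0] - a[0], b[1] - a[1]
            steps = max(abs(dr), abs(dc))
            return [(a[0] + i * dr / steps, a[1] + i * dc / steps)
                    for i in range(1, steps)]

        coords = [(r, c) for r in range(7) for c in range(7)]
        checked = 0
        for m in coords:
            for n in coords:
                if m >= n:
                    continue
                got = bresenham_line(m, n)
                exp = oracle_positions(m, n)
                assert len(got) == len(exp)
                for (gr, gc), (er, ec) in zip(got, exp):
                    assert abs(gr - er) <= 0.5 + 1e-9
                    assert abs(gc - ec) <= 0.5 + 1e-9
                checked += 1
        assert checked == 7 * 7 * (7 * 7 - 1) // 2


class TestCouplingWeight:
    def test_no_edges_unit_distance_gives_one(self):
        st = _edge_state(np.zeros((5, 5)))
        assert coupling_weight((2, 2), (2, 3), st) == pytest.approx(1.0)

    def test_diagonal_no_intermediates_gives_inv_sqrt2(self):
        st = _edge_state(np.zeros((5, 5)))
        assert coupling_weight((1, 1), (2, 2), st) == pytest.approx(1 / np.sqrt(2))

    def test_one_edge_pixel_on_line(self):
        """Edge at the midpoint, D=0, T_b=0.9, L=2 -> G = 0.05."""
        e = np.zeros((5, 5), dtype=bool)
        e[2, 2] = True
        st = _edge_state(e)
        g = coupling_weight((2, 1), (2, 3), st, t_b=0.9)
        assert g == pytest.approx(0.5 * 0.1 * 1.0)

    def test_endpoint_edge_attenuates_by_default_but_not_interior_mode(self):
        e = np.zeros((5, 5), dtype=bool)
        e[2, 3] = True
        st = _edge_state(e)
        g_inc = coupling_weight((2, 2), (2, 3), st, t_b=0.9)
        g_exc = coupling_weight((2, 2), (2, 3), st, t_b=0.9,
                                include_endpoints=False)
        assert g_inc == pytest.approx(0.1)
        assert g_exc == pytest.approx(1.0)

    def test_matches_scalar_transcription_on_random_cases(self):
        """Vectorized build_couplings equals the direct per-pair formula."""
        rng = np.random.default_rng(9)
        for _ in range(100):
            h, w = 6, 6
            edges = rng.uniform(size=(h, w)) < 0.3
            grad = rng.uniform(0, 1, (h, w))
            st = _edge_state(edges, grad)
            t_ed = rng.choice([1.0, 1.5, 2.0])
            cw = build_couplings((h, w), st, t_ed=t_ed, t_b=0.9)
            m = (int(rng.integers(0, h)), int(rng.integers(0, w)))
            for (n, g_fast) in cw.neighbors(*m):
                g_ref = coupling_weight(m, n, st, t_b=0.9)
                assert g_fast == pytest.approx(g_ref, rel=1e-12)


class TestBuildCouplings:
    def test_neighbor_counts_by_radius(self):
        assert len(neighbor_offsets(1.0)) == 4
        assert len(neighbor_offsets(1.5)) == 8
        assert len(neighbor_offsets(2.0)) == 12

    def test_interior_corner_neighbor_counts(self):
        st = _edge_state(np.zeros((5, 5)))
        cw = build_couplings((5, 5), st, t_ed=1.0)
        assert len(list(cw.neighbors(2, 2))) == 4
        assert len(list(cw.neighbors(0, 0))) == 2
        cw8 = build_couplings((5, 5), st, t_ed=1.5)
        assert len(list(cw8.neighbors(2, 2))) == 8

    def test_symmetric_weights(self):
        rng = np.random.default_rng(10)
        edges = rng.uniform(size=(6, 6)) < 0.25
        st = _edge_state(edges, rng.uniform(0, 1, (6, 6)))
        for t_ed in (1.0, 2.0):
            cw = build_couplings((6, 6), st, t_ed=t_ed)
            for r in range(6):
                for c in range(6):
                    for (n, gmn) in cw.neighbors(r, c):
                        assert cw.weight(n, (r, c)) == pytest.approx(gmn)

    def test_no_edges_gives_pure_smoothing(self):
        st = _edge_state(np.zeros((6, 6)))
        cw = build_couplings((6, 6), st, t_ed=1.5)
        for (dr, dc), j in zip(cw.offsets, range(len(cw.offsets))):
            l_mn = np.hypot(dr, dc)
            vals = cw.weights[:, :, j]
            assert np.allclose(vals[np.isfinite(vals)], 1.0 / l_mn)

    def test_boundary_weights_smaller_than_interior(self):
        """Couplings across an edge line drop by at least (1 - T_b)."""
        edges = np.zeros((8, 8), dtype=bool)
        edges[:, 4] = True
        st = _edge_state(edges)
        cw = build_couplings((8, 8), st, t_ed=1.0, t_b=0.9)
        across = cw.weight((3, 4), (3, 5))    # involves the edge column
        interior = cw.weight((3, 1), (3, 2))
        assert across <= (1 - 0.9) * interior + 1e-12
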