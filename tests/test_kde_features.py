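"""Density-map featurization: kernel, KDE grid, positional encoding, stacking."""

import numpy as np
import pytest

from combosyn.kde_features import (
    DKPETensor,
    ExpressionVector,
    channel_cascade,
    dkde_map,
    featurize_expression,
    gaussian_kernel,
    position_encoding,
    render_dkpe_image,
    split_expression_vector,
)


def naive_kde(x, y, h, xp, yq):
    """Independent double-loop evaluation of the bivariate KDE."""
    total = 0.0
    for xm, ym in zip(x, y):
        total += gaussian_kernel((xp - xm) / h, (yq - ym) / h)
    return total / (len(x) * h * h)


class TestSplit:
    def test_even_split_halves_and_roundtrip(self):
        v = ExpressionVector("c1", np.arange(496, dtype=float))
        x, y = split_expression_vector(v)
        assert len(x) == len(y) == 248
        np.testing.assert_array_equal(np.concatenate([x, y]), v.values)

    def test_tiny_example(self):
        x, y = split_expression_vector(ExpressionVector("c", [1.0, 2.0, 3.0, 4.0]))
        np.testing.assert_array_equal(x, [1, 2])
        np.testing.assert_array_equal(y, [3, 4])

    def test_odd_length_rejected(self):
        with pytest.raises(ValueError, match="odd length"):
            split_expression_vector(ExpressionVector("c", [1.0, 2.0, 3.0, 4.0, 5.0]))

    def test_nonfinite_rejected(self):
        with pytest.raises(ValueError):
            ExpressionVector("c", [1.0, np.nan])


class TestGaussianKernel:
    def test_origin_value(self):
        assert gaussian_kernel(0.0, 0.0) == pytest.approx(1 / (2 * np.pi), abs=1e-12)

    def test_point_value(self):
        # direct scalar evaluation: (1/2pi)*exp(-1)
        assert gaussian_kernel(1.0, 1.0) == pytest.approx(0.05854983152431917, abs=1e-12)

    def test_symmetries(self, rng):
        for _ in range(20):
            u, v = rng.normal(size=2)
            k = gaussian_kernel(u, v)
            assert k == pytest.approx(gaussian_kernel(-u, -v), abs=1e-15)
            assert k == pytest.approx(gaussian_kernel(v, u), abs=1e-15)
            assert k > 0
            assert k <= 1 / (2 * np.pi)


class TestDkdeMap:
    def test_single_kernel_peak(self):
        grid = dkde_map([0.0], [0.0], bandwidth_h=1.0, grid_size=9)
        p = np.argmin(np.abs(grid.x_coords))
        q = np.argmin(np.abs(grid.y_coords))
        assert grid.density[p, q] == pytest.approx(1 / (2 * np.pi), abs=1e-12)

    def test_matches_naive_double_loop(self, rng):
        """Grid values equal the brute-force double-loop KDE to 1e-10."""
        for _ in range(5):
            n = int(rng.integers(2, 50))
            x, y = rng.normal(size=n), rng.normal(size=n)
            grid = dkde_map(x, y, bandwidth_h="auto", grid_size=12)
            for _ in range(5):
                p, q = rng.integers(0, 12, size=2)
                expected = naive_kde(x, y, grid.bandwidth_h, grid.x_coords[p], grid.y_coords[q])
                assert abs(grid.density[p, q] - expected) < 1e-10

    def test_integrates_to_one(self, rng):
        for seed in range(3):
            r = np.random.default_rng(seed)
            x, y = r.normal(size=40), r.normal(size=40)
            grid = dkde_map(x, y, grid_size=96, pad_bandwidths=4.0)
            dx = grid.x_coords[1] - grid.x_coords[0]
            dy = grid.y_coords[1] - grid.y_coords[0]
            assert grid.density.sum() * dx * dy == pytest.approx(1.0, abs=0.02)

    def test_transpose_identity(self, rng):
        """Swapping the halves transposes the map: f_xy(p,q) = f_yx(q,p)."""
        x, y = rng.normal(size=30), rng.normal(size=30) * 2 + 1
        g1 = dkde_map(x, y, bandwidth_h=0.7, grid_size=10)
        g2 = dkde_map(y, x, bandwidth_h=0.7, grid_size=10)
        np.testing.assert_allclose(g1.density, g2.density.T, atol=1e-10)

    def test_scale_equivariance(self, rng):
        """Scaling data and bandwidth by c scales density by 1/c^2."""
        x, y = rng.normal(size=25), rng.normal(size=25)
        c = 3.0
        g1 = dkde_map(x, y, bandwidth_h=0.5, grid_size=8)
        g2 = dkde_map(c * x, c * y, bandwidth_h=0.5 * c, grid_size=8)
        np.testing.assert_allclose(g2.density, g1.density / c**2, rtol=1e-9)

    def test_empty_input_rejected(self):
        with pytest.raises(ValueError):
            dkde_map([], [], bandwidth_h=1.0)

    def test_zero_variance_handled(self):
        grid = dkde_map([1.0] * 5, [1.0] * 5, bandwidth_h="auto", grid_size=8)
        assert grid.bandwidth_h > 0
        assert np.all(np.isfinite(grid.density))


class TestPositionEncoding:
    def test_bounds_and_corners(self, rng):
        for _ in range(5):
            x, y = rng.normal(size=20), rng.normal(size=20)
            pe = position_encoding(dkde_map(x, y, grid_size=16))
            for chan in (pe.a_chan, pe.b_chan):
                assert chan.min() == 0.0
                assert chan.max() == 1.0
                assert np.all((chan >= 0) & (chan <= 1))
            assert pe.a_chan[0, 0] == 0.0 and pe.b_chan[0, 0] == 0.0
            assert pe.a_chan[-1, -1] == 1.0 and pe.b_chan[-1, -1] == 1.0

    def test_midpoint_of_uniform_axis(self, rng):
        grid = dkde_map(rng.normal(size=10), rng.normal(size=10), grid_size=17)
        pe = position_encoding(grid)
        assert pe.a_chan[8, 0] == pytest.approx(0.5, abs=1e-12)

    def test_affine_invariance(self, rng):
        """Shifting/scaling the underlying data leaves the PE unchanged."""
        x, y = rng.normal(size=15), rng.normal(size=15)
        pe1 = position_encoding(dkde_map(x, y, bandwidth_h=0.5, grid_size=12))
        pe2 = position_encoding(dkde_map(5 * x - 2, 5 * y + 3, bandwidth_h=2.5, grid_size=12))
        np.testing.assert_allclose(pe1.a_chan, pe2.a_chan, atol=1e-12)
        np.testing.assert_allclose(pe1.b_chan, pe2.b_chan, atol=1e-12)


class TestChannelCascade:
    def test_shape_and_passthrough(self, rng):
        grid = dkde_map(rng.normal(size=20), rng.normal(size=20), grid_size=64)
        pe = position_encoding(grid)
        t = channel_cascade(grid, pe, normalize_density=False)
        assert t.channels.shape == (3, 64, 64)
        assert t.grid_size == 64
        np.testing.assert_array_equal(t.channels[0], grid.density)
        np.testing.assert_array_equal(t.channels[1], pe.a_chan)
        np.testing.assert_array_equal(t.channels[2], pe.b_chan)

    def test_normalized_density_in_unit_interval(self, rng):
        grid = dkde_map(rng.normal(size=20), rng.normal(size=20), grid_size=16)
        t = channel_cascade(grid, position_encoding(grid), normalize_density=True)
        assert t.channels[0].min() == 0.0
        assert t.channels[0].max() == 1.0

    def test_shape_mismatch_rejected(self, rng):
        g1 = dkde_map(rng.normal(size=10), rng.normal(size=10), grid_size=8)
        g2 = dkde_map(rng.normal(size=10), rng.normal(size=10), grid_size=16)
        with pytest.raises(ValueError, match="mismatch"):
            channel_cascade(g1, position_encoding(g2))

    def test_tensor_invariants_enforced(self):
        with pytest.raises(ValueError):
            DKPETensor(channels=np.ones((2, 8, 8)))
        bad = np.ones((3, 8, 8))
        bad[1] = 2.0  # PE channel out of range
        with pytest.raises(ValueError):
            DKPETensor(channels=bad)


class TestRenderImage:
    def test_png_written_and_deterministic(self, rng, tmp_path):
        v = ExpressionVector("c", rng.normal(size=64))
        t = featurize_expression(v, grid_size=32)
        p1, p2 = tmp_path / "a.png", tmp_path / "b.png"
        render_dkpe_image(t, p1)
        render_dkpe_image(t, p2)
        assert p1.exists() and p1.stat().st_size > 0
        assert p1.read_bytes() == p2.read_bytes()
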