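import numpy as np
import pytest
from hypothesis import given
from hypothesis import strategies as st

import gifdemons as gd
from gifdemons.grid_ops import DisplacementField, zero_field

from conftest import naive_trilinear


def _random_field(rng, shape, amplitude=1.5):
    return DisplacementField(amplitude * (rng.random(shape + (3,)) - 0.5))


class TestWarp:
    def test_zero_field_is_identity(self, small_volume):
        out = gd.warp_volume(small_volume, zero_field(small_volume))
        np.testing.assert_array_equal(out.data, small_volume.data)

    def test_constant_shift_of_ramp(self):
        x = np.arange(10, dtype=float)
        vol = gd.Volume(np.broadcast_to(x[:, None, None], (10, 6, 6)).copy())
        vec = np.zeros((10, 6, 6, 3))
        vec[..., 0] = 2.0
        out = gd.warp_volume(vol, DisplacementField(vec))
        # pull-back of the affine image: output(x) = x + 2 while in bounds
        np.testing.assert_allclose(out.data[:7, 2, 2], x[:7] + 2.0, atol=1e-12)

    def test_matches_naive_interpolation(self, rng, small_volume):
        field = _random_field(rng, small_volume.shape)
        out = gd.warp_volume(small_volume, field)
        for idx in [(0, 0, 0), (5, 3, 8), (11, 11, 11), (2, 9, 4)]:
            expected = naive_trilinear(
                small_volume.data,
                *(idx[c] + field.vectors[idx][c] for c in range(3)),
            )
            assert out.data[idx] == pytest.approx(expected, abs=1e-6)

    def test_grid_mismatch_raises(self, small_volume):
        bad = DisplacementField(np.zeros((4, 4, 4, 3)))
        with pytest.raises(ValueError, match="mismatch"):
            gd.warp_volume(small_volume, bad)


class TestCompose:
    def test_zero_on_either_side_is_identity(self, rng):
        u = _random_field(rng, (8, 8, 8))
        zero = DisplacementField(np.zeros((8, 8, 8, 3)))
        np.testing.assert_array_equal(gd.compose_fields(u, zero).vectors, u.vectors)
        np.testing.assert_array_equal(gd.compose_fields(zero, u).vectors, u.vectors)

    def test_translations_add(self):
        shape = (6, 6, 6)
        a = np.zeros(shape + (3,)); a[..., 0] = 1.0
        f = np.zeros(shape + (3,)); f[..., 0] = 2.0
        out = gd.compose_fields(DisplacementField(a), DisplacementField(f))
        np.testing.assert_allclose(out.vectors[..., 0], 3.0)
        np.testing.assert_allclose(out.vectors[..., 1:], 0.0)

    def test_matches_naive_oracle(self, rng):
        shape = (7, 7, 7)
        u = _random_field(rng, shape, 1.0)
        f = _random_field(rng, shape, 1.0)
        out = gd.compose_fields(u, f)
        for idx in [(0, 0, 0), (3, 4, 5), (6, 6, 6)]:
            sample = [idx[c] + f.vectors[idx][c] for c in range(3)]
            expected = [
                f.vectors[idx][c] + naive_trilinear(u.vectors[..., c], *sample)
                for c in range(3)
            ]
            np.testing.assert_allclose(out.vectors[idx], expected, atol=1e-6)


class TestGaussianSmoothing:
    def test_sigma_zero_identity(self, rng):
        u = _random_field(rng, (6, 6, 6))
        np.testing.assert_array_equal(
            gd.gaussian_smooth_field(u, 0.0).vectors, u.vectors
        )

    def test_constant_field_fixed_point(self):
        vec = np.zeros((8, 8, 8, 3)); vec[..., 1] = 2.5
        out = gd.gaussian_smooth_field(DisplacementField(vec), 2.0)
        np.testing.assert_allclose(out.vectors, vec, atol=1e-6)

    def test_impulse_matches_sampled_kernel(self):
        n = 11
        vec = np.zeros((n, n, n, 3))
        vec[5, 5, 5, 0] = 1.0
        out = gd.gaussian_smooth_field(DisplacementField(vec), 1.0)
        x = np.arange(n) - 5.0
        k1 = np.exp(-0.5 * x**2)
        k1 /= k1.sum()
        expected = k1[:, None, None] * k1[None, :, None] * k1[None, None, :]
        np.testing.assert_allclose(out.vectors[..., 0], expected, atol=1e-4)


class TestPyramid:
    def test_single_level(self, small_volume):
        assert gd.build_pyramid(small_volume, 1)[0] is small_volume

    def test_factor_two_sizes(self, rng):
        vol = gd.Volume(rng.random((64, 64, 64)))
        pyr = gd.build_pyramid(vol, 3)
        assert [p.shape for p in pyr] == [(64,) * 3, (32,) * 3, (16,) * 3]
        assert pyr[2].spacing == (4.0, 4.0, 4.0)

    def test_constant_stays_constant(self):
        pyr = gd.build_pyramid(gd.Volume(np.full((16, 16, 16), 0.3)), 2)
        np.testing.assert_allclose(pyr[1].data, 0.3, atol=1e-12)

    def test_too_many_levels_rejected(self, small_volume):
        with pytest.raises(ValueError, match="levels"):
            gd.build_pyramid(small_volume, 4)


class TestUpsampleField:
    def test_zero_stays_zero(self):
        u = DisplacementField(np.zeros((8, 8, 8, 3)))
        out = gd.upsample_field(u, (16, 16, 16))
        assert not np.any(out.vectors)
        assert out.shape == (16, 16, 16)

    def test_constant_doubles(self):
        vec = np.zeros((8, 8, 8, 3)); vec[..., 0] = 1.0
        out = gd.upsample_field(DisplacementField(vec), (16, 16, 16))
        np.testing.assert_allclose(out.vectors[..., 0], 2.0, atol=1e-12)

    def test_down_up_reconstructs_smooth_field(self, rng):
        from scipy.ndimage import gaussian_filter

        shape = (32, 32, 32)
        vec = np.stack(
            [gaussian_filter(rng.standard_normal(shape), 4.0) for _ in range(3)],
            axis=-1,
        )
        vec *= 3.0 / np.abs(vec).max()
        full = DisplacementField(vec)
        coarse = DisplacementField(vec[::2, ::2, ::2] / 2.0)
        back = gd.upsample_field(coarse, shape)
        err = np.abs(back.vectors - full.vectors).mean()
        assert err / np.abs(full.vectors).mean() < 0.1


class TestGradientAndJacobian:
    def test_constant_volume_zero_gradient(self):
        g = gd.spatial_gradient(gd.Volume(np.full((6, 6, 6), 2.0)))
        np.testing.assert_array_equal(g, 0)

    def test_ramp_gradient(self):
        x = np.arange(8, dtype=float) * 3.0
        vol = gd.Volume(np.broadcast_to(x[:, None, None], (8, 8, 8)).copy())
        g = gd.spatial_gradient(vol)
        np.testing.assert_allclose(g[..., 0], 3.0)
        np.testing.assert_allclose(g[..., 1:], 0.0)

    def test_matches_finite_difference_oracle(self, rng):
        data = rng.random((5, 5, 5))
        g = gd.spatial_gradient(gd.Volume(data))
        # interior central differences recomputed by hand
        for i in range(1, 4):
            assert g[i, 2, 2, 0] == pytest.approx((data[i + 1, 2, 2] - data[i - 1, 2, 2]) / 2)
        assert g[0, 2, 2, 0] == pytest.approx(data[1, 2, 2] - data[0, 2, 2])

    def test_jacobian_zero_field_is_one(self):
        u = DisplacementField(np.zeros((6, 6, 6, 3)))
        np.testing.assert_allclose(gd.jacobian_determinant(u).data, 1.0)

    def test_jacobian_translation_is_one(self):
        vec = np.zeros((6, 6, 6, 3)); vec[:] = (1.0, -2.0, 0.5)
        np.testing.assert_allclose(
            gd.jacobian_determinant(DisplacementField(vec)).data, 1.0
        )

    def test_jacobian_linear_expansion(self):
        shape = (9, 9, 9)
        coords = np.indices(shape).astype(float)
        vec = np.stack([0.1 * coords[a] for a in range(3)], axis=-1)
        det = gd.jacobian_determinant(DisplacementField(vec)).data
        np.testing.assert_allclose(det[1:-1, 1:-1, 1:-1], 1.1**3, atol=1e-10)


@given(seed=st.integers(0, 10_000))
def test_compose_constant_fields_is_vector_addition(seed):
    rng = np.random.default_rng(seed)
    a, b = rng.uniform(-2, 2, 3), rng.uniform(-2, 2, 3)
    shape = (5, 5, 5)
    fa = DisplacementField(np.broadcast_to(a, shape + (3,)).copy())
    fb = DisplacementField(np.broadcast_to(b, shape + (3,)).copy())
    out = gd.compose_fields(fa, fb)
    np.testing.assert_allclose(
        out.vectors, np.broadcast_to(a + b, shape + (3,)), atol=1e-12
    )
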