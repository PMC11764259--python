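"""Trilinear warping against independent oracles; field downsampling and
Jacobian conventions."""

import numpy as np
import pytest
from scipy.ndimage import map_coordinates

from cyclereg._autodiff import Tensor
from cyclereg.io_formats import TimeSeries4D, Volume3D
from cyclereg.spatial_transform import (DeformationField, base_grid,
                                        downsample_field,
                                        jacobian_determinant, warp_series,
                                        warp_tensor, warp_volume)

from conftest import numeric_gradient


def brute_force_trilinear(vol, phi):
    """Per-voxel 8-corner interpolation, written independently of the
    implementation under test."""
    dims = vol.shape
    out = np.zeros(dims)
    for p in np.ndindex(dims):
        q = [min(max(phi[d][p], 0.0), dims[d] - 1.0) for d in range(3)]
        c0 = [min(int(np.floor(q[d])), dims[d] - 2) for d in range(3)]
        acc = 0.0
        for dx in (0, 1):
            for dy in (0, 1):
                for dz in (0, 1):
                    w = 1.0
                    for d, b in zip(range(3), (dx, dy, dz)):
                        f = q[d] - c0[d]
                        w *= f if b else 1.0 - f
                    acc += w * vol[c0[0] + dx, c0[1] + dy, c0[2] + dz]
        out[p] = acc
    return out


class TestWarpVolume:
    def test_zero_field_is_identity(self):
        rng = np.random.default_rng(0)
        vol = Volume3D(rng.random((6, 6, 6)))
        out = warp_volume(vol, DeformationField.zero((6, 6, 6)))
        np.testing.assert_allclose(out.data, vol.data)

    def test_integer_shift_matches_index_shift(self):
        ramp = np.arange(6 * 6 * 6, dtype=float).reshape(6, 6, 6)
        u = np.zeros((3, 6, 6, 6))
        u[0] = 1.0                      # sample at x+1
        out = warp_volume(Volume3D(ramp), DeformationField(u)).data
        np.testing.assert_allclose(out[:-1], ramp[1:])
        np.testing.assert_allclose(out[-1], ramp[-1])   # border replication

    def test_half_voxel_shift_on_linear_ramp(self):
        x = base_grid((6, 6, 6))[0]
        u = np.zeros((3, 6, 6, 6))
        u[0] = 0.5
        out = warp_volume(Volume3D(x), DeformationField(u)).data
        np.testing.assert_allclose(out[:-1], x[:-1] + 0.5)

    def test_matches_brute_force_oracle(self):
        rng = np.random.default_rng(1)
        vol = rng.random((8, 8, 8))
        field = DeformationField(rng.uniform(-2, 2, (3, 8, 8, 8)))
        ours = warp_volume(Volume3D(vol), field).data
        ref = brute_force_trilinear(vol, field.phi())
        np.testing.assert_allclose(ours, ref, atol=1e-6)

    def test_matches_scipy_map_coordinates(self):
        rng = np.random.default_rng(2)
        vol = rng.random((8, 8, 8))
        field = DeformationField(rng.uniform(-1.5, 1.5, (3, 8, 8, 8)))
        ours = warp_volume(Volume3D(vol), field).data
        coords = np.clip(field.phi(), 0, 7).reshape(3, -1)
        ref = map_coordinates(vol, coords, order=1, mode="nearest").reshape(8, 8, 8)
        np.testing.assert_allclose(ours, ref, atol=1e-12)

    def test_shape_mismatch_rejected(self):
        with pytest.raises(ValueError, match="mismatch"):
            warp_volume(Volume3D(np.zeros((4, 4, 4))),
                        DeformationField.zero((5, 5, 5)))

    def test_gradients_match_finite_differences(self):
        rng = np.random.default_rng(3)
        vol = Tensor(rng.random((6, 6, 6)))
        u = Tensor(rng.uniform(-1.2, 1.2, (3, 6, 6, 6)), requires_grad=True)
        c = rng.standard_normal((6, 6, 6))

        def f():
            return (warp_tensor(vol, u) * c).sum().item()

        (warp_tensor(vol, u) * c).sum().backward()
        num = numeric_gradient(u, f, sample_every=5)
        mask = num != 0
        assert np.abs(u.grad[mask] - num[mask]).max() < 1e-3


class TestWarpSeries:
    def test_framewise_consistency(self):
        rng = np.random.default_rng(4)
        series = TimeSeries4D(rng.random((5, 5, 5, 4)))
        field = DeformationField(rng.uniform(-1, 1, (3, 5, 5, 5)))
        warped = warp_series(series, field)
        assert warped.n_timepoints == 4
        for t in range(4):
            frame = warp_volume(series.frame(t), field).data
            np.testing.assert_allclose(warped.data[..., t], frame, atol=1e-12)

    def test_zero_field_identity(self):
        rng = np.random.default_rng(5)
        series = TimeSeries4D(rng.random((4, 4, 4, 3)))
        out = warp_series(series, DeformationField.zero((4, 4, 4)))
        np.testing.assert_allclose(out.data, series.data)


class TestDownsampleField:
    def test_constant_field_unit_conversion(self):
        u = np.zeros((3, 12, 12, 12))
        u[1] = 3.0                      # 3 fine voxels == 1 coarse voxel
        coarse = downsample_field(DeformationField(u), factor=3)
        assert coarse.shape == (4, 4, 4)
        np.testing.assert_allclose(coarse.u[1], 1.0)
        np.testing.assert_allclose(coarse.u[0], 0.0)

    def test_zero_maps_to_zero(self):
        coarse = downsample_field(DeformationField.zero((9, 9, 9)), factor=3)
        np.testing.assert_allclose(coarse.u, 0.0)

    def test_linear_field_closed_form(self):
        u = np.zeros((3, 24, 24, 24))
        u[0] = 0.3 * base_grid((24, 24, 24))[0]
        coarse = downsample_field(DeformationField(u), factor=3)
        c = np.arange(8)
        np.testing.assert_allclose(coarse.u[0][:, 0, 0], 0.3 * (3 * c + 1) / 3,
                                   atol=1e-12)

    def test_indivisible_dims_rejected(self):
        with pytest.raises(ValueError, match="divisible"):
            downsample_field(DeformationField.zero((10, 10, 10)), factor=3)

    def test_spacing_scales(self):
        coarse = downsample_field(DeformationField.zero((6, 6, 6)), factor=3)
        assert coarse.spacing == (3.0, 3.0, 3.0)


class TestJacobian:
    def test_zero_field_unit_determinant(self):
        det = jacobian_determinant(DeformationField.zero((5, 5, 5)))
        np.testing.assert_allclose(det, 1.0)

    def test_doubling_map_det8(self):
        det = jacobian_determinant(DeformationField(base_grid((6, 6, 6))))
        np.testing.assert_allclose(det, 8.0)

    def test_point_reflection_det_minus1(self):
        det = jacobian_determinant(DeformationField(-2 * base_grid((6, 6, 6))))
        np.testing.assert_allclose(det, -1.0)

    def test_affine_field_matches_analytic_determinant(self):
        rng = np.random.default_rng(6)
        M = 0.2 * rng.standard_normal((3, 3))
        g = base_grid((7, 7, 7))
        u = np.einsum("ij,jxyz->ixyz", M, g) + rng.standard_normal(3)[:, None, None, None]
        det = jacobian_determinant(DeformationField(u))
        np.testing.assert_allclose(det, np.linalg.det(np.eye(3) + M), atol=1e-9)

    def test_small_grid_rejected(self):
        with pytest.raises(ValueError):
            jacobian_determinant(DeformationField.zero((2, 5, 5)))
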