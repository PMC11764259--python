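"""Differentiable spatial transformer: trilinear warping of volumes and
time series by a dense displacement field, field downsampling for the
functional grid, and Jacobian-determinant analysis.

A deformation maps fixed-grid voxel p to sampling position
phi(p) = p + u(p), with u stored in voxel units of the field's own grid.
Sampling positions falling outside the volume are clamped to the valid
cube (border replication).
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from ._autodiff import Tensor, as_tensor
from .io_formats import Volume3D, LabelMap, TimeSeries4D

__all__ = [
    "DeformationField", "warp_volume", "warp_labels", "warp_series",
    "downsample_field", "jacobian_determinant",
    "sample_trilinear", "warp_tensor", "downsample_field_tensor", "base_grid",
]


@dataclass
class DeformationField:
    """Per-voxel 3-component displacement u (voxel units of its own grid)."""

    u: np.ndarray                       # (3, D, H, W)
    spacing: tuple = (1.0, 1.0, 1.0)

    def __post_init__(self):
        self.u = np.asarray(self.u, dtype=np.float64)
        if self.u.ndim != 4 or self.u.shape[0] != 3:
            raise ValueError("displacement must have shape (3, D, H, W)")
        if not np.all(np.isfinite(self.u)):
            raise ValueError("non-finite displacements")
        self.spacing = tuple(float(s) for s in self.spacing)

    @property
    def shape(self):
        return self.u.shape[1:]

    def phi(self) -> np.ndarray:
        """Absolute sampling positions phi(p) = p + u(p), shape (3, D, H, W)."""
        return base_grid(self.shape) + self.u

    def magnitude(self) -> np.ndarray:
        return np.sqrt((self.u ** 2).sum(axis=0))

    @classmethod
    def zero(cls, shape, spacing=(1.0, 1.0, 1.0)) -> "DeformationField":
        return cls(np.zeros((3,) + tuple(shape)), spacing=spacing)


def base_grid(shape) -> np.ndarray:
    """Identity sampling grid: (3, D, H, W) array of voxel coordinates."""
    axes = [np.arange(n, dtype=np.float64) for n in shape]
    return np.stack(np.meshgrid(*axes, indexing="ij"), axis=0)


# ---------------------------------------------------------------------------
# Core differentiable sampling
# ---------------------------------------------------------------------------

def sample_trilinear(vol: Tensor, coords: Tensor, leading: bool = False) -> Tensor:
    """Trilinearly sample `vol` at absolute voxel `coords` (3, *out_shape).

    Differentiable with respect to both the volume and the coordinates.
    If `leading` is True the volume has one extra leading axis (channels or
    time) sampled with the same grid.
    """
    vol = as_tensor(vol)
    coords = as_tensor(coords)
    dims = vol.shape[-3:]
    c = [coords[i].clip(0.0, dims[i] - 1.0) for i in range(3)]
    lo = [np.minimum(np.floor(ci.data).astype(np.intp), dims[i] - 2) for i, ci in enumerate(c)]
    frac = [ci - lo_i for ci, lo_i in zip(c, lo)]       # in [0, 1]
    out = None
    for corner in range(8):
        bits = ((corner >> 2) & 1, (corner >> 1) & 1, corner & 1)
        idx = tuple(lo[d] + bits[d] for d in range(3))
        w = None
        for d in range(3):
            wd = frac[d] if bits[d] else 1.0 - frac[d]
            w = wd if w is None else w * wd
        if leading:
            gathered = vol[(slice(None),) + idx]
        else:
            gathered = vol[idx]
        term = gathered * w
        out = term if out is None else out + term
    return out


def warp_tensor(vol: Tensor, u: Tensor, leading: bool = False) -> Tensor:
    """Warp a (D,H,W) tensor (or (C,D,H,W) with leading=True) by displacement u."""
    u = as_tensor(u)
    grid = base_grid(u.shape[1:])
    coords = u + grid
    return sample_trilinear(vol, coords, leading=leading)


# ---------------------------------------------------------------------------
# Public volume/series API
# ---------------------------------------------------------------------------

def _check_grids(shape, field: DeformationField):
    if tuple(shape) != tuple(field.shape):
        raise ValueError(f"grid mismatch: image {tuple(shape)} vs field {tuple(field.shape)}")


def warp_volume(vol: Volume3D, field: DeformationField) -> Volume3D:
    """Resample a volume through phi = id + u with trilinear interpolation."""
    _check_grids(vol.shape, field)
    out = warp_tensor(Tensor(vol.data), Tensor(field.u)).data
    return Volume3D(out, spacing=vol.spacing, affine=vol.affine)


def warp_labels(labels: LabelMap, field: DeformationField) -> LabelMap:
    """Warp an integer label map with nearest-neighbour sampling."""
    _check_grids(labels.shape, field)
    phi = field.phi()
    dims = labels.shape
    idx = tuple(
        np.clip(np.rint(phi[d]).astype(np.intp), 0, dims[d] - 1) for d in range(3)
    )
    return LabelMap(labels.data[idx], spacing=labels.spacing, affine=labels.affine)


def warp_series(series: TimeSeries4D, field: DeformationField) -> TimeSeries4D:
    """Warp every time frame of a 4D series by the same field."""
    _check_grids(series.spatial_shape, field)
    vol = Tensor(np.moveaxis(series.data, -1, 0))    # (T, D, H, W)
    out = warp_tensor(vol, Tensor(field.u), leading=True).data
    return TimeSeries4D(np.moveaxis(out, 0, -1), spacing=series.spacing,
                        affine=series.affine, tr=series.tr)


# ---------------------------------------------------------------------------
# Field downsampling (structural grid -> functional grid)
# ---------------------------------------------------------------------------

def _coarse_coords(fine_shape, factor: int):
    coarse_shape = tuple(n // factor for n in fine_shape)
    axes = [factor * np.arange(n, dtype=np.float64) + (factor - 1) / 2.0
            for n in coarse_shape]
    return coarse_shape, np.stack(np.meshgrid(*axes, indexing="ij"), axis=0)


def downsample_field_tensor(u: Tensor, factor: int) -> Tensor:
    """Differentiable core of :func:`downsample_field` on a (3,D,H,W) tensor."""
    fine_shape = u.shape[1:]
    _, coords = _coarse_coords(fine_shape, factor)
    sampled = sample_trilinear(u, Tensor(coords), leading=True)
    return sampled * (1.0 / factor)


def downsample_field(field: DeformationField, factor: int = 3) -> DeformationField:
    """Resample a fine-grid field onto a `factor`-times coarser grid.

    Coarse voxel c samples the fine grid at the block centre
    factor*c + (factor-1)/2; displacements are divided by `factor` to
    convert from fine-voxel to coarse-voxel units (physical millimetres
    are conserved).
    """
    if factor == 1:
        return DeformationField(field.u.copy(), spacing=field.spacing)
    if factor < 2:
        raise ValueError("factor must be >= 2 (or 1 for the identity)")
    if any(n % factor for n in field.shape):
        raise ValueError(f"field shape {field.shape} not divisible by factor {factor}")
    u_coarse = downsample_field_tensor(Tensor(field.u), factor).data
    spacing = tuple(s * factor for s in field.spacing)
    return DeformationField(u_coarse, spacing=spacing)


# ---------------------------------------------------------------------------
# Jacobian analysis
# ---------------------------------------------------------------------------

def jacobian_determinant(field: DeformationField) -> np.ndarray:
    """det(I + grad u) per voxel; central differences in the interior,
    one-sided at the borders."""
    shape = field.shape
    if any(n < 3 for n in shape):
        raise ValueError("grid must be at least 3 voxels per axis")
    u = field.u
    # J[i][j] = d u_i / d x_j
    J = [[np.gradient(u[i], axis=j) for j in range(3)] for i in range(3)]
    for i in range(3):
        J[i][i] = J[i][i] + 1.0
    det = (
        J[0][0] * (J[1][1] * J[2][2] - J[1][2] * J[2][1])
        - J[0][1] * (J[1][0] * J[2][2] - J[1][2] * J[2][0])
        + J[0][2] * (J[1][0] * J[2][1] - J[1][1] * J[2][0])
    )
    return det
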