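"""Local functional connectivity (LFC) pattern features.

Each voxel of an fMRI series carries a time course I(p).  Its LFC pattern
is the set of Pearson correlations C(p, q) between I(p) and the time
courses of all voxels q in a cubic spatial neighbourhood (half-width
`radius`, centre excluded).  Because the raw set depends on an arbitrary
enumeration order of the neighbours, it is summarised as a probability
density: a Gaussian kernel density estimate of the correlation values,
evaluated at n sample points spread uniformly over [-1, 1].  The KDE is
invariant to neighbour ordering, which is the point of the construction.

Border voxels use the clipped (in-bounds) neighbourhood, and the KDE
normaliser is the actual neighbour count.  Zero-variance time courses
(e.g. empty background) are assigned a correlation of 0 so feature maps
stay finite everywhere.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from ._autodiff import Tensor, as_tensor
from .io_formats import TimeSeries4D

__all__ = [
    "LFCFeatureMap", "pearson_fc", "local_fc_values", "kde_density",
    "lfc_feature_map", "sample_points", "neighborhood_offsets",
    "lfc_feature_tensor",
]

_SQRT_2PI = float(np.sqrt(2.0 * np.pi))


@dataclass
class LFCFeatureMap:
    """Per-voxel probability-density feature vectors f(I_p)."""

    features: np.ndarray          # (D, H, W, n) non-negative densities
    sample_points: np.ndarray     # (n,) strictly increasing, spanning [-1, 1]
    bandwidth: float
    radius: int
    mask: np.ndarray              # (D, H, W) bool

    def __post_init__(self):
        self.features = np.asarray(self.features, dtype=np.float64)
        self.sample_points = np.asarray(self.sample_points, dtype=np.float64)
        self.mask = np.asarray(self.mask, dtype=bool)
        if self.features.ndim != 4:
            raise ValueError("features must be (D, H, W, n)")
        if (self.features < 0).any():
            raise ValueError("densities must be non-negative")

    @property
    def n_points(self) -> int:
        return self.sample_points.size


def sample_points(n: int) -> np.ndarray:
    """`n` uniform sample points on [-1, 1], endpoints included."""
    if n < 2:
        raise ValueError("need at least 2 sample points")
    return np.linspace(-1.0, 1.0, n)


def pearson_fc(x, y) -> float:
    """Pearson correlation of two equal-length time courses.

    Returns 0.0 if either series has zero variance.
    """
    x = np.asarray(x, dtype=np.float64)
    y = np.asarray(y, dtype=np.float64)
    if x.shape != y.shape:
        raise ValueError(f"length mismatch: {x.shape} vs {y.shape}")
    if x.size < 2:
        raise ValueError("series must have length >= 2")
    dx = x - x.mean()
    dy = y - y.mean()
    nx = np.linalg.norm(dx)
    ny = np.linalg.norm(dy)
    if nx == 0.0 or ny == 0.0:
        return 0.0
    return float(np.dot(dx, dy) / (nx * ny))


def neighborhood_offsets(radius: int) -> list[tuple[int, int, int]]:
    """All integer offsets of the cubic neighbourhood, centre excluded."""
    if radius < 1:
        raise ValueError("radius must be >= 1")
    r = range(-radius, radius + 1)
    return [(a, b, c) for a in r for b in r for c in r if (a, b, c) != (0, 0, 0)]


def local_fc_values(series: TimeSeries4D, p, radius: int = 1) -> list[float]:
    """C(p, q) for every in-bounds neighbour q != p of voxel p."""
    data = series.data
    dims = data.shape[:3]
    p = tuple(int(v) for v in p)
    if any(not (0 <= p[d] < dims[d]) for d in range(3)):
        raise ValueError(f"voxel {p} outside grid {dims}")
    xs = data[p]
    values = []
    for off in neighborhood_offsets(radius):
        q = tuple(p[d] + off[d] for d in range(3))
        if any(not (0 <= q[d] < dims[d]) for d in range(3)):
            continue
        values.append(pearson_fc(xs, data[q]))
    return values


def kde_density(values, points, h: float) -> np.ndarray:
    """Gaussian KDE of `values`, evaluated at `points`.

    f_n = (1/N) sum_v (2 pi h^2)^(-1/2) exp(-(n - v)^2 / (2 h^2))
    """
    if h <= 0:
        raise ValueError("bandwidth h must be positive")
    values = np.asarray(values, dtype=np.float64)
    if values.size == 0:
        raise ValueError("empty value set")
    points = np.atleast_1d(np.asarray(points, dtype=np.float64))
    diff = points[:, None] - values[None, :]
    k = np.exp(-0.5 * (diff / h) ** 2) / (_SQRT_2PI * h)
    return k.mean(axis=1)


# ---------------------------------------------------------------------------
# Whole-image feature maps (vectorised)
# ---------------------------------------------------------------------------

def _offset_slices(off, dims):
    """Paired slices (into p-grid and q-grid) where p + off stays in bounds."""
    src, dst = [], []
    for d in range(3):
        o = off[d]
        src.append(slice(max(0, -o), dims[d] - max(0, o)))
        dst.append(slice(max(0, o), dims[d] + min(0, o)))
    return tuple(src), tuple(dst)


def lfc_feature_map(series: TimeSeries4D, radius: int = 1, n_points: int = 64,
                    h: float = 0.1, mask=None) -> LFCFeatureMap:
    """KDE feature vectors for every masked voxel of a 4D series."""
    if n_points < 2:
        raise ValueError("n_points must be >= 2")
    if h <= 0:
        raise ValueError("bandwidth h must be positive")
    data = series.data
    dims = data.shape[:3]
    if mask is None:
        mask = np.ones(dims, dtype=bool)
    mask = np.asarray(mask, dtype=bool)
    if mask.shape != dims:
        raise ValueError(f"mask shape {mask.shape} does not match grid {dims}")
    pts = sample_points(n_points)

    centered = data - data.mean(axis=3, keepdims=True)
    norms = np.sqrt((centered ** 2).sum(axis=3))
    nonzero = norms > 0

    acc = np.zeros(dims + (n_points,))
    counts = np.zeros(dims)
    for off in neighborhood_offsets(radius):
        src, dst = _offset_slices(off, dims)
        a = centered[src]
        b = centered[dst]
        dot = (a * b).sum(axis=3)
        denom = norms[src] * norms[dst]
        corr = np.zeros_like(dot)
        ok = (norms[src] > 0) & (norms[dst] > 0)
        corr[ok] = dot[ok] / denom[ok]
        diff = pts.reshape((1, 1, 1, -1)) - corr[..., None]
        kern = np.exp(-0.5 * (diff / h) ** 2) / (_SQRT_2PI * h)
        acc[src] += kern
        counts[src] += 1.0
    feats = np.zeros_like(acc)
    valid = mask & (counts > 0)
    feats[valid] = acc[valid] / counts[valid][..., None]
    return LFCFeatureMap(features=feats, sample_points=pts, bandwidth=h,
                         radius=radius, mask=mask)


# ---------------------------------------------------------------------------
# Differentiable feature maps (training path)
# ---------------------------------------------------------------------------

def lfc_feature_tensor(series: Tensor, radius: int, points: np.ndarray,
                       h: float, mask: np.ndarray | None = None) -> Tensor:
    """Differentiable analogue of :func:`lfc_feature_map`.

    `series` is a (D, H, W, T) tensor; returns a (D, H, W, n) tensor of
    densities.  Gradients flow through the correlations and the Gaussian
    kernel; the zero-variance cutoff acts as a constant gate.
    """
    series = as_tensor(series)
    dims = series.shape[:3]
    if mask is None:
        mask = np.ones(dims, dtype=bool)
    pts = np.asarray(points, dtype=np.float64)
    n_points = pts.size

    centered = series - series.mean(axis=3, keepdims=True)
    sq = (centered * centered).sum(axis=3)
    norms = (sq + 1e-30).sqrt()
    nz = sq.data > 1e-24

    acc = None
    counts = np.zeros(dims)
    inv_h2 = 1.0 / (2.0 * h * h)
    scale = 1.0 / (_SQRT_2PI * h)
    for off in neighborhood_offsets(radius):
        src, dst = _offset_slices(off, dims)
        a = centered[src]
        b = centered[dst]
        dot = (a * b).sum(axis=3)
        corr = dot / (norms[src] * norms[dst])
        gate = (nz[src] & nz[dst]).astype(np.float64)
        corr = corr * gate
        # (valid-region, n) kernel values
        diff = corr.reshape(corr.shape + (1,)) - pts.reshape((1, 1, 1, n_points))
        kern = (diff * diff * (-inv_h2)).exp() * scale
        pad = tuple((s.start, dims[d] - s.stop) for d, s in enumerate(src)) + ((0, 0),)
        kern_full = kern.pad(pad)
        acc = kern_full if acc is None else acc + kern_full
        counts[src] += 1.0
    inv_counts = np.zeros(dims)
    valid = mask & (counts > 0)
    inv_counts[valid] = 1.0 / counts[valid]
    return acc * inv_counts[..., None]
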