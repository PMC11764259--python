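"""Loss terms of the bidirectional registration objective.

Total objective (defaults alpha=0.2, beta=0.1, gamma=0.5, lambda=0.02):

    L = L_register_mri + alpha * L_register_fmri + beta * L_cycle + gamma * L_identity

* L_register_mri: MSE similarity + lambda * field smoothness, both directions.
* L_register_fmri: 4D MSE + local-functional-connectivity feature distance on
  the downsampled fields, both directions.
* L_cycle: L1 between each image and its twice-deformed version.
* L_identity: MSE between an image and itself warped by the field the
  network emits when moving == fixed.

Every sum over the spatial domain is a mean (voxel-count normalised) so
the weights are resolution independent.  All terms are non-negative and
vanish on their exact-match configuration.
"""

from __future__ import annotations

from dataclasses import dataclass, field as dc_field

import numpy as np

from ._autodiff import Tensor, as_tensor
from .io_formats import TimeSeries4D, Volume3D
from .lfc_features import lfc_feature_tensor, sample_points
from .spatial_transform import DeformationField, warp_tensor

__all__ = [
    "LossReport", "similarity_mse", "smoothness", "lfc_loss",
    "structural_loss", "functional_loss", "cycle_loss", "identity_loss",
    "total_loss",
    "similarity_mse_t", "smoothness_t", "lfc_distance_t", "l1_mean_t",
]


@dataclass
class LossReport:
    """Per-iteration loss breakdown; total respects the stated weights."""

    l_register_mri: float
    l_register_fmri: float
    l_cycle: float
    l_identity: float
    total: float
    alpha: float
    beta: float
    gamma: float
    breakdown: dict = dc_field(default_factory=dict)

    def as_dict(self) -> dict:
        d = {
            "l_register_mri": self.l_register_mri,
            "l_register_fmri": self.l_register_fmri,
            "l_cycle": self.l_cycle,
            "l_identity": self.l_identity,
            "total": self.total,
        }
        d.update(self.breakdown)
        return d


def _data(x) -> np.ndarray:
    if isinstance(x, (Volume3D, TimeSeries4D)):
        return x.data
    if isinstance(x, DeformationField):
        return x.u
    if isinstance(x, Tensor):
        return x.data
    return np.asarray(x, dtype=np.float64)


# ---------------------------------------------------------------------------
# Differentiable cores (Tensor in, scalar Tensor out)
# ---------------------------------------------------------------------------

def similarity_mse_t(a: Tensor, b: Tensor) -> Tensor:
    a, b = as_tensor(a), as_tensor(b)
    if a.shape != b.shape:
        raise ValueError(f"shape mismatch: {a.shape} vs {b.shape}")
    d = a - b
    return (d * d).mean()


def l1_mean_t(a: Tensor, b: Tensor) -> Tensor:
    a, b = as_tensor(a), as_tensor(b)
    if a.shape != b.shape:
        raise ValueError(f"shape mismatch: {a.shape} vs {b.shape}")
    return (a - b).abs().mean()


def smoothness_t(u: Tensor) -> Tensor:
    """Mean squared forward-difference gradient of all field components."""
    u = as_tensor(u)
    total = None
    for axis in (1, 2, 3):
        sl_hi = [slice(None)] * 4
        sl_lo = [slice(None)] * 4
        sl_hi[axis] = slice(1, None)
        sl_lo[axis] = slice(None, -1)
        d = u[tuple(sl_hi)] - u[tuple(sl_lo)]
        term = (d * d).sum(axis=0).mean()
        total = term if total is None else total + term
    return total


def lfc_distance_t(series_a: Tensor, series_b: Tensor, radius: int,
                   points: np.ndarray, h: float,
                   mask: np.ndarray | None = None) -> Tensor:
    """Mean Euclidean distance of LFC feature vectors over masked voxels."""
    series_a, series_b = as_tensor(series_a), as_tensor(series_b)
    if series_a.shape != series_b.shape:
        raise ValueError("series grids differ")
    if mask is None:
        # default: voxels with temporal variance in the second (fixed) series
        mask = series_b.data.std(axis=3) > 0
    fa = lfc_feature_tensor(series_a, radius, points, h, mask=mask)
    fb = lfc_feature_tensor(series_b, radius, points, h, mask=mask)
    d = fa - fb
    # smoothed Euclidean norm, shifted so exact equality scores exactly 0
    # while the gradient at 0 stays finite
    eps = 1e-12
    dist = ((d * d).sum(axis=-1) + eps).sqrt() - np.sqrt(eps)
    n = max(int(mask.sum()), 1)
    return (dist * mask.astype(np.float64)).sum() * (1.0 / n)


# ---------------------------------------------------------------------------
# Public operations (numpy in, float out)
# ---------------------------------------------------------------------------

def similarity_mse(a, b) -> float:
    """Mean squared intensity difference over the full domain (3D or 4D)."""
    return similarity_mse_t(Tensor(_data(a)), Tensor(_data(b))).item()


def smoothness(field) -> float:
    """Field-gradient penalty: mean summed squared forward differences."""
    return smoothness_t(Tensor(_data(field))).item()


def lfc_loss(warped_func, fixed_func, radius: int = 1, n_points: int = 64,
             h: float = 0.1, mask=None) -> float:
    """Local functional connectivity distance between two series."""
    pts = sample_points(n_points)
    return lfc_distance_t(Tensor(_data(warped_func)), Tensor(_data(fixed_func)),
                          radius, pts, h, mask=mask).item()


def structural_loss(a, b, phi_ab, phi_ba, smooth_weight: float = 0.02) -> float:
    """Bidirectional structural term: MSE(B, A.phi_AB) + lambda*smooth(phi_AB)
    plus the mirrored direction."""
    a_t, b_t = Tensor(_data(a)), Tensor(_data(b))
    u_ab, u_ba = Tensor(_data(phi_ab)), Tensor(_data(phi_ba))
    fwd = similarity_mse_t(b_t, warp_tensor(a_t, u_ab)) + smooth_weight * smoothness_t(u_ab)
    rev = similarity_mse_t(a_t, warp_tensor(b_t, u_ba)) + smooth_weight * smoothness_t(u_ba)
    return (fwd + rev).item()


def functional_loss(x, y, phi_ab_13, phi_ba_13, radius: int = 1,
                    n_points: int = 64, h: float = 0.1,
                    use_lfc: bool = True) -> float:
    """Bidirectional functional term on the coarse (functional) grid."""
    x_t = Tensor(np.moveaxis(_data(x), -1, 0))     # (T, D, H, W)
    y_t = Tensor(np.moveaxis(_data(y), -1, 0))
    pts = sample_points(n_points)
    total = 0.0
    for mov, fix, u in ((x_t, y_t, phi_ab_13), (y_t, x_t, phi_ba_13)):
        warped = warp_tensor(mov, Tensor(_data(u)), leading=True)
        total += similarity_mse_t(fix, warped).item()
        if use_lfc:
            w4 = Tensor(np.moveaxis(warped.data, 0, -1))
            f4 = Tensor(np.moveaxis(fix.data, 0, -1))
            total += lfc_distance_t(w4, f4, radius, pts, h).item()
    return total


def cycle_loss(a, b, phi_ab, phi_ba, phi_ab2, phi_ba2) -> float:
    """L1 between each image and its twice-deformed version.

    B' = T(A, phi_AB), A' = T(B, phi_BA); the second-pass fields
    phi_BA2 = G_B(B', A) and phi_AB2 = G_A(A', B) bring them back:
    A'' = T(B', phi_BA2), B'' = T(A', phi_AB2).
    """
    a_t, b_t = Tensor(_data(a)), Tensor(_data(b))
    bp = warp_tensor(a_t, Tensor(_data(phi_ab)))
    ap = warp_tensor(b_t, Tensor(_data(phi_ba)))
    a2 = warp_tensor(bp, Tensor(_data(phi_ba2)))
    b2 = warp_tensor(ap, Tensor(_data(phi_ab2)))
    return (l1_mean_t(a2, a_t) + l1_mean_t(b2, b_t)).item()


def identity_loss(a, b, g_a, g_b, pairing: str = "crossed") -> float:
    """Self-registration penalty.

    With the "crossed" pairing the forward network sees (B, B) and the
    reverse network (A, A); "matched" swaps the roles.
    """
    a_t, b_t = Tensor(_data(a)), Tensor(_data(b))
    if pairing == "crossed":
        u1 = g_a.forward_tensor(b_t, b_t)
        u2 = g_b.forward_tensor(a_t, a_t)
    elif pairing == "matched":
        u1 = g_a.forward_tensor(a_t, a_t)
        u2 = g_b.forward_tensor(b_t, b_t)
    else:
        raise ValueError("pairing must be 'crossed' or 'matched'")
    return (similarity_mse_t(b_t, warp_tensor(b_t, u1))
            + similarity_mse_t(a_t, warp_tensor(a_t, u2))).item()


def total_loss(l_register_mri, l_register_fmri, l_cycle, l_identity,
               alpha: float = 0.2, beta: float = 0.1, gamma: float = 0.5,
               breakdown: dict | None = None) -> LossReport:
    """Weighted combination of the four loss groups."""
    for name, w in (("alpha", alpha), ("beta", beta), ("gamma", gamma)):
        if w < 0:
            raise ValueError(f"{name} must be non-negative")
    total = (float(l_register_mri) + alpha * float(l_register_fmri)
             + beta * float(l_cycle) + gamma * float(l_identity))
    return LossReport(
        l_register_mri=float(l_register_mri),
        l_register_fmri=float(l_register_fmri),
        l_cycle=float(l_cycle),
        l_identity=float(l_identity),
        total=total, alpha=alpha, beta=beta, gamma=gamma,
        breakdown=breakdown or {},
    )
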