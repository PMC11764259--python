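"""Synthetic structural/functional image pairs with known ground truth.

The generator emulates the study conditions the registration framework is
designed for: affinely pre-aligned structural volumes with anatomical
label maps, functional time series on a 3x coarser grid, and a smooth
ground-truth deformation linking the two members of each pair.

* Structural anatomy is a set of nested smooth ellipsoidal shells, one
  structure ID per shell, each with its own intensity level, plus white
  noise (intensities in [0, 1]).
* The ground-truth field is Gaussian-smoothed white noise, rescaled to a
  chosen peak displacement; amplitudes at or below half the smoothing
  length produce fold-free (positive-Jacobian) fields.
* Functional series are region-structured: each structure has one latent
  time course, every voxel of the structure observes it plus white noise
  (snr = latent sd / noise sd); background voxels are pure noise.
* The moving member is the fixed member warped by the ground-truth field
  (trilinear for intensities and time series, nearest-neighbour for
  labels), so ``moving == warp(fixed, truth_field)`` up to interpolation
  error and the true forward field for (A=fixed, B=moving) is known.
"""

from __future__ import annotations

import json
import os
from dataclasses import dataclass

import numpy as np
from scipy.ndimage import gaussian_filter

from .io_formats import (LabelMap, TimeSeries4D, Volume3D, write_labels,
                         write_series, write_volume)
from .spatial_transform import (DeformationField, downsample_field,
                                jacobian_determinant, warp_labels,
                                warp_series, warp_volume)

__all__ = [
    "SyntheticPair", "sample_smooth_field", "make_structural_pair",
    "make_functional_series", "make_pair", "make_dataset",
]

# Desk-scale study conditions (defaults used throughout tests and the
# acceptance runs): 24^3 structural grid, 4 nested structures, peak
# displacement 2 voxels with smoothing length 4 voxels (fold-free), 8^3
# functional grid at the 3:1 ratio, 40 time points at snr 2.
DEFAULT_SHAPE = (24, 24, 24)
DEFAULT_N_STRUCTURES = 4
DEFAULT_AMPLITUDE = 2.0
DEFAULT_SMOOTHNESS = 4.0
DEFAULT_NOISE_SD = 0.02
DEFAULT_T = 40
DEFAULT_SNR = 2.0


@dataclass
class SyntheticPair:
    """A fixed/moving pair with known ground-truth deformation."""

    fixed: Volume3D
    moving: Volume3D
    fixed_labels: LabelMap
    moving_labels: LabelMap
    truth_field: DeformationField
    fixed_func: TimeSeries4D | None = None
    moving_func: TimeSeries4D | None = None


def sample_smooth_field(shape, amplitude: float = DEFAULT_AMPLITUDE,
                        smoothness: float = DEFAULT_SMOOTHNESS,
                        seed: int = 0) -> DeformationField:
    """Smooth random displacement field with peak magnitude `amplitude`.

    Each component is Gaussian-smoothed white noise (sd `smoothness`
    voxels); the vector field is rescaled so max_p |u(p)| == amplitude.
    """
    if amplitude < 0:
        raise ValueError("amplitude must be non-negative")
    if smoothness <= 0:
        raise ValueError("smoothness must be positive")
    shape = tuple(int(n) for n in shape)
    rng = np.random.default_rng(seed)
    u = rng.standard_normal((3,) + shape)
    for c in range(3):
        u[c] = gaussian_filter(u[c], sigma=smoothness, mode="reflect")
    mag = np.sqrt((u ** 2).sum(axis=0)).max()
    if amplitude == 0 or mag == 0:
        u = np.zeros_like(u)
    else:
        u *= amplitude / mag
    return DeformationField(u)


def _shell_labels(shape, n_structures: int, rng) -> np.ndarray:
    """Nested ellipsoidal shells: IDs 1..n from the centre outwards."""
    shape = tuple(shape)
    semi = np.array([0.45 * n for n in shape]) * rng.uniform(0.9, 1.0, size=3)
    if semi.min() / n_structures < 2.0:
        raise ValueError(
            f"shape {shape} too small to host {n_structures} shells of >= 2 voxels")
    centre = (np.array(shape) - 1) / 2.0 + rng.uniform(-0.5, 0.5, size=3)
    grids = np.meshgrid(*[np.arange(n, dtype=np.float64) for n in shape], indexing="ij")
    rho = np.sqrt(sum(((g - c) / a) ** 2 for g, c, a in zip(grids, centre, semi)))
    labels = np.zeros(shape, dtype=np.int32)
    edges = np.linspace(0.0, 1.0, n_structures + 1)
    for s in range(1, n_structures + 1):
        labels[(rho >= edges[s - 1]) & (rho < edges[s])] = s
    return labels


def make_structural_pair(shape=DEFAULT_SHAPE, n_structures: int = DEFAULT_N_STRUCTURES,
                         amplitude: float = DEFAULT_AMPLITUDE, seed: int = 0,
                         smoothness: float = DEFAULT_SMOOTHNESS,
                         noise_sd: float = DEFAULT_NOISE_SD) -> SyntheticPair:
    """Structural part of a pair: shells + labels + known deformation."""
    if n_structures < 2:
        raise ValueError("need at least 2 structures")
    rng = np.random.default_rng(seed)
    labels = _shell_labels(shape, n_structures, rng)
    levels = rng.permutation(np.linspace(0.3, 0.9, n_structures))
    intensity = np.zeros(labels.shape)
    for s in range(1, n_structures + 1):
        intensity[labels == s] = levels[s - 1]
    intensity = gaussian_filter(intensity, sigma=0.7, mode="nearest")
    # smooth intratissue texture: real structural MRI is not piecewise
    # constant, and texture makes the deformation observable everywhere
    # inside the head, not only at tissue boundaries
    texture = gaussian_filter(rng.standard_normal(labels.shape), sigma=2.0,
                              mode="reflect")
    texture *= 0.12 / max(texture.std(), 1e-12)
    intensity += texture * (labels > 0)
    intensity += noise_sd * rng.standard_normal(labels.shape)
    intensity = np.clip(intensity, 0.0, 1.0)

    fixed = Volume3D(intensity)
    fixed_labels = LabelMap(labels)
    truth = sample_smooth_field(shape, amplitude=amplitude,
                                smoothness=smoothness,
                                seed=int(rng.integers(0, 2 ** 31 - 1)))
    moving = warp_volume(fixed, truth)
    moving_labels = warp_labels(fixed_labels, truth)
    return SyntheticPair(fixed=fixed, moving=moving, fixed_labels=fixed_labels,
                         moving_labels=moving_labels, truth_field=truth)


def make_functional_series(labels: LabelMap, T: int = DEFAULT_T,
                           snr: float = DEFAULT_SNR, seed: int = 0) -> TimeSeries4D:
    """Region-structured voxel time series over a label map.

    Every structure gets an independent latent time course (unit sd);
    each of its voxels observes latent + white noise with
    sd = 1 / snr.  Background voxels are pure unit-sd noise.
    """
    if T < 8:
        raise ValueError("need at least 8 time points")
    rng = np.random.default_rng(seed)
    lab = labels.data
    data = np.zeros(lab.shape + (T,))
    noise_sd = 0.0 if np.isinf(snr) else 1.0 / snr
    for s in labels.structure_ids():
        latent = rng.standard_normal(T)
        m = lab == s
        data[m] = latent
    data += noise_sd * rng.standard_normal(data.shape)
    bg = lab == 0
    data[bg] = rng.standard_normal((int(bg.sum()), T))
    return TimeSeries4D(data, spacing=tuple(s for s in labels.spacing))


def make_pair(shape=DEFAULT_SHAPE, n_structures: int = DEFAULT_N_STRUCTURES,
              amplitude: float = DEFAULT_AMPLITUDE, seed: int = 0,
              smoothness: float = DEFAULT_SMOOTHNESS,
              with_functional: bool = True, T: int = DEFAULT_T,
              snr: float = DEFAULT_SNR, functional_factor: int = 3) -> SyntheticPair:
    """Full pair: structural images plus functional series.

    The functional grid is the structural grid downsampled by
    `functional_factor` (3 by default, matching a 3 mm functional /
    1 mm structural acquisition; 1 gives "toy" equal-resolution grids).
    """
    pair = make_structural_pair(shape, n_structures, amplitude, seed,
                                smoothness=smoothness)
    if not with_functional:
        return pair
    f = functional_factor
    if any(n % f for n in pair.fixed.shape):
        raise ValueError(f"shape {shape} not divisible by functional factor {f}")
    if f == 1:
        coarse_labels = pair.fixed_labels
        coarse_field = pair.truth_field
    else:
        centre = (f - 1) // 2
        coarse = pair.fixed_labels.data[centre::f, centre::f, centre::f]
        coarse_labels = LabelMap(coarse, spacing=tuple(s * f for s in pair.fixed_labels.spacing))
        coarse_field = downsample_field(pair.truth_field, factor=f)
    rng = np.random.default_rng(seed + 1)
    fixed_func = make_functional_series(coarse_labels, T=T, snr=snr,
                                        seed=int(rng.integers(0, 2 ** 31 - 1)))
    moving_func = warp_series(fixed_func, coarse_field)
    pair.fixed_func = fixed_func
    pair.moving_func = moving_func
    return pair


def make_dataset(n_pairs: int, out_dir, shape=DEFAULT_SHAPE,
                 n_structures: int = DEFAULT_N_STRUCTURES,
                 amplitude: float = DEFAULT_AMPLITUDE, seed: int = 0,
                 with_functional: bool = True, T: int = DEFAULT_T,
                 snr: float = DEFAULT_SNR, functional_factor: int = 3,
                 augment: bool = False) -> dict:
    """Write `n_pairs` NIfTI pairs plus a JSON manifest to `out_dir`.

    With `augment`, every pair is additionally listed with the moving and
    fixed roles swapped (the training-time pair-flipping augmentation).
    Returns the manifest dict (also written to out_dir/manifest.json).
    """
    os.makedirs(out_dir, exist_ok=True)
    entries = []
    for i in range(n_pairs):
        pair = make_pair(shape=shape, n_structures=n_structures,
                         amplitude=amplitude, seed=seed + 1000 * i,
                         with_functional=with_functional, T=T, snr=snr,
                         functional_factor=functional_factor)
        names = {}
        for key, obj, writer in [
            ("fixed", pair.fixed, write_volume),
            ("moving", pair.moving, write_volume),
            ("fixed_labels", pair.fixed_labels, write_labels),
            ("moving_labels", pair.moving_labels, write_labels),
        ]:
            path = os.path.join(out_dir, f"pair{i:03d}_{key}.nii.gz")
            writer(obj, path)
            names[key] = path
        tf_path = os.path.join(out_dir, f"pair{i:03d}_truth_field.nii.gz")
        write_series(TimeSeries4D(np.moveaxis(pair.truth_field.u, 0, -1)), tf_path)
        names["truth_field"] = tf_path
        if pair.fixed_func is not None:
            for key, obj in [("fixed_func", pair.fixed_func),
                             ("moving_func", pair.moving_func)]:
                path = os.path.join(out_dir, f"pair{i:03d}_{key}.nii.gz")
                write_series(obj, path)
                names[key] = path
        entries.append(names)
        if augment:
            swapped = dict(names)
            swapped["fixed"], swapped["moving"] = names["moving"], names["fixed"]
            swapped["fixed_labels"], swapped["moving_labels"] = (
                names["moving_labels"], names["fixed_labels"])
            if "fixed_func" in names:
                swapped["fixed_func"], swapped["moving_func"] = (
                    names["moving_func"], names["fixed_func"])
            swapped["augmented"] = True
            entries.append(swapped)
    manifest = {"n_pairs": n_pairs, "augment": augment, "seed": seed,
                "functional_factor": functional_factor, "entries": entries}
    with open(os.path.join(out_dir, "manifest.json"), "w") as fh:
        json.dump(manifest, fh, indent=2)
    return manifest
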