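"""NIfTI I/O, container types and the run configuration.

Conventions shared by every other module:

* voxel indices are 0-based; axis order is (x, y, z) matching the first
  three array axes; world coordinates only through the 4x4 affine.
* intensities are read untouched (no rescaling); the synthetic generator
  produces values in [0, 1].
* displacement fields are stored in voxel units of their own grid.
"""

from __future__ import annotations

import dataclasses
import os
from dataclasses import dataclass, field

import nibabel as nib
import numpy as np
import yaml

__all__ = [
    "Volume3D", "LabelMap", "TimeSeries4D", "RegistrationConfig",
    "read_volume", "read_labels", "read_series",
    "write_volume", "write_labels", "write_series",
    "load_config", "save_config",
]

CONFIG_VERSION = 1


def _default_affine(spacing) -> np.ndarray:
    aff = np.eye(4)
    aff[0, 0], aff[1, 1], aff[2, 2] = spacing
    return aff


@dataclass
class Volume3D:
    """A scalar 3D intensity grid (structural-MRI role)."""

    data: np.ndarray
    spacing: tuple = (1.0, 1.0, 1.0)
    affine: np.ndarray | None = None

    def __post_init__(self):
        self.data = np.asarray(self.data, dtype=np.float64)
        if self.data.ndim != 3:
            raise ValueError(f"Volume3D needs 3 dims, got {self.data.ndim}")
        if any(s < 2 for s in self.data.shape):
            raise ValueError("each spatial extent must be >= 2")
        if not np.all(np.isfinite(self.data)):
            raise ValueError("non-finite voxel values")
        self.spacing = tuple(float(s) for s in self.spacing)
        if any(s <= 0 for s in self.spacing):
            raise ValueError("spacing must be strictly positive")
        if self.affine is None:
            self.affine = _default_affine(self.spacing)
        self.affine = np.asarray(self.affine, dtype=np.float64)

    @property
    def shape(self):
        return self.data.shape


@dataclass
class LabelMap:
    """Integer anatomical structure IDs on a 3D grid; 0 is background."""

    data: np.ndarray
    spacing: tuple = (1.0, 1.0, 1.0)
    affine: np.ndarray | None = None

    def __post_init__(self):
        arr = np.asarray(self.data)
        if arr.ndim != 3:
            raise ValueError("LabelMap needs 3 dims")
        if not np.issubdtype(arr.dtype, np.integer):
            rounded = np.rint(arr)
            if not np.allclose(arr, rounded):
                raise ValueError("label map is not integer-valued")
            arr = rounded.astype(np.int32)
        if arr.min() < 0:
            raise ValueError("labels must be non-negative")
        self.data = arr.astype(np.int32)
        self.spacing = tuple(float(s) for s in self.spacing)
        if self.affine is None:
            self.affine = _default_affine(self.spacing)
        self.affine = np.asarray(self.affine, dtype=np.float64)

    @property
    def shape(self):
        return self.data.shape

    def structure_ids(self) -> np.ndarray:
        ids = np.unique(self.data)
        return ids[ids != 0]


@dataclass
class TimeSeries4D:
    """A 3D grid of voxel time series (fMRI role)."""

    data: np.ndarray
    spacing: tuple = (1.0, 1.0, 1.0)
    affine: np.ndarray | None = None
    tr: float | None = None

    def __post_init__(self):
        self.data = np.asarray(self.data, dtype=np.float64)
        if self.data.ndim != 4:
            raise ValueError("TimeSeries4D needs 4 dims (x, y, z, t)")
        if self.data.shape[3] < 2:
            raise ValueError("a time series needs at least 2 time points")
        if not np.all(np.isfinite(self.data)):
            raise ValueError("non-finite values in time series")
        self.spacing = tuple(float(s) for s in self.spacing)
        if self.affine is None:
            self.affine = _default_affine(self.spacing)
        self.affine = np.asarray(self.affine, dtype=np.float64)

    @property
    def shape(self):
        return self.data.shape

    @property
    def spatial_shape(self):
        return self.data.shape[:3]

    @property
    def n_timepoints(self) -> int:
        return self.data.shape[3]

    def frame(self, t: int) -> Volume3D:
        return Volume3D(self.data[..., t], spacing=self.spacing, affine=self.affine)


@dataclass
class RegistrationConfig:
    """Hyperparameters of the bidirectional registration model.

    Loss weights follow the published defaults: alpha (functional term),
    beta (cycle term), gamma (identity term), smooth_weight = lambda
    (field-gradient regulariser inside each registration loss).
    """

    alpha: float = 0.2
    beta: float = 0.1
    gamma: float = 0.5
    smooth_weight: float = 0.02        # the lambda of the smoothness penalty
    learning_rate: float = 1e-4
    max_iterations: int = 500
    batch_size: int = 1
    window_size: tuple = (6, 6, 6)
    block_depths: tuple = (2, 2, 4, 2)
    heads: tuple = (2, 4, 8, 8)
    embed_dim: int = 24
    patch_size: int = 2
    mlp_ratio: float = 4.0
    lfc_radius: int = 1
    kde_points: int = 64
    kde_bandwidth: float = 0.1
    identity_pairing: str = "crossed"  # "crossed": G_A(B,B)/G_B(A,A); "matched": G_A(A,A)/G_B(B,B)
    use_lfc_loss: bool = True
    standardize: bool = True           # z-score intensities before network/losses
    max_grad_norm: float = 1.0         # global gradient-norm clip (0 disables)
    lr_schedule: str = "warmup_cosine"  # or "constant"
    displacement_cap_fraction: float = 0.25   # tanh-bound on |u| per axis,
                                              # as a fraction of the smallest
                                              # grid extent (0 disables)
    seed: int = 0

    # yaml keys accepted as aliases for the conventional symbol names
    _ALIASES = {"lambda": "smooth_weight", "lambda_": "smooth_weight", "lr": "learning_rate"}

    def __post_init__(self):
        for name in ("alpha", "beta", "gamma", "smooth_weight"):
            if getattr(self, name) < 0:
                raise ValueError(f"loss weight {name!r} must be non-negative")
        if self.learning_rate <= 0:
            raise ValueError("learning_rate must be positive")
        if self.max_iterations < 0:
            raise ValueError("max_iterations must be non-negative")
        if self.kde_points < 2:
            raise ValueError("kde_points must be >= 2")
        if self.kde_bandwidth <= 0:
            raise ValueError("kde_bandwidth must be positive")
        if self.lfc_radius < 1:
            raise ValueError("lfc_radius must be >= 1")
        self.window_size = tuple(int(m) for m in self.window_size)
        if len(self.window_size) != 3 or any(m < 1 for m in self.window_size):
            raise ValueError("window_size must be 3 positive ints")
        self.block_depths = tuple(int(d) for d in self.block_depths)
        if len(self.block_depths) != 4:
            raise ValueError("block_depths must have 4 entries")
        if any(d % 2 for d in self.block_depths):
            raise ValueError("block depths must be even (attention blocks come in "
                             "window/shifted-window pairs)")
        self.heads = tuple(int(h) for h in self.heads)
        if self.identity_pairing not in ("crossed", "matched"):
            raise ValueError("identity_pairing must be 'crossed' or 'matched'")
        if self.lr_schedule not in ("warmup_cosine", "constant"):
            raise ValueError("lr_schedule must be 'warmup_cosine' or 'constant'")

    def tiny(self) -> "RegistrationConfig":
        """Preset with a 6-dim embedding for desk-scale experiments."""
        return dataclasses.replace(self, embed_dim=6, heads=(2, 2, 2, 2))

    def to_dict(self) -> dict:
        d = dataclasses.asdict(self)
        d["window_size"] = list(self.window_size)
        d["block_depths"] = list(self.block_depths)
        d["heads"] = list(self.heads)
        d["config_version"] = CONFIG_VERSION
        return d


# ---------------------------------------------------------------------------
# NIfTI round-trips
# ---------------------------------------------------------------------------

def _load_nifti(path):
    if not os.path.exists(path):
        raise FileNotFoundError(path)
    img = nib.load(str(path))
    data = np.asanyarray(img.dataobj)
    spacing = tuple(float(z) for z in img.header.get_zooms()[:3])
    return data, spacing, np.asarray(img.affine, dtype=np.float64), img


def read_volume(path) -> Volume3D:
    """Read a 3D NIfTI volume; intensities are not rescaled."""
    data, spacing, affine, _ = _load_nifti(path)
    if data.ndim == 4:
        raise ValueError(f"{path} is 4D; use read_series for time series data")
    if data.ndim != 3:
        raise ValueError(f"{path} has {data.ndim} dims, expected 3")
    return Volume3D(np.asarray(data, dtype=np.float64), spacing=spacing, affine=affine)


def read_labels(path) -> LabelMap:
    data, spacing, affine, _ = _load_nifti(path)
    if data.ndim != 3:
        raise ValueError(f"{path} has {data.ndim} dims, expected 3")
    return LabelMap(data, spacing=spacing, affine=affine)


def read_series(path) -> TimeSeries4D:
    """Read a 4D NIfTI time series (x, y, z, t)."""
    data, spacing, affine, img = _load_nifti(path)
    if data.ndim == 3:
        raise ValueError(f"{path} is 3D; use read_volume for single volumes")
    if data.ndim != 4:
        raise ValueError(f"{path} has {data.ndim} dims, expected 4")
    zooms = img.header.get_zooms()
    tr = float(zooms[3]) if len(zooms) > 3 and zooms[3] > 0 else None
    return TimeSeries4D(np.asarray(data, dtype=np.float64), spacing=spacing,
                        affine=affine, tr=tr)


def _save(data, affine, spacing, path, tr=None):
    img = nib.Nifti1Image(np.asarray(data), affine)
    zooms = tuple(spacing)[:3]
    if data.ndim == 4:
        zooms = zooms + (float(tr) if tr else 1.0,)
    img.header.set_zooms(zooms)
    nib.save(img, str(path))


def write_volume(vol: Volume3D, path) -> None:
    _save(vol.data, vol.affine, vol.spacing, path)


def write_labels(labels: LabelMap, path) -> None:
    _save(labels.data.astype(np.int16), labels.affine, labels.spacing, path)


def write_series(series: TimeSeries4D, path) -> None:
    _save(series.data, series.affine, series.spacing, path, tr=series.tr)


# ---------------------------------------------------------------------------
# Configuration files (YAML key: value)
# ---------------------------------------------------------------------------

def load_config(path=None) -> RegistrationConfig:
    """Load a YAML config; missing keys fall back to the published defaults."""
    raw = {}
    if path is not None:
        with open(path) as fh:
            loaded = yaml.safe_load(fh)
        if loaded is None:
            loaded = {}
        if not isinstance(loaded, dict):
            raise ValueError(f"config {path} must be a mapping of key: value pairs")
        raw = dict(loaded)
    raw.pop("config_version", None)
    for alias, target in RegistrationConfig._ALIASES.items():
        if alias in raw:
            raw[target] = raw.pop(alias)
    known = {f.name for f in dataclasses.fields(RegistrationConfig)}
    unknown = set(raw) - known
    if unknown:
        raise ValueError(f"unknown config keys: {sorted(unknown)}")
    return RegistrationConfig(**raw)


def save_config(cfg: RegistrationConfig, path) -> None:
    with open(path, "w") as fh:
        yaml.safe_dump(cfg.to_dict(), fh, sort_keys=True)
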