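"""Structural- and functional-consistency evaluation metrics.

Structural quality is measured by per-structure Dice overlap of warped
anatomical label maps and by the percentage of voxels whose deformation
Jacobian determinant det(I + grad u) is non-positive (folding).
Functional consistency across a registered group is measured on
group-level one-sample t-maps of brain functional networks: the peak t
value and the number of voxels exceeding a fixed threshold (t > 5.01,
strict).

`REFERENCE_PEAK_T` and `REFERENCE_SUPRATHRESHOLD` hold published
benchmark values of these statistics for six registration approaches on
four canonical resting-state networks (default mode, visual, central
executive, sensorimotor); `mean_relative_improvement` and `mean_count`
compute the summary statistics usually quoted from such tables.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .io_formats import LabelMap
from .spatial_transform import DeformationField, jacobian_determinant

__all__ = [
    "TMap", "dice", "neg_jacobian_percent", "one_sample_tmap",
    "summarize_tmap", "mean_relative_improvement", "mean_count",
    "REFERENCE_PEAK_T", "REFERENCE_SUPRATHRESHOLD", "DEFAULT_T_THRESHOLD",
]

DEFAULT_T_THRESHOLD = 5.01

NETWORKS = ["DMN", "VN", "CEN", "SMN"]

# Published benchmark peak t values of group-level t-maps per network.
REFERENCE_PEAK_T = pd.DataFrame(
    {
        "DMN": [16.9, 17.3, 17.7, 18.5, 18.2, 18.7],
        "VN": [13.8, 22.9, 15.2, 15.9, 15.6, 16.5],
        "CEN": [12.4, 13.5, 13.8, 14.5, 14.4, 16.6],
        "SMN": [13.2, 11.7, 15.1, 16.9, 16.4, 17.3],
    },
    index=["Affine", "SyN", "Transmorph-tiny", "VoxelMorph x2",
           "Cyclemorph", "Our method"],
)

# Published benchmark suprathreshold voxel counts (t > 5.01) per network.
REFERENCE_SUPRATHRESHOLD = pd.DataFrame(
    {
        "DMN": [1834, 1868, 1891, 1984, 1925, 2085],
        "VN": [841, 2799, 1218, 2295, 2197, 2336],
        "CEN": [1292, 1410, 1333, 2790, 2481, 2978],
        "SMN": [2505, 1836, 2637, 2910, 2803, 2986],
    },
    index=REFERENCE_PEAK_T.index,
)


@dataclass
class TMap:
    """A voxelwise t-statistic map with its significance threshold."""

    t: np.ndarray                 # (D, H, W); NaN where undefined
    threshold: float = DEFAULT_T_THRESHOLD
    n_subjects: int = 0

    def __post_init__(self):
        self.t = np.asarray(self.t, dtype=np.float64)
        if self.threshold <= 0:
            raise ValueError("threshold must be positive")

    @property
    def defined(self) -> np.ndarray:
        return np.isfinite(self.t)


def dice(a: LabelMap | np.ndarray, b: LabelMap | np.ndarray,
         structures=None) -> tuple[dict, float]:
    """Per-structure Dice overlap 2|A_s & B_s| / (|A_s| + |B_s|).

    Structures absent from both maps are reported as NaN and excluded
    from the mean.  Returns (per-structure dict, mean over defined).
    """
    da = a.data if isinstance(a, LabelMap) else np.asarray(a)
    db = b.data if isinstance(b, LabelMap) else np.asarray(b)
    if da.shape != db.shape:
        raise ValueError(f"grid mismatch: {da.shape} vs {db.shape}")
    if structures is None:
        structures = np.union1d(np.unique(da), np.unique(db))
        structures = structures[structures != 0]
    scores = {}
    for s in structures:
        ma, mb = da == s, db == s
        denom = int(ma.sum()) + int(mb.sum())
        if denom == 0:
            scores[int(s)] = float("nan")
            continue
        scores[int(s)] = 2.0 * int((ma & mb).sum()) / denom
    defined = [v for v in scores.values() if np.isfinite(v)]
    if not defined:
        raise ValueError("no requested structure present in either map")
    return scores, float(np.mean(defined))


def neg_jacobian_percent(field: DeformationField, mask=None) -> float:
    """Percentage of (masked) voxels with det(I + grad u) <= 0."""
    det = jacobian_determinant(field)
    if mask is not None:
        mask = np.asarray(mask, dtype=bool)
        if mask.shape != det.shape:
            raise ValueError("mask shape mismatch")
        det = det[mask]
    n = det.size
    return 100.0 * float((det <= 0).sum()) / n


def one_sample_tmap(maps, threshold: float = DEFAULT_T_THRESHOLD) -> TMap:
    """Voxelwise one-sample t-test (against 0) over subject maps.

    t = mean / (sd / sqrt(n)) with the n-1 sd; voxels with zero sd are
    flagged undefined (NaN), not infinite.
    """
    stack = np.stack([np.asarray(m, dtype=np.float64) for m in maps], axis=0)
    n = stack.shape[0]
    if n < 2:
        raise ValueError("need at least 2 subject maps")
    mean = stack.mean(axis=0)
    sd = stack.std(axis=0, ddof=1)
    t = np.full(mean.shape, np.nan)
    ok = sd > 0
    t[ok] = mean[ok] / (sd[ok] / np.sqrt(n))
    t[(~ok) & (mean == 0)] = 0.0
    return TMap(t=t, threshold=threshold, n_subjects=n)


def summarize_tmap(tmap: TMap) -> tuple[float, int]:
    """(peak t over defined voxels, count of voxels with t > threshold)."""
    defined = tmap.defined
    if not defined.any():
        raise ValueError("t-map has no defined voxels")
    vals = tmap.t[defined]
    peak = float(vals.max())
    count = int((vals > tmap.threshold).sum())
    return peak, count


def mean_relative_improvement(table: pd.DataFrame, method: str,
                              baseline: str) -> float:
    """Mean over networks of 100 * (v_method - v_baseline) / v_baseline,
    rounded to 2 decimals."""
    for row in (method, baseline):
        if row not in table.index:
            raise KeyError(f"row {row!r} not in table")
    v_m = table.loc[method].to_numpy(dtype=np.float64)
    v_b = table.loc[baseline].to_numpy(dtype=np.float64)
    if (v_b == 0).any():
        raise ZeroDivisionError("baseline row contains zero entries")
    return float(np.round(np.mean(100.0 * (v_m - v_b) / v_b), 2))


def mean_count(row) -> float:
    """Arithmetic mean of a table row (e.g. suprathreshold counts)."""
    values = np.asarray(row, dtype=np.float64)
    if values.size == 0:
        raise ValueError("empty row")
    return float(values.mean())
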