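"""Quantitative readouts of reconstructed volumes.

Total recovered power, peak detection with sub-voxel refinement, peak
separation and radial displacement from the gantry axis, and maximum
intensity projections / single-slice sections for display.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import ndimage

from .geometry import VoxelGrid
from .reconstruction import FluenceField, SourceEstimate

__all__ = [
    "Peak",
    "PeakSet",
    "total_power",
    "find_peaks",
    "peak_separation",
    "radial_displacement",
    "max_intensity_projection",
    "volume_slice",
]

#: mapping of anatomical projection names to grid axes (x, y, z) = (0, 1, 2);
#: with the animal axis along z, a coronal view projects along x, a sagittal
#: view along y, and a transverse section is a constant-z slice
AXIS_NAMES = {"x": 0, "y": 1, "z": 2, "coronal": 0, "sagittal": 1, "transverse": 2}


@dataclass(frozen=True)
class Peak:
    position_mm: tuple[float, float, float]
    intensity: float
    prominence: float
    index: tuple[int, int, int]


@dataclass
class PeakSet:
    """Detected local maxima, sorted by intensity (descending)."""

    peaks: list[Peak]
    threshold: float

    def __len__(self) -> int:
        return len(self.peaks)

    def __getitem__(self, i) -> Peak:
        return self.peaks[i]

    def positions(self) -> np.ndarray:
        return np.array([p.position_mm for p in self.peaks]).reshape(-1, 3)

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            [
                {
                    "x_mm": p.position_mm[0],
                    "y_mm": p.position_mm[1],
                    "z_mm": p.position_mm[2],
                    "intensity": p.intensity,
                    "prominence": p.prominence,
                }
                for p in self.peaks
            ]
        )


def _volume_and_grid(volume) -> tuple[np.ndarray, VoxelGrid | None]:
    if isinstance(volume, (SourceEstimate, FluenceField)):
        return volume.values, volume.grid
    return np.asarray(volume, dtype=float), None


def total_power(volume) -> float:
    """Total emission of a reconstructed volume (photons/s): sum over voxels."""
    vals, _ = _volume_and_grid(volume)
    if np.any(vals < 0):
        raise ValueError("total_power expects a non-negative volume")
    return float(vals.sum())


def _parabolic_offset(fm1: float, f0: float, fp1: float) -> float:
    """Sub-voxel offset of the vertex of a 3-point parabola through the max."""
    denom = fm1 - 2.0 * f0 + fp1
    if denom >= 0:  # flat or non-concave: stay on the grid point
        return 0.0
    off = 0.5 * (fm1 - fp1) / denom
    return float(np.clip(off, -0.5, 0.5))


def find_peaks(
    volume,
    min_separation_mm: float = 5.0,
    threshold_fraction: float = 0.5,
    grid: VoxelGrid | None = None,
    refine: bool = True,
) -> PeakSet:
    """Local maxima above a fraction of the global max, greedily separated.

    A voxel is a candidate peak when it is a strict neighborhood maximum
    (26-connectivity, lexicographic tie-break on plateaus); candidates are
    accepted in decreasing intensity order, suppressing any candidate within
    ``min_separation_mm`` of an accepted peak.  With ``refine`` the reported
    position is sharpened by 3-point parabolic interpolation per axis.
    """
    vals, vgrid = _volume_and_grid(volume)
    grid = grid or vgrid
    if grid is None:
        grid = VoxelGrid(vals.shape, 1.0, (0.0, 0.0, 0.0))
    if not np.all(np.isfinite(vals)):
        raise ValueError("volume must be finite")
    vmax = vals.max()
    if vmax <= 0:
        return PeakSet([], threshold=0.0)
    thresh = threshold_fraction * vmax

    footprint = np.ones((3, 3, 3), dtype=bool)
    localmax = (vals == ndimage.maximum_filter(vals, footprint=footprint, mode="constant")) & (
        vals >= thresh
    )
    cand = np.argwhere(localmax)
    # lexicographic tie-break on plateaus: keep the first voxel of each plateau
    if len(cand) > 1:
        lab, n_lab = ndimage.label(localmax)
        keep = []
        seen = set()
        for c in cand:  # argwhere is already lexicographic
            l = lab[tuple(c)]
            if l not in seen:
                seen.add(l)
                keep.append(c)
        cand = np.array(keep)

    order = np.lexsort((cand[:, 2], cand[:, 1], cand[:, 0], -vals[tuple(cand.T)]))
    cand = cand[order]

    accepted: list[Peak] = []
    accepted_pos: list[np.ndarray] = []
    for c in cand:
        pos = grid.index_to_world(c.astype(float))
        if any(np.linalg.norm(pos - q) < min_separation_mm for q in accepted_pos):
            continue
        idx = tuple(int(v) for v in c)
        refined = pos.astype(float).copy()
        if refine:
            for ax in range(3):
                i = idx[ax]
                if 0 < i < vals.shape[ax] - 1:
                    lo = list(idx)
                    hi = list(idx)
                    lo[ax] -= 1
                    hi[ax] += 1
                    off = _parabolic_offset(vals[tuple(lo)], vals[idx], vals[tuple(hi)])
                    refined[ax] += off * grid.voxel_size
        prominence = float(vals[idx] - thresh)
        accepted.append(Peak(tuple(refined), float(vals[idx]), prominence, idx))
        accepted_pos.append(pos)
    return PeakSet(accepted, threshold=float(thresh))


def peak_separation(peaks: PeakSet) -> float:
    """Euclidean distance (mm) between the two strongest peaks."""
    if len(peaks) < 2:
        raise ValueError("need at least two peaks to measure a separation")
    p0 = np.asarray(peaks[0].position_mm)
    p1 = np.asarray(peaks[1].position_mm)
    return float(np.linalg.norm(p0 - p1))


def radial_displacement(position_mm, axis_point=(0.0, 0.0, 0.0), axis_direction=(0.0, 0.0, 1.0)) -> float:
    """Perpendicular distance (mm) of a point from the gantry rotation axis."""
    p = np.asarray(position_mm, dtype=float)
    a = np.asarray(axis_point, dtype=float)
    d = np.asarray(axis_direction, dtype=float)
    d = d / np.linalg.norm(d)
    v = p - a
    return float(np.linalg.norm(v - (v @ d) * d))


def max_intensity_projection(volume, axis) -> np.ndarray:
    """Maximum intensity projection along a named or numbered axis."""
    vals, _ = _volume_and_grid(volume)
    if vals.ndim != 3:
        raise ValueError("expected a 3-D volume")
    ax = AXIS_NAMES.get(axis, axis) if isinstance(axis, str) else axis
    if ax not in (0, 1, 2):
        raise ValueError(f"unknown projection axis {axis!r}")
    return vals.max(axis=ax)


def volume_slice(volume, axis, index: int) -> np.ndarray:
    """Single section (e.g. a transverse slice) perpendicular to an axis."""
    vals, _ = _volume_and_grid(volume)
    ax = AXIS_NAMES.get(axis, axis) if isinstance(axis, str) else axis
    if ax not in (0, 1, 2):
        raise ValueError(f"unknown slice axis {axis!r}")
    return np.take(vals, index, axis=ax)
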