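"""Group-level spatial summaries: convex hulls, grid area usage, polarisation.

The group's spread at one instant is the convex polygon spanned by all
members; its perimeter and area, averaged over frames, summarise how tightly
the group holds together.  Area usage instead asks where the group went: the
fraction of a coarse grid of arena cells visited by any member at any frame.
Polarisation distinguishes a contracted fission-fusion group from a school:
the normalised length of the mean unit velocity vector of the focal
individuals, 1 for perfect alignment and 0 for cancelling directions.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Sequence

import numpy as np
import pandas as pd

from . import _kernels
from .trajectories import ArenaSpec, TrackTable

__all__ = [
    "hull_metrics",
    "mean_hull_metrics",
    "per_frame_hull_metrics",
    "polygon_reduction",
    "area_usage",
    "polarisation",
    "GroupGeometrySummary",
    "summarise_geometry",
]

#: A focal moving less than this (cm) over the polarisation interval has no
#: meaningful direction; such time points are skipped.
MOTION_THRESHOLD_CM = 0.1


def hull_metrics(points: np.ndarray) -> tuple[float, float]:
    """Perimeter (cm) and area (cm^2) of the convex hull of one frame.

    Degenerate frames follow closed-traversal conventions: one distinct point
    gives (0, 0); collinear points give area 0 and perimeter twice the
    extent.
    """
    points = np.asarray(points, float)
    if points.ndim != 2 or points.shape[1] != 2:
        raise ValueError("points must have shape (n, 2)")
    if len(points) == 0:
        raise ValueError("need at least one point")
    per, area = _kernels.hull_perimeter_area(
        np.ascontiguousarray(points[:, 0]), np.ascontiguousarray(points[:, 1])
    )
    return float(per), float(area)


def per_frame_hull_metrics(table: TrackTable) -> pd.DataFrame:
    """Hull perimeter/area for every frame of a recording."""
    metrics = _kernels.hull_metrics_frames(np.ascontiguousarray(table.positions))
    return pd.DataFrame(
        {
            "time_s": table.times,
            "perimeter_cm": metrics[:, 0],
            "area_cm2": metrics[:, 1],
        }
    )


def mean_hull_metrics(table: TrackTable) -> tuple[float, float]:
    """Mean hull perimeter and area over all frames of a recording."""
    metrics = _kernels.hull_metrics_frames(np.ascontiguousarray(table.positions))
    return float(metrics[:, 0].mean()), float(metrics[:, 1].mean())


def polygon_reduction(high: float, low: float) -> float:
    """Percent reduction 100 * (1 - low/high), computed on unrounded means."""
    if high <= 0:
        raise ValueError("the high-density baseline must be positive")
    return 100.0 * (1.0 - low / high)


def area_usage(table: TrackTable, arena: ArenaSpec | None = None) -> float:
    """Fraction of grid cells visited by any individual at any frame.

    Cell membership uses half-open intervals [k*cell, (k+1)*cell) with the
    top and right arena edges closed, so positions exactly on the outer
    boundary belong to the outermost cells.  The grid always spans the full
    nominal arena, also for area-restricted recordings.
    """
    arena = arena or table.arena
    nx = int(round(arena.width / arena.grid_cell))
    ny = int(round(arena.height / arena.grid_cell))
    ix = np.floor(table.positions[..., 0] / arena.grid_cell).astype(int)
    iy = np.floor(table.positions[..., 1] / arena.grid_cell).astype(int)
    ix = np.clip(ix, 0, nx - 1)
    iy = np.clip(iy, 0, ny - 1)
    visited = np.unique(ix * ny + iy)
    return float(len(visited) / (nx * ny))


def polarisation(
    table: TrackTable,
    focal_ids: Sequence[str],
    interval: float = 3.0,
    motion_threshold: float = MOTION_THRESHOLD_CM,
) -> float | None:
    """Mean normalised resultant of focal unit velocity vectors.

    Every ``interval`` seconds each focal contributes the unit vector of its
    displacement over the preceding interval; the statistic at that time point
    is |sum of unit vectors| / n_focals, so it lies in [0, 1].  Time points
    where any focal moved less than ``motion_threshold`` are skipped (no
    defined direction); returns None when every time point is skipped.
    """
    stride = interval * table.sample_rate
    if abs(stride - round(stride)) > 1e-9 or round(stride) < 1:
        raise ValueError("interval must be a positive multiple of the sample spacing")
    stride = int(round(stride))
    cols = [table.index_of(i) for i in focal_ids]
    pos = table.positions[::stride][:, cols, :]
    if len(pos) < 2:
        raise ValueError("recording shorter than one polarisation interval")
    disp = np.diff(pos, axis=0)  # (K, F, 2)
    norms = np.hypot(disp[..., 0], disp[..., 1])
    keep = (norms >= motion_threshold).all(axis=1)
    if not keep.any():
        return None
    unit = disp[keep] / norms[keep][..., None]
    resultant = np.linalg.norm(unit.sum(axis=1), axis=1) / len(cols)
    return float(resultant.mean())


@dataclass
class GroupGeometrySummary:
    """Spatial summary of one recording."""

    mean_perimeter: float
    mean_area: float
    area_usage: float
    mean_polarisation: float | None
    n_frames: int

    def to_dict(self) -> dict:
        return {
            "mean_perimeter_cm": self.mean_perimeter,
            "mean_area_cm2": self.mean_area,
            "area_usage": self.area_usage,
            "mean_polarisation": self.mean_polarisation,
            "n_frames": self.n_frames,
        }


def summarise_geometry(
    table: TrackTable,
    focal_ids: Sequence[str] | None = None,
    polarisation_interval: float = 3.0,
) -> GroupGeometrySummary:
    """All group-geometry metrics for one recording in one pass."""
    per, area = mean_hull_metrics(table)
    pol = polarisation(
        table, focal_ids if focal_ids is not None else table.ids,
        interval=polarisation_interval,
    )
    return GroupGeometrySummary(
        mean_perimeter=per,
        mean_area=area,
        area_usage=area_usage(table),
        mean_polarisation=pol,
        n_frames=table.n_frames,
    )
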