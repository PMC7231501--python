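"""Arena geometry and multi-individual trajectory tables.

The experimental unit is a 3-minute recording of a small fish group in a
square netting arena, tracked at a constant frame rate.  Positions live in an
arena-fixed frame with the origin at one corner, x to the right, y up, in cm.
Recordings are assumed gap-free: the tracks this package targets were curated
frame by frame, so a missing sample indicates a broken file, not an occlusion
to be papered over, and ingest rejects it.
"""

from __future__ import annotations

import io
from dataclasses import dataclass, field, replace
from pathlib import Path
from typing import Mapping, Sequence

import numpy as np
import pandas as pd

__all__ = [
    "ArenaSpec",
    "Trajectory",
    "TrackTable",
    "TrackIngestError",
    "read_tracks",
    "write_tracks",
    "resample",
    "path_length",
    "mean_individual_distance",
    "DEFAULT_COLUMNS",
]

#: Column names of the tracking-file dialect, in file order.
DEFAULT_COLUMNS = {
    "frame": "frame",
    "time": "time_s",
    "id": "fish_id",
    "x": "x_cm",
    "y": "y_cm",
}

#: Tracking jitter tolerance: positions up to this far outside the arena are
#: clamped to the boundary; anything farther is rejected.
BOUNDS_TOLERANCE_CM = 1.0

_TIME_ATOL = 1e-6


class TrackIngestError(ValueError):
    """Raised when a tracking file fails structural validation."""


@dataclass(frozen=True)
class ArenaSpec:
    """Rectangular arena with an analysis grid.

    ``area_scale`` models a counterfactual restriction of the usable area:
    the effective arena is the full rectangle with both dimensions multiplied
    by sqrt(area_scale), so ``area_scale=0.79`` removes 21% of the area.
    """

    width: float = 60.0
    height: float = 60.0
    grid_cell: float = 15.0
    area_scale: float = 1.0

    def __post_init__(self) -> None:
        if self.width <= 0 or self.height <= 0 or self.grid_cell <= 0:
            raise ValueError("arena dimensions and grid cell must be positive")
        if not 0.0 < self.area_scale <= 1.0:
            raise ValueError("area_scale must lie in (0, 1]")
        for side in (self.width, self.height):
            ratio = side / self.grid_cell
            if abs(ratio - round(ratio)) > 1e-9:
                raise ValueError(
                    f"grid_cell {self.grid_cell} does not divide side {side}"
                )

    @property
    def effective_width(self) -> float:
        return self.width * np.sqrt(self.area_scale)

    @property
    def effective_height(self) -> float:
        return self.height * np.sqrt(self.area_scale)

    @property
    def effective_area(self) -> float:
        return self.width * self.height * self.area_scale

    @property
    def n_grid_cells(self) -> int:
        return int(round(self.width / self.grid_cell)) * int(
            round(self.height / self.grid_cell)
        )

    def scaled(self, extra_area_scale: float) -> "ArenaSpec":
        """Arena with an additional fraction of the area removed."""
        return replace(self, area_scale=self.area_scale * extra_area_scale)


@dataclass
class Trajectory:
    """One individual's regularly sampled 2-D path."""

    individual_id: str
    times: np.ndarray
    xs: np.ndarray
    ys: np.ndarray
    sample_rate: float = 5.0
    group_id: str | None = None

    def __post_init__(self) -> None:
        self.times = np.asarray(self.times, float)
        self.xs = np.asarray(self.xs, float)
        self.ys = np.asarray(self.ys, float)
        if not (len(self.times) == len(self.xs) == len(self.ys)):
            raise ValueError("times, xs, ys must have equal length")
        if len(self.times) >= 2:
            dt = np.diff(self.times)
            if np.any(dt <= 0):
                raise ValueError("times must be strictly increasing")
            if np.any(np.abs(dt - 1.0 / self.sample_rate) > _TIME_ATOL):
                raise ValueError("times must be uniform at 1/sample_rate spacing")

    def __len__(self) -> int:
        return len(self.times)

    @property
    def positions(self) -> np.ndarray:
        return np.column_stack([self.xs, self.ys])


@dataclass
class TrackTable:
    """All individuals of one recording on a common time grid.

    ``positions`` is (n_frames, n_individuals, 2); column order follows
    ``ids`` which is kept lexicographically sorted so that positional argmins
    resolve distance ties toward the smallest identifier.
    """

    arena: ArenaSpec
    ids: list[str]
    times: np.ndarray
    positions: np.ndarray
    sample_rate: float = 5.0
    group_id: str | None = None

    def __post_init__(self) -> None:
        self.times = np.asarray(self.times, float)
        self.positions = np.asarray(self.positions, float)
        if len(self.ids) != len(set(self.ids)):
            raise ValueError("individual ids must be unique")
        if list(self.ids) != sorted(self.ids):
            order = np.argsort(np.asarray(self.ids, object))
            self.ids = [self.ids[i] for i in order]
            self.positions = self.positions[:, order, :]
        if self.positions.shape != (len(self.times), len(self.ids), 2):
            raise ValueError("positions must have shape (n_frames, n_ids, 2)")

    @property
    def n_individuals(self) -> int:
        return len(self.ids)

    @property
    def n_frames(self) -> int:
        return len(self.times)

    @property
    def duration(self) -> float:
        return self.n_frames / self.sample_rate

    def index_of(self, individual_id: str) -> int:
        try:
            return self.ids.index(individual_id)
        except ValueError:
            raise KeyError(f"unknown individual id {individual_id!r}") from None

    def trajectory(self, individual_id: str) -> Trajectory:
        j = self.index_of(individual_id)
        return Trajectory(
            individual_id=individual_id,
            times=self.times.copy(),
            xs=self.positions[:, j, 0].copy(),
            ys=self.positions[:, j, 1].copy(),
            sample_rate=self.sample_rate,
            group_id=self.group_id,
        )

    def trajectories(self) -> list[Trajectory]:
        return [self.trajectory(i) for i in self.ids]

    def subset(self, ids: Sequence[str]) -> "TrackTable":
        cols = [self.index_of(i) for i in ids]
        return TrackTable(
            arena=self.arena,
            ids=list(ids),
            times=self.times.copy(),
            positions=self.positions[:, cols, :].copy(),
            sample_rate=self.sample_rate,
            group_id=self.group_id,
        )

    @classmethod
    def from_trajectories(
        cls, trajectories: Sequence[Trajectory], arena: ArenaSpec
    ) -> "TrackTable":
        if not trajectories:
            raise ValueError("need at least one trajectory")
        base = trajectories[0]
        for tr in trajectories[1:]:
            if len(tr) != len(base) or np.any(
                np.abs(tr.times - base.times) > _TIME_ATOL
            ):
                raise ValueError("trajectories do not share a common time grid")
        ids = [tr.individual_id for tr in trajectories]
        positions = np.stack([tr.positions for tr in trajectories], axis=1)
        return cls(
            arena=arena,
            ids=ids,
            times=base.times.copy(),
            positions=positions,
            sample_rate=base.sample_rate,
            group_id=base.group_id,
        )

    def to_dataframe(self) -> pd.DataFrame:
        frames = np.arange(self.n_frames)
        records = []
        for j, ind in enumerate(self.ids):
            records.append(
                pd.DataFrame(
                    {
                        DEFAULT_COLUMNS["frame"]: frames,
                        DEFAULT_COLUMNS["time"]: self.times,
                        DEFAULT_COLUMNS["id"]: ind,
                        DEFAULT_COLUMNS["x"]: self.positions[:, j, 0],
                        DEFAULT_COLUMNS["y"]: self.positions[:, j, 1],
                    }
                )
            )
        return pd.concat(records, ignore_index=True)


def _validate_positions(df: pd.DataFrame, arena: ArenaSpec, xc: str, yc: str) -> None:
    """Clamp small out-of-bounds excursions, reject large ones."""
    for col, hi in ((xc, arena.effective_width), (yc, arena.effective_height)):
        vals = df[col].to_numpy()
        bad = (vals < -BOUNDS_TOLERANCE_CM) | (vals > hi + BOUNDS_TOLERANCE_CM)
        if bad.any():
            line = int(df.index[bad][0]) + 2  # header occupies line 1
            raise TrackIngestError(
                f"position outside arena by more than {BOUNDS_TOLERANCE_CM} cm "
                f"at line {line} (column {col!r})"
            )
        df[col] = np.clip(vals, 0.0, hi)


def read_tracks(
    path: str | Path | io.IOBase,
    arena: ArenaSpec | None = None,
    columns: Mapping[str, str] | None = None,
    sample_rate: float | None = None,
) -> TrackTable:
    """Read a delimited tracking file into a validated :class:`TrackTable`.

    The expected dialect has header columns for frame, time (s), individual
    id, and x/y (cm); ``columns`` remaps the logical roles onto other header
    names for files using a different convention.  Every individual must
    cover the identical, uniformly spaced time grid; duplicated (id, time)
    rows and gaps are errors.
    """
    arena = arena or ArenaSpec()
    cols = dict(DEFAULT_COLUMNS)
    if columns:
        cols.update(columns)
    df = pd.read_csv(path, dtype={cols["id"]: str})
    missing = [c for c in (cols["time"], cols["id"], cols["x"], cols["y"]) if c not in df]
    if missing:
        raise TrackIngestError(f"missing columns: {missing}")
    for col in (cols["time"], cols["x"], cols["y"]):
        converted = pd.to_numeric(df[col], errors="coerce")
        bad = converted.isna() & df[col].notna() | df[col].isna()
        if bad.any():
            raise TrackIngestError(
                f"unparseable value in column {col!r} at line {int(df.index[bad][0]) + 2}"
            )
        df[col] = converted.astype(float)
    if df.duplicated([cols["id"], cols["time"]]).any():
        dup = df[df.duplicated([cols["id"], cols["time"]])]
        raise TrackIngestError(
            f"duplicated (id, time) pair at line {int(dup.index[0]) + 2}"
        )
    _validate_positions(df, arena, cols["x"], cols["y"])
    df = df.sort_values([cols["id"], cols["time"]], kind="stable")

    ids = sorted(df[cols["id"]].unique())
    grid = np.sort(df[cols["time"]].unique())
    if len(grid) >= 2:
        dt = np.diff(grid)
        if np.any(np.abs(dt - dt[0]) > _TIME_ATOL):
            raise TrackIngestError("time grid is not uniformly spaced")
        rate = 1.0 / dt[0]
    else:
        if sample_rate is None:
            raise TrackIngestError("cannot infer sample rate from a single frame")
        rate = sample_rate
    if sample_rate is not None and abs(rate - sample_rate) > 1e-6:
        raise TrackIngestError(
            f"file sample rate {rate:g} Hz does not match expected {sample_rate:g} Hz"
        )

    n_t = len(grid)
    positions = np.empty((n_t, len(ids), 2))
    for j, ind in enumerate(ids):
        sub = df[df[cols["id"]] == ind]
        if len(sub) != n_t:
            raise TrackIngestError(
                f"individual {ind!r} has {len(sub)} samples, expected {n_t} "
                "(gap in track)"
            )
        positions[:, j, 0] = sub[cols["x"]].to_numpy()
        positions[:, j, 1] = sub[cols["y"]].to_numpy()
    return TrackTable(
        arena=arena, ids=ids, times=grid, positions=positions, sample_rate=rate
    )


def write_tracks(table: TrackTable, path: str | Path | io.IOBase) -> None:
    """Write a TrackTable in the tracking dialect read by :func:`read_tracks`."""
    table.to_dataframe().to_csv(path, index=False, float_format="%.6f")


def resample(table: TrackTable, target_rate: float) -> TrackTable:
    """Decimate to ``target_rate`` by keeping every k-th sample from the first.

    The source rate must be an integer multiple of the target rate; timestamps
    of the retained samples are preserved unchanged.
    """
    factor = table.sample_rate / target_rate
    if abs(factor - round(factor)) > 1e-9 or factor < 1:
        raise ValueError(
            f"target rate {target_rate:g} Hz does not evenly divide "
            f"source rate {table.sample_rate:g} Hz"
        )
    k = int(round(factor))
    return TrackTable(
        arena=table.arena,
        ids=list(table.ids),
        times=table.times[::k].copy(),
        positions=table.positions[::k].copy(),
        sample_rate=target_rate,
        group_id=table.group_id,
    )


def path_length(traj: Trajectory) -> float:
    """Total swimming distance: summed Euclidean steps between raw samples."""
    if len(traj) < 2:
        raise ValueError("path length needs at least 2 samples")
    return float(
        np.hypot(np.diff(traj.xs), np.diff(traj.ys)).sum()
    )


def mean_individual_distance(table: TrackTable, ids: Sequence[str]) -> float:
    """Mean swimming distance over the listed individuals.

    The comparison across treatments is restricted to the individuals present
    in every treatment, so the caller passes that focal subset explicitly.
    """
    ids = list(ids)
    if not ids:
        raise ValueError("ids must be non-empty")
    return float(
        np.mean([path_length(table.trajectory(i)) for i in ids])
    )
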