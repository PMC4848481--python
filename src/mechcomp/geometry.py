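"""Core containers shared across the pipeline.

Coordinate conventions, stated once and used everywhere:

* physical positions are in micrometres (μm), times in hours (h);
* pixel origin at the top-left corner, x rightward, y downward;
* physical coordinate = pixel coordinate × ``pixel_size``;
* frames are 0-based and frame 0 is t = 0.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Iterator

import numpy as np
import pandas as pd

__all__ = [
    "SceneGeometry",
    "PointScene",
    "TrackSet",
    "ImageStack",
    "CountSeries",
]


@dataclass(frozen=True)
class SceneGeometry:
    """Geometry and calibration of one imaged field.

    Parameters
    ----------
    shape
        ``"rectangle"`` (a ``width`` × ``height`` μm field) or ``"disc"``
        (a circular micropattern of the given ``diameter`` in μm).
    pixel_size
        Camera calibration in μm per pixel.
    frame_interval
        Time between consecutive frames in hours.
    """

    shape: str = "rectangle"
    width: float = 500.0
    height: float = 500.0
    diameter: float = 800.0
    pixel_size: float = 1.0
    frame_interval: float = 1.0

    def __post_init__(self) -> None:
        if self.shape not in ("rectangle", "disc"):
            raise ValueError(f"unknown geometry shape {self.shape!r}")
        if self.shape == "rectangle" and (self.width <= 0 or self.height <= 0):
            raise ValueError("rectangle dimensions must be positive")
        if self.shape == "disc" and self.diameter <= 0:
            raise ValueError("disc diameter must be positive")
        if self.pixel_size <= 0 or self.frame_interval <= 0:
            raise ValueError("pixel_size and frame_interval must be positive")

    @property
    def area(self) -> float:
        """Field area in μm²."""
        if self.shape == "rectangle":
            return self.width * self.height
        return math.pi * (self.diameter / 2.0) ** 2

    @property
    def bounds(self) -> tuple[float, float]:
        """(extent_x, extent_y) of the bounding box in μm."""
        if self.shape == "rectangle":
            return (self.width, self.height)
        return (self.diameter, self.diameter)

    def contains(self, x: np.ndarray, y: np.ndarray) -> np.ndarray:
        """Boolean mask of points inside the field (μm coordinates)."""
        x = np.asarray(x, dtype=float)
        y = np.asarray(y, dtype=float)
        if self.shape == "rectangle":
            return (x >= 0) & (x <= self.width) & (y >= 0) & (y <= self.height)
        r = self.diameter / 2.0
        return (x - r) ** 2 + (y - r) ** 2 <= r**2

    def edge_distance(self, x: np.ndarray, y: np.ndarray) -> np.ndarray:
        """Distance (μm) from each point to the field boundary."""
        x = np.asarray(x, dtype=float)
        y = np.asarray(y, dtype=float)
        if self.shape == "rectangle":
            return np.minimum.reduce([x, self.width - x, y, self.height - y])
        r = self.diameter / 2.0
        return r - np.hypot(x - r, y - r)

    @property
    def raster_shape(self) -> tuple[int, int]:
        """(height_px, width_px) of the image raster covering the field."""
        ex, ey = self.bounds
        return (int(round(ey / self.pixel_size)), int(round(ex / self.pixel_size)))


@dataclass
class PointScene:
    """One frame's cells as points: the in-memory analogue of a counted
    nuclear-label (DAPI / nuclear GFP) field.

    Arrays are parallel, one entry per cell.  ``marker`` holds an arbitrary
    nuclear-intensity value (NaN when unmeasured); ``alive`` is False for
    cells annotated as death events.
    """

    cell_id: np.ndarray
    x: np.ndarray
    y: np.ndarray
    population: np.ndarray
    geometry: SceneGeometry
    time: float = 0.0
    marker: np.ndarray | None = None
    alive: np.ndarray | None = None

    def __post_init__(self) -> None:
        self.cell_id = np.asarray(self.cell_id, dtype=int)
        self.x = np.asarray(self.x, dtype=float)
        self.y = np.asarray(self.y, dtype=float)
        self.population = np.asarray(self.population, dtype=object)
        n = self.cell_id.size
        if not (self.x.size == self.y.size == self.population.size == n):
            raise ValueError("scene arrays must have equal length")
        if n and np.unique(self.cell_id).size != n:
            raise ValueError("cell_ids must be unique within a scene")
        if self.marker is None:
            self.marker = np.full(n, np.nan)
        else:
            self.marker = np.asarray(self.marker, dtype=float)
        if self.alive is None:
            self.alive = np.ones(n, dtype=bool)
        else:
            self.alive = np.asarray(self.alive, dtype=bool)

    @property
    def n_cells(self) -> int:
        return int(self.cell_id.size)

    @property
    def positions(self) -> np.ndarray:
        """(n, 2) array of (x, y) in μm."""
        return np.column_stack([self.x, self.y])

    def subset(self, mask: np.ndarray) -> "PointScene":
        return PointScene(
            cell_id=self.cell_id[mask],
            x=self.x[mask],
            y=self.y[mask],
            population=self.population[mask],
            geometry=self.geometry,
            time=self.time,
            marker=self.marker[mask],
            alive=self.alive[mask],
        )

    def to_dataframe(self) -> pd.DataFrame:
        frame = int(round(self.time / self.geometry.frame_interval))
        return pd.DataFrame(
            {
                "frame": frame,
                "time_h": self.time,
                "cell_id": self.cell_id,
                "x_um": self.x,
                "y_um": self.y,
                "population": self.population,
                "marker": self.marker,
                "alive": self.alive,
            }
        )


@dataclass
class TrackSet:
    """Identity-linked trajectories over frames.

    ``df`` has columns frame, time_h, cell_id, x_um, y_um, population
    (marker/alive optional), sorted by (cell_id, frame).  ``meta`` carries
    generator ground truth (e.g. true migration-onset times) when the set
    was synthesised.
    """

    df: pd.DataFrame
    frame_interval: float = 1.0
    meta: dict = field(default_factory=dict)

    REQUIRED = ("frame", "time_h", "cell_id", "x_um", "y_um", "population")

    def __post_init__(self) -> None:
        missing = [c for c in self.REQUIRED if c not in self.df.columns]
        if missing:
            raise ValueError(f"TrackSet dataframe missing columns {missing}")
        self.df = self.df.sort_values(["cell_id", "frame"]).reset_index(drop=True)

    @property
    def track_ids(self) -> np.ndarray:
        return self.df["cell_id"].unique()

    @property
    def n_tracks(self) -> int:
        return int(self.track_ids.size)

    def get_track(self, cell_id) -> pd.DataFrame:
        return self.df[self.df["cell_id"] == cell_id]

    def iter_tracks(self) -> Iterator[tuple[int, pd.DataFrame]]:
        yield from self.df.groupby("cell_id", sort=True)

    def scene_at(self, frame: int, geometry: SceneGeometry) -> PointScene:
        sub = self.df[self.df["frame"] == frame]
        return PointScene(
            cell_id=sub["cell_id"].to_numpy(),
            x=sub["x_um"].to_numpy(),
            y=sub["y_um"].to_numpy(),
            population=sub["population"].to_numpy(),
            geometry=geometry,
            time=float(sub["time_h"].iloc[0]) if len(sub) else frame * self.frame_interval,
        )


@dataclass
class ImageStack:
    """A T×H×W grayscale movie with physical calibration."""

    data: np.ndarray
    pixel_size: float
    frame_interval: float
    ground_truth: list | None = None

    def __post_init__(self) -> None:
        self.data = np.asarray(self.data)
        if self.data.ndim != 3:
            raise ValueError("ImageStack data must be T×H×W")
        if self.pixel_size <= 0 or self.frame_interval <= 0:
            raise ValueError("calibration must be positive")

    @property
    def n_frames(self) -> int:
        return self.data.shape[0]

    @property
    def times(self) -> np.ndarray:
        return np.arange(self.n_frames) * self.frame_interval


@dataclass
class CountSeries:
    """Per-field, per-population cell counts and effective areas over time."""

    time_h: np.ndarray
    counts: dict[str, np.ndarray]
    area_um2: np.ndarray
    field_id: str = "field0"
    meta: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        self.time_h = np.asarray(self.time_h, dtype=float)
        if self.time_h.ndim != 1 or np.any(np.diff(self.time_h) <= 0):
            raise ValueError("time_h must be 1-D and strictly increasing")
        self.area_um2 = np.broadcast_to(
            np.asarray(self.area_um2, dtype=float), self.time_h.shape
        ).copy()
        for pop, c in self.counts.items():
            c = np.asarray(c)
            if c.shape != self.time_h.shape:
                raise ValueError(f"counts[{pop!r}] length mismatch")
            if np.any(c < 0) or not np.issubdtype(c.dtype, np.integer):
                raise ValueError("counts must be non-negative integers")
            self.counts[pop] = c

    @property
    def populations(self) -> list[str]:
        return list(self.counts)

    def total(self) -> np.ndarray:
        return np.sum([c for c in self.counts.values()], axis=0)

    def to_dataframe(self) -> pd.DataFrame:
        d = {"time_h": self.time_h, "area_um2": self.area_um2}
        for pop, c in self.counts.items():
            d[f"count_{pop}"] = c
        return pd.DataFrame(d)
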