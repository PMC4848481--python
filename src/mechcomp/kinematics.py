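"""Per-track migration metrics, projected front displacement, time-base
alignment and migration-onset change-point detection.

The directionality index D = net (Euclidean) displacement / total path
length is 1 for ballistic motion and tends to 0 for confined motion.
Front displacement is the population-mean position projected on the axis
joining the two populations' centroids.  Migration onset is found by an
exhaustive two-segment continuous piecewise-linear fit, and the
winner-leads-loser lag is the difference of the two populations' onsets.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .geometry import PointScene, TrackSet

__all__ = [
    "TrajectoryMetrics",
    "FrontSeries",
    "OnsetEstimate",
    "trajectory_metrics",
    "population_axis",
    "project_displacement",
    "align_timebase",
    "detect_onset",
    "onset_lag",
]


@dataclass(frozen=True)
class TrajectoryMetrics:
    directionality: float  # net / path, in [0, 1]; NaN when path length is 0
    mean_speed: float  # μm/h
    path_length: float  # μm
    net_displacement: float  # μm
    defined: bool = True


@dataclass
class FrontSeries:
    """Mean ± sd projected displacement of one population over time."""

    time_h: np.ndarray
    mean_um: np.ndarray
    sd_um: np.ndarray
    n: int
    axis: np.ndarray
    population: str

    def __post_init__(self) -> None:
        self.time_h = np.asarray(self.time_h, dtype=float)
        self.mean_um = np.asarray(self.mean_um, dtype=float)
        self.sd_um = np.asarray(self.sd_um, dtype=float)
        self.axis = np.asarray(self.axis, dtype=float)
        if not np.isclose(np.linalg.norm(self.axis), 1.0):
            raise ValueError("axis must be a unit vector")
        if np.any(np.diff(self.time_h) <= 0):
            raise ValueError("time must be strictly increasing")

    def speeds(self) -> np.ndarray:
        """Forward-difference projected speeds (μm/h), length T−1."""
        return np.diff(self.mean_um) / np.diff(self.time_h)


@dataclass(frozen=True)
class OnsetEstimate:
    t_onset: float  # h
    pre_slope: float  # μm/h
    post_slope: float  # μm/h
    sse: float


def trajectory_metrics(track: pd.DataFrame | np.ndarray, times=None) -> TrajectoryMetrics:
    """Directionality, speed and path lengths of one track.

    ``track`` is either a TrackSet-style dataframe (x_um, y_um, time_h)
    or an (n, 2) position array with ``times`` given separately.
    """
    if isinstance(track, pd.DataFrame):
        xy = track[["x_um", "y_um"]].to_numpy(float)
        t = track["time_h"].to_numpy(float)
    else:
        xy = np.asarray(track, dtype=float)
        t = np.asarray(times, dtype=float) if times is not None else np.arange(len(xy))
    if len(xy) < 2:
        raise ValueError("track must have at least 2 points")
    steps = np.linalg.norm(np.diff(xy, axis=0), axis=1)
    path = float(steps.sum())
    net = float(np.linalg.norm(xy[-1] - xy[0]))
    duration = float(t[-1] - t[0])
    speed = path / duration if duration > 0 else np.nan
    if path == 0:
        return TrajectoryMetrics(np.nan, speed, 0.0, 0.0, defined=False)
    return TrajectoryMetrics(net / path, speed, path, net)


def population_axis(
    scene: PointScene | pd.DataFrame, winner: str = "winner", loser: str = "loser"
) -> np.ndarray:
    """Unit vector from the winner centroid to the loser centroid."""
    if isinstance(scene, PointScene):
        pops = scene.population
        pos = scene.positions
    else:
        pops = scene["population"].to_numpy()
        pos = scene[["x_um", "y_um"]].to_numpy(float)
    cw = pos[pops == winner]
    cl = pos[pops == loser]
    if len(cw) == 0 or len(cl) == 0:
        raise ValueError(
            f"need both populations present ({winner!r}: {len(cw)}, {loser!r}: {len(cl)})"
        )
    v = cl.mean(axis=0) - cw.mean(axis=0)
    norm = np.linalg.norm(v)
    if norm == 0:
        raise ValueError("population centroids coincide; axis undefined")
    return v / norm


def project_displacement(tracks: TrackSet, axis: np.ndarray) -> dict[str, FrontSeries]:
    """Population-mean projected displacement over time.

    For each cell, displacement from its first observed position is
    projected on ``axis``; the per-frame mean ± sd over each population's
    cells gives that population's front series.  Only unbroken tracks
    spanning all frames enter the average.
    """
    axis = np.asarray(axis, dtype=float)
    if not np.isclose(np.linalg.norm(axis), 1.0):
        raise ValueError("axis must be unit-norm")
    df = tracks.df
    frames = np.sort(df["frame"].unique())
    out: dict[str, FrontSeries] = {}
    for pop, sub in df.groupby("population"):
        lengths = sub.groupby("cell_id")["frame"].count()
        full = lengths[lengths == len(frames)].index
        sub = sub[sub["cell_id"].isin(full)].sort_values(["cell_id", "frame"])
        if not len(full):
            continue
        xy = sub[["x_um", "y_um"]].to_numpy(float).reshape(len(full), len(frames), 2)
        disp = ((xy - xy[:, :1, :]) @ axis).T  # (frames, cells)
        t = np.sort(sub["time_h"].unique())
        out[str(pop)] = FrontSeries(
            time_h=t,
            mean_um=disp.mean(axis=1),
            sd_um=disp.std(axis=1, ddof=0),
            n=len(full),
            axis=axis,
            population=str(pop),
        )
    return out


def align_timebase(
    front_series_pair: dict[str, FrontSeries] | tuple[FrontSeries, FrontSeries],
    speed_threshold: float = 2.0,
    k_frames: int = 4,
    t_star: float = 5.0,
) -> dict[str, FrontSeries]:
    """Re-index a pair of front series so concerted motion starts at t* = 5 h.

    The concerted-motion frame is the first frame at which BOTH
    populations' forward-difference projected speed is at least
    ``speed_threshold`` (μm/h) for ``k_frames`` consecutive frames.  Both
    series are shifted so that frame maps to ``t_star``.  Raises, naming
    the maximum observed speeds, if the criterion is never met.
    """
    series = (
        list(front_series_pair.values())
        if isinstance(front_series_pair, dict)
        else list(front_series_pair)
    )
    if len(series) != 2:
        raise ValueError("expected exactly two front series")
    a, b = series
    if len(a.time_h) != len(b.time_h) or not np.allclose(a.time_h, b.time_h):
        raise ValueError("front series must share a time base")
    va, vb = a.speeds(), b.speeds()
    ok = (va >= speed_threshold) & (vb >= speed_threshold)
    run = 0
    hit = None
    for i, flag in enumerate(ok):
        run = run + 1 if flag else 0
        if run >= k_frames:
            hit = i - k_frames + 1
            break
    if hit is None:
        raise ValueError(
            "concerted-motion criterion never met "
            f"(threshold {speed_threshold} μm/h for {k_frames} frames; "
            f"max speeds {np.nanmax(va):.2f} and {np.nanmax(vb):.2f} μm/h)"
        )
    shift = t_star - a.time_h[hit]
    out = {}
    for s in (a, b):
        out[s.population] = FrontSeries(
            time_h=s.time_h + shift,
            mean_um=s.mean_um,
            sd_um=s.sd_um,
            n=s.n,
            axis=s.axis,
            population=s.population,
        )
    return out


def _hinge_fit(t: np.ndarray, y: np.ndarray, k: int):
    """Continuous two-segment least squares with the breakpoint at t[k]."""
    tk = t[k]
    X = np.column_stack(
        [np.ones_like(t), np.minimum(t - tk, 0.0), np.maximum(t - tk, 0.0)]
    )
    coef, _, _, _ = np.linalg.lstsq(X, y, rcond=None)
    resid = y - X @ coef
    return coef, float(resid @ resid)


def detect_onset(
    series: FrontSeries | tuple[np.ndarray, np.ndarray],
    min_slope_ratio: float = 3.0,
    min_slope_change: float = 0.5,
) -> OnsetEstimate | None:
    """Change-point estimate of migration onset on a displacement series.

    Fits a continuous two-segment piecewise-linear model for every
    interior breakpoint (exhaustive scan) and keeps the minimum-SSE fit.
    An onset is reported only when |post slope| exceeds
    ``min_slope_ratio`` × |pre slope| and the slope change is at least
    ``min_slope_change`` μm/h; otherwise returns None ("no onset" is a
    valid result, e.g. for pure noise).
    """
    if isinstance(series, FrontSeries):
        t, y = series.time_h, series.mean_um
    else:
        t, y = (np.asarray(a, dtype=float) for a in series)
    if len(t) < 5:
        raise ValueError("need at least 5 samples for onset detection")
    best = None
    for k in range(2, len(t) - 2):
        coef, sse = _hinge_fit(t, y, k)
        if best is None or sse < best[1]:
            best = (k, sse, coef)
    k, sse, coef = best
    pre, post = float(coef[1]), float(coef[2])
    if abs(post) < min_slope_ratio * abs(pre):
        return None
    if abs(post - pre) < min_slope_change:
        return None
    return OnsetEstimate(t_onset=float(t[k]), pre_slope=pre, post_slope=post, sse=sse)


def onset_lag(
    winner_series: FrontSeries | OnsetEstimate,
    loser_series: FrontSeries | OnsetEstimate,
    **kwargs,
) -> float:
    """Loser onset minus winner onset, in hours (positive = winner leads)."""
    ests = {}
    for name, s in (("winner", winner_series), ("loser", loser_series)):
        est = s if isinstance(s, OnsetEstimate) else detect_onset(s, **kwargs)
        if est is None:
            raise ValueError(f"no migration onset detected for the {name} population")
        ests[name] = est
    return ests["loser"].t_onset - ests["winner"].t_onset
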