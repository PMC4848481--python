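"""Moment-based ellipse fits, aspect-ratio-vs-interface profiles, and
axis-versus-motion angle statistics.

A cell's shape is summarised by the ellipse with the same second central
moments as its mask (or point cloud): full axes are 4·sqrt of the
covariance eigenvalues, the orientation is the major-eigenvector angle
(axial, degrees in [0, 180)), and the aspect ratio is major/minor ≥ 1.
Angles between the (unoriented) long axis and the motion direction are
acute, in [0°, 90°], and binned at 40° ([0,40), [40,80), [80,90]).
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

__all__ = [
    "CellShape",
    "AngleHistogram",
    "fit_shape",
    "aspect_vs_distance",
    "axis_motion_angle",
    "angle_histogram",
]

ANGLE_BIN_EDGES = (0.0, 40.0, 80.0, 90.0)


@dataclass(frozen=True)
class CellShape:
    centroid: tuple[float, float]  # μm
    major_axis: float  # μm, full axis length
    minor_axis: float  # μm
    orientation: float  # degrees in [0, 180), axial
    aspect_ratio: float  # major / minor, >= 1


@dataclass(frozen=True)
class AngleHistogram:
    bin_edges: tuple[float, ...]
    counts: tuple[int, ...]


def fit_shape(mask_or_points, pixel_size: float = 1.0) -> CellShape:
    """Fit the second-moment-equivalent ellipse of a mask or point cloud.

    ``mask_or_points`` is a 2-D boolean mask (pixels, scaled by
    ``pixel_size``) or an (n, 2) array of (x, y) points in μm.  Raises for
    degenerate (fewer than 3, or collinear) input.
    """
    arr = np.asarray(mask_or_points)
    if arr.ndim == 2 and arr.dtype == bool:
        ys, xs = np.nonzero(arr)
        pts = np.column_stack([xs, ys]).astype(float) * pixel_size
    else:
        pts = np.asarray(arr, dtype=float)
        if pts.ndim != 2 or pts.shape[1] != 2:
            raise ValueError("points must be an (n, 2) array")
    if len(pts) < 3:
        raise ValueError("need at least 3 pixels/points to fit a shape")
    centroid = pts.mean(axis=0)
    cov = np.cov(pts.T, bias=True)
    evals, evecs = np.linalg.eigh(cov)  # ascending
    lam_minor, lam_major = float(evals[0]), float(evals[1])
    if lam_major <= 0 or lam_minor <= 1e-12 * lam_major:
        raise ValueError("degenerate (collinear) input; ellipse fit undefined")
    vx, vy = evecs[:, 1]
    theta = np.degrees(np.arctan2(vy, vx)) % 180.0
    major = 4.0 * np.sqrt(lam_major)
    minor = 4.0 * np.sqrt(lam_minor)
    return CellShape(
        centroid=(float(centroid[0]), float(centroid[1])),
        major_axis=major,
        minor_axis=minor,
        orientation=float(theta),
        aspect_ratio=major / minor,
    )


def aspect_vs_distance(
    shapes: pd.DataFrame,
    interface_point: np.ndarray,
    interface_normal: np.ndarray,
    bin_width_um: float,
) -> pd.DataFrame:
    """Mean ± sd aspect ratio per signed-distance bin per population.

    ``shapes`` needs columns x_um, y_um, aspect_ratio, population.  The
    signed distance of each cell to the interface line (through
    ``interface_point``, with unit normal ``interface_normal``) is binned
    at ``bin_width_um``; empty bins are simply absent from the output
    (reported as missing, not zero).
    """
    if bin_width_um <= 0:
        raise ValueError("bin_width_um must be > 0")
    n = np.asarray(interface_normal, dtype=float)
    n = n / np.linalg.norm(n)
    p0 = np.asarray(interface_point, dtype=float)
    xy = shapes[["x_um", "y_um"]].to_numpy(float)
    sdist = (xy - p0) @ n
    bins = np.floor(sdist / bin_width_um).astype(int)
    df = shapes.assign(signed_distance_um=sdist, bin=bins)
    grouped = (
        df.groupby(["population", "bin"])["aspect_ratio"]
        .agg(["mean", "std", "count"])
        .reset_index()
    )
    grouped["bin_center_um"] = (grouped["bin"] + 0.5) * bin_width_um
    return grouped.rename(columns={"mean": "ar_mean", "std": "ar_sd", "count": "n"})


def axis_motion_angle(orientation_deg: float, velocity) -> float:
    """Acute angle (degrees, [0, 90]) between the unoriented long axis and
    the direction of motion.  Raises for zero velocity."""
    v = np.asarray(velocity, dtype=float)
    speed = np.linalg.norm(v)
    if speed == 0:
        raise ValueError("zero velocity: axis-motion angle undefined")
    motion_deg = np.degrees(np.arctan2(v[1], v[0]))
    delta = abs(orientation_deg - motion_deg) % 180.0
    return float(min(delta, 180.0 - delta))


def angle_histogram(angles) -> AngleHistogram:
    """Bin axis-motion angles at 40°: [0,40), [40,80), [80,90].

    The last bin is narrower by construction because axial deviations are
    inherently acute.  The boundary value 40 (resp. 80) falls in the
    second (resp. third) bin; 90 is included in the last.
    """
    a = np.asarray(angles, dtype=float)
    if a.size and (a.min() < 0 or a.max() > 90):
        raise ValueError("angles must lie in [0, 90]")
    counts = (
        int(np.sum((a >= 0) & (a < 40))),
        int(np.sum((a >= 40) & (a < 80))),
        int(np.sum((a >= 80) & (a <= 90))),
    )
    return AngleHistogram(bin_edges=ANGLE_BIN_EDGES, counts=counts)
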