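"""Global and per-cell local densities, nuclear intensities, and the
density–intensity association.

Global density follows the counting convention of the source assays:
nuclei counted in a field divided by the effective (exclusion-corrected)
area, reported in cells per 10,000 μm².  Local density is the per-cell
crowding score Σ_{j≠i, d_ij ≤ radius} exp(−d_ij²/(2σ²)) with σ = 20 μm and
a 50 μm cutoff by default; it is a dimensionless kernel sum (no
normalisation constant), increasing with crowding.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats
from scipy.spatial import cKDTree

from .geometry import PointScene

__all__ = [
    "GlobalDensity",
    "LocalDensityParams",
    "CorrelationResult",
    "global_density",
    "local_density",
    "nuclear_intensity",
    "density_intensity_correlation",
    "density_timecourse",
]


@dataclass(frozen=True)
class GlobalDensity:
    count: int
    effective_area: float  # μm²
    density: float  # cells per 10,000 μm²


@dataclass(frozen=True)
class LocalDensityParams:
    """Kernel bandwidth σ and neighbour cutoff radius, both in μm."""

    sigma: float = 20.0
    radius: float = 50.0

    def __post_init__(self) -> None:
        if self.sigma <= 0 or self.radius <= 0:
            raise ValueError("sigma and radius must be positive")


@dataclass(frozen=True)
class CorrelationResult:
    rho: float
    n: int
    p_value: float


def global_density(scene_or_count, effective_area: float | None = None) -> GlobalDensity:
    """Cell count divided by effective area, in cells per 10⁴ μm².

    ``scene_or_count`` may be a :class:`PointScene` (area defaults to its
    field geometry's area), an integer count, or a detections table
    (anything with ``__len__``).
    """
    if isinstance(scene_or_count, PointScene):
        count = scene_or_count.n_cells
        if effective_area is None:
            effective_area = scene_or_count.geometry.area
    elif np.isscalar(scene_or_count):
        count = int(scene_or_count)
    else:
        count = len(scene_or_count)
    if effective_area is None or effective_area <= 0:
        raise ValueError("effective_area must be positive")
    return GlobalDensity(
        count=count,
        effective_area=float(effective_area),
        density=count / (effective_area / 1e4),
    )


def local_density(
    scene_or_positions,
    params: LocalDensityParams = LocalDensityParams(),
    kernel: str = "gaussian",
) -> np.ndarray:
    """Per-cell Gaussian-kernel crowding score.

    For each cell i, sums exp(−d_ij²/2σ²) over neighbours j within the
    cutoff radius (``kernel="gaussian"``, the default).  The literal
    distance-weighted variant Σ d_ij·exp(−d_ij²/2σ²) is available as
    ``kernel="distance_weighted"`` for comparison.  An isolated cell
    scores 0; pair contributions are symmetric.  Neighbour search uses a
    k-d tree, exact within floating tolerance.
    """
    pos = (
        scene_or_positions.positions
        if isinstance(scene_or_positions, PointScene)
        else np.asarray(scene_or_positions, dtype=float)
    )
    n = len(pos)
    out = np.zeros(n)
    if n < 2:
        return out
    tree = cKDTree(pos)
    pairs = tree.query_pairs(r=params.radius, output_type="ndarray")
    if len(pairs) == 0:
        return out
    d = np.linalg.norm(pos[pairs[:, 0]] - pos[pairs[:, 1]], axis=1)
    w = np.exp(-(d**2) / (2.0 * params.sigma**2))
    if kernel == "distance_weighted":
        w = d * w
    elif kernel != "gaussian":
        raise ValueError(f"unknown kernel {kernel!r}")
    np.add.at(out, pairs[:, 0], w)
    np.add.at(out, pairs[:, 1], w)
    return out


def nuclear_intensity(
    image: np.ndarray,
    detections: pd.DataFrame,
    aperture_radius_px: float,
) -> pd.DataFrame:
    """Mean pixel intensity in a circular aperture around each detection.

    Stands in for nuclear-mask segmentation: a fixed circular aperture of
    ``aperture_radius_px`` centred on (x_px, y_px).  Apertures clipped by
    the image border are measured on the in-image part and flagged.
    """
    if aperture_radius_px <= 0:
        raise ValueError("aperture_radius_px must be positive")
    img = np.asarray(image, dtype=float)
    H, W = img.shape
    r = aperture_radius_px
    ri = int(np.ceil(r))
    yy, xx = np.mgrid[-ri : ri + 1, -ri : ri + 1]
    disk = (xx**2 + yy**2) <= r**2
    means = np.empty(len(detections))
    clipped = np.zeros(len(detections), dtype=bool)
    for i, (x, y) in enumerate(
        zip(detections["x_px"].to_numpy(), detections["y_px"].to_numpy())
    ):
        cx, cy = int(round(x)), int(round(y))
        x0, x1 = cx - ri, cx + ri + 1
        y0, y1 = cy - ri, cy + ri + 1
        dx0, dy0 = max(0, -x0), max(0, -y0)
        dx1 = disk.shape[1] - max(0, x1 - W)
        dy1 = disk.shape[0] - max(0, y1 - H)
        if dx0 or dy0 or x1 > W or y1 > H:
            clipped[i] = True
        sub = img[max(0, y0) : min(H, y1), max(0, x0) : min(W, x1)]
        m = disk[dy0:dy1, dx0:dx1]
        means[i] = sub[m].mean() if m.any() else np.nan
    out = detections.copy()
    out["intensity_mean"] = means
    out["aperture_clipped"] = clipped
    return out


def density_intensity_correlation(
    local_densities: np.ndarray, intensities: np.ndarray
) -> CorrelationResult:
    """Spearman rank correlation (average-rank ties, two-sided p) between
    per-cell local density and marker intensity."""
    d = np.asarray(local_densities, dtype=float)
    m = np.asarray(intensities, dtype=float)
    if d.shape != m.shape or d.ndim != 1:
        raise ValueError("inputs must be paired 1-D arrays")
    if d.size < 3:
        raise ValueError("need at least 3 pairs")
    if np.ptp(d) == 0 or np.ptp(m) == 0:
        raise ValueError("Spearman correlation undefined for a constant input")
    res = stats.spearmanr(d, m)
    return CorrelationResult(
        rho=float(res.statistic), n=int(d.size), p_value=float(res.pvalue)
    )


def density_timecourse(counts_or_scenes, areas=None) -> pd.DataFrame:
    """Per-frame global densities, no smoothing.

    Accepts a list of :class:`PointScene` (areas default to the field
    area), or a sequence of counts plus one effective area per frame.
    Returns a dataframe with time_h, count, area_um2 and density
    (cells per 10⁴ μm²).
    """
    rows = []
    if len(counts_or_scenes) and isinstance(counts_or_scenes[0], PointScene):
        scenes = counts_or_scenes
        for i, scene in enumerate(scenes):
            area = scene.geometry.area if areas is None else areas[i]
            g = global_density(scene, area)
            rows.append((scene.time, g.count, g.effective_area, g.density))
    else:
        counts = np.asarray(counts_or_scenes)
        if areas is None:
            raise ValueError("areas are required when passing raw counts")
        areas = np.broadcast_to(np.asarray(areas, dtype=float), counts.shape)
        for i, (c, a) in enumerate(zip(counts, areas)):
            g = global_density(int(c), a)
            rows.append((float(i), g.count, g.effective_area, g.density))
    return pd.DataFrame(rows, columns=["time_h", "count", "area_um2", "density"])
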