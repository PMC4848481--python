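"""PIV velocity fields, first-contact-row displacement, and kymographs.

PIV is single-pass windowed FFT cross-correlation: each interrogation
window's displacement is the argmax of the normalised cross-correlation
between frames, refined to subpixel by a Gaussian three-point fit.
Kymographs are built by drift-correcting each frame, rotating the stack so
the mean motion direction is horizontal, max-projecting across the
transverse dimension, and stacking the resulting rows over time.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import ndimage

from .detection import subtract_drift
from .geometry import ImageStack, TrackSet

__all__ = [
    "PIVConfig",
    "VelocityField",
    "Kymograph",
    "piv_pair",
    "first_row_displacement",
    "build_kymograph",
    "kymograph_from_scenes",
]


@dataclass(frozen=True)
class PIVConfig:
    window_px: int = 32
    overlap: float = 0.5
    min_peak_ratio: float = 1.2

    def __post_init__(self) -> None:
        if self.window_px < 8 or self.window_px & (self.window_px - 1):
            raise ValueError("window_px must be a power of two >= 8")
        if not 0 <= self.overlap < 1:
            raise ValueError("overlap must be in [0, 1)")


@dataclass
class VelocityField:
    """Per-window displacement vectors between one frame pair.

    ``u``/``v`` are in px per frame pair; ``quality`` is the
    first-to-second correlation peak ratio and ``valid`` flags vectors
    with quality above the configured minimum.
    """

    x: np.ndarray  # window-centre columns, px
    y: np.ndarray  # window-centre rows, px
    u: np.ndarray  # (ny, nx) displacement along x, px/frame
    v: np.ndarray  # (ny, nx) displacement along y, px/frame
    quality: np.ndarray
    valid: np.ndarray
    window_px: int

    def to_um_per_h(self, pixel_size: float, frame_interval: float):
        """Calibrate to μm/h: (px/frame) × pixel_size / frame_interval."""
        scale = pixel_size / frame_interval
        return self.u * scale, self.v * scale


def _subpixel(cm: float, cc: float, cp: float) -> float:
    # Gaussian three-point estimator; requires positive ordinates
    eps = 1e-12
    lm, lc, lp = (np.log(max(v, eps)) for v in (cm, cc, cp))
    denom = lm - 2.0 * lc + lp
    if denom >= 0:
        return 0.0
    return float(np.clip(0.5 * (lm - lp) / denom, -0.5, 0.5))


def piv_pair(
    frame_a: np.ndarray, frame_b: np.ndarray, config: PIVConfig = PIVConfig()
) -> VelocityField:
    """Displacement field from frame_a to frame_b by windowed FFT
    cross-correlation.

    Each window's vector is limited to ±window/2; windows whose
    first-to-second peak ratio falls below ``config.min_peak_ratio`` (or
    that are featureless) are flagged invalid.
    """
    a = np.asarray(frame_a, dtype=float)
    b = np.asarray(frame_b, dtype=float)
    if a.shape != b.shape:
        raise ValueError("frames must have equal shape")
    w = config.window_px
    H, W = a.shape
    if w > min(H, W):
        raise ValueError(f"window ({w} px) larger than image {a.shape}")
    step = max(1, int(round(w * (1.0 - config.overlap))))
    xs = np.arange(0, W - w + 1, step)
    ys = np.arange(0, H - w + 1, step)
    u = np.zeros((len(ys), len(xs)))
    v = np.zeros_like(u)
    quality = np.zeros_like(u)
    valid = np.zeros(u.shape, dtype=bool)
    # linear (zero-padded) cross-correlation, normalised by the overlap
    # area per lag: removes the bias toward zero displacement that plain
    # circular correlation introduces
    half = w // 2
    pad = 2 * w
    lag = np.arange(-half, half + 1)
    overlap = np.minimum(w - np.abs(lag)[:, None], w) * np.minimum(
        w - np.abs(lag)[None, :], w
    )
    for iy, y0 in enumerate(ys):
        for ix, x0 in enumerate(xs):
            wa = a[y0 : y0 + w, x0 : x0 + w]
            wb = b[y0 : y0 + w, x0 : x0 + w]
            sa, sb = wa.std(), wb.std()
            if sa == 0 or sb == 0:
                continue
            fa = np.fft.fft2(wa - wa.mean(), s=(pad, pad))
            fb = np.fft.fft2(wb - wb.mean(), s=(pad, pad))
            full = np.fft.fftshift(np.real(np.fft.ifft2(fb * np.conj(fa))))
            centre = pad // 2
            raw = full[centre - half : centre + half + 1,
                       centre - half : centre + half + 1]
            corr = raw / (overlap * sa * sb)
            py, px = np.unravel_index(np.argmax(corr), corr.shape)
            peak = corr[py, px]
            masked = corr.copy()
            masked[max(0, py - 1) : py + 2, max(0, px - 1) : px + 2] = -np.inf
            second = masked.max()
            q = peak / second if second > 0 else np.inf
            if 0 < py < corr.shape[0] - 1:
                dy = py - half + _subpixel(corr[py - 1, px], peak, corr[py + 1, px])
            else:
                dy = py - half
            if 0 < px < corr.shape[1] - 1:
                dx = px - half + _subpixel(corr[py, px - 1], peak, corr[py, px + 1])
            else:
                dx = px - half
            u[iy, ix], v[iy, ix] = dx, dy
            quality[iy, ix] = q
            valid[iy, ix] = q >= config.min_peak_ratio
    return VelocityField(
        x=xs + w / 2.0,
        y=ys + w / 2.0,
        u=u,
        v=v,
        quality=quality,
        valid=valid,
        window_px=w,
    )


def first_row_displacement(
    tracks: TrackSet,
    interface_point,
    axis,
    band_width_um: float,
    population: str | None = None,
) -> pd.DataFrame:
    """Projected displacement-vs-time of cells in the first contact row.

    Selects cells whose first observed position lies within
    ``band_width_um`` of the interface line (through ``interface_point``,
    perpendicular to the unit ``axis``), optionally restricted to one
    population, and returns their per-frame displacement projected on the
    population axis.  Raises if the band is empty.
    """
    if band_width_um <= 0:
        raise ValueError("band_width_um must be > 0")
    ax = np.asarray(axis, dtype=float)
    ax = ax / np.linalg.norm(ax)
    p0 = np.asarray(interface_point, dtype=float)
    rows = []
    for cid, tr in tracks.iter_tracks():
        if population is not None and tr["population"].iloc[0] != population:
            continue
        xy = tr[["x_um", "y_um"]].to_numpy(float)
        if abs((xy[0] - p0) @ ax) > band_width_um:
            continue
        disp = (xy - xy[0]) @ ax
        for f, t, d in zip(tr["frame"], tr["time_h"], disp):
            rows.append((cid, tr["population"].iloc[0], int(f), float(t), float(d)))
    if not rows:
        raise ValueError("no cells start within the contact band")
    return pd.DataFrame(
        rows, columns=["cell_id", "population", "frame", "time_h", "displacement_um"]
    )


@dataclass
class Kymograph:
    """Space–time image: rows are frames, columns positions along the
    motion direction (μm = column × pixel_size)."""

    image: np.ndarray  # (T, L)
    pixel_size: float
    frame_interval: float
    direction: tuple[float, float]


def build_kymograph(
    stack: ImageStack | np.ndarray,
    drift: np.ndarray | None = None,
    direction=(1.0, 0.0),
    pixel_size: float | None = None,
    frame_interval: float | None = None,
) -> Kymograph:
    """Drift-correct, rotate the motion direction horizontal, max-project
    transversely and stack rows over time.

    ``drift`` is a (T, 2) cumulative (dx, dy) array in px (e.g. from
    ``estimate_drift``); ``direction`` is the mean motion direction.
    Intensities are clipped to the input range after the bicubic rotation.
    """
    if isinstance(stack, ImageStack):
        data = stack.data.astype(float)
        pixel_size = stack.pixel_size if pixel_size is None else pixel_size
        frame_interval = (
            stack.frame_interval if frame_interval is None else frame_interval
        )
    else:
        data = np.asarray(stack, dtype=float)
        pixel_size = 1.0 if pixel_size is None else pixel_size
        frame_interval = 1.0 if frame_interval is None else frame_interval
    d = np.asarray(direction, dtype=float)
    if np.linalg.norm(d) == 0:
        raise ValueError("direction must be non-zero")
    if drift is not None:
        data = subtract_drift(data, drift)
    angle = np.degrees(np.arctan2(d[1], d[0]))
    lo, hi = data.min(), data.max()
    rows = []
    for t in range(data.shape[0]):
        frame = data[t]
        if angle != 0.0:
            frame = ndimage.rotate(frame, angle, reshape=True, order=3, cval=lo)
            frame = np.clip(frame, lo, hi)
        rows.append(frame.max(axis=0))
    img = np.vstack(rows)
    if not np.any(img > lo):
        raise ValueError("rotation left no image content to project")
    return Kymograph(
        image=img,
        pixel_size=pixel_size,
        frame_interval=frame_interval,
        direction=(float(d[0]), float(d[1])),
    )


def kymograph_from_scenes(
    scenes, direction=(1.0, 0.0), bin_um: float = 2.0
) -> Kymograph:
    """Centroid-scatter kymograph variant: per frame, histogram the cell
    centroid positions projected on ``direction`` (counts per spatial bin),
    and stack the histograms over time.  This is the alternative reading of
    projecting nuclear centroids instead of raw intensity."""
    d = np.asarray(direction, dtype=float)
    d = d / np.linalg.norm(d)
    projs = [scene.positions @ d for scene in scenes]
    lo = min(p.min() for p in projs if len(p))
    hi = max(p.max() for p in projs if len(p))
    edges = np.arange(lo, hi + bin_um, bin_um)
    img = np.vstack([np.histogram(p, bins=edges)[0] for p in projs]).astype(float)
    return Kymograph(
        image=img,
        pixel_size=bin_um,
        frame_interval=scenes[0].geometry.frame_interval,
        direction=(float(d[0]), float(d[1])),
    )
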