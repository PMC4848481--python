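"""CSV and TIFF input/output for scenes, tracks, masks and image stacks.

Tables use the shared column set frame, time_h, cell_id, x_um, y_um,
population, marker, alive.  Images go through tifffile as multi-page
TIFF; ground truth travels as a JSON sidecar keyed by seed.
"""

from __future__ import annotations

import json
from pathlib import Path

import numpy as np
import pandas as pd
import tifffile

from .geometry import ImageStack, PointScene, SceneGeometry, TrackSet

__all__ = [
    "write_scene_csv",
    "read_scene_csv",
    "write_tracks_csv",
    "read_tracks_csv",
    "write_stack_tiff",
    "read_stack_tiff",
    "write_mask_tiff",
    "write_ground_truth_json",
    "read_ground_truth_json",
]

SCENE_COLUMNS = ["frame", "time_h", "cell_id", "x_um", "y_um", "population", "marker", "alive"]


def write_scene_csv(path, scenes: list[PointScene] | PointScene) -> None:
    if isinstance(scenes, PointScene):
        scenes = [scenes]
    df = pd.concat([s.to_dataframe() for s in scenes], ignore_index=True)
    df[SCENE_COLUMNS].to_csv(path, index=False)


def read_scene_csv(path, geometry: SceneGeometry) -> list[PointScene]:
    df = pd.read_csv(path)
    scenes = []
    for _, sub in df.groupby("frame", sort=True):
        scenes.append(
            PointScene(
                cell_id=sub["cell_id"].to_numpy(),
                x=sub["x_um"].to_numpy(),
                y=sub["y_um"].to_numpy(),
                population=sub["population"].to_numpy(),
                geometry=geometry,
                time=float(sub["time_h"].iloc[0]),
                marker=sub["marker"].to_numpy(),
                alive=sub["alive"].to_numpy(bool),
            )
        )
    return scenes


def write_tracks_csv(path, tracks: TrackSet) -> None:
    tracks.df.to_csv(path, index=False)


def read_tracks_csv(path, frame_interval: float = 1.0) -> TrackSet:
    return TrackSet(df=pd.read_csv(path), frame_interval=frame_interval)


def write_stack_tiff(path, stack: ImageStack) -> None:
    tifffile.imwrite(
        path,
        stack.data,
        metadata={
            "pixel_size_um": stack.pixel_size,
            "frame_interval_h": stack.frame_interval,
        },
    )


def read_stack_tiff(path, pixel_size: float = 1.0, frame_interval: float = 1.0) -> ImageStack:
    data = tifffile.imread(path)
    if data.ndim == 2:
        data = data[None]
    return ImageStack(data=data, pixel_size=pixel_size, frame_interval=frame_interval)


def write_mask_tiff(path, mask: np.ndarray) -> None:
    tifffile.imwrite(path, np.asarray(mask, dtype=np.uint8))


def write_ground_truth_json(path, seed: int, payload: dict) -> None:
    """Sidecar ground-truth record keyed by seed (lists are JSON-ified)."""
    def _default(o):
        if isinstance(o, np.ndarray):
            return o.tolist()
        if isinstance(o, (np.integer, np.floating)):
            return o.item()
        raise TypeError(f"not JSON-serialisable: {type(o)}")

    record = {"seed": int(seed), **payload}
    Path(path).write_text(json.dumps(record, indent=1, default=_default))


def read_ground_truth_json(path) -> dict:
    return json.loads(Path(path).read_text())
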