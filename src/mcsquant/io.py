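"""File formats and in-memory containers shared across the pipeline.

Stacks are written as multi-page TIFF with the pixel size recorded in the
resolution tags (pixels per centimeter); masks as 8-bit TIFF; tracks and
gold annotations as long-format CSV; generator parameters as YAML sidecars.
"""

from __future__ import annotations

from dataclasses import dataclass, asdict, is_dataclass
from pathlib import Path

import numpy as np
import pandas as pd
import tifffile
import yaml

from .segmentation import Mask
from .tracking import Detection, Track, TrackSet

__all__ = [
    "ImageStack",
    "write_stack",
    "read_stack",
    "write_mask",
    "read_mask",
    "tracks_to_frame",
    "frame_to_tracks",
    "write_tracks_csv",
    "read_tracks_csv",
    "write_params_yaml",
]

CHANNELS = ("puncta", "er", "mito", "membrane")


@dataclass
class ImageStack:
    """Multi-frame, multi-channel intensity data, axes (t, c, row, col)."""

    data: np.ndarray
    pixel_size: float  # nm/px
    channel_names: tuple[str, ...] = CHANNELS

    def __post_init__(self):
        self.data = np.asarray(self.data)
        if self.data.ndim != 4:
            raise ValueError("stack must have axes (t, c, row, col)")
        if self.data.shape[1] != len(self.channel_names):
            raise ValueError("channel_names length must match axis 1")

    @property
    def n_frames(self) -> int:
        return self.data.shape[0]

    def channel(self, name: str) -> np.ndarray:
        """(t, row, col) view of one named channel."""
        return self.data[:, self.channel_names.index(name)]


def _resolution(pixel_size_nm: float):
    # pixels per centimeter from nm/px
    px_per_cm = 1e7 / pixel_size_nm
    return (px_per_cm, px_per_cm, "CENTIMETER")


def write_stack(path, stack: ImageStack) -> None:
    res = _resolution(stack.pixel_size)
    tifffile.imwrite(
        path, stack.data.astype(np.float32),
        photometric="minisblack",
        resolution=res[:2], resolutionunit=res[2],
        metadata={"axes": "TCYX", "channels": list(stack.channel_names)},
    )


def read_stack(path, channel_names: tuple[str, ...] = CHANNELS) -> ImageStack:
    with tifffile.TiffFile(path) as tf:
        data = tf.asarray()
        page = tf.pages[0]
        xres = page.tags["XResolution"].value
        px_per_cm = xres[0] / xres[1]
        pixel_size = 1e7 / px_per_cm
    if data.ndim == 3:  # single frame
        data = data[None]
    return ImageStack(data, pixel_size, channel_names)


def write_mask(path, mask: Mask) -> None:
    res = _resolution(mask.pixel_size)
    tifffile.imwrite(path, mask.pixels.astype(np.uint8) * 255,
                     resolution=res[:2], resolutionunit=res[2])


def read_mask(path) -> Mask:
    with tifffile.TiffFile(path) as tf:
        data = tf.asarray()
        xres = tf.pages[0].tags["XResolution"].value
        pixel_size = 1e7 / (xres[0] / xres[1])
    return Mask(data > 0, pixel_size)


def tracks_to_frame(ts: TrackSet) -> pd.DataFrame:
    rows = []
    for t in ts.tracks:
        for d in t.detections:
            rows.append({
                "cell_id": t.cell_id, "track_id": t.track_id,
                "frame": d.frame_index,
                "row_px": d.centroid[0], "col_px": d.centroid[1],
                "intensity": d.intensity,
                "associated_truth": t.associated_truth,
            })
    return pd.DataFrame(rows, columns=["cell_id", "track_id", "frame",
                                       "row_px", "col_px", "intensity",
                                       "associated_truth"])


def frame_to_tracks(df: pd.DataFrame, pixel_size: float,
                    n_frames: int | None = None) -> TrackSet:
    tracks = []
    for (cell, tid), g in df.groupby(["cell_id", "track_id"], sort=True):
        g = g.sort_values("frame")
        dets = [Detection(int(r.frame), (float(r.row_px), float(r.col_px)),
                          float(getattr(r, "intensity", 0.0)))
                for r in g.itertuples()]
        assoc = None
        if "associated_truth" in g and g["associated_truth"].notna().all():
            assoc = bool(g["associated_truth"].iloc[0])
        tracks.append(Track(int(tid), dets, cell_id=str(cell),
                            associated_truth=assoc))
    if n_frames is None:
        n_frames = int(df["frame"].max()) + 1 if len(df) else 0
    return TrackSet(tracks, pixel_size=pixel_size, n_frames=n_frames)


def write_tracks_csv(path, ts: TrackSet) -> None:
    tracks_to_frame(ts).to_csv(path, index=False)


def read_tracks_csv(path, pixel_size: float,
                    n_frames: int | None = None) -> TrackSet:
    return frame_to_tracks(pd.read_csv(path), pixel_size, n_frames)


def write_params_yaml(path, params) -> None:
    obj = asdict(params) if is_dataclass(params) else dict(params)
    for k, v in obj.items():
        if isinstance(v, tuple):
            obj[k] = list(v)
    Path(path).write_text(yaml.safe_dump(obj, sort_keys=False))
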