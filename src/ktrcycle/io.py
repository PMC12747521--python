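"""Containers and file I/O for image stacks, tables, and configuration.

The package moves data around in two shapes: :class:`ImageStack` for pixel
data with physical calibration, and tidy :class:`pandas.DataFrame` tables for
everything derived from pixels (detections, tracks, traces, annotations).
Stacks round-trip through multi-page TIFF with a JSON metadata sidecar in the
ImageDescription tag; tables round-trip through plain CSV.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
import tifffile
import yaml

__all__ = [
    "ImageStack",
    "LabelMap",
    "save_stack",
    "load_stack",
    "save_labelmap",
    "load_labelmap",
    "save_table",
    "load_table",
    "load_config",
    "save_config",
]


@dataclass
class ImageStack:
    """Multichannel time-lapse (or single-frame) pixel data with calibration.

    Parameters
    ----------
    pixels
        Array indexed ``(time, channel, row, column)``.
    pixel_size_um
        Lateral calibration in micrometres per pixel.
    frame_interval_min
        Acquisition interval in minutes (0 for single-frame fixed images).
    channel_roles
        Mapping from role name (``"h2b"``, ``"cdk2"``, ...) to channel index.
    """

    pixels: np.ndarray
    pixel_size_um: float
    frame_interval_min: float
    channel_roles: dict = field(default_factory=dict)

    def __post_init__(self):
        self.pixels = np.asarray(self.pixels)
        if self.pixels.ndim == 3:  # single frame, (C, Y, X)
            self.pixels = self.pixels[None]
        if self.pixels.ndim != 4:
            raise ValueError("pixels must be (T, C, Y, X) or (C, Y, X)")
        if self.pixel_size_um <= 0:
            raise ValueError("pixel_size_um must be positive")

    @property
    def n_frames(self) -> int:
        return self.pixels.shape[0]

    @property
    def n_channels(self) -> int:
        return self.pixels.shape[1]

    @property
    def shape_yx(self) -> tuple:
        return self.pixels.shape[2:]

    def frame(self, t: int, role: str) -> np.ndarray:
        """Return one 2D frame by time index and channel role."""
        return self.pixels[t, self.channel_roles[role]]

    def times_h(self) -> np.ndarray:
        """Frame times in hours from movie start."""
        return np.arange(self.n_frames) * self.frame_interval_min / 60.0


@dataclass
class LabelMap:
    """Per-frame integer nuclear segmentation; 0 is background.

    ``provenance`` records which nuclear stain produced the map
    (``"live_h2b"`` or ``"fixed_hoechst"``).
    """

    labels: np.ndarray
    frame_index: int = 0
    provenance: str = "live_h2b"

    def __post_init__(self):
        self.labels = np.asarray(self.labels)
        if self.labels.ndim != 2:
            raise ValueError("labels must be 2D")

    @property
    def n_labels(self) -> int:
        return int(self.labels.max())


def save_stack(stack: ImageStack, path) -> None:
    """Write a stack to multi-page TIFF with JSON calibration metadata."""
    meta = {
        "pixel_size_um": stack.pixel_size_um,
        "frame_interval_min": stack.frame_interval_min,
        "channel_roles": stack.channel_roles,
        "shape": list(stack.pixels.shape),
    }
    tifffile.imwrite(
        str(path),
        np.asarray(stack.pixels, dtype=np.float32),
        photometric="minisblack",
        description=json.dumps(meta),
    )


def load_stack(path) -> ImageStack:
    """Read a stack written by :func:`save_stack`."""
    with tifffile.TiffFile(str(path)) as tf:
        pixels = tf.asarray()
        desc = tf.pages[0].description
    meta = json.loads(desc)
    pixels = pixels.reshape(meta["shape"])
    return ImageStack(
        pixels=pixels,
        pixel_size_um=meta["pixel_size_um"],
        frame_interval_min=meta["frame_interval_min"],
        channel_roles=meta["channel_roles"],
    )


def save_labelmap(labelmap: LabelMap, path) -> None:
    """Write a label map as 16-bit TIFF (metadata in the description tag)."""
    if labelmap.labels.max() > np.iinfo(np.uint16).max:
        raise ValueError("more than 65535 labels; cannot store as 16-bit")
    meta = {"frame_index": labelmap.frame_index,
            "provenance": labelmap.provenance}
    tifffile.imwrite(str(path), labelmap.labels.astype(np.uint16),
                     description=json.dumps(meta))


def load_labelmap(path) -> LabelMap:
    with tifffile.TiffFile(str(path)) as tf:
        labels = tf.asarray().astype(np.int32)
        meta = json.loads(tf.pages[0].description)
    return LabelMap(labels=labels, frame_index=meta["frame_index"],
                    provenance=meta["provenance"])


def save_table(df: pd.DataFrame, path) -> None:
    df.to_csv(path, index=False)


def load_table(path) -> pd.DataFrame:
    return pd.read_csv(path)


def load_config(path) -> dict:
    with open(path) as fh:
        return yaml.safe_load(fh)


def save_config(cfg: dict, path) -> None:
    Path(path).write_text(yaml.safe_dump(cfg, sort_keys=False))
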