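"""3D image containers and TIFF round trip.

Arrays are indexed (z, y, x), 0-based, with an optional leading channel
axis; physical voxel sizes and the micrometre offset of voxel (0, 0, 0)
are carried explicitly so centroids measured in an image can be mapped
back to simulation/world coordinates.
"""
from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import tifffile


@dataclass
class VoxelImage:
    """Multi-channel 3D intensity stack. ``data`` is (C, Z, Y, X) or
    (Z, Y, X); ``voxel_size`` and ``origin`` are (z, y, x) in um."""

    data: np.ndarray
    voxel_size: tuple[float, float, float]
    channel_names: list[str] = field(default_factory=list)
    origin: tuple[float, float, float] = (0.0, 0.0, 0.0)

    def __post_init__(self) -> None:
        if min(self.voxel_size) <= 0:
            raise ValueError("voxel sizes must be > 0")
        if self.data.ndim not in (3, 4):
            raise ValueError("data must be (Z, Y, X) or (C, Z, Y, X)")

    @property
    def n_channels(self) -> int:
        return 1 if self.data.ndim == 3 else self.data.shape[0]

    def channel(self, key: int | str) -> "VoxelImage":
        """Single-channel view (by index or name)."""
        if self.data.ndim == 3:
            if key in (0, *self.channel_names):
                return self
            raise KeyError(key)
        idx = self.channel_names.index(key) if isinstance(key, str) else key
        return VoxelImage(self.data[idx], self.voxel_size,
                          [self.channel_names[idx]] if self.channel_names else [],
                          self.origin)


@dataclass
class LabelImage:
    """3D integer label stack; 0 is background."""

    labels: np.ndarray
    voxel_size: tuple[float, float, float]
    origin: tuple[float, float, float] = (0.0, 0.0, 0.0)

    def __post_init__(self) -> None:
        if min(self.voxel_size) <= 0:
            raise ValueError("voxel sizes must be > 0")
        if self.labels.ndim != 3:
            raise ValueError("labels must be (Z, Y, X)")
        if self.labels.min() < 0:
            raise ValueError("labels must be non-negative")

    @property
    def voxel_volume(self) -> float:
        return float(np.prod(self.voxel_size))

    @property
    def ids(self) -> np.ndarray:
        u = np.unique(self.labels)
        return u[u > 0]


def _meta(obj) -> str:
    return json.dumps({
        "voxel_size": list(obj.voxel_size),
        "origin": list(obj.origin),
        "channel_names": getattr(obj, "channel_names", []),
    })


def write_tiff(image: VoxelImage | LabelImage, path: str | Path) -> None:
    """Write a stack as TIFF; voxel size/origin go into the description
    tag so :func:`read_tiff` / :func:`read_label_tiff` can restore them."""
    if isinstance(image, LabelImage):
        data = image.labels.astype(np.uint16)
    else:
        data = image.data.astype(np.float32)
    tifffile.imwrite(str(path), data, description=_meta(image))


def _read(path: str | Path) -> tuple[np.ndarray, dict]:
    with tifffile.TiffFile(str(path)) as tf:
        data = tf.asarray()
        desc = tf.pages[0].description or "{}"
    try:
        meta = json.loads(desc)
    except json.JSONDecodeError:
        meta = {}
    return data, meta


def read_tiff(path: str | Path) -> VoxelImage:
    data, meta = _read(path)
    return VoxelImage(data=data,
                      voxel_size=tuple(meta.get("voxel_size", (1., 1., 1.))),
                      channel_names=list(meta.get("channel_names", [])),
                      origin=tuple(meta.get("origin", (0., 0., 0.))))


def read_label_tiff(path: str | Path) -> LabelImage:
    data, meta = _read(path)
    return LabelImage(labels=data.astype(np.int32),
                      voxel_size=tuple(meta.get("voxel_size", (1., 1., 1.))),
                      origin=tuple(meta.get("origin", (0., 0., 0.))))
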