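"""Stack container and TIFF/CSV/JSON readers and writers.

Conventions used throughout the package: axis order ``(channel, z, y, x)``,
0-based coordinates, half-open intervals, label 0 reserved for background
and for voxels left unassigned after a merge event.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path
from typing import Optional, Union

import numpy as np
import tifffile

__all__ = ["MultiChannelStack", "read_stack", "write_stack",
           "write_labels", "read_labels"]

PathLike = Union[str, Path]


@dataclass
class MultiChannelStack:
    """A multichannel 3D fluorescence stack, axes ``(channel, z, y, x)``."""

    data: np.ndarray
    channel_names: list[str] = field(default_factory=list)
    segmentation_channel: int = 0
    voxel_size_zyx: Optional[tuple[float, float, float]] = None

    def __post_init__(self) -> None:
        if self.data.ndim == 3:  # single channel
            self.data = self.data[None]
        if self.data.ndim != 4:
            raise ValueError("stack data must be (channel, z, y, x)")
        if not self.channel_names:
            self.channel_names = [f"ch{i}" for i in range(self.data.shape[0])]

    @property
    def n_channels(self) -> int:
        return self.data.shape[0]

    @property
    def shape_zyx(self) -> tuple[int, int, int]:
        return self.data.shape[1:]

    def channel(self, index: int) -> np.ndarray:
        return self.data[index]

    @property
    def segmentation(self) -> np.ndarray:
        return self.data[self.segmentation_channel]


def read_stack(path: PathLike) -> MultiChannelStack:
    """Read a TIFF/OME-TIFF into a :class:`MultiChannelStack`.

    Accepts 2D (single slice), 3D (z, y, x), 4D (c, z, y, x or z, c, y, x
    per OME axes metadata) and 5D with a singleton time axis.
    """
    path = Path(path)
    try:
        with tifffile.TiffFile(path) as tf:
            arr = tf.asarray()
            axes = tf.series[0].axes if tf.series else ""
    except (tifffile.TiffFileError, ValueError) as e:
        raise ValueError(f"{path} is not a readable TIFF image: {e}") from e
    if arr.ndim > 5:
        raise ValueError(f"unsupported dimensionality {arr.ndim} in {path}")
    if arr.ndim == 5:
        if "T" in axes and arr.shape[axes.index("T")] == 1:
            arr = np.squeeze(arr, axis=axes.index("T"))
            axes = axes.replace("T", "")
        else:
            raise ValueError(f"unsupported 5D layout {axes!r} in {path}")
    if arr.ndim == 2:
        arr = arr[None, None]
    elif arr.ndim == 3:
        arr = arr[None]
    elif arr.ndim == 4 and axes[:2] == "ZC":
        arr = np.moveaxis(arr, 1, 0)
    return MultiChannelStack(data=arr)


def write_stack(stack: MultiChannelStack, path: PathLike) -> None:
    """Write as OME-TIFF with CZYX axes so round trips preserve layout."""
    tifffile.imwrite(Path(path), stack.data, ome=True,
                     metadata={"axes": "CZYX"})


def write_labels(result, path: PathLike) -> None:
    """Write a segmentation result as 16-bit label TIFF plus JSON sidecar.

    The sidecar (``<path>.json``) stores trajectories, merge events and the
    parameters used, so the full result can be re-validated on read-back.
    """
    path = Path(path)
    labels = result.labels
    if labels.max() > 65535:
        raise ValueError("more than 65535 labels cannot be stored as uint16")
    tifffile.imwrite(path, labels.astype(np.uint16))
    sidecar = {
        "params": result.params.to_dict(),
        "trajectories": [t.to_dict() for t in result.trajectories],
        "merge_events": [m.to_dict() for m in result.merge_events],
    }
    path.with_suffix(path.suffix + ".json").write_text(
        json.dumps(sidecar, indent=1))


def read_labels(path: PathLike):
    """Read back a label TIFF and its sidecar; returns (labels, sidecar dict)."""
    path = Path(path)
    labels = tifffile.imread(path)
    sidecar_path = path.with_suffix(path.suffix + ".json")
    sidecar = json.loads(sidecar_path.read_text()) if sidecar_path.exists() else None
    return labels, sidecar
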