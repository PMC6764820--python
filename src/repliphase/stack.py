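"""Multichannel, time-resolved image stacks with physical calibration.

The :class:`ImageStack` is the common substrate of every imaging stage:
a float array with axes ``(t, c, z, y, x)`` (volumetric movies) or
``(t, c, y, x)`` (single-plane movies), a voxel size in micrometres per
spatial axis, channel names, and the frame interval in seconds.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import tifffile


@dataclass
class ImageStack:
    """A calibrated multichannel time-lapse image stack.

    Parameters
    ----------
    data
        Array of shape ``(t, c, z, y, x)`` or ``(t, c, y, x)`` with
        non-negative, finite intensities.
    voxel_size
        Physical size of one voxel in µm, ordered like the spatial axes
        (``(z, y, x)`` for volumetric data, ``(y, x)`` otherwise).
    channel_names
        One name per channel; defaults to ``channel_0`` ... style names.
    frame_interval
        Seconds between consecutive frames.
    """

    data: np.ndarray
    voxel_size: tuple[float, ...]
    channel_names: list[str] = field(default_factory=list)
    frame_interval: float = 1.0

    def __post_init__(self) -> None:
        self.data = np.asarray(self.data)
        if self.data.ndim not in (4, 5):
            raise ValueError(
                f"expected (t, c, z, y, x) or (t, c, y, x) data, got ndim={self.data.ndim}"
            )
        n_spatial = self.data.ndim - 2
        self.voxel_size = tuple(float(v) for v in self.voxel_size)
        if len(self.voxel_size) != n_spatial:
            raise ValueError(
                f"voxel_size has {len(self.voxel_size)} entries for {n_spatial} spatial axes"
            )
        if any(v <= 0 for v in self.voxel_size):
            raise ValueError("voxel_size must be positive")
        if not np.all(np.isfinite(self.data)):
            raise ValueError("intensities must be finite")
        if not self.channel_names:
            self.channel_names = [f"channel_{i}" for i in range(self.data.shape[1])]
        if len(self.channel_names) != self.data.shape[1]:
            raise ValueError("channel_names length does not match channel axis")

    # -- basic geometry -------------------------------------------------
    @property
    def n_frames(self) -> int:
        return self.data.shape[0]

    @property
    def n_channels(self) -> int:
        return self.data.shape[1]

    @property
    def is_volumetric(self) -> bool:
        return self.data.ndim == 5

    @property
    def axes(self) -> str:
        return "TCZYX" if self.is_volumetric else "TCYX"

    def frame(self, t: int, c: int) -> np.ndarray:
        """Single-channel volume (or plane) at frame ``t``."""
        return self.data[t, c]

    def times(self) -> np.ndarray:
        """Acquisition time of each frame in seconds."""
        return np.arange(self.n_frames) * self.frame_interval

    # -- IO -------------------------------------------------------------
    def to_tiff(self, path) -> None:
        """Write as OME-TIFF with pixel-size and time-interval metadata."""
        meta = {"axes": self.axes, "TimeIncrement": self.frame_interval,
                "TimeIncrementUnit": "s",
                "Channel": {"Name": list(self.channel_names)}}
        if self.is_volumetric:
            meta["PhysicalSizeZ"], meta["PhysicalSizeY"], meta["PhysicalSizeX"] = self.voxel_size
        else:
            meta["PhysicalSizeY"], meta["PhysicalSizeX"] = self.voxel_size
        for key in ("PhysicalSizeZ", "PhysicalSizeY", "PhysicalSizeX"):
            if key in meta:
                meta[key + "Unit"] = "µm"
        tifffile.imwrite(path, np.asarray(self.data, dtype=np.float32), ome=True,
                         metadata=meta)

    @classmethod
    def from_tiff(cls, path) -> "ImageStack":
        """Read an OME-TIFF written by :meth:`to_tiff` (or compatible)."""
        with tifffile.TiffFile(path) as tf:
            series = tf.series[0]
            data = series.asarray()
            axes = series.axes.upper()
            ome = tf.ome_metadata
        # Normalize to TCZYX / TCYX ordering; tolerate missing singleton axes.
        order = "TCZYX" if "Z" in axes else "TCYX"
        for ax in order:
            if ax not in axes:
                data = np.expand_dims(data, 0)
                axes = ax + axes
        perm = [axes.index(ax) for ax in order]
        data = np.transpose(data, perm)
        voxel_size, channel_names, interval = _parse_ome(ome, order)
        if voxel_size is None:
            voxel_size = (1.0,) * (len(order) - 2)
        return cls(data=data, voxel_size=voxel_size,
                   channel_names=channel_names or [], frame_interval=interval)


def _parse_ome(ome: str | None, order: str):
    """Pull voxel size, channel names and frame interval out of OME-XML."""
    if not ome:
        return None, None, 1.0
    import re

    def attr(name):
        m = re.search(rf'{name}="([^"]+)"', ome)
        return m.group(1) if m else None

    sizes = []
    for ax in ("Z", "Y", "X"):
        if ax in order:
            v = attr(f"PhysicalSize{ax}")
            sizes.append(float(v) if v else 1.0)
    names = re.findall(r'<Channel[^>]*Name="([^"]+)"', ome)
    interval = attr("TimeIncrement")
    return tuple(sizes), names, float(interval) if interval else 1.0
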