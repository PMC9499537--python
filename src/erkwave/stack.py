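"""Calibrated multi-channel time-lapse image stacks (OME-TIFF backed)."""

from __future__ import annotations

import xml.etree.ElementTree as ET
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import tifffile


class StackError(IOError):
    """Raised when a stack file cannot be read or is inconsistent."""


@dataclass
class FrameStack:
    """A (frame, channel, row, col) image array with physical calibration.

    Attributes
    ----------
    data : float32 array of shape (T, C, H, W); intensities non-negative.
    channels : channel names, length C (e.g. ["H2B", "KTR", "CASP"]).
    pixel_size : µm per pixel.
    frame_interval : minutes per frame.
    """

    data: np.ndarray
    channels: list[str]
    pixel_size: float
    frame_interval: float
    meta: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        self.data = np.asarray(self.data)
        if self.data.ndim != 4:
            raise ValueError(f"expected (T, C, H, W) data, got shape {self.data.shape}")
        if len(self.channels) != self.data.shape[1]:
            raise ValueError("channel-name count does not match data")
        if self.pixel_size <= 0 or self.frame_interval <= 0:
            raise ValueError("pixel_size and frame_interval must be positive")

    @property
    def n_frames(self) -> int:
        return self.data.shape[0]

    @property
    def shape_px(self) -> tuple[int, int]:
        return self.data.shape[2], self.data.shape[3]

    def channel(self, name: str) -> np.ndarray:
        """Return the (T, H, W) sub-stack for a named channel."""
        try:
            idx = self.channels.index(name)
        except ValueError:
            raise KeyError(f"no channel named {name!r}; have {self.channels}") from None
        return self.data[:, idx]

    def save(self, path: str | Path) -> None:
        """Write an OME-TIFF with channel names and calibration metadata."""
        tifffile.imwrite(
            str(path),
            self.data.astype(np.float32),
            ome=True,
            metadata={
                "axes": "TCYX",
                "Channel": {"Name": list(self.channels)},
                "PhysicalSizeX": self.pixel_size,
                "PhysicalSizeXUnit": "µm",
                "PhysicalSizeY": self.pixel_size,
                "PhysicalSizeYUnit": "µm",
                "TimeIncrement": self.frame_interval,
                "TimeIncrementUnit": "min",
            },
        )

    @classmethod
    def load(cls, path: str | Path) -> "FrameStack":
        """Read an OME-TIFF written by :meth:`save` (or compatible)."""
        path = Path(path)
        if not path.exists():
            raise StackError(f"stack file not found: {path}")
        try:
            with tifffile.TiffFile(str(path)) as tf:
                series = tf.series[0]
                data = series.asarray()
                axes = series.axes
                ome = tf.ome_metadata
        except Exception as exc:  # corrupt / non-TIFF input
            raise StackError(f"cannot read stack {path}: {exc}") from exc
        # normalise axis order to TCYX
        if axes in ("TCYX", "CTYX", "TYX", "CYX", "YX"):
            if axes == "YX":
                data = data[None, None]
            elif axes == "TYX":
                data = data[:, None]
            elif axes == "CYX":
                data = data[None]
            elif axes == "CTYX":
                data = np.swapaxes(data, 0, 1)
        else:
            raise StackError(f"unsupported axis layout {axes!r} in {path}")
        channels, px, dt = _parse_ome(ome, n_channels=data.shape[1])
        return cls(
            data=np.asarray(data, dtype=np.float32),
            channels=channels,
            pixel_size=px,
            frame_interval=dt,
        )


def _parse_ome(ome: str | None, n_channels: int) -> tuple[list[str], float, float]:
    channels = [f"C{i}" for i in range(n_channels)]
    px, dt = 1.0, 1.0
    if not ome:
        return channels, px, dt
    try:
        root = ET.fromstring(ome)
    except ET.ParseError:
        return channels, px, dt
    ns = {"ome": root.tag.split("}")[0].strip("{")} if "}" in root.tag else {}
    pixels = root.find(".//ome:Pixels" if ns else ".//Pixels", ns)
    if pixels is not None:
        px = float(pixels.get("PhysicalSizeX", px))
        dt = float(pixels.get("TimeIncrement", dt))
        names = [
            ch.get("Name")
            for ch in pixels.findall("ome:Channel" if ns else "Channel", ns)
        ]
        if names and all(n is not None for n in names) and len(names) == n_channels:
            channels = list(names)  # type: ignore[arg-type]
    return channels, px, dt
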