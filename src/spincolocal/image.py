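"""In-memory containers for multichannel fluorescence image fields and ROI masks.

All physical quantities are in micrometers. Pixel indices are 0-based with the
origin at the top-left corner; a pixel's physical coordinate is its index times
``pixel_size_um``.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Mapping

import numpy as np

__all__ = ["ImageField", "ROIMask"]


@dataclass
class ImageField:
    """A multichannel 2D raster with a known physical pixel size.

    Parameters
    ----------
    channels
        Mapping of channel name to a 2D non-negative float/int array. All
        channels must share the same shape.
    pixel_size_um
        Edge length of one pixel in micrometers (> 0).
    field_id
        Identifier used in provenance records and output tables.
    """

    channels: Mapping[str, np.ndarray]
    pixel_size_um: float
    field_id: str = "field"

    def __post_init__(self) -> None:
        if self.pixel_size_um <= 0:
            raise ValueError("pixel_size_um must be > 0")
        if not self.channels:
            raise ValueError("ImageField requires at least one channel")
        shapes = {np.asarray(a).shape for a in self.channels.values()}
        if len(shapes) != 1:
            raise ValueError(f"channel shapes differ: {sorted(shapes)}")
        (shape,) = shapes
        if len(shape) != 2:
            raise ValueError("channels must be 2D rasters")
        chans = {}
        for name, arr in self.channels.items():
            a = np.asarray(arr, dtype=float)
            if not np.all(np.isfinite(a)):
                raise ValueError(f"channel {name!r} contains non-finite values")
            if a.min() < 0:
                raise ValueError(f"channel {name!r} contains negative intensities")
            chans[name] = a
        self.channels = chans

    @property
    def shape(self) -> tuple[int, int]:
        return next(iter(self.channels.values())).shape

    @property
    def channel_names(self) -> list[str]:
        return list(self.channels)

    def area_um2(self) -> float:
        """Physical area of the full field in µm²."""
        h, w = self.shape
        return h * w * self.pixel_size_um**2


@dataclass
class ROIMask:
    """A binary region-of-interest mask aligned to an :class:`ImageField`.

    ``label`` typically names a dorsal-horn stratum (``superficial_dorsal_horn``
    or ``deep_dorsal_horn``) but any string is accepted.
    """

    label: str
    mask: np.ndarray
    pixel_size_um: float

    def __post_init__(self) -> None:
        self.mask = np.asarray(self.mask, dtype=bool)
        if self.mask.ndim != 2:
            raise ValueError("ROI mask must be 2D")
        if self.pixel_size_um <= 0:
            raise ValueError("pixel_size_um must be > 0")
        if not self.mask.any():
            raise ValueError(f"ROI {self.label!r} has zero area")

    @property
    def area_um2(self) -> float:
        return float(self.mask.sum()) * self.pixel_size_um**2

    @classmethod
    def full_field(cls, field: ImageField, label: str = "full_field") -> "ROIMask":
        return cls(label=label, mask=np.ones(field.shape, dtype=bool),
                   pixel_size_um=field.pixel_size_um)

    @classmethod
    def rectangle(cls, shape: tuple[int, int], pixel_size_um: float,
                  row_slice: slice, col_slice: slice, label: str = "custom") -> "ROIMask":
        mask = np.zeros(shape, dtype=bool)
        mask[row_slice, col_slice] = True
        return cls(label=label, mask=mask, pixel_size_um=pixel_size_um)

    def contains(self, row: int, col: int) -> bool:
        h, w = self.mask.shape
        if not (0 <= row < h and 0 <= col < w):
            return False
        return bool(self.mask[row, col])
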