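"""Detection and size filtering of fluorescent puncta, and cluster densities.

The procedure mirrors the common particle-analysis workflow for synaptic
cluster quantification: intensity thresholding of one channel, 8-connected
component labeling, conversion of each component to a punctum with physical
area and equivalent circular diameter, and an inclusive size-retention window
(default 0.2–3.0 µm equivalent diameter). Densities are objects per µm² with
objects assigned to an ROI by their centroid.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Iterator, Sequence

import numpy as np
from skimage.filters import threshold_otsu, threshold_triangle
from skimage.measure import label as cc_label

from .image import ImageField, ROIMask

__all__ = [
    "Punctum",
    "PunctaSet",
    "detect_puncta",
    "filter_by_size",
    "cluster_density",
]

THRESHOLD_METHODS = ("otsu", "triangle", "fixed")


@dataclass
class Punctum:
    """One connected bright object: a receptor/scaffold cluster or FISH dot."""

    id: int
    channel: str
    rows: np.ndarray  # pixel row indices, 8-connected component
    cols: np.ndarray
    pixel_size_um: float

    def __post_init__(self) -> None:
        self.rows = np.asarray(self.rows, dtype=np.intp)
        self.cols = np.asarray(self.cols, dtype=np.intp)
        if self.rows.size == 0 or self.rows.size != self.cols.size:
            raise ValueError("punctum needs a non-empty, consistent pixel set")

    @property
    def n_pixels(self) -> int:
        return int(self.rows.size)

    @property
    def area_um2(self) -> float:
        return self.n_pixels * self.pixel_size_um**2

    @property
    def equivalent_diameter_um(self) -> float:
        """Diameter of the circle with the same area, 2·sqrt(A/π)."""
        return 2.0 * np.sqrt(self.area_um2 / np.pi)

    @property
    def centroid_px(self) -> tuple[float, float]:
        """(row, col) centroid in pixel coordinates."""
        return float(self.rows.mean()), float(self.cols.mean())

    @property
    def centroid_um(self) -> tuple[float, float]:
        """(x, y) centroid in µm; x along columns, y along rows."""
        r, c = self.centroid_px
        return c * self.pixel_size_um, r * self.pixel_size_um


@dataclass
class PunctaSet:
    """All puncta detected in one channel of one field, plus provenance."""

    field_id: str
    channel: str
    shape: tuple[int, int]
    pixel_size_um: float
    puncta: list[Punctum] = field(default_factory=list)
    provenance: dict = field(default_factory=dict)

    def __len__(self) -> int:
        return len(self.puncta)

    def __iter__(self) -> Iterator[Punctum]:
        return iter(self.puncta)

    def replace(self, puncta: Sequence[Punctum], **prov) -> "PunctaSet":
        return PunctaSet(
            field_id=self.field_id,
            channel=self.channel,
            shape=self.shape,
            pixel_size_um=self.pixel_size_um,
            puncta=list(puncta),
            provenance={**self.provenance, **prov},
        )

    def label_image(self) -> np.ndarray:
        """Raster with each pixel carrying its punctum id (0 = background)."""
        out = np.zeros(self.shape, dtype=np.int32)
        for p in self.puncta:
            out[p.rows, p.cols] = p.id
        return out


def _threshold(img: np.ndarray, method: str, fixed_value: float | None) -> float:
    if method == "otsu":
        return float(threshold_otsu(img))
    if method == "triangle":
        return float(threshold_triangle(img))
    if method == "fixed":
        if fixed_value is None:
            raise ValueError("threshold_method='fixed' requires fixed_value")
        return float(fixed_value)
    raise ValueError(f"unknown threshold_method {method!r}; choose from {THRESHOLD_METHODS}")


def detect_puncta(
    field: ImageField,
    channel: str,
    threshold_method: str = "otsu",
    fixed_value: float | None = None,
) -> PunctaSet:
    """Threshold one channel and label 8-connected components as puncta.

    No size filtering is applied here; apply :func:`filter_by_size` afterwards
    for the immunohistochemistry workflow (RNAscope dot counting uses the raw
    detection). A constant image cannot support a data-driven threshold; in
    that case an empty set is returned with ``provenance['constant_image']``
    set instead of raising.
    """
    if channel not in field.channels:
        raise KeyError(f"channel {channel!r} not in field (has {field.channel_names})")
    img = field.channels[channel]
    prov = {"threshold_method": threshold_method}
    if img.max() == img.min():
        if threshold_method != "fixed":
            prov["constant_image"] = True
            return PunctaSet(field.field_id, channel, img.shape, field.pixel_size_um,
                             [], prov)
    thr = _threshold(img, threshold_method, fixed_value)
    prov["threshold_value"] = thr
    mask = img > thr
    labels = cc_label(mask, connectivity=2)  # 8-connectivity
    puncta: list[Punctum] = []
    for lab in range(1, labels.max() + 1):
        rows, cols = np.nonzero(labels == lab)
        puncta.append(Punctum(id=lab, channel=channel, rows=rows, cols=cols,
                              pixel_size_um=field.pixel_size_um))
    return PunctaSet(field.field_id, channel, img.shape, field.pixel_size_um,
                     puncta, prov)


def filter_by_size(
    puncta: PunctaSet,
    min_diameter_um: float = 0.2,
    max_diameter_um: float = 3.0,
) -> PunctaSet:
    """Retain puncta with equivalent diameter in [min, max] µm, ids preserved.

    Exclusion is strict outside the bounds (objects smaller than the minimum
    or larger than the maximum are dropped; ties are kept), so the operation
    is idempotent and monotone in the bounds.
    """
    if min_diameter_um <= 0 or max_diameter_um <= 0:
        raise ValueError("size bounds must be positive")
    if min_diameter_um >= max_diameter_um:
        raise ValueError("min_diameter_um must be < max_diameter_um")
    kept = [p for p in puncta
            if min_diameter_um <= p.equivalent_diameter_um <= max_diameter_um]
    return puncta.replace(kept, size_filter_um=(min_diameter_um, max_diameter_um))


def centroid_in_roi(p: Punctum, roi: ROIMask) -> bool:
    r, c = p.centroid_px
    return roi.contains(int(round(r)), int(round(c)))


def cluster_density(puncta: PunctaSet, roi: ROIMask) -> float:
    """Puncta per µm²: count of centroids inside the ROI over the ROI area.

    Counting by centroid avoids double counting objects straddling an ROI
    boundary, so density is additive over disjoint ROIs.
    """
    if roi.mask.shape != puncta.shape:
        raise ValueError("ROI mask shape does not match the puncta field")
    n = sum(centroid_in_roi(p, roi) for p in puncta)
    return n / roi.area_um2
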