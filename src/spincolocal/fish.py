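"""RNAscope-style cell calling: dot counting within expanded nuclear areas.

A cell is called positive for a marker when three or more fluorescent dots
fall within an area 2 µm larger than its nucleus. Marker dots are detected
with the plain puncta detector (no size filter — single-transcript dots are
small) and each dot is assigned by its centroid; a dot landing in two cells'
overlapping expanded areas goes to the cell with the nearer nucleus centroid
(tie broken toward the lower cell id). Background staining, which differs
between fluorophores, is handled only through the ≥3-dot rule — no background
subtraction is performed.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from skimage.filters import threshold_otsu
from skimage.measure import label as cc_label

from .colocal import dilate_pixel_set
from .image import ImageField, ROIMask
from .puncta import PunctaSet, detect_puncta

__all__ = [
    "Nucleus",
    "CellCall",
    "segment_nuclei",
    "expand_nucleus",
    "call_positive",
    "assign_dots_to_cells",
    "quantify_fish_field",
    "coexpression_fractions",
]


@dataclass
class Nucleus:
    cell_id: int
    rows: np.ndarray
    cols: np.ndarray

    @property
    def centroid_px(self) -> tuple[float, float]:
        return float(self.rows.mean()), float(self.cols.mean())


@dataclass
class CellCall:
    """Per-cell marker dot counts and positivity within the expanded area."""

    cell_id: int
    region: str
    nucleus_rows: np.ndarray
    nucleus_cols: np.ndarray
    expanded_rows: np.ndarray
    expanded_cols: np.ndarray
    counts: dict[str, int] = field(default_factory=dict)
    positive: dict[str, bool] = field(default_factory=dict)
    section_id: str | None = None


def segment_nuclei(
    field: ImageField,
    nuclear_channel: str = "dapi",
    min_area_um2: float = 3.0,
) -> list[Nucleus]:
    """Threshold the nuclear stain and label connected components as nuclei.

    Touching nuclei merge into one component under plain labeling; the
    simulator places disjoint nuclei so this is adequate for its fields.
    Components smaller than ``min_area_um2`` are discarded as debris.
    """
    img = field.channels[nuclear_channel]
    if img.max() == img.min():
        return []
    thr = threshold_otsu(img)
    labels = cc_label(img > thr, connectivity=2)
    min_px = min_area_um2 / field.pixel_size_um**2
    nuclei = []
    cid = 0
    for lab in range(1, labels.max() + 1):
        rows, cols = np.nonzero(labels == lab)
        if rows.size < min_px:
            continue
        cid += 1
        nuclei.append(Nucleus(cell_id=cid, rows=rows, cols=cols))
    return nuclei


def expand_nucleus(
    rows: np.ndarray,
    cols: np.ndarray,
    expansion_um: float,
    pixel_size_um: float,
    shape: tuple[int, int],
) -> tuple[np.ndarray, np.ndarray]:
    """Dilate a nuclear pixel set by a disk of radius ``expansion_um``.

    The result is clipped to the field bounds; expansion 0 is the identity.
    """
    if expansion_um < 0:
        raise ValueError("expansion_um must be >= 0")
    radius_px = expansion_um / pixel_size_um
    return dilate_pixel_set(np.asarray(rows, dtype=np.intp),
                            np.asarray(cols, dtype=np.intp), radius_px, shape)


def call_positive(
    expanded_rows: np.ndarray,
    expanded_cols: np.ndarray,
    marker_dots: PunctaSet,
    min_puncta: int = 3,
    shape: tuple[int, int] | None = None,
) -> tuple[bool, int]:
    """Count marker dots whose centroid lies in the expanded area.

    Returns ``(positive, count)`` with positive iff count ≥ ``min_puncta``.
    """
    shape = shape or marker_dots.shape
    area = np.zeros(shape, dtype=bool)
    area[expanded_rows, expanded_cols] = True
    count = 0
    for dot in marker_dots:
        r, c = dot.centroid_px
        ri, ci = int(round(r)), int(round(c))
        if 0 <= ri < shape[0] and 0 <= ci < shape[1] and area[ri, ci]:
            count += 1
    return count >= min_puncta, count


def assign_dots_to_cells(
    marker_dots: PunctaSet,
    cells: list[CellCall],
) -> dict[int, list[int]]:
    """Map cell_id → dot ids, resolving contested dots by nearer nucleus.

    A dot inside several cells' expanded areas is assigned to the cell whose
    nucleus centroid is closest; exact distance ties go to the lower cell id.
    """
    shape = marker_dots.shape
    cover = np.zeros(shape, dtype=np.int8)
    for cell in cells:
        cover[cell.expanded_rows, cell.expanded_cols] += 1
    membership = {}
    for cell in cells:
        area = np.zeros(shape, dtype=bool)
        area[cell.expanded_rows, cell.expanded_cols] = True
        membership[cell.cell_id] = area
    centroids = {c.cell_id: (float(c.nucleus_rows.mean()), float(c.nucleus_cols.mean()))
                 for c in cells}

    assigned: dict[int, list[int]] = {c.cell_id: [] for c in cells}
    for dot in marker_dots:
        r, c = dot.centroid_px
        ri, ci = int(round(r)), int(round(c))
        if not (0 <= ri < shape[0] and 0 <= ci < shape[1]) or cover[ri, ci] == 0:
            continue
        candidates = [cid for cid, area in membership.items() if area[ri, ci]]
        best = min(candidates,
                   key=lambda cid: ((centroids[cid][0] - r) ** 2
                                    + (centroids[cid][1] - c) ** 2, cid))
        assigned[best].append(dot.id)
    return assigned


def quantify_fish_field(
    field: ImageField,
    nuclear_channel: str,
    marker_channels: list[str],
    regions: dict[str, ROIMask] | None = None,
    expansion_um: float = 2.0,
    min_puncta: int = 3,
    threshold_method: str = "otsu",
    section_id: str | None = None,
) -> list[CellCall]:
    """End-to-end cell calling on one field: segment, expand, count, call."""
    nuclei = segment_nuclei(field, nuclear_channel)
    cells: list[CellCall] = []
    for nuc in nuclei:
        er, ec = expand_nucleus(nuc.rows, nuc.cols, expansion_um,
                                field.pixel_size_um, field.shape)
        region = "all"
        if regions:
            rc = nuc.centroid_px
            for name, roi in regions.items():
                if roi.contains(int(round(rc[0])), int(round(rc[1]))):
                    region = name
                    break
        cells.append(CellCall(cell_id=nuc.cell_id, region=region,
                              nucleus_rows=nuc.rows, nucleus_cols=nuc.cols,
                              expanded_rows=er, expanded_cols=ec,
                              section_id=section_id))
    for marker in marker_channels:
        dots = detect_puncta(field, marker, threshold_method=threshold_method)
        assigned = assign_dots_to_cells(dots, cells)
        for cell in cells:
            n = len(assigned[cell.cell_id])
            cell.counts[marker] = n
            cell.positive[marker] = n >= min_puncta
    return cells


def coexpression_fractions(
    calls: list[CellCall],
    spec: list[tuple[str, str, str]],
) -> pd.DataFrame:
    """Tabulate P(target+ | conditioning+) per region.

    ``spec`` rows are (region, conditioning marker, target marker); the
    fraction is double-positive cells over conditioning-positive cells in the
    region. A zero denominator yields NaN with ``undefined=True``. When
    section ids are present, per-section fractions give a mean and SD.
    """
    rows = []
    for region, cond, target in spec:
        in_region = [c for c in calls if c.region == region]
        denom = [c for c in in_region if c.positive.get(cond, False)]
        numer = [c for c in denom if c.positive.get(target, False)]
        frac = len(numer) / len(denom) if denom else float("nan")
        sec_mean = sec_sd = float("nan")
        sections = sorted({c.section_id for c in in_region if c.section_id})
        if sections:
            per_sec = []
            for s in sections:
                d = [c for c in denom if c.section_id == s]
                n = [c for c in numer if c.section_id == s]
                if d:
                    per_sec.append(len(n) / len(d))
            if per_sec:
                sec_mean = float(np.mean(per_sec))
                sec_sd = float(np.std(per_sec, ddof=1)) if len(per_sec) > 1 else 0.0
        rows.append({
            "region": region,
            "conditioning_marker": cond,
            "target_marker": target,
            "n_conditioning": len(denom),
            "n_double_positive": len(numer),
            "fraction": frac,
            "undefined": not denom,
            "section_mean": sec_mean,
            "section_sd": sec_sd,
        })
    return pd.DataFrame(rows)
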