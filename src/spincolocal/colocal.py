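"""Object-based colocalization between two puncta channels.

A reference punctum (e.g. a GABA_A receptor subunit cluster) is declared
colocalized with the other channel (e.g. gephyrin) when, after both channels'
puncta are enlarged by a small dilation radius (default 0.1 µm, guarding
against edge exclusion), strictly more than an overlap-fraction threshold
(default 0.5) of its dilated pixel footprint is covered by the union of the
other channel's dilated puncta. The measure is intentionally asymmetric:
swapping the argument order changes which channel's areas normalize the
overlap.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np
from scipy import stats

from .image import ROIMask
from .puncta import Punctum, PunctaSet, centroid_in_roi

__all__ = [
    "ColocalizationResult",
    "GroupComparison",
    "dilate_puncta",
    "colocalize",
    "percent_reduction",
    "compare_groups",
]


def _disk_offsets(radius_px: float) -> tuple[np.ndarray, np.ndarray]:
    """Row/col offsets of the Euclidean disk of the given pixel radius."""
    r_int = int(math.ceil(radius_px))
    dr, dc = np.mgrid[-r_int:r_int + 1, -r_int:r_int + 1]
    keep = dr**2 + dc**2 <= radius_px**2 + 1e-12
    return dr[keep], dc[keep]


def dilate_pixel_set(rows: np.ndarray, cols: np.ndarray, radius_px: float,
                     shape: tuple[int, int]) -> tuple[np.ndarray, np.ndarray]:
    """Morphological dilation of a sparse pixel set by a Euclidean disk."""
    if radius_px <= 0:
        return rows, cols
    dr, dc = _disk_offsets(radius_px)
    rr = (rows[:, None] + dr[None, :]).ravel()
    cc = (cols[:, None] + dc[None, :]).ravel()
    inb = (rr >= 0) & (rr < shape[0]) & (cc >= 0) & (cc < shape[1])
    rr, cc = rr[inb], cc[inb]
    flat = np.unique(rr * shape[1] + cc)
    return flat // shape[1], flat % shape[1]


def _dilation_radius_px(dilation_um: float, pixel_size_um: float) -> float:
    if dilation_um <= 0:
        return 0.0
    # sub-pixel dilations are rounded up to one full pixel so the enlargement
    # is never silently lost to rasterization
    return max(1.0, dilation_um / pixel_size_um)


def dilate_puncta(puncta: PunctaSet, dilation_um: float = 0.1) -> PunctaSet:
    """Enlarge every punctum by a disk of the given radius (µm), ids kept.

    Dilated puncta may overlap each other; the operation never shrinks a
    pixel set. ``dilation_um=0`` is the identity.
    """
    if dilation_um < 0:
        raise ValueError("dilation_um must be >= 0")
    if dilation_um == 0:
        return puncta
    radius_px = _dilation_radius_px(dilation_um, puncta.pixel_size_um)
    out = []
    for p in puncta:
        rows, cols = dilate_pixel_set(p.rows, p.cols, radius_px, puncta.shape)
        out.append(Punctum(id=p.id, channel=p.channel, rows=rows, cols=cols,
                           pixel_size_um=p.pixel_size_um))
    return puncta.replace(out, dilation_um=dilation_um)


@dataclass
class ColocalizationResult:
    """Per-field colocalization summary for one ordered channel pair."""

    field_id: str
    reference_channel: str
    other_channel: str
    dilation_um: float
    overlap_threshold: float
    n_reference: int
    n_colocalized: int
    overlap_fractions: np.ndarray          # per reference punctum, dilated-area basis
    colocalized_ids: list[int]
    colocalized_density_per_um2: float | None = None
    reference_density_per_um2: float | None = None
    roi_label: str | None = None

    @property
    def colocalized_fraction(self) -> float:
        """n_colocalized / n_reference; NaN when the reference set is empty."""
        if self.n_reference == 0:
            return float("nan")
        return self.n_colocalized / self.n_reference

    @property
    def undefined(self) -> bool:
        return self.n_reference == 0


def colocalize(
    reference: PunctaSet,
    other: PunctaSet,
    overlap_threshold: float = 0.5,
    dilation_um: float = 0.1,
    roi: ROIMask | None = None,
) -> ColocalizationResult:
    """Classify each reference punctum as colocalized with the other channel.

    Both sets are dilated by ``dilation_um``; a reference punctum counts as
    colocalized iff the fraction of its dilated pixels covered by the union of
    the other channel's dilated puncta strictly exceeds ``overlap_threshold``.
    A punctum straddling several partners sums its covered pixels and is
    counted at most once. When an ROI is given, colocalized and reference
    densities are computed by the centroid rule over the ROI area (centroids
    of the undilated puncta).
    """
    if reference.shape != other.shape:
        raise ValueError("reference and other puncta come from different fields")
    if not (0 < overlap_threshold <= 1):
        raise ValueError("overlap_threshold must be in (0, 1]")
    ref_d = dilate_puncta(reference, dilation_um)
    oth_d = dilate_puncta(other, dilation_um)

    union = np.zeros(reference.shape, dtype=bool)
    for p in oth_d:
        union[p.rows, p.cols] = True

    fractions = np.empty(len(ref_d))
    coloc_ids: list[int] = []
    for i, p in enumerate(ref_d):
        frac = float(union[p.rows, p.cols].mean())
        fractions[i] = frac
        if frac > overlap_threshold:
            coloc_ids.append(p.id)

    result = ColocalizationResult(
        field_id=reference.field_id,
        reference_channel=reference.channel,
        other_channel=other.channel,
        dilation_um=dilation_um,
        overlap_threshold=overlap_threshold,
        n_reference=len(reference),
        n_colocalized=len(coloc_ids),
        overlap_fractions=fractions,
        colocalized_ids=coloc_ids,
    )
    if roi is not None:
        coloc_set = set(coloc_ids)
        by_id = {p.id: p for p in reference}
        n_ref_roi = sum(centroid_in_roi(p, roi) for p in reference)
        n_col_roi = sum(centroid_in_roi(by_id[i], roi) for i in coloc_set)
        result.reference_density_per_um2 = n_ref_roi / roi.area_um2
        result.colocalized_density_per_um2 = n_col_roi / roi.area_um2
        result.roi_label = roi.label
    return result


def percent_reduction(control_mean: float, test_mean: float) -> float:
    """100·(control − test)/control, rounded to one decimal.

    A negative value means an increase. ``control_mean`` must be positive.
    """
    if control_mean <= 0:
        raise ValueError("control_mean must be > 0")
    return round(100.0 * (control_mean - test_mean) / control_mean, 1)


@dataclass
class GroupComparison:
    """Two-group summary: means ± SEM, percent reduction, unpaired t test."""

    measure: str
    control_label: str
    test_label: str
    control_mean: float
    test_mean: float
    control_sem: float
    test_sem: float
    percent_reduction: float
    t_statistic: float
    p_value: float
    n_control: int
    n_test: int
    p_undefined: bool = False


def compare_groups(
    control_values,
    test_values,
    measure: str = "density_per_um2",
    control_label: str = "control",
    test_label: str = "test",
) -> GroupComparison:
    """Unpaired two-sided t test between two labeled samples.

    With zero variance in both groups and equal means the t statistic is
    undefined; the result is flagged (``p_undefined``) rather than raising.
    """
    a = np.asarray(control_values, dtype=float)
    b = np.asarray(test_values, dtype=float)
    if a.size < 2 or b.size < 2:
        raise ValueError("need at least 2 values per group")
    mean_a, mean_b = float(a.mean()), float(b.mean())
    degenerate = a.std() == 0 and b.std() == 0 and mean_a == mean_b
    if degenerate:
        t_stat, p_val = float("nan"), float("nan")
    else:
        t_stat, p_val = stats.ttest_ind(a, b)
        t_stat, p_val = float(t_stat), float(p_val)
    reduction = percent_reduction(mean_a, mean_b) if mean_a > 0 else float("nan")
    return GroupComparison(
        measure=measure,
        control_label=control_label,
        test_label=test_label,
        control_mean=mean_a,
        test_mean=mean_b,
        control_sem=float(stats.sem(a)),
        test_sem=float(stats.sem(b)),
        percent_reduction=reduction,
        t_statistic=t_stat,
        p_value=p_val,
        n_control=int(a.size),
        n_test=int(b.size),
        p_undefined=degenerate,
    )
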