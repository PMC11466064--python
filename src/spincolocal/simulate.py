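"""Seeded synthetic-data generators with ground truth for every pipeline stage.

Four generators emulate the statistical structure of the study's raw data:

* two-channel puncta fields — Gaussian-profile spots (FWHM = nominal
  diameter) at Poisson-random positions on a constant background with
  additive Gaussian noise, with a controllable fraction of channel-2 spots
  placed concentric with channel-1 spots (true colocalization);
* multiplex-FISH fields — disjoint disk nuclei plus per-marker transcript
  dots: positive cells receive Poisson-many dots inside the 2 µm-expanded
  nuclear disk, background dots land uniformly at a per-fluorophore rate;
* Hill-shaped dose-response tables with additive Gaussian noise;
* injury/drug behavioral cohorts: per-animal pre-injury baseline, a
  sensitized pre-drug baseline, and a post-drug threshold time course whose
  expected peak %MPE equals the requested drug effect.

Every generator is driven by one integer seed; per-channel sub-streams are
derived deterministically, so identical parameters and seed give bit-identical
outputs.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .behavior import BehaviorSeries
from .doseresponse import HillFit, hill
from .image import ImageField, ROIMask

__all__ = [
    "PunctaChannelSpec",
    "PunctaSimParams",
    "FishSimParams",
    "GroundTruth",
    "generate_puncta_field",
    "generate_fish_field",
    "fish_region_masks",
    "generate_dose_response",
    "generate_behavior_cohort",
]

GAUSSIAN_FWHM_PER_SIGMA = 2.0 * math.sqrt(2.0 * math.log(2.0))


@dataclass
class PunctaChannelSpec:
    """Per-channel truth parameters for the puncta-field generator."""

    name: str
    density_per_um2: float = 0.3      # true clusters per µm²
    diameter_mean_um: float = 0.45    # nominal spot FWHM, inside the 0.2-3 µm filter
    diameter_sd_um: float = 0.06
    peak_intensity: float = 200.0
    background_level: float = 10.0
    noise_sd: float = 0.0

    def __post_init__(self) -> None:
        if self.density_per_um2 < 0:
            raise ValueError("density_per_um2 must be >= 0")
        if self.diameter_mean_um <= 0 or self.diameter_sd_um < 0:
            raise ValueError("invalid diameter distribution")
        if self.noise_sd < 0 or self.background_level < 0:
            raise ValueError("background and noise must be >= 0")


@dataclass
class PunctaSimParams:
    """Truth parameters for a two-channel (or n-channel) puncta field."""

    field_size_um: tuple[float, float] = (50.0, 50.0)   # (width, height)
    pixel_size_um: float = 0.15
    channels: list[PunctaChannelSpec] = field(default_factory=lambda: [
        PunctaChannelSpec(name="receptor"),
        PunctaChannelSpec(name="gephyrin"),
    ])
    true_coloc_fraction: float = 0.0
    seed: int = 0

    def __post_init__(self) -> None:
        if self.pixel_size_um <= 0:
            raise ValueError("pixel_size_um must be > 0")
        w, h = self.field_size_um
        if w / self.pixel_size_um < 64 or h / self.pixel_size_um < 64:
            raise ValueError("field must be at least 64x64 pixels")
        if not (0 <= self.true_coloc_fraction <= 1):
            raise ValueError("true_coloc_fraction must be in [0, 1]")
        for spec in self.channels:
            # Boolean-model overlap probability: a spot overlaps a neighbor when
            # another center falls within one diameter; unusable truth beyond 20%
            p_overlap = 1.0 - math.exp(
                -spec.density_per_um2 * math.pi * spec.diameter_mean_um**2)
            if p_overlap > 0.20:
                raise ValueError(
                    f"channel {spec.name!r}: expected object overlap "
                    f"{p_overlap:.0%} exceeds 20%; lower the density or size")

    @property
    def shape_px(self) -> tuple[int, int]:
        w, h = self.field_size_um
        return (int(round(h / self.pixel_size_um)),
                int(round(w / self.pixel_size_um)))

    def area_um2(self) -> float:
        h, w = self.shape_px
        return h * w * self.pixel_size_um**2


@dataclass
class FishSimParams:
    """Truth parameters for a multiplex-FISH field of nuclei and dots."""

    n_cells: int = 40
    field_size_um: tuple[float, float] = (100.0, 100.0)
    pixel_size_um: float = 0.15
    nucleus_radius_um: float = 4.0
    expression_probability: dict[str, float] = field(
        default_factory=lambda: {"gabrg1": 0.44, "gabrg2": 0.95})
    dots_per_positive_cell: float = 12.0
    background_dots_per_um2: dict[str, float] | float = 0.001
    expansion_um: float = 2.0
    region_labels: tuple[str, ...] = ("superficial_dorsal_horn",
                                      "deep_dorsal_horn")
    dot_diameter_um: float = 0.5
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_cells < 0 or self.nucleus_radius_um <= 0:
            raise ValueError("invalid cell geometry")
        for m, p in self.expression_probability.items():
            if not (0 <= p <= 1):
                raise ValueError(f"expression probability for {m!r} not in [0,1]")
        bg = self.background_dots_per_um2
        rates = bg.values() if isinstance(bg, dict) else [bg]
        if any(r < 0 for r in rates):
            raise ValueError("background dot rates must be >= 0")
        w, h = self.field_size_um
        # nuclei must stay disjoint even after placement jitter
        exclusion = math.pi * (self.nucleus_radius_um + 1.0) ** 2
        if self.n_cells * exclusion > 0.4 * w * h:
            raise ValueError("nucleus packing too dense for disjoint placement")

    @property
    def markers(self) -> list[str]:
        return list(self.expression_probability)

    @property
    def shape_px(self) -> tuple[int, int]:
        w, h = self.field_size_um
        return (int(round(h / self.pixel_size_um)),
                int(round(w / self.pixel_size_um)))

    def background_rate(self, marker: str) -> float:
        bg = self.background_dots_per_um2
        return bg[marker] if isinstance(bg, dict) else float(bg)


@dataclass
class GroundTruth:
    """Truth records serialized alongside a generated field.

    ``objects`` (puncta fields): one row per spot — channel, x_um, y_um,
    diameter_um, is_colocalized. ``cells`` (FISH fields): one row per cell —
    cell_id, region, x_um, y_um, plus a boolean column per marker.
    """

    objects: pd.DataFrame | None = None
    cells: pd.DataFrame | None = None
    params: dict = field(default_factory=dict)

    def to_csv(self, path) -> None:
        table = self.objects if self.objects is not None else self.cells
        if table is None:
            pd.DataFrame().to_csv(path, index=False)
        else:
            table.to_csv(path, index=False)


def _render_spots(img: np.ndarray, rows_um, cols_um, diameters_um,
                  peak: float, pixel_size_um: float) -> None:
    """Add isotropic Gaussian spots (FWHM = diameter) in place."""
    h, w = img.shape
    for y_um, x_um, d_um in zip(rows_um, cols_um, diameters_um):
        sigma_px = (d_um / GAUSSIAN_FWHM_PER_SIGMA) / pixel_size_um
        r0, c0 = y_um / pixel_size_um, x_um / pixel_size_um
        half = max(2, int(math.ceil(4 * sigma_px)))
        rlo, rhi = max(0, int(r0) - half), min(h, int(r0) + half + 1)
        clo, chi = max(0, int(c0) - half), min(w, int(c0) + half + 1)
        if rlo >= rhi or clo >= chi:
            continue
        rr, cc = np.mgrid[rlo:rhi, clo:chi]
        img[rlo:rhi, clo:chi] += peak * np.exp(
            -((rr - r0) ** 2 + (cc - c0) ** 2) / (2 * sigma_px**2))


def generate_puncta_field(params: PunctaSimParams) -> tuple[ImageField, GroundTruth]:
    """Simulate a multichannel puncta field with per-object ground truth.

    Channel order follows ``params.channels``; with ``true_coloc_fraction`` f,
    each spot of the second channel is, with probability f, placed concentric
    with a uniformly chosen first-channel spot (marked ``is_colocalized``),
    otherwise at an independent uniform position.
    """
    shape = params.shape_px
    w_um = shape[1] * params.pixel_size_um
    h_um = shape[0] * params.pixel_size_um
    area = params.area_um2()

    channels: dict[str, np.ndarray] = {}
    records = []
    positions: dict[int, tuple[np.ndarray, np.ndarray]] = {}
    for ci, spec in enumerate(params.channels):
        rng = np.random.default_rng([params.seed, ci])
        n = rng.poisson(spec.density_per_um2 * area)
        xs = rng.uniform(0, w_um, size=n)
        ys = rng.uniform(0, h_um, size=n)
        coloc = np.zeros(n, dtype=bool)
        if ci == 1 and n > 0 and params.true_coloc_fraction > 0:
            ref_x, ref_y = positions.get(0, (np.empty(0), np.empty(0)))
            if ref_x.size > 0:
                # a deterministic rounded fraction of channel-2 objects is
                # made concentric with distinct channel-1 partners; partners
                # are drawn without replacement so two truth spots never
                # coincide exactly (which would merge them into one object)
                n_col = min(int(round(params.true_coloc_fraction * n)),
                            ref_x.size)
                which = rng.permutation(n)[:n_col]
                coloc[which] = True
                pick = rng.choice(ref_x.size, size=n_col, replace=False)
                xs[which] = ref_x[pick]
                ys[which] = ref_y[pick]
        diam = np.clip(rng.normal(spec.diameter_mean_um, spec.diameter_sd_um,
                                  size=n), 0.05, None)
        positions[ci] = (xs, ys)

        img = np.full(shape, spec.background_level, dtype=float)
        _render_spots(img, ys, xs, diam, spec.peak_intensity,
                      params.pixel_size_um)
        if spec.noise_sd > 0:
            img += rng.normal(0.0, spec.noise_sd, size=shape)
        channels[spec.name] = np.clip(img, 0.0, None)

        for i in range(n):
            records.append({"channel": spec.name, "x_um": xs[i], "y_um": ys[i],
                            "diameter_um": diam[i],
                            "is_colocalized": bool(coloc[i])})

    truth = GroundTruth(
        objects=pd.DataFrame(
            records,
            columns=["channel", "x_um", "y_um", "diameter_um", "is_colocalized"]),
        params={"kind": "puncta", "seed": params.seed,
                "field_size_um": list(params.field_size_um),
                "pixel_size_um": params.pixel_size_um,
                "true_coloc_fraction": params.true_coloc_fraction},
    )
    field_obj = ImageField(channels=channels, pixel_size_um=params.pixel_size_um,
                           field_id=f"sim_puncta_seed{params.seed}")
    return field_obj, truth


def _place_nuclei(params: FishSimParams, rng: np.random.Generator
                  ) -> tuple[np.ndarray, np.ndarray]:
    """Rejection-sample disjoint nucleus centers (µm), margin 1 µm."""
    w_um, h_um = params.field_size_um
    r = params.nucleus_radius_um
    min_dist = 2 * r + 1.0
    xs, ys = [], []
    attempts = 0
    max_attempts = 20000 * max(params.n_cells, 1)
    while len(xs) < params.n_cells:
        attempts += 1
        if attempts > max_attempts:
            raise ValueError("could not place disjoint nuclei; packing too dense")
        x = rng.uniform(r, w_um - r)
        y = rng.uniform(r, h_um - r)
        if all((x - xi) ** 2 + (y - yi) ** 2 >= min_dist**2
               for xi, yi in zip(xs, ys)):
            xs.append(x)
            ys.append(y)
    return np.array(xs), np.array(ys)


def fish_region_masks(params: FishSimParams) -> dict[str, ROIMask]:
    """Vertical-strip ROI masks, one per region label, covering the field."""
    shape = params.shape_px
    n = len(params.region_labels)
    masks = {}
    edges = np.linspace(0, shape[1], n + 1).astype(int)
    for i, label in enumerate(params.region_labels):
        m = np.zeros(shape, dtype=bool)
        m[:, edges[i]:edges[i + 1]] = True
        masks[label] = ROIMask(label=label, mask=m,
                               pixel_size_um=params.pixel_size_um)
    return masks


def generate_fish_field(params: FishSimParams) -> tuple[ImageField, GroundTruth]:
    """Simulate a FISH field: nuclear channel plus one dot channel per marker.

    Cell regions are vertical strips of the field (see
    :func:`fish_region_masks`); each cell belongs to the strip containing its
    nucleus center. Dots of positive cells fall uniformly in the expanded
    nuclear disk (nucleus radius + ``expansion_um``); background dots fall
    uniformly over the whole field at the per-fluorophore rate.
    """
    shape = params.shape_px
    w_um, h_um = params.field_size_um
    area = shape[0] * shape[1] * params.pixel_size_um**2
    rng_cells = np.random.default_rng([params.seed, 0])
    xs, ys = _place_nuclei(params, rng_cells)

    # nuclear channel: solid disks
    dapi = np.zeros(shape, dtype=float)
    rr, cc = np.mgrid[0:shape[0], 0:shape[1]]
    r_px = params.nucleus_radius_um / params.pixel_size_um
    for x, y in zip(xs, ys):
        c0, r0 = x / params.pixel_size_um, y / params.pixel_size_um
        lo_r, hi_r = max(0, int(r0 - r_px) - 1), min(shape[0], int(r0 + r_px) + 2)
        lo_c, hi_c = max(0, int(c0 - r_px) - 1), min(shape[1], int(c0 + r_px) + 2)
        sub_r, sub_c = rr[lo_r:hi_r, lo_c:hi_c], cc[lo_r:hi_r, lo_c:hi_c]
        disk = (sub_r - r0) ** 2 + (sub_c - c0) ** 2 <= r_px**2
        dapi[lo_r:hi_r, lo_c:hi_c][disk] = 150.0

    # region assignment by nucleus center
    n_reg = len(params.region_labels)
    strip = np.minimum((xs / w_um * n_reg).astype(int), n_reg - 1)
    regions = [params.region_labels[s] for s in strip]

    channels: dict[str, np.ndarray] = {"dapi": dapi}
    cell_rows = [{"cell_id": i + 1, "region": regions[i],
                  "x_um": xs[i], "y_um": ys[i],
                  "radius_um": params.nucleus_radius_um}
                 for i in range(params.n_cells)]

    reach = params.nucleus_radius_um + params.expansion_um
    for mi, marker in enumerate(params.markers):
        rng = np.random.default_rng([params.seed, 1 + mi])
        img = np.zeros(shape, dtype=float)
        p_expr = params.expression_probability[marker]
        positive = rng.random(params.n_cells) < p_expr
        dot_x, dot_y = [], []
        for i in range(params.n_cells):
            cell_rows[i][marker] = bool(positive[i])
            if not positive[i]:
                continue
            k = rng.poisson(params.dots_per_positive_cell)
            # uniform in the expanded disk, clipped to the field
            theta = rng.uniform(0, 2 * math.pi, size=k)
            rad = reach * np.sqrt(rng.uniform(0, 1, size=k))
            dot_x.append(np.clip(xs[i] + rad * np.cos(theta), 0, w_um - 1e-9))
            dot_y.append(np.clip(ys[i] + rad * np.sin(theta), 0, h_um - 1e-9))
        n_bg = rng.poisson(params.background_rate(marker) * area)
        dot_x.append(rng.uniform(0, w_um, size=n_bg))
        dot_y.append(rng.uniform(0, h_um, size=n_bg))
        dx = np.concatenate(dot_x) if dot_x else np.empty(0)
        dy = np.concatenate(dot_y) if dot_y else np.empty(0)
        _render_spots(img, dy, dx, np.full(dx.size, params.dot_diameter_um),
                      200.0, params.pixel_size_um)
        channels[marker] = np.clip(img, 0.0, None)

    marker_cols = params.markers
    truth = GroundTruth(
        cells=pd.DataFrame(cell_rows, columns=["cell_id", "region", "x_um",
                                               "y_um", "radius_um"] + marker_cols),
        params={"kind": "fish", "seed": params.seed, "n_cells": params.n_cells,
                "expansion_um": params.expansion_um,
                "pixel_size_um": params.pixel_size_um},
    )
    field_obj = ImageField(channels=channels, pixel_size_um=params.pixel_size_um,
                           field_id=f"sim_fish_seed{params.seed}")
    return field_obj, truth


def generate_dose_response(
    true_params: HillFit,
    concentrations,
    noise_sd: float = 0.0,
    seed: int = 0,
    n_replicates: int = 1,
) -> pd.DataFrame:
    """Hill-curve responses with additive Gaussian noise.

    Returns a table with columns ``concentration_uM``, ``response``,
    ``replicate_id`` (concentrations sorted ascending, replicates pooled).
    """
    c = np.asarray(sorted(concentrations), dtype=float)
    if np.any(c <= 0):
        raise ValueError("concentrations must be > 0")
    if noise_sd < 0:
        raise ValueError("noise_sd must be >= 0")
    rng = np.random.default_rng(seed)
    rows = []
    for rep in range(n_replicates):
        y = true_params.predict(c)
        if noise_sd > 0:
            y = y + rng.normal(0.0, noise_sd, size=c.size)
        for ci, yi in zip(c, y):
            rows.append({"concentration_uM": ci, "response": yi,
                         "replicate_id": rep})
    return pd.DataFrame(rows)


def generate_behavior_cohort(
    n_per_group: int = 7,
    baseline_g: float = 6.0,
    cci_drop_fraction: float = 0.6,
    drug_effect_mpe: float = 0.6,
    timepoints_h: tuple[float, ...] = (0.5, 1.0, 2.0, 3.0, 4.0),
    noise_sd_g: float = 0.0,
    seed: int = 0,
    group_label: str = "cohort",
) -> list[BehaviorSeries]:
    """Simulate one cohort of injury/drug withdrawal-threshold series.

    Per animal: E_preCCI ~ N(baseline_g, noise_sd_g); the sensitized baseline
    is E_predrug = E_preCCI·(1 − cci_drop_fraction) plus measurement noise;
    post-drug thresholds follow E_predrug + drug_effect_mpe·(E_preCCI −
    E_predrug)·profile(t) + noise, where the drug-effect profile is 1 up to
    1 h (the peak window) and decays as exp(−(t−1)) afterwards, so the
    expected window-mean %MPE over {0.5, 1} h equals 100·drug_effect_mpe.
    """
    if not (0 <= cci_drop_fraction <= 1):
        raise ValueError("cci_drop_fraction must be in [0, 1]")
    if not (0 <= drug_effect_mpe <= 1):
        raise ValueError("drug_effect_mpe must be in [0, 1]")
    if baseline_g <= 0:
        raise ValueError("baseline_g must be > 0")
    rng = np.random.default_rng(seed)
    cohort = []
    for i in range(n_per_group):
        e_pre = max(baseline_g + rng.normal(0, noise_sd_g), 0.1)
        e_predrug_true = e_pre * (1.0 - cci_drop_fraction)
        e_predrug = max(e_predrug_true + rng.normal(0, noise_sd_g), 0.05)
        thresholds = {}
        for t in timepoints_h:
            profile = 1.0 if t <= 1.0 else math.exp(-(t - 1.0))
            e_t = e_predrug + drug_effect_mpe * (e_pre - e_predrug) * profile
            thresholds[t] = max(e_t + rng.normal(0, noise_sd_g), 0.01)
        cohort.append(BehaviorSeries(
            animal_id=f"{group_label}_{i + 1}",
            e_pre_cci=e_pre, e_predrug=e_predrug, thresholds=thresholds,
            treatment=group_label))
    return cohort


def behavior_table(cohorts: list[list[BehaviorSeries]]) -> pd.DataFrame:
    """Long-format table with reserved times ``preCCI`` and ``predrug``."""
    rows = []
    for cohort in cohorts:
        for s in cohort:
            base = {"animal_id": s.animal_id, "genotype": s.genotype,
                    "treatment": s.treatment, "sex": s.sex}
            rows.append({**base, "time_h": "preCCI", "threshold_g": s.e_pre_cci})
            rows.append({**base, "time_h": "predrug", "threshold_g": s.e_predrug})
            for t, v in sorted(s.thresholds.items()):
                rows.append({**base, "time_h": t, "threshold_g": v})
    return pd.DataFrame(rows)
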