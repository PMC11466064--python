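"""Readers, writers, run configuration, and the reproducible pipeline runner.

Images travel as multi-page TIFF (one page per channel) with a JSON sidecar
carrying the mandatory physical metadata (pixel size in µm, channel names,
field id) — pixel size is never defaulted at analysis time, because every
threshold in the pipeline is in physical units. Tables are CSV with fixed
column orders; configs and manifests are YAML/JSON.
"""

from __future__ import annotations

import hashlib
import json
import logging
from dataclasses import dataclass, field, asdict
from pathlib import Path

import numpy as np
import pandas as pd
import tifffile
import yaml

from . import __version__
from .colocal import colocalize
from .image import ImageField, ROIMask
from .puncta import PunctaSet, detect_puncta, filter_by_size
from .simulate import PunctaChannelSpec, PunctaSimParams, generate_puncta_field

logger = logging.getLogger("spincolocal")

PUNCTA_CSV_COLUMNS = ["field_id", "channel", "id", "centroid_x_um",
                      "centroid_y_um", "area_um2", "diameter_um"]


def _sidecar_path(image_path: Path) -> Path:
    return image_path.with_suffix(image_path.suffix + ".json")


def write_image(field: ImageField, path, sidecar=None) -> Path:
    """Write a field as multi-page TIFF plus a JSON metadata sidecar."""
    path = Path(path)
    sidecar = Path(sidecar) if sidecar else _sidecar_path(path)
    stack = np.stack([field.channels[name] for name in field.channel_names])
    tifffile.imwrite(path, stack.astype(np.float32),
                     photometric="minisblack")
    sidecar.write_text(json.dumps({
        "pixel_size_um": field.pixel_size_um,
        "channels": field.channel_names,
        "field_id": field.field_id,
    }, indent=2))
    return sidecar


def load_image(path, sidecar=None) -> ImageField:
    """Load a multi-page TIFF with its sidecar metadata.

    Raises if the sidecar is missing a pixel size or if the channel list does
    not match the page count — physical calibration is never assumed.
    """
    path = Path(path)
    sidecar = Path(sidecar) if sidecar else _sidecar_path(path)
    if not sidecar.exists():
        raise FileNotFoundError(f"metadata sidecar {sidecar} not found")
    meta = json.loads(sidecar.read_text())
    if "pixel_size_um" not in meta:
        raise ValueError(f"{sidecar}: missing pixel_size_um")
    pages = tifffile.imread(path)
    if pages.ndim == 2:
        pages = pages[None]
    names = meta.get("channels")
    if not names or len(names) != pages.shape[0]:
        raise ValueError(
            f"{sidecar}: {len(names or [])} channel names for "
            f"{pages.shape[0]} TIFF pages")
    shapes = {pages[i].shape for i in range(pages.shape[0])}
    if len(shapes) != 1:
        raise ValueError(f"{path}: TIFF pages have differing shapes {shapes}")
    return ImageField(
        channels={n: pages[i] for i, n in enumerate(names)},
        pixel_size_um=float(meta["pixel_size_um"]),
        field_id=meta.get("field_id", path.stem),
    )


def write_puncta_csv(puncta: PunctaSet, path) -> None:
    rows = [{
        "field_id": puncta.field_id,
        "channel": p.channel,
        "id": p.id,
        "centroid_x_um": p.centroid_um[0],
        "centroid_y_um": p.centroid_um[1],
        "area_um2": p.area_um2,
        "diameter_um": p.equivalent_diameter_um,
    } for p in puncta]
    pd.DataFrame(rows, columns=PUNCTA_CSV_COLUMNS).to_csv(path, index=False)


def load_roi_mask(path, label: str, pixel_size_um: float) -> ROIMask:
    """Binary mask from a TIFF/PNG image (nonzero pixels are inside)."""
    from imageio.v3 import imread  # local import: only needed for mask files
    arr = imread(path)
    if arr.ndim == 3:
        arr = arr[..., 0]
    return ROIMask(label=label, mask=arr > 0, pixel_size_um=pixel_size_um)


@dataclass
class RunConfig:
    """Validated parameters for one pipeline run."""

    stage: str = "simulate_colocalize"
    out_dir: str = "results"
    seed: int = 0
    image: str | None = None
    reference_channel: str = "receptor"
    other_channel: str = "gephyrin"
    threshold_method: str = "otsu"
    min_diameter_um: float = 0.2
    max_diameter_um: float = 3.0
    dilation_um: float = 0.1
    overlap_threshold: float = 0.5
    expansion_um: float = 2.0
    min_puncta: int = 3
    mpe_window: tuple[float, ...] = (0.5, 1.0)
    field_size_um: tuple[float, float] = (50.0, 50.0)
    pixel_size_um: float = 0.15
    density_per_um2: float = 0.3
    true_coloc_fraction: float = 0.5

    def __post_init__(self) -> None:
        for name in ("min_diameter_um", "max_diameter_um", "dilation_um",
                     "expansion_um", "pixel_size_um"):
            if getattr(self, name) < 0:
                raise ValueError(f"{name} must be >= 0")
        if not (0 < self.overlap_threshold <= 1):
            raise ValueError("overlap_threshold must be in (0, 1]")
        if self.min_puncta < 1:
            raise ValueError("min_puncta must be >= 1")

    @classmethod
    def from_yaml(cls, path) -> "RunConfig":
        data = yaml.safe_load(Path(path).read_text()) or {}
        for key in ("mpe_window", "field_size_um"):
            if key in data:
                data[key] = tuple(data[key])
        return cls(**data)

    def to_yaml(self, path) -> None:
        data = asdict(self)
        data["mpe_window"] = list(self.mpe_window)
        data["field_size_um"] = list(self.field_size_um)
        Path(path).write_text(yaml.safe_dump(data, sort_keys=False))


def _sha256(path: Path) -> str:
    return hashlib.sha256(path.read_bytes()).hexdigest()


def run_pipeline(config: RunConfig) -> dict:
    """Execute the configured stage and write artifacts plus a manifest.

    The ``simulate_colocalize`` stage runs the full synthetic round trip:
    generate a seeded two-channel puncta field, detect and size-filter both
    channels, colocalize, and write the image, both puncta CSVs, the result
    JSON, and a manifest with record counts and artifact checksums. The
    ``analyze_colocalize`` stage does the same from an existing image on
    disk.
    """
    out = Path(config.out_dir)
    out.mkdir(parents=True, exist_ok=True)
    artifacts: dict[str, Path] = {}
    counts: dict[str, int] = {}

    if config.stage == "simulate_colocalize":
        params = PunctaSimParams(
            field_size_um=config.field_size_um,
            pixel_size_um=config.pixel_size_um,
            channels=[
                PunctaChannelSpec(name=config.reference_channel,
                                  density_per_um2=config.density_per_um2),
                PunctaChannelSpec(name=config.other_channel,
                                  density_per_um2=config.density_per_um2),
            ],
            true_coloc_fraction=config.true_coloc_fraction,
            seed=config.seed,
        )
        field_obj, truth = generate_puncta_field(params)
        img_path = out / "field.tif"
        write_image(field_obj, img_path)
        truth_path = out / "ground_truth.csv"
        truth.to_csv(truth_path)
        artifacts["image"] = img_path
        artifacts["ground_truth"] = truth_path
        counts["truth_objects"] = 0 if truth.objects is None else len(truth.objects)
    elif config.stage == "analyze_colocalize":
        if not config.image:
            raise ValueError("analyze_colocalize requires an input image path")
        if not Path(config.image).exists():
            raise FileNotFoundError(config.image)
        field_obj = load_image(config.image)
    else:
        raise ValueError(f"unknown stage {config.stage!r}")

    sets = {}
    for chan in (config.reference_channel, config.other_channel):
        try:
            detected = detect_puncta(field_obj, chan, config.threshold_method)
            filtered = filter_by_size(detected, config.min_diameter_um,
                                      config.max_diameter_um)
        except Exception as exc:
            raise RuntimeError(
                f"stage puncta failed on field {field_obj.field_id!r}, "
                f"channel {chan!r}: {exc}") from exc
        sets[chan] = filtered
        csv_path = out / f"puncta_{chan}.csv"
        write_puncta_csv(filtered, csv_path)
        artifacts[f"puncta_{chan}"] = csv_path
        counts[f"puncta_{chan}"] = len(filtered)
        logger.info("field %s channel %s: %d puncta after size filter",
                    field_obj.field_id, chan, len(filtered))

    roi = ROIMask.full_field(field_obj)
    result = colocalize(sets[config.reference_channel],
                        sets[config.other_channel],
                        overlap_threshold=config.overlap_threshold,
                        dilation_um=config.dilation_um, roi=roi)
    result_path = out / "colocalization.json"
    result_path.write_text(json.dumps({
        "field_id": result.field_id,
        "reference_channel": result.reference_channel,
        "other_channel": result.other_channel,
        "n_reference": result.n_reference,
        "n_colocalized": result.n_colocalized,
        "colocalized_fraction": (None if result.undefined
                                 else result.colocalized_fraction),
        "colocalized_density_per_um2": result.colocalized_density_per_um2,
        "reference_density_per_um2": result.reference_density_per_um2,
        "dilation_um": result.dilation_um,
        "overlap_threshold": result.overlap_threshold,
    }, indent=2))
    artifacts["colocalization"] = result_path
    counts["colocalized"] = result.n_colocalized

    manifest = {
        "software": {"name": "spincolocal", "version": __version__},
        "config": {**asdict(config),
                   "mpe_window": list(config.mpe_window),
                   "field_size_um": list(config.field_size_um)},
        "seed": config.seed,
        "counts": counts,
        "artifacts": {k: {"path": str(v), "sha256": _sha256(v)}
                      for k, v in sorted(artifacts.items())},
    }
    manifest_path = out / "manifest.json"
    manifest_path.write_text(json.dumps(manifest, indent=2, sort_keys=True))
    return manifest
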