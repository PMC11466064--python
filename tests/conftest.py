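"""Shared fixtures and hand-rolled oracles, independent of the library paths."""

from __future__ import annotations

import numpy as np
import pytest

from spincolocal.image import ImageField
from spincolocal.puncta import Punctum, PunctaSet


def brute_force_components(pixels: set[tuple[int, int]]) -> list[set[tuple[int, int]]]:
    """8-connected components of a pixel set by plain BFS (oracle)."""
    remaining = set(pixels)
    comps = []
    while remaining:
        seed = next(iter(remaining))
        comp, frontier = {seed}, [seed]
        remaining.discard(seed)
        while frontier:
            r, c = frontier.pop()
            for dr in (-1, 0, 1):
                for dc in (-1, 0, 1):
                    nb = (r + dr, c + dc)
                    if nb in remaining:
                        remaining.discard(nb)
                        comp.add(nb)
                        frontier.append(nb)
        comps.append(comp)
    return comps


def brute_force_disk(radius_px: float) -> set[tuple[int, int]]:
    """Offsets of the Euclidean disk by exhaustive scan (oracle)."""
    r_int = int(np.ceil(radius_px)) + 1
    out = set()
    for dr in range(-r_int, r_int + 1):
        for dc in range(-r_int, r_int + 1):
            if dr * dr + dc * dc <= radius_px**2 + 1e-12:
                out.add((dr, dc))
    return out


def brute_force_dilate(pixels: set[tuple[int, int]], radius_px: float,
                       shape: tuple[int, int]) -> set[tuple[int, int]]:
    disk = brute_force_disk(radius_px)
    out = set()
    for r, c in pixels:
        for dr, dc in disk:
            rr, cc = r + dr, c + dc
            if 0 <= rr < shape[0] and 0 <= cc < shape[1]:
                out.add((rr, cc))
    return out


def brute_force_colocalize(ref_sets: list[set[tuple[int, int]]],
                           other_sets: list[set[tuple[int, int]]],
                           threshold: float) -> list[bool]:
    """Per-reference-object colocalization by Python-set arithmetic (oracle)."""
    union: set[tuple[int, int]] = set()
    for s in other_sets:
        union |= s
    return [len(s & union) / len(s) > threshold for s in ref_sets]


def make_punctum_set(pixel_sets: list[set[tuple[int, int]]],
                     shape: tuple[int, int], pixel_size_um: float,
                     channel: str = "test") -> PunctaSet:
    """Build a PunctaSet directly from explicit pixel sets."""
    puncta = []
    for i, pixels in enumerate(pixel_sets, start=1):
        rows = np.array([p[0] for p in sorted(pixels)])
        cols = np.array([p[1] for p in sorted(pixels)])
        puncta.append(Punctum(id=i, channel=channel, rows=rows, cols=cols,
                              pixel_size_um=pixel_size_um))
    return PunctaSet(field_id="manual", channel=channel, shape=shape,
                     pixel_size_um=pixel_size_um, puncta=puncta)


def spot_image(shape: tuple[int, int], centers_px, sigma_px: float = 1.5,
               peak: float = 200.0, background: float = 10.0) -> np.ndarray:
    """Noise-free image of Gaussian spots at the given (row, col) centers."""
    img = np.full(shape, background, dtype=float)
    rr, cc = np.mgrid[0:shape[0], 0:shape[1]]
    for r0, c0 in centers_px:
        img += peak * np.exp(-((rr - r0) ** 2 + (cc - c0) ** 2) / (2 * sigma_px**2))
    return img


@pytest.fixture
def ten_spot_field() -> tuple[ImageField, list[tuple[int, int]]]:
    """A noise-free field with 10 well-separated bright spots."""
    centers = [(r, c) for r in (15, 45, 75, 105, 135) for c in (30, 90)]
    img = spot_image((150, 120), centers)
    field = ImageField(channels={"a2": img}, pixel_size_um=0.15,
                       field_id="ten_spots")
    return field, centers
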