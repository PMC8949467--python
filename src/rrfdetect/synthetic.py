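"""Synthetic 110 x 110 trichrome-like tiles for the three classes.

The generator emulates, at the level of color and texture statistics, what
the three tile classes look like under Gomori's trichrome:

* ``not_ragged`` — a mosaic of green-cyan muscle fibers (Voronoi cells with
  per-fiber color jitter and thin dark boundary lines);
* ``ragged`` — the same mosaic plus a red, granular subsarcolemmal rim
  (an annulus band with salt-speckle granules), the stain pattern of
  subsarcolemmal mitochondrial accumulation;
* ``waste`` — pale, weakly saturated background with one or more dark
  artifact structures (bubbles rendered as ellipses, slide folds as
  streaks).

A single separation scalar ``s`` in [0, 1] interpolates every class-
specific parameter toward the common mixture: at ``s = 0`` the three class
generators are identical (null data), at ``s = 1`` the classes are
maximally distinct.  All randomness flows from one seeded generator.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from skimage.color import hsv2rgb

from .config import CLASS_LABELS, LABEL_NOT_RAGGED, LABEL_RAGGED, LABEL_WASTE
from .tiling import MANIFEST_COLUMNS, Tile, TileManifest

#: default class sizes (waste / ragged / not_ragged)
DEFAULT_COUNTS = {LABEL_WASTE: 250, LABEL_RAGGED: 100, LABEL_NOT_RAGGED: 138}


@dataclass(frozen=True)
class SyntheticConfig:
    tile_side: int = 110
    separation: float = 1.0  # 0 = identical classes, 1 = maximal contrast

    # fiber mosaic (tissue classes; HSV units)
    fiber_hsv: tuple[float, float, float] = (0.45, 0.50, 0.55)
    fiber_hsv_sd: tuple[float, float, float] = (0.015, 0.06, 0.06)
    fiber_count_range: tuple[int, int] = (8, 16)
    boundary_width: float = 1.6  # px
    boundary_contrast: float = 0.18  # subtracted from V on fiber borders

    # ragged rim
    rim_hsv: tuple[float, float, float] = (0.99, 0.85, 0.50)
    rim_radius_range: tuple[float, float] = (22.0, 38.0)
    rim_thickness_range: tuple[float, float] = (5.0, 10.0)
    rim_speckle_density: float = 0.35
    rim_speckle_depth: float = 0.30  # V drop on rim granules
    #: declared admissible fraction of rim pixels per ragged tile
    rim_fraction_range: tuple[float, float] = (0.03, 0.40)

    # waste background and artifacts
    waste_hsv: tuple[float, float, float] = (0.40, 0.06, 0.92)
    artifact_count_range: tuple[int, int] = (1, 3)
    artifact_depth: float = 0.40  # V drop inside bubbles/folds

    noise_sd: float = 0.02  # additive HSV noise
    seed: int = 0

    def __post_init__(self) -> None:
        if not 0.0 <= self.separation <= 1.0:
            raise ValueError("separation must lie in [0, 1]")


def _mixture_hsv(cfg: SyntheticConfig) -> np.ndarray:
    bases = np.array([cfg.fiber_hsv, cfg.fiber_hsv, cfg.waste_hsv])
    return bases.mean(axis=0)


def _interp(base: tuple[float, float, float], cfg: SyntheticConfig) -> np.ndarray:
    """Class base color pulled toward the common mixture by (1 - s)."""
    mix = _mixture_hsv(cfg)
    return mix + cfg.separation * (np.asarray(base) - mix)


def _fiber_mosaic(
    cfg: SyntheticConfig, rng: np.random.Generator, base: np.ndarray, amp: float
) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    """HSV planes of a Voronoi fiber mosaic with contrast amplitude ``amp``."""
    s = cfg.tile_side
    k = int(rng.integers(cfg.fiber_count_range[0], cfg.fiber_count_range[1] + 1))
    pts = rng.uniform(0, s, size=(k, 2))
    jit = rng.normal(0.0, 1.0, size=(k, 3)) * np.asarray(cfg.fiber_hsv_sd)

    yy, xx = np.mgrid[0:s, 0:s]
    d = np.sqrt(
        (yy[..., None] - pts[:, 0]) ** 2 + (xx[..., None] - pts[:, 1]) ** 2
    )
    order = np.argsort(d, axis=-1)
    nearest = order[..., 0]
    d0 = np.take_along_axis(d, order[..., :1], axis=-1)[..., 0]
    d1 = np.take_along_axis(d, order[..., 1:2], axis=-1)[..., 0]
    boundary = (d1 - d0) < cfg.boundary_width

    h = base[0] + amp * jit[nearest, 0]
    sat = base[1] + amp * jit[nearest, 1]
    v = base[2] + amp * jit[nearest, 2]
    v = v - amp * cfg.boundary_contrast * boundary
    sat = sat - amp * 0.5 * cfg.boundary_contrast * boundary
    return h, sat, v


def _rim_mask(
    cfg: SyntheticConfig, rng: np.random.Generator
) -> np.ndarray:
    """Annulus band emulating a subsarcolemmal rim, mostly inside the tile."""
    s = cfg.tile_side
    cy, cx = rng.uniform(0.35 * s, 0.65 * s, size=2)
    radius = rng.uniform(*cfg.rim_radius_range)
    thickness = rng.uniform(*cfg.rim_thickness_range)
    yy, xx = np.mgrid[0:s, 0:s]
    dist = np.sqrt((yy - cy) ** 2 + (xx - cx) ** 2)
    return np.abs(dist - radius) < thickness / 2.0


def _artifacts(
    cfg: SyntheticConfig, rng: np.random.Generator
) -> np.ndarray:
    """Union mask of bubble ellipses and fold streaks."""
    s = cfg.tile_side
    yy, xx = np.mgrid[0:s, 0:s]
    mask = np.zeros((s, s), dtype=bool)
    n = int(rng.integers(cfg.artifact_count_range[0], cfg.artifact_count_range[1] + 1))
    for i in range(n):
        if i % 2 == 0:  # bubble
            cy, cx = rng.uniform(0.1 * s, 0.9 * s, size=2)
            ry, rx = rng.uniform(6, 22, size=2)
            mask |= ((yy - cy) / ry) ** 2 + ((xx - cx) / rx) ** 2 < 1.0
        else:  # fold streak
            angle = rng.uniform(0, np.pi)
            offset = rng.uniform(0.2 * s, 0.8 * s)
            width = rng.uniform(2, 6)
            proj = xx * np.cos(angle) + yy * np.sin(angle)
            mask |= np.abs(proj - offset) < width
    return mask


def generate_tile(
    label: str, cfg: SyntheticConfig, rng: np.random.Generator,
    tile_id: str | None = None,
) -> Tile:
    """One synthetic tile of the requested class; deterministic given the
    generator state."""
    if label not in CLASS_LABELS:
        raise ValueError(f"unknown class label {label!r}")
    sep = cfg.separation

    # Every class consumes the identical draw sequence (mosaic, rim,
    # speckle, artifacts, noise) and differs only in the amplitudes applied,
    # so at separation 0 all three generators are byte-identical for the
    # same generator state.
    is_waste = label == LABEL_WASTE
    base = _interp(cfg.waste_hsv if is_waste else cfg.fiber_hsv, cfg)
    mosaic_amp = 1.0 - sep if is_waste else 1.0
    rim_amp = sep if label == LABEL_RAGGED else 0.0
    art_amp = sep if is_waste else 0.0

    h, sat, v = _fiber_mosaic(cfg, rng, base, amp=mosaic_amp)

    rim = _rim_mask(cfg, rng)
    speckle = rim & (rng.random(rim.shape) < cfg.rim_speckle_density)
    rim_h, rim_s, rim_v = cfg.rim_hsv
    h = np.where(rim, (1 - rim_amp) * h + rim_amp * rim_h, h)
    sat = np.where(rim, (1 - rim_amp) * sat + rim_amp * rim_s, sat)
    v = np.where(rim, (1 - rim_amp) * v + rim_amp * rim_v, v)
    v = v - rim_amp * cfg.rim_speckle_depth * speckle

    art = _artifacts(cfg, rng)
    v = v - art_amp * cfg.artifact_depth * art
    sat = sat + art_amp * 0.15 * art

    side = cfg.tile_side
    h = (h + rng.normal(0, cfg.noise_sd, (side, side))) % 1.0
    sat = np.clip(sat + rng.normal(0, cfg.noise_sd, (side, side)), 0, 1)
    v = np.clip(v + rng.normal(0, cfg.noise_sd, (side, side)), 0, 1)

    rgb = hsv2rgb(np.stack([h, sat, v], axis=-1))
    pixels = np.round(rgb * 255).astype(np.uint8)
    return Tile(
        pixels=pixels, grid_row=0, grid_col=0,
        source_id="synthetic", label=label, id=tile_id,
    )


def generate_dataset(
    counts: dict[str, int] | None = None,
    cfg: SyntheticConfig = SyntheticConfig(),
    seed: int = 0,
) -> tuple[list[Tile], TileManifest]:
    """A labeled synthetic tile set plus its manifest.

    Classes are generated in the fixed order ragged, not_ragged, waste;
    each tile consumes an independent child stream of the seed, so the
    same seed always reproduces the same tiles byte for byte.
    """
    if counts is None:
        counts = DEFAULT_COUNTS
    bad = {k: v for k, v in counts.items() if v < 0}
    if bad:
        raise ValueError(f"negative class counts: {bad}")

    n_total = sum(counts.get(lbl, 0) for lbl in CLASS_LABELS)
    children = np.random.SeedSequence(seed).spawn(n_total)
    tiles: list[Tile] = []
    records = []
    idx = 0
    for label in CLASS_LABELS:
        for i in range(counts.get(label, 0)):
            tile_id = f"syn-{label}-{i:04d}"
            rng = np.random.default_rng(children[idx])
            idx += 1
            tiles.append(generate_tile(label, cfg, rng, tile_id=tile_id))
            records.append(
                {"tile_id": tile_id, "source_id": "synthetic",
                 "grid_row": 0, "grid_col": 0, "label": label}
            )
    manifest = TileManifest(records=pd.DataFrame(records, columns=MANIFEST_COLUMNS))
    return tiles, manifest
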