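"""Acquisition-image loading, grid tiling, and tile label manifests.

Light-microscopy acquisitions (nominally 1653 x 1239 px at 20x) are cut
into a fixed grid of square tiles anchored at the top-left corner; the
residual right/bottom margins are discarded.  A 110 px tile side therefore
turns a full acquisition into 15 x 11 = 165 tiles.

Manifests are plain CSV with header ``tile_id,source_id,grid_row,grid_col,
label`` so they can be hand-edited and diffed.
"""

from __future__ import annotations

import os
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from PIL import Image, UnidentifiedImageError

from .config import (
    CLASS_LABELS,
    DEFAULT_TILE_SIDE,
    LABEL_UNLABELED,
    logger,
)

MANIFEST_COLUMNS = ["tile_id", "source_id", "grid_row", "grid_col", "label"]
VALID_LABELS = set(CLASS_LABELS) | {LABEL_UNLABELED}


class ManifestError(ValueError):
    """Raised when a tile manifest violates its contract."""


@dataclass
class AcquisitionImage:
    """One RGB microscopy image as an ``H x W x 3`` uint8 array."""

    pixels: np.ndarray
    source_id: str

    def __post_init__(self) -> None:
        self.pixels = np.asarray(self.pixels, dtype=np.uint8)
        if self.pixels.ndim != 3 or self.pixels.shape[2] != 3:
            raise ValueError(
                f"expected H x W x 3 pixel array, got shape {self.pixels.shape}"
            )
        if self.pixels.shape[0] < 1 or self.pixels.shape[1] < 1:
            raise ValueError("image must be at least 1 x 1")

    @property
    def height(self) -> int:
        return self.pixels.shape[0]

    @property
    def width(self) -> int:
        return self.pixels.shape[1]


@dataclass
class Tile:
    """One square sub-image with its grid position and optional label.

    ``grid_row``/``grid_col`` are 0-based, row-major, origin at the image's
    top-left; tile (r, c) covers pixel rows [r*S, (r+1)*S) and columns
    [c*S, (c+1)*S).
    """

    pixels: np.ndarray
    grid_row: int
    grid_col: int
    source_id: str
    label: str = LABEL_UNLABELED
    id: str | None = None  # explicit id overrides the grid-derived one

    def __post_init__(self) -> None:
        self.pixels = np.asarray(self.pixels, dtype=np.uint8)
        s0, s1 = self.pixels.shape[:2]
        if self.pixels.ndim != 3 or self.pixels.shape[2] != 3 or s0 != s1:
            raise ValueError(
                f"tile pixels must be S x S x 3, got shape {self.pixels.shape}"
            )
        if self.label not in VALID_LABELS:
            raise ValueError(f"unknown tile label {self.label!r}")

    @property
    def side(self) -> int:
        return self.pixels.shape[0]

    @property
    def tile_id(self) -> str:
        if self.id is not None:
            return self.id
        return f"{self.source_id}:r{self.grid_row:02d}c{self.grid_col:02d}"


@dataclass
class TileManifest:
    """Tabular record of tiles: id, source, grid position, label."""

    records: pd.DataFrame = field(
        default_factory=lambda: pd.DataFrame(columns=MANIFEST_COLUMNS)
    )

    def __post_init__(self) -> None:
        df = pd.DataFrame(self.records, columns=MANIFEST_COLUMNS).copy()
        df["label"] = df["label"].map(_normalize_label)
        bad = sorted(set(df["label"]) - VALID_LABELS)
        if bad:
            raise ManifestError(f"unknown label tokens: {bad}")
        dupes = df["tile_id"][df["tile_id"].duplicated()].tolist()
        if dupes:
            raise ManifestError(f"duplicate tile_id values: {sorted(set(dupes))}")
        df["grid_row"] = df["grid_row"].astype(int)
        df["grid_col"] = df["grid_col"].astype(int)
        self.records = df.reset_index(drop=True)

    def __len__(self) -> int:
        return len(self.records)

    def label_counts(self) -> dict[str, int]:
        return self.records["label"].value_counts().to_dict()


def _normalize_label(token: object) -> str:
    # manifests are hand-edited: case-fold and map spaces/dashes to "_"
    return str(token).strip().lower().replace(" ", "_").replace("-", "_")


def load_image(path: str | os.PathLike, source_id: str | None = None) -> AcquisitionImage:
    """Load a JPEG/PNG raster as an RGB acquisition image.

    Grayscale inputs are replicated to three channels; alpha is dropped.
    """
    if not os.path.exists(path):
        raise FileNotFoundError(f"image file not found: {path}")
    try:
        with Image.open(path) as img:
            rgb = img.convert("RGB")
            pixels = np.asarray(rgb, dtype=np.uint8)
    except UnidentifiedImageError as exc:
        raise ValueError(f"not a decodable image: {path}") from exc
    except OSError as exc:
        raise ValueError(f"corrupt or truncated image: {path}") from exc
    if source_id is None:
        source_id = os.path.splitext(os.path.basename(path))[0]
    return AcquisitionImage(pixels=pixels, source_id=source_id)


def tile_image(img: AcquisitionImage, tile_side: int = DEFAULT_TILE_SIDE) -> list[Tile]:
    """Cut an image into non-overlapping ``tile_side`` squares, row-major.

    Returns floor(H/S) * floor(W/S) tiles; margins that do not fill a whole
    tile are discarded.  An image smaller than one tile yields an empty
    list so batch runs skip degenerate inputs.
    """
    if tile_side < 1:
        raise ValueError("tile_side must be >= 1")
    n_rows = img.height // tile_side
    n_cols = img.width // tile_side
    if n_rows == 0 or n_cols == 0:
        logger.warning(
            "image %s (%d x %d) smaller than one %d px tile; skipping",
            img.source_id, img.width, img.height, tile_side,
        )
        return []
    tiles = []
    for r in range(n_rows):
        for c in range(n_cols):
            block = img.pixels[
                r * tile_side : (r + 1) * tile_side,
                c * tile_side : (c + 1) * tile_side,
            ]
            tiles.append(
                Tile(pixels=block.copy(), grid_row=r, grid_col=c,
                     source_id=img.source_id)
            )
    return tiles


def read_manifest(path: str | os.PathLike) -> TileManifest:
    """Read a tile manifest CSV; labels are case-folded on read."""
    df = pd.read_csv(path, dtype=str)
    missing = [c for c in MANIFEST_COLUMNS if c not in df.columns]
    if missing:
        raise ManifestError(f"manifest {path} missing columns: {missing}")
    return TileManifest(records=df[MANIFEST_COLUMNS])


def write_manifest(manifest: TileManifest, path: str | os.PathLike) -> None:
    manifest.records.to_csv(path, index=False)
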