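"""Assembly of the 134-feature table and z-score normalization.

Each tile is described by 39 color + 43 texture + 52 wavelet features, in
that fixed order; the names are part of the public contract so that a
trained model can refuse a mismatched table.  Normalization records (per-
column mean and population SD) are fit on a chosen row set — typically the
training split only, so that validation folds and the test split see
statistics they did not contribute to.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .color import COLOR_FEATURE_NAMES, color_features
from .config import DEFAULT_FEATURE_CONFIG, FeatureConfig
from .texture import TEXTURE_FEATURE_NAMES, texture_features
from .tiling import Tile, TileManifest
from .wavelet import WAVELET_FEATURE_NAMES, wavelet_features

#: All 134 feature names in extraction order (39 color, 43 texture, 52 wavelet).
FEATURE_NAMES: tuple[str, ...] = (
    COLOR_FEATURE_NAMES + TEXTURE_FEATURE_NAMES + WAVELET_FEATURE_NAMES
)

LABEL_COLUMN = "label"


@dataclass
class NormalizationRecord:
    """Per-column mean and population SD fitted on a specific row set."""

    mean: pd.Series
    sd: pd.Series
    fit_rows: tuple[str, ...]

    def __post_init__(self) -> None:
        if not self.mean.index.equals(self.sd.index):
            raise ValueError("mean and sd must cover the same columns")
        if (self.sd < 0).any():
            raise ValueError("negative standard deviation in record")


def extract_features(
    tile: Tile, cfg: FeatureConfig = DEFAULT_FEATURE_CONFIG
) -> pd.Series:
    """The 134-feature vector of one tile, indexed by feature name."""
    values: dict[str, float] = {}
    values.update(color_features(tile, cfg.color))
    values.update(texture_features(tile, cfg.texture))
    values.update(wavelet_features(tile, cfg.wavelet))
    vec = pd.Series(values, dtype=float).reindex(list(FEATURE_NAMES))
    bad = vec.index[~np.isfinite(vec.to_numpy())].tolist()
    if bad:
        raise ValueError(f"non-finite feature values for {tile.tile_id}: {bad}")
    return vec


def extract_feature_table(
    tiles: list[Tile], cfg: FeatureConfig = DEFAULT_FEATURE_CONFIG
) -> pd.DataFrame:
    """Feature table for a tile set: one row per tile, label in the last
    column, tile_id as the index."""
    rows = {t.tile_id: extract_features(t, cfg) for t in tiles}
    table = pd.DataFrame.from_dict(rows, orient="index", columns=list(FEATURE_NAMES))
    table[LABEL_COLUMN] = [t.label for t in tiles]
    table.index.name = "tile_id"
    table.attrs["schema_hash"] = cfg.schema_hash()
    return table


def attach_labels(table: pd.DataFrame, manifest: TileManifest) -> pd.DataFrame:
    """Overwrite the label column from a manifest, matching on tile_id."""
    labels = manifest.records.set_index("tile_id")["label"]
    out = table.copy()
    out[LABEL_COLUMN] = labels.reindex(out.index)
    return out


def feature_matrix(table: pd.DataFrame) -> pd.DataFrame:
    """The numeric feature columns of a table, in canonical order."""
    missing = [c for c in FEATURE_NAMES if c not in table.columns]
    if missing:
        raise ValueError(f"table is missing feature columns: {missing[:5]} ...")
    return table[list(FEATURE_NAMES)]


def zscore_fit(table: pd.DataFrame, rows: list[str] | None = None) -> NormalizationRecord:
    """Fit per-column mean and population SD on the given rows."""
    x = feature_matrix(table)
    if rows is not None:
        if len(rows) == 0:
            raise ValueError("cannot fit normalization on an empty row set")
        x = x.loc[list(rows)]
    return NormalizationRecord(
        mean=x.mean(axis=0),
        sd=x.std(axis=0, ddof=0),
        fit_rows=tuple(x.index),
    )


def zscore_apply(table: pd.DataFrame, record: NormalizationRecord) -> pd.DataFrame:
    """Map x -> (x - mean) / sd per column; constant columns map to 0."""
    x = feature_matrix(table)
    if list(x.columns) != list(record.mean.index):
        diff = set(x.columns) ^ set(record.mean.index)
        raise ValueError(f"feature columns do not match record: {sorted(diff)[:5]}")
    sd = record.sd.replace(0.0, np.nan)
    z = (x - record.mean) / sd
    z = z.fillna(0.0)
    if LABEL_COLUMN in table.columns:
        z[LABEL_COLUMN] = table[LABEL_COLUMN]
    return z


def write_feature_table(table: pd.DataFrame, path) -> None:
    table.to_csv(path, index=True)


def read_feature_table(path) -> pd.DataFrame:
    table = pd.read_csv(path, index_col="tile_id")
    feature_matrix(table)  # validates schema
    return table
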