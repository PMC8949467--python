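"""Run-wide configuration for the feature extractor and cascade trainer.

All tunables that the individual modules expose are collected here so a
single object can be logged with a run and reused for prediction.  The
defaults are the package's fixed conventions; anything not listed here is
not configurable.
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
import logging
from dataclasses import dataclass, field

logger = logging.getLogger("rrfdetect")

#: Tile side in pixels.  110 px tiles cut a 1653 x 1239 acquisition into a
#: 15 x 11 grid of 165 tiles.
DEFAULT_TILE_SIDE = 110

#: Class vocabulary for tile labels.
LABEL_RAGGED = "ragged"
LABEL_NOT_RAGGED = "not_ragged"
LABEL_WASTE = "waste"
LABEL_UNLABELED = "unlabeled"
CLASS_LABELS = (LABEL_RAGGED, LABEL_NOT_RAGGED, LABEL_WASTE)

#: Stage-level labels used by the cascade.
LABEL_TISSUE = "tissue"


@dataclass(frozen=True)
class ColorConfig:
    """First-order color statistics over HSV channels."""

    n_bins: int = 32  # histogram bins for entropy/uniformity


@dataclass(frozen=True)
class TextureConfig:
    """Gray-level matrix texture features."""

    n_gray_levels: int = 32
    glcm_distance: int = 1
    #: angles in degrees; GLCM and GLRLM are averaged over these.
    angles: tuple[int, ...] = (0, 45, 90, 135)


@dataclass(frozen=True)
class WaveletConfig:
    """One-level 2D discrete wavelet decomposition."""

    filter: str = "la8"  # least-asymmetric Daubechies, 8 taps
    boundary: str = "periodic"
    n_bins: int = 32


@dataclass(frozen=True)
class FeatureConfig:
    color: ColorConfig = field(default_factory=ColorConfig)
    texture: TextureConfig = field(default_factory=TextureConfig)
    wavelet: WaveletConfig = field(default_factory=WaveletConfig)

    def schema_hash(self) -> str:
        """Stable digest of the configuration, recorded with feature tables."""
        payload = json.dumps(dataclasses.asdict(self), sort_keys=True)
        return hashlib.sha256(payload.encode()).hexdigest()[:16]


DEFAULT_FEATURE_CONFIG = FeatureConfig()
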