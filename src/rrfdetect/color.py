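"""HSV color features: 13 first-order statistics per channel, 39 in total.

Tiles are mapped from RGB to HSV (each channel scaled to [0, 1]) and each
channel plane is summarised by the standard radiomics first-order panel:
moment statistics on the raw values plus histogram entropy/uniformity on a
fixed equal-width binning of the observed range.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from skimage.color import rgb2hsv

from .config import ColorConfig, DEFAULT_FEATURE_CONFIG
from .tiling import Tile

#: The 13 first-order statistics, in output order.
FIRST_ORDER_STATS = (
    "mean", "median", "min", "max", "range", "variance",
    "mean_absolute_deviation", "root_mean_square", "skewness", "kurtosis",
    "energy", "entropy", "uniformity",
)

HSV_CHANNELS = ("h", "s", "v")

COLOR_FEATURE_NAMES = tuple(
    f"color.{ch}.{stat}" for ch in HSV_CHANNELS for stat in FIRST_ORDER_STATS
)


@dataclass
class HSVTile:
    """Hue/saturation/value planes of one tile, each in [0, 1]."""

    h: np.ndarray
    s: np.ndarray
    v: np.ndarray


def rgb_to_hsv(tile: Tile) -> HSVTile:
    """Standard RGB -> HSV conversion; hue wraps on [0, 1).

    Achromatic pixels get S = 0 and, by convention, H = 0.
    """
    hsv = rgb2hsv(tile.pixels)
    return HSVTile(h=hsv[..., 0], s=hsv[..., 1], v=hsv[..., 2])


def first_order_stats(values: np.ndarray, n_bins: int = 32) -> dict[str, float]:
    """The 13-statistic first-order panel for a collection of real values.

    Moments use the population convention (variance with denominator n;
    skewness and kurtosis as standardized third and fourth moments, both
    defined as 0 for a zero-variance sample so blank tiles stay finite).
    Energy is the mean of squared values.  Entropy (base 2) and uniformity
    are computed on an equal-width ``n_bins`` histogram spanning the
    observed [min, max]; a constant input occupies a single bin, giving
    entropy 0 and uniformity 1.
    """
    x = np.asarray(values, dtype=float).ravel()
    if x.size == 0:
        raise ValueError("first_order_stats requires a non-empty collection")
    if n_bins < 1:
        raise ValueError("n_bins must be >= 1")

    mean = float(x.mean())
    vmin = float(x.min())
    vmax = float(x.max())
    var = float(x.var())  # population
    sd = np.sqrt(var)
    centered = x - mean
    if sd > 0:
        skew = float(np.mean(centered**3) / sd**3)
        kurt = float(np.mean(centered**4) / sd**4)
    else:
        skew = 0.0
        kurt = 0.0

    if vmax > vmin:
        counts, _ = np.histogram(x, bins=n_bins, range=(vmin, vmax))
    else:
        counts = np.array([x.size])
    p = counts[counts > 0] / x.size
    entropy = float(-(p * np.log2(p)).sum() + 0.0)  # + 0.0 avoids -0.0
    uniformity = float((p**2).sum())

    return {
        "mean": mean,
        "median": float(np.median(x)),
        "min": vmin,
        "max": vmax,
        "range": vmax - vmin,
        "variance": var,
        "mean_absolute_deviation": float(np.abs(centered).mean()),
        "root_mean_square": float(np.sqrt(np.mean(x**2))),
        "skewness": skew,
        "kurtosis": kurt,
        "energy": float(np.mean(x**2)),
        "entropy": entropy,
        "uniformity": uniformity,
    }


def color_features(
    tile: Tile, cfg: ColorConfig = DEFAULT_FEATURE_CONFIG.color
) -> dict[str, float]:
    """39 color features: the first-order panel over the H, S and V planes."""
    hsv = rgb_to_hsv(tile)
    out: dict[str, float] = {}
    for ch in HSV_CHANNELS:
        stats = first_order_stats(getattr(hsv, ch), n_bins=cfg.n_bins)
        for stat in FIRST_ORDER_STATS:
            out[f"color.{ch}.{stat}"] = stats[stat]
    return out
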