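"""One-level 2D discrete wavelet features (52 in total).

The grayscale tile is decomposed with the 8-tap least-asymmetric Daubechies
orthonormal filter pair (PyWavelets ``sym4``) using periodic boundary
extension, which keeps the transform exactly orthonormal: the four
quarter-size subbands (LL approximation; LH, HL, HH details) conserve the
input's energy and reconstruct it perfectly.  Each subband's coefficients
are summarised by the same 13-statistic first-order panel used for the
color channels, giving 4 x 13 = 52 features.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pywt

from .color import FIRST_ORDER_STATS, first_order_stats
from .config import DEFAULT_FEATURE_CONFIG, WaveletConfig
from .texture import to_gray
from .tiling import Tile

#: PyWavelets name of the least-asymmetric Daubechies length-8 filter.
LA8 = "sym4"
#: Periodic ("periodization") extension preserves orthonormality exactly.
_MODE = "periodization"

MIN_SIDE = pywt.Wavelet(LA8).dec_len  # 8-tap filter

SUBBANDS = ("ll", "lh", "hl", "hh")

WAVELET_FEATURE_NAMES = tuple(
    f"wavelet.{band}.{stat}" for band in SUBBANDS for stat in FIRST_ORDER_STATS
)


@dataclass
class SubbandSet:
    """The four quarter-size coefficient planes of a one-level 2D DWT.

    ``input_shape`` records the decomposed image's dimensions so the
    inverse transform can undo the padding that periodization applies to
    odd lengths.  For even dimensions the transform is exactly orthonormal
    (energy-conserving); odd dimensions are padded and gain redundancy.
    """

    ll: np.ndarray
    lh: np.ndarray
    hl: np.ndarray
    hh: np.ndarray
    input_shape: tuple[int, int] | None = None

    def planes(self) -> dict[str, np.ndarray]:
        return {"ll": self.ll, "lh": self.lh, "hl": self.hl, "hh": self.hh}


def dwt2(gray: np.ndarray) -> SubbandSet:
    """One-level separable 2D DWT with the la8 filter, periodic boundaries.

    Requires the image side to be at least the filter length (8).
    """
    gray = np.asarray(gray, dtype=float)
    if min(gray.shape) < MIN_SIDE:
        raise ValueError(
            f"image side {min(gray.shape)} is below the minimum of {MIN_SIDE}"
            " (filter length)"
        )
    ll, (lh, hl, hh) = pywt.dwt2(gray, LA8, mode=_MODE)
    return SubbandSet(ll=ll, lh=lh, hl=hl, hh=hh, input_shape=gray.shape)


def idwt2(bands: SubbandSet) -> np.ndarray:
    """Inverse of :func:`dwt2`; reconstructs the input to round-off."""
    rec = pywt.idwt2((bands.ll, (bands.lh, bands.hl, bands.hh)), LA8, mode=_MODE)
    if bands.input_shape is not None:
        rec = rec[: bands.input_shape[0], : bands.input_shape[1]]
    return rec


def wavelet_features(
    tile: Tile, cfg: WaveletConfig = DEFAULT_FEATURE_CONFIG.wavelet
) -> dict[str, float]:
    """52 wavelet features: the first-order panel per subband."""
    bands = dwt2(to_gray(tile))
    out: dict[str, float] = {}
    for band, plane in bands.planes().items():
        stats = first_order_stats(plane, n_bins=cfg.n_bins)
        for stat in FIRST_ORDER_STATS:
            out[f"wavelet.{band}.{stat}"] = stats[stat]
    return out
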