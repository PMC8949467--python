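"""Second-order texture features from gray-level matrices (43 in total).

The tile is converted to luminance, quantized to ``Ng`` gray levels by
equal-width binning of its own range, and summarised by three matrix
families:

* GLCM ``P(i,j | delta, theta)`` — counts of ordered gray-level pairs at a
  fixed pixel offset, accumulated symmetrically; 21 Haralick-style
  features, averaged over the four standard angles.
* GLRLM ``P(i,j | theta)`` — counts of maximal collinear runs of equal
  level, by level i and run length j; 11 features averaged over angles.
* GLSZM ``P(i,j)`` — counts of 8-connected equal-level zones by level and
  zone size; direction-independent, so a single matrix; 11 features.

Formulas follow the standard Haralick / Galloway / Thibault definitions;
logarithms are base 2.  Degenerate single-level images yield defined
values everywhere (entropy 0, correlation 0 when a marginal variance
vanishes).
"""

from __future__ import annotations

import numpy as np
from scipy import ndimage

from .config import DEFAULT_FEATURE_CONFIG, TextureConfig
from .tiling import Tile

GLCM_FEATURES = (
    "mean", "variance", "autocorrelation", "cluster_prominence",
    "cluster_shade", "cluster_tendency", "contrast", "correlation",
    "difference_entropy", "dissimilarity", "energy", "entropy",
    "homogeneity1", "homogeneity2", "idmn", "idn", "inverse_variance",
    "maximum_probability", "sum_average", "sum_entropy", "sum_variance",
)
GLRLM_FEATURES = (
    "sre", "lre", "gln", "rln", "rp",
    "lglre", "hglre", "srlgle", "srhgle", "lrlgle", "lrhgle",
)
GLSZM_FEATURES = (
    "sae", "lae", "intensity_variability", "size_zone_variability",
    "zone_percentage", "lie", "hie", "lisae", "hisae", "lilae", "hilae",
)

TEXTURE_FEATURE_NAMES = tuple(
    [f"texture.glcm.{f}" for f in GLCM_FEATURES]
    + [f"texture.glrlm.{f}" for f in GLRLM_FEATURES]
    + [f"texture.glszm.{f}" for f in GLSZM_FEATURES]
)

#: (row, col) steps for the four standard angles.  Angles differing by
#: 180 degrees index the same pixel-pair / run family.
ANGLE_OFFSETS = {0: (0, 1), 45: (-1, 1), 90: (-1, 0), 135: (-1, -1)}

def _entropy2(p: np.ndarray) -> float:
    """Shannon entropy in bits of a positive probability vector."""
    return float(-(p * np.log2(p)).sum() + 0.0)


def to_gray(tile: Tile) -> np.ndarray:
    """Luminance plane, 0.299 R + 0.587 G + 0.114 B, range [0, 255]."""
    rgb = tile.pixels.astype(float)
    return 0.299 * rgb[..., 0] + 0.587 * rgb[..., 1] + 0.114 * rgb[..., 2]


def quantize(gray: np.ndarray, n_gray_levels: int = 32) -> np.ndarray:
    """Equal-width quantization of the image's own range into levels 1..Ng.

    The maximum value maps to level Ng; a constant image maps entirely to
    level 1.  Quantization is monotone in the input values.
    """
    if n_gray_levels < 1:
        raise ValueError("n_gray_levels must be >= 1")
    gray = np.asarray(gray, dtype=float)
    lo, hi = gray.min(), gray.max()
    if hi == lo:
        return np.ones(gray.shape, dtype=np.int64)
    levels = np.floor((gray - lo) / (hi - lo) * n_gray_levels).astype(np.int64) + 1
    return np.clip(levels, 1, n_gray_levels)


# ---------------------------------------------------------------------------
# Matrix builders
# ---------------------------------------------------------------------------

def glcm_matrix(
    q: np.ndarray, n_gray_levels: int, distance: int = 1, angle: int = 0,
    symmetric: bool = True,
) -> np.ndarray:
    """Co-occurrence count matrix for one offset.  Index (i-1, j-1) holds
    the number of ordered pairs (i, j) at the given distance and angle;
    with ``symmetric`` both orderings of each pair are accumulated."""
    dr, dc = ANGLE_OFFSETS[angle]
    dr, dc = dr * distance, dc * distance
    h, w = q.shape
    r0, r1 = max(0, -dr), min(h, h - dr)
    c0, c1 = max(0, -dc), min(w, w - dc)
    mat = np.zeros((n_gray_levels, n_gray_levels), dtype=np.int64)
    if r0 >= r1 or c0 >= c1:
        return mat
    a = q[r0:r1, c0:c1].ravel() - 1
    b = q[r0 + dr : r1 + dr, c0 + dc : c1 + dc].ravel() - 1
    np.add.at(mat, (a, b), 1)
    if symmetric:
        np.add.at(mat, (b, a), 1)
    return mat


def _lines(q: np.ndarray, angle: int) -> list[np.ndarray]:
    """The maximal 1D pixel lines of the image along one direction."""
    if angle == 0:
        return list(q)
    if angle == 90:
        return list(q.T)
    if angle == 135:  # direction (1,1): main diagonals
        src = q
    else:  # 45, direction (-1,1): diagonals of the vertically flipped image
        src = np.flipud(q)
    h, w = src.shape
    return [np.diagonal(src, offset=k) for k in range(-(h - 1), w)]


def _run_lengths(line: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    """Gray level and length of each maximal run of equal values."""
    line = np.asarray(line)
    if line.size == 0:
        return np.array([], dtype=np.int64), np.array([], dtype=np.int64)
    change = np.flatnonzero(line[1:] != line[:-1])
    starts = np.concatenate(([0], change + 1))
    ends = np.concatenate((change + 1, [line.size]))
    return line[starts].astype(np.int64), (ends - starts).astype(np.int64)


def glrlm_matrix(q: np.ndarray, n_gray_levels: int, angle: int = 0) -> np.ndarray:
    """Run-length count matrix ``P(i, j | theta)`` of shape Ng x max_dim."""
    max_len = max(q.shape)
    mat = np.zeros((n_gray_levels, max_len), dtype=np.int64)
    for line in _lines(q, angle):
        levels, lengths = _run_lengths(line)
        np.add.at(mat, (levels - 1, lengths - 1), 1)
    return mat


def glszm_matrix(q: np.ndarray, n_gray_levels: int) -> np.ndarray:
    """Size-zone count matrix ``P(i, j)``: 8-connected equal-level zones by
    level i and zone size j.  Rotation-independent by construction."""
    structure = np.ones((3, 3), dtype=int)  # chebyshev distance 1
    sizes_per_level: list[tuple[int, np.ndarray]] = []
    max_size = 1
    for level in np.unique(q):
        labeled, n_zones = ndimage.label(q == level, structure=structure)
        if n_zones == 0:
            continue
        sizes = np.bincount(labeled.ravel())[1:]
        sizes_per_level.append((int(level), sizes))
        max_size = max(max_size, int(sizes.max()))
    mat = np.zeros((n_gray_levels, max_size), dtype=np.int64)
    for level, sizes in sizes_per_level:
        np.add.at(mat, (level - 1, sizes - 1), 1)
    return mat


# ---------------------------------------------------------------------------
# Feature panels
# ---------------------------------------------------------------------------

def _glcm_panel(counts: np.ndarray) -> dict[str, float]:
    total = counts.sum()
    p = counts / total
    ng = p.shape[0]
    i = np.arange(1, ng + 1)
    ii, jj = np.meshgrid(i, i, indexing="ij")

    px = p.sum(axis=1)  # symmetric: px == py
    mu = float((i * px).sum())
    sigma2 = float(((i - mu) ** 2 * px).sum())

    # distributions of i+j and |i-j|
    psum = np.zeros(2 * ng - 1)
    np.add.at(psum, (ii + jj).ravel() - 2, p.ravel())
    ksum = np.arange(2, 2 * ng + 1)
    pdiff = np.zeros(ng)
    np.add.at(pdiff, np.abs(ii - jj).ravel(), p.ravel())

    nz = p > 0
    sum_avg = float((ksum * psum).sum())
    autocorr = float((ii * jj * p).sum())
    off = ii != jj

    return {
        "mean": mu,
        "variance": float((((ii - mu) ** 2) * p).sum()),
        "autocorrelation": autocorr,
        "cluster_prominence": float(((ii + jj - 2 * mu) ** 4 * p).sum()),
        "cluster_shade": float(((ii + jj - 2 * mu) ** 3 * p).sum()),
        "cluster_tendency": float(((ii + jj - 2 * mu) ** 2 * p).sum()),
        "contrast": float(((ii - jj) ** 2 * p).sum()),
        "correlation": (autocorr - mu * mu) / sigma2 if sigma2 > 0 else 0.0,
        "difference_entropy": _entropy2(pdiff[pdiff > 0]),
        "dissimilarity": float((np.abs(ii - jj) * p).sum()),
        "energy": float((p**2).sum()),
        "entropy": _entropy2(p[nz]),
        "homogeneity1": float((p / (1.0 + np.abs(ii - jj))).sum()),
        "homogeneity2": float((p / (1.0 + (ii - jj) ** 2)).sum()),
        "idmn": float((p / (1.0 + ((ii - jj) / ng) ** 2)).sum()),
        "idn": float((p / (1.0 + np.abs(ii - jj) / ng)).sum()),
        "inverse_variance": float((p[off] / (ii[off] - jj[off]) ** 2).sum()),
        "maximum_probability": float(p.max()),
        "sum_average": sum_avg,
        "sum_entropy": _entropy2(psum[psum > 0]),
        "sum_variance": float(((ksum - sum_avg) ** 2 * psum).sum()),
    }


def _run_zone_panel(counts: np.ndarray, n_pixels: int, names: tuple[str, ...]) -> dict[str, float]:
    """The 11-feature Galloway/Thibault panel over a Ng x J count matrix.

    ``names`` gives, in order: small-emphasis, large-emphasis, gray-level
    nonuniformity, size nonuniformity, percentage, low-gray emphasis,
    high-gray emphasis, then the four joint small/large x low/high terms.
    """
    n = counts.sum()
    if n == 0:
        raise ValueError("empty run/zone matrix")
    i = np.arange(1, counts.shape[0] + 1, dtype=float)[:, None]
    j = np.arange(1, counts.shape[1] + 1, dtype=float)[None, :]
    c = counts.astype(float)
    vals = (
        (c / j**2).sum(),
        (c * j**2).sum(),
        (c.sum(axis=1) ** 2).sum(),
        (c.sum(axis=0) ** 2).sum(),
        n * n / n_pixels,  # divided by n below -> n_runs / n_pixels
        (c / i**2).sum(),
        (c * i**2).sum(),
        (c / (i**2 * j**2)).sum(),
        (c * i**2 / j**2).sum(),
        (c * j**2 / i**2).sum(),
        (c * i**2 * j**2).sum(),
    )
    out = {name: float(v / n) for name, v in zip(names, vals)}
    return out


def glcm_features(
    q: np.ndarray, n_gray_levels: int, distance: int = 1,
    angles: tuple[int, ...] = (0, 45, 90, 135),
) -> dict[str, float]:
    """The 21 GLCM features, averaged over the angles with valid pairs."""
    panels = []
    for angle in angles:
        counts = glcm_matrix(q, n_gray_levels, distance, angle)
        if counts.sum() > 0:
            panels.append(_glcm_panel(counts))
    if not panels:
        raise ValueError("no valid pixel pairs for any requested angle")
    return {
        f"texture.glcm.{name}": float(np.mean([p[name] for p in panels]))
        for name in GLCM_FEATURES
    }


def glrlm_features(
    q: np.ndarray, n_gray_levels: int, angles: tuple[int, ...] = (0, 45, 90, 135),
) -> dict[str, float]:
    """The 11 run-length features, averaged over angles."""
    panels = [
        _run_zone_panel(glrlm_matrix(q, n_gray_levels, angle), q.size, GLRLM_FEATURES)
        for angle in angles
    ]
    return {
        f"texture.glrlm.{name}": float(np.mean([p[name] for p in panels]))
        for name in GLRLM_FEATURES
    }


def glszm_features(q: np.ndarray, n_gray_levels: int) -> dict[str, float]:
    """The 11 size-zone features from the single direction-free matrix."""
    panel = _run_zone_panel(glszm_matrix(q, n_gray_levels), q.size, GLSZM_FEATURES)
    return {f"texture.glszm.{name}": panel[name] for name in GLSZM_FEATURES}


def texture_features(
    tile: Tile, cfg: TextureConfig = DEFAULT_FEATURE_CONFIG.texture
) -> dict[str, float]:
    """All 43 texture features of one tile."""
    q = quantize(to_gray(tile), cfg.n_gray_levels)
    out = glcm_features(q, cfg.n_gray_levels, cfg.glcm_distance, cfg.angles)
    out.update(glrlm_features(q, cfg.n_gray_levels, cfg.angles))
    out.update(glszm_features(q, cfg.n_gray_levels))
    return out
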