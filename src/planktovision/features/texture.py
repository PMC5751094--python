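"""Texture descriptors: Gabor bank, variogram, grid LBP, binary gradient contours.

Gabor
    A bank of 48 complex filters (6 center frequencies × 8 orientations),
    each with an isotropic Gaussian envelope:

        g(x, y) = 1/(2πσ²) · exp(−(x²+y²)/(2σ²) + 2πjF(x·cosθ + y·sinθ))

    The image is convolved with every filter and the mean and standard
    deviation of the response magnitude |Q| summarize each channel,
    giving a 96-dimensional vector.

Variogram
    The geostatistical function γ(h) = 1/(2N(h)) · Σ [I(x) − I(x+h)]²
    over all N(h) pixel pairs at lag h, averaged over the four principal
    directions, evaluated at a fixed roster of lags.

LBP
    Classical 8-neighbor local binary patterns (neighbor ≥ center sets the
    bit, clockwise from the top-left neighbor, top-left = most significant
    bit), histogrammed per cell of a grid and concatenated — a part-based
    texture signature.

BGC (single loop)
    Signs of the gradients between consecutive neighbors along the closed
    3×3 ring; the 8 sign bits form a code in [0, 254] after the −1 offset
    (ties count as nonnegative, so the all-zero bit pattern cannot occur).
    The descriptor is the normalized 255-bin code histogram.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy.signal import fftconvolve

from planktovision.features._base import FeatureVector

__all__ = [
    "GaborBank",
    "gabor_features",
    "variogram_directional",
    "variogram_features",
    "DEFAULT_LAGS",
    "lbp_code_image",
    "lbp_features",
    "bgc1_code_image",
    "bgc1_features",
]


# --------------------------------------------------------------------------
# Gabor
# --------------------------------------------------------------------------


def _gabor_kernel(frequency: float, theta: float, sigma: float) -> np.ndarray:
    half = int(np.ceil(3.0 * sigma))
    y, x = np.mgrid[-half : half + 1, -half : half + 1].astype(float)
    envelope = np.exp(-(x**2 + y**2) / (2.0 * sigma**2)) / (2.0 * np.pi * sigma**2)
    carrier = np.exp(2j * np.pi * frequency * (x * np.cos(theta) + y * np.sin(theta)))
    return envelope * carrier


@dataclass
class GaborBank:
    """48 complex Gabor filters: 6 frequencies × 8 orientations.

    Frequencies follow a half-octave ladder ``F_k = f0 / √2^k`` and the
    envelope width tracks the frequency (σ = 0.56/F, roughly one octave
    bandwidth).  Orientations are θ_j = jπ/8.
    """

    f0: float = 0.25
    n_frequencies: int = 6
    n_orientations: int = 8
    sigma_factor: float = 0.56
    kernels: list[np.ndarray] = field(default_factory=list, repr=False)

    def __post_init__(self) -> None:
        if not self.kernels:
            for k in range(self.n_frequencies):
                f = self.f0 / (np.sqrt(2.0) ** k)
                sigma = self.sigma_factor / f
                for j in range(self.n_orientations):
                    theta = j * np.pi / self.n_orientations
                    self.kernels.append(_gabor_kernel(f, theta, sigma))

    def __len__(self) -> int:
        return len(self.kernels)


def gabor_features(image: np.ndarray, bank: GaborBank | None = None) -> FeatureVector:
    """Mean and std of |image ∗ g| for every filter in the bank (96 values).

    Ordered frequency-major, orientation-minor, mean before std.
    """
    if bank is None:
        bank = GaborBank()
    image = np.asarray(image, dtype=float)
    out = np.empty(2 * len(bank))
    names = []
    for i, kernel in enumerate(bank.kernels):
        mag = np.abs(fftconvolve(image, kernel, mode="same"))
        out[2 * i] = mag.mean()
        out[2 * i + 1] = mag.std()
        names += [f"g{i}_mean", f"g{i}_std"]
    return FeatureVector(out, "gabor", names)


# --------------------------------------------------------------------------
# variogram
# --------------------------------------------------------------------------

#: log-spaced lags covering fine-to-coarse texture
DEFAULT_LAGS = (1, 2, 3, 4, 6, 8, 12, 16)

#: unit displacement per direction: 0°, 45°, 90°, 135°
_DIRECTIONS = ((0, 1), (1, 1), (1, 0), (1, -1))


def variogram_directional(image: np.ndarray, offset: tuple[int, int]) -> float:
    """γ for a single displacement vector, over all in-bounds pixel pairs."""
    image = np.asarray(image, dtype=float)
    dr, dc = offset
    h, w = image.shape
    if abs(dr) >= h or abs(dc) >= w:
        raise ValueError(f"offset {offset} exceeds image extent {image.shape}")
    r0, r1 = max(0, -dr), min(h, h - dr)
    c0, c1 = max(0, -dc), min(w, w - dc)
    a = image[r0:r1, c0:c1]
    b = image[r0 + dr : r1 + dr, c0 + dc : c1 + dc]
    diff = a - b
    return float((diff**2).sum() / (2.0 * diff.size))


def variogram_features(
    image: np.ndarray,
    mask: np.ndarray | None = None,
    lags: tuple[int, ...] = DEFAULT_LAGS,
) -> FeatureVector:
    """γ(h) per lag, averaged over the four principal directions.

    The image is cropped to the mask's bounding box first when a mask is
    given, so the statistic describes the organism rather than the frame.
    """
    image = np.asarray(image, dtype=float)
    if mask is not None and np.asarray(mask).any():
        rows = np.flatnonzero(np.asarray(mask, bool).any(axis=1))
        cols = np.flatnonzero(np.asarray(mask, bool).any(axis=0))
        image = image[rows[0] : rows[-1] + 1, cols[0] : cols[-1] + 1]
    values, names = [], []
    for h in lags:
        gammas = []
        for dr, dc in _DIRECTIONS:
            off = (dr * h, dc * h)
            if abs(off[0]) < image.shape[0] and abs(off[1]) < image.shape[1]:
                gammas.append(variogram_directional(image, off))
        if not gammas:
            raise ValueError(f"lag {h} admits no pixel pair in a {image.shape} crop")
        values.append(float(np.mean(gammas)))
        names.append(f"gamma_{h}")
    return FeatureVector(np.asarray(values), "variogram", names)


# --------------------------------------------------------------------------
# LBP
# --------------------------------------------------------------------------

# (dr, dc) of the 8 neighbors, clockwise from top-left; first = MSB
_RING = ((-1, -1), (-1, 0), (-1, 1), (0, 1), (1, 1), (1, 0), (1, -1), (0, -1))


def lbp_code_image(image: np.ndarray) -> np.ndarray:
    """8-bit LBP code of every interior pixel (neighbor ≥ center → bit 1)."""
    image = np.asarray(image, dtype=float)
    if image.shape[0] < 3 or image.shape[1] < 3:
        raise ValueError("LBP needs at least a 3x3 image")
    center = image[1:-1, 1:-1]
    codes = np.zeros(center.shape, dtype=np.int32)
    for bit, (dr, dc) in enumerate(_RING):
        nb = image[1 + dr : image.shape[0] - 1 + dr, 1 + dc : image.shape[1] - 1 + dc]
        codes |= (nb >= center).astype(np.int32) << (7 - bit)
    return codes


def lbp_features(image: np.ndarray, grid: int = 4) -> FeatureVector:
    """Concatenated per-cell 256-bin LBP histograms over a grid×grid split.

    Each cell is coded independently on its interior pixels, so a cell's
    histogram totals the number of its interior pixels.
    """
    image = np.asarray(image, dtype=float)
    hists, names = [], []
    for ci, rows in enumerate(np.array_split(image, grid, axis=0)):
        for cj, cell in enumerate(np.array_split(rows, grid, axis=1)):
            if cell.shape[0] < 3 or cell.shape[1] < 3:
                raise ValueError("each grid cell must be at least 3x3")
            codes = lbp_code_image(cell)
            hists.append(np.bincount(codes.ravel(), minlength=256))
            names += [f"c{ci}{cj}_b{b}" for b in range(256)]
    return FeatureVector(np.concatenate(hists).astype(float), "lbp", names)


# --------------------------------------------------------------------------
# BGC1
# --------------------------------------------------------------------------


def bgc1_code_image(image: np.ndarray) -> np.ndarray:
    """Single-loop binary-gradient-contour code of every interior pixel.

    Bits are the signs of differences between consecutive ring neighbors
    (wrapping), MSB first; the −1 offset maps codes into [0, 254].
    """
    image = np.asarray(image, dtype=float)
    if image.shape[0] < 3 or image.shape[1] < 3:
        raise ValueError("BGC needs at least a 3x3 image")

    def neighbor(k: int) -> np.ndarray:
        dr, dc = _RING[k]
        return image[1 + dr : image.shape[0] - 1 + dr, 1 + dc : image.shape[1] - 1 + dc]

    codes = np.zeros(image[1:-1, 1:-1].shape, dtype=np.int32)
    for bit in range(8):
        diff = neighbor(bit) - neighbor((bit + 1) % 8)
        codes |= (diff >= 0).astype(np.int32) << (7 - bit)
    return codes - 1


def bgc1_features(image: np.ndarray) -> FeatureVector:
    """Normalized 255-bin histogram of BGC1 codes over the interior pixels."""
    codes = bgc1_code_image(image)
    hist = np.bincount(codes.ravel(), minlength=255).astype(float)
    hist /= hist.sum()
    return FeatureVector(hist, "bgc", [f"b{b}" for b in range(255)])
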