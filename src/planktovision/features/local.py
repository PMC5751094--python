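"""Local descriptors: HOG over a fixed grid, and SIFT keypoints + bag-of-words.

HOG
    The image is padded to a square with a flat background fill, resized to
    256×256, split into 32×32-pixel cells (an 8×8 grid), and each cell
    contributes a 9-bin unsigned gradient-orientation histogram weighted by
    gradient magnitude.  Concatenation row-major gives 576 values.  No block
    normalization is applied.

SIFT bag-of-words
    Difference-of-Gaussians keypoints with 128-dim SIFT descriptors are
    quantized against a K-means codebook (K = 100 by default, trained on
    the training split only); an image becomes the histogram of its
    keypoints' nearest codewords.  Images without detectable keypoints map
    to the zero vector.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from skimage.feature import SIFT
from skimage.transform import resize
from sklearn.cluster import KMeans

from planktovision.features._base import FeatureVector

__all__ = [
    "hog_features",
    "Codebook",
    "build_codebook",
    "sift_descriptors",
    "sift_bow_features",
]


# --------------------------------------------------------------------------
# HOG
# --------------------------------------------------------------------------

HOG_SIZE = 256
HOG_CELL = 32
HOG_BINS = 9


def _pad_to_square(image: np.ndarray) -> np.ndarray:
    h, w = image.shape
    if h == w:
        return image
    border = np.concatenate([image[0, :], image[-1, :], image[1:-1, 0], image[1:-1, -1]])
    fill = float(np.median(border))
    side = max(h, w)
    out = np.full((side, side), fill, dtype=float)
    r0 = (side - h) // 2
    c0 = (side - w) // 2
    out[r0 : r0 + h, c0 : c0 + w] = image
    return out


def hog_features(image: np.ndarray) -> FeatureVector:
    """576-dim histogram-of-oriented-gradients descriptor on a 256×256 canvas."""
    image = np.asarray(image, dtype=float)
    if image.size == 0:
        raise ValueError("empty image")
    sq = _pad_to_square(image)
    if sq.shape != (HOG_SIZE, HOG_SIZE):
        sq = resize(sq, (HOG_SIZE, HOG_SIZE), anti_aliasing=True, preserve_range=True)
    gy, gx = np.gradient(sq)
    mag = np.hypot(gx, gy)
    ang = np.mod(np.arctan2(gy, gx), np.pi)  # unsigned orientation in [0, π)
    bins = np.minimum((ang / (np.pi / HOG_BINS)).astype(int), HOG_BINS - 1)

    grid = HOG_SIZE // HOG_CELL
    out = np.zeros((grid, grid, HOG_BINS))
    names = []
    for i in range(grid):
        for j in range(grid):
            sl = (slice(i * HOG_CELL, (i + 1) * HOG_CELL), slice(j * HOG_CELL, (j + 1) * HOG_CELL))
            out[i, j] = np.bincount(bins[sl].ravel(), weights=mag[sl].ravel(), minlength=HOG_BINS)
            names += [f"c{i}{j}_o{b}" for b in range(HOG_BINS)]
    return FeatureVector(out.ravel(), "hog", names)


# --------------------------------------------------------------------------
# SIFT bag-of-words
# --------------------------------------------------------------------------


@dataclass
class Codebook:
    """K-means centers over 128-dim SIFT descriptor space."""

    centers: np.ndarray
    seed: int

    @property
    def k(self) -> int:
        return int(self.centers.shape[0])


def sift_descriptors(image: np.ndarray) -> np.ndarray:
    """Detect DoG keypoints and return their descriptors, shape (n, 128).

    Returns an empty (0, 128) array when no keypoint can be extracted
    (blank or too-small images).
    """
    image = np.asarray(image, dtype=float)
    rng = np.ptp(image)
    if rng == 0:
        return np.zeros((0, 128))
    norm = (image - image.min()) / rng
    det = SIFT()
    try:
        det.detect_and_extract(norm)
    except RuntimeError:
        return np.zeros((0, 128))
    if det.descriptors is None or len(det.descriptors) == 0:
        return np.zeros((0, 128))
    return np.asarray(det.descriptors, dtype=float)


def build_codebook(descriptors: np.ndarray, k: int = 100, seed: int = 0) -> Codebook:
    """Cluster descriptors into a K-word codebook (k-means++, fixed seed)."""
    descriptors = np.asarray(descriptors, dtype=float)
    if descriptors.ndim != 2 or descriptors.shape[0] < k:
        raise ValueError(
            f"need at least k={k} descriptors to build the codebook, got "
            f"{descriptors.shape[0]}; lower k or supply more training images"
        )
    km = KMeans(n_clusters=k, n_init=1, random_state=seed).fit(descriptors)
    return Codebook(centers=km.cluster_centers_, seed=seed)


def sift_bow_features(image: np.ndarray, codebook: Codebook) -> FeatureVector:
    """Histogram of nearest-codeword assignments of the image's keypoints."""
    desc = sift_descriptors(image)
    hist = np.zeros(codebook.k)
    if len(desc):
        d2 = ((desc[:, None, :] - codebook.centers[None, :, :]) ** 2).sum(axis=2)
        words = d2.argmin(axis=1)
        hist = np.bincount(words, minlength=codebook.k).astype(float)
    return FeatureVector(hist, "sift", [f"w{i}" for i in range(codebook.k)])
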