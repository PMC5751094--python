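"""Geometric + grayscale features (43-dim) and morphological granulometry.

The geometric/grayscale group summarizes the segmented organism with 25
size-and-shape measurements, 8 intensity statistics over the foreground,
and 10 moment invariants of the foreground intensity — 43 elements total.

Granulometry measures the size distribution of the binary silhouette with a
series of morphological openings by flat disks of increasing diameter λ:
``F_B(λ) = 1 − v(B ∘ λT) / v(B)`` where ``v`` counts foreground pixels.
``F_B`` rises from 0 to 1 as the disk grows past the silhouette's internal
structures, so the curve is a multiscale shape signature.  Two element-size
setups are used: diameters 2..50 step 4 (13 values) and 5..60 step 5
(12 values).
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy import ndimage, stats
from scipy.spatial import ConvexHull
from skimage import measure

from planktovision.features._base import FeatureVector

__all__ = [
    "geometric_grayscale_features",
    "GranulometrySetup",
    "SETUP1",
    "SETUP2",
    "granulometry_curve",
    "GEOMETRIC_FEATURE_NAMES",
]


# --------------------------------------------------------------------------
# geometric + grayscale (43 elements)
# --------------------------------------------------------------------------

GEOMETRIC_FEATURE_NAMES = [
    # 25 geometric
    "area",
    "filled_area",
    "convex_area",
    "convex_rate",
    "perimeter",
    "convex_perimeter",
    "circularity",
    "eccentricity",
    "elongation",
    "major_axis",
    "minor_axis",
    "equivalent_diameter",
    "extent",
    "solidity",
    "orientation_sin",
    "orientation_cos",
    "bbox_aspect",
    "feret_max",
    "feret_min",
    "feret_ratio",
    "euler_number",
    "hole_count",
    "hole_area_fraction",
    "boundary_roughness",
    "radial_dispersion",
    # 8 grayscale statistics over the foreground
    "gray_sum",
    "gray_mean",
    "gray_std",
    "gray_min",
    "gray_max",
    "gray_median",
    "gray_skewness",
    "gray_kurtosis",
    # 10 intensity-weighted moment invariants
    "hu1",
    "hu2",
    "hu3",
    "hu4",
    "hu5",
    "hu6",
    "hu7",
    "nu11",
    "nu20",
    "nu02",
]


def _feret_diameters(mask: np.ndarray) -> tuple[float, float]:
    """Maximum and minimum caliper diameters of the foreground pixel set."""
    pts = np.argwhere(mask).astype(float)
    if len(pts) == 1:
        return 1.0, 1.0
    try:
        hull = ConvexHull(pts)
        verts = pts[hull.vertices]
    except Exception:  # collinear / degenerate point sets
        verts = pts
    d = verts[:, None, :] - verts[None, :, :]
    feret_max = float(np.sqrt((d**2).sum(-1)).max()) + 1.0
    # rotating calipers: min width is attained on a hull-edge normal
    edges = np.diff(np.vstack([verts, verts[:1]]), axis=0)
    lengths = np.sqrt((edges**2).sum(axis=1))
    keep = lengths > 1e-12
    if keep.any():
        u = edges[keep] / lengths[keep, None]
        normals = np.stack([-u[:, 1], u[:, 0]], axis=1)
    else:
        normals = np.array([[1.0, 0.0], [0.0, 1.0]])
    proj = verts @ normals.T  # projections of vertices on each edge normal
    widths = proj.max(axis=0) - proj.min(axis=0)
    feret_min = float(widths.min()) + 1.0
    return feret_max, feret_min


def geometric_grayscale_features(image: np.ndarray, mask: np.ndarray) -> FeatureVector:
    """Compute the 43-element geometric and grayscale feature vector.

    All foreground pixels are treated as one region (the organism may be
    fragmented after thresholding).  Raises ``ValueError`` on an empty mask.
    """
    image = np.asarray(image, dtype=float)
    mask = np.asarray(mask, dtype=bool)
    if image.shape != mask.shape:
        raise ValueError("image/mask shape mismatch")
    if not mask.any():
        raise ValueError("empty mask: no object to measure")

    region = measure.regionprops(mask.astype(np.uint8), intensity_image=image)[0]

    area = float(region.area)
    filled_area = float(region.area_filled)
    convex_area = float(region.area_convex)
    perimeter = max(float(region.perimeter), 1.0)
    convex_perimeter = max(float(measure.perimeter(region.image_convex)), 1.0)
    major = float(region.axis_major_length)
    minor = float(region.axis_minor_length)
    ori = float(region.orientation)

    n_comp = int(ndimage.label(mask, structure=np.ones((3, 3)))[1])
    filled = ndimage.binary_fill_holes(mask)
    holes = filled & ~mask
    hole_count = int(ndimage.label(holes)[1])

    boundary = mask & ~ndimage.binary_erosion(mask)
    com = np.array(ndimage.center_of_mass(mask))
    radii = np.sqrt(((np.argwhere(boundary) - com) ** 2).sum(axis=1))
    radial_mean = max(float(radii.mean()), 1e-12)

    feret_max, feret_min = _feret_diameters(mask)

    minr, minc, maxr, maxc = region.bbox
    bbox_aspect = (maxc - minc) / (maxr - minr)

    fg = image[mask]
    gray_std = float(fg.std())
    if gray_std > 1e-12:
        skewness = float(stats.skew(fg))
        kurt = float(stats.kurtosis(fg))
    else:
        skewness, kurt = 0.0, 0.0

    hu = np.asarray(region.moments_weighted_hu, dtype=float)
    nu = np.asarray(region.moments_weighted_normalized, dtype=float)

    values = [
        area,
        filled_area,
        convex_area,
        area / convex_area,
        perimeter,
        convex_perimeter,
        4.0 * np.pi * area / perimeter**2,
        float(region.eccentricity),
        major / max(minor, 1.0),
        major,
        minor,
        float(region.equivalent_diameter_area),
        float(region.extent),
        float(region.solidity),
        np.sin(ori),
        np.cos(ori),
        bbox_aspect,
        feret_max,
        feret_min,
        feret_max / feret_min,
        float(n_comp - hole_count),
        float(hole_count),
        (filled_area - area) / filled_area,
        perimeter / convex_perimeter,
        float(radii.std()) / radial_mean,
        float(fg.sum()),
        float(fg.mean()),
        gray_std,
        float(fg.min()),
        float(fg.max()),
        float(np.median(fg)),
        skewness,
        kurt,
        *hu.tolist(),
        float(nu[1, 1]),
        float(nu[2, 0]),
        float(nu[0, 2]),
    ]
    out = np.nan_to_num(np.asarray(values, dtype=float), nan=0.0, posinf=0.0, neginf=0.0)
    return FeatureVector(out, "geometric-grayscale", list(GEOMETRIC_FEATURE_NAMES))


# --------------------------------------------------------------------------
# granulometry
# --------------------------------------------------------------------------


@dataclass(frozen=True)
class GranulometrySetup:
    """Strictly increasing roster of structuring-element diameters (pixels)."""

    element_sizes: tuple[int, ...]

    def __post_init__(self) -> None:
        sizes = self.element_sizes
        if not sizes or any(s < 1 for s in sizes):
            raise ValueError("element sizes must be >= 1")
        if any(b <= a for a, b in zip(sizes, sizes[1:])):
            raise ValueError("element sizes must be strictly increasing")


SETUP1 = GranulometrySetup(tuple(range(2, 51, 4)))  # 13 diameters
SETUP2 = GranulometrySetup(tuple(range(5, 61, 5)))  # 12 diameters


def _opened_pixel_count(mask: np.ndarray, diameter: int) -> int:
    """Area of the morphological opening by a flat disk of given diameter.

    The disk element is ``{(i, j): i² + j² ≤ (diameter/2)²}``.  The opening
    is computed through Euclidean distance transforms, which is exactly
    equivalent to erosion-then-dilation with the explicit element (outside
    the frame counts as background; the caller pads accordingly).
    Integer squared distances keep the comparison exact.
    """
    d2x4 = diameter * diameter  # compare 4·dist² with diameter²
    dist = ndimage.distance_transform_edt(mask)
    dist2x4 = np.round(4.0 * dist * dist).astype(np.int64)
    eroded = dist2x4 > d2x4
    if not eroded.any():
        return 0
    dist_bg = ndimage.distance_transform_edt(~eroded)
    dist_bg2x4 = np.round(4.0 * dist_bg * dist_bg).astype(np.int64)
    opened = eroded | (dist_bg2x4 <= d2x4)
    return int(np.count_nonzero(opened))


def granulometry_curve(
    mask: np.ndarray,
    setup: GranulometrySetup = SETUP1,
    group: str = "granulometry1",
) -> FeatureVector:
    """Granulometric size distribution ``F_B(λ)`` over the setup's diameters.

    Each value is the fraction of foreground removed by opening with a disk
    of diameter λ; the curve is nondecreasing in λ and bounded in [0, 1].
    """
    mask = np.asarray(mask, dtype=bool)
    total = int(np.count_nonzero(mask))
    if total == 0:
        raise ValueError("empty mask: granulometry undefined")
    pad = setup.element_sizes[-1] // 2 + 2
    padded = np.pad(mask, pad)
    values = [
        1.0 - _opened_pixel_count(padded, lam) / total for lam in setup.element_sizes
    ]
    names = [f"F_{lam}" for lam in setup.element_sizes]
    return FeatureVector(np.asarray(values), group, names)
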