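"""Inner-distance shape context (IDSC) and template-library shape features.

A silhouette is represented by ``n`` points sampled uniformly by arclength
along its outer contour.  Instead of Euclidean distances, point pairs are
related by the *inner distance*: the length of the shortest path between
them that stays inside the silhouette (computed on the visibility graph of
the sample points).  Each point gets a log-polar histogram of the other
``n−1`` points over (inner distance, inner angle) bins; inner angles are
measured between the departing direction of the shortest path and the local
contour tangent, which makes the descriptor insensitive to articulation.

Two shapes are compared by the χ²/2 cost between point histograms and an
order-preserving circular correspondence found by dynamic programming with
a fixed per-point occlusion penalty; the minimal matching cost is the shape
distance.  An image's shape feature vector is its distance to every
template in a per-category template library (three templates per category).
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from numba import njit
from scipy import ndimage
from scipy.sparse import csr_matrix
from scipy.sparse.csgraph import shortest_path
from skimage import measure

from planktovision.features._base import FeatureVector

__all__ = [
    "ShapeSample",
    "sample_boundary",
    "idsc_histograms",
    "match_cost",
    "cost_matrix",
    "shape_distance",
    "TemplateLibrary",
    "idsc_features",
]

DEFAULT_N_POINTS = 100
DEFAULT_DIST_BINS = 8
DEFAULT_ANGLE_BINS = 12
DEFAULT_PENALTY = 0.3

# relative inner-distance range covered by the log bins (fractions of the
# mean inner distance); values outside are clamped into the end bins
_REL_DIST_RANGE = (0.125, 2.0)


@dataclass
class ShapeSample:
    """Sampled contour points with inner-distance / inner-angle structure."""

    points: np.ndarray          # (n, 2) float, (row, col), contour order
    inner_dist: np.ndarray      # (n, n) shortest within-shape path lengths
    inner_angle: np.ndarray     # (n, n) tangent-relative departure angle
    tangents: np.ndarray = field(default=None, repr=False)

    @property
    def n(self) -> int:
        return int(self.points.shape[0])


def _largest_component(mask: np.ndarray) -> np.ndarray:
    lab, nlab = ndimage.label(mask, structure=np.ones((3, 3)))
    if nlab == 0:
        raise ValueError("empty mask: no shape to sample")
    sizes = np.bincount(lab.ravel())[1:]
    return lab == (int(sizes.argmax()) + 1)


def _resample_contour(contour: np.ndarray, n: int) -> np.ndarray:
    """n points equally spaced by arclength along a closed polyline."""
    pts = contour
    if np.allclose(pts[0], pts[-1]):
        pts = pts[:-1]
    # counterclockwise orientation (positive signed area with x=col, y=row)
    nxt = np.roll(pts, -1, axis=0)
    signed = 0.5 * np.sum(pts[:, 1] * nxt[:, 0] - nxt[:, 1] * pts[:, 0])
    if signed < 0:
        pts = pts[::-1]
    # canonical start: lexicographically smallest vertex
    start = np.lexsort((pts[:, 1], pts[:, 0]))[0]
    pts = np.roll(pts, -start, axis=0)
    closed = np.vstack([pts, pts[:1]])
    seg = np.sqrt(((np.diff(closed, axis=0)) ** 2).sum(axis=1))
    cum = np.concatenate([[0.0], np.cumsum(seg)])
    total = cum[-1]
    if total <= 0:
        raise ValueError("degenerate contour")
    targets = np.arange(n) * total / n
    idx = np.searchsorted(cum, targets, side="right") - 1
    idx = np.clip(idx, 0, len(seg) - 1)
    frac = (targets - cum[idx]) / np.maximum(seg[idx], 1e-12)
    return closed[idx] + frac[:, None] * (closed[idx + 1] - closed[idx])


def _visible(points: np.ndarray, inside: np.ndarray) -> np.ndarray:
    """Boolean (n, n) line-of-sight table: segment lies inside the shape."""
    n = len(points)
    h, w = inside.shape
    vis = np.zeros((n, n), dtype=bool)
    d = np.sqrt(((points[:, None, :] - points[None, :, :]) ** 2).sum(-1))
    n_steps = int(np.ceil(d.max())) * 2 + 2
    t = np.linspace(0.0, 1.0, n_steps)
    for i in range(n):
        # sample every segment from point i at fixed parameter steps
        seg = points[i][None, None, :] + t[None, :, None] * (
            points[None, :, :] - points[i][None, None, :]
        ).transpose(1, 0, 2)
        rr = np.clip(np.round(seg[..., 0]).astype(int), 0, h - 1)
        cc = np.clip(np.round(seg[..., 1]).astype(int), 0, w - 1)
        vis[i] = inside[rr, cc].all(axis=1)
    return vis


def sample_boundary(mask: np.ndarray, n: int = DEFAULT_N_POINTS) -> ShapeSample:
    """Sample ``n`` arclength-uniform contour points and build the inner graph.

    Only the largest 8-connected component defines the shape (marine-snow
    remnants must not perturb the contour).  Line-of-sight tests run on the
    mask dilated by one pixel to absorb raster discretization at the
    boundary; shortest paths are completed by Dijkstra search, with the
    contour ring itself always connected.
    """
    mask = np.asarray(mask, dtype=bool)
    comp = _largest_component(mask)
    contours = measure.find_contours(comp.astype(float), 0.5)
    contour = max(contours, key=len)
    if len(contour) < n:
        raise ValueError(
            f"main component boundary has {len(contour)} vertices < n={n}"
        )
    points = _resample_contour(contour, n)

    inside = ndimage.binary_dilation(comp, structure=np.ones((3, 3)))
    vis = _visible(points, inside)
    vis |= vis.T  # symmetrize (rounding can make sight checks asymmetric)
    euclid = np.sqrt(((points[:, None, :] - points[None, :, :]) ** 2).sum(-1))
    w = np.where(vis, euclid, 0.0)
    # the contour ring keeps the graph connected
    ring = np.arange(n)
    w[ring, (ring + 1) % n] = euclid[ring, (ring + 1) % n]
    w[(ring + 1) % n, ring] = euclid[(ring + 1) % n, ring]
    np.fill_diagonal(w, 0.0)

    graph = csr_matrix(w)
    dist, pred = shortest_path(
        graph, method="D", directed=False, return_predecessors=True
    )

    # first hop of the shortest path from each source, by walking predecessors
    first = np.empty((n, n), dtype=np.int64)
    targets = np.arange(n)
    for i in range(n):
        cur = targets.copy()
        p = pred[i]
        for _ in range(n):
            back = p[cur]
            move = (back >= 0) & (back != i) & (cur != i)
            if not move.any():
                break
            cur[move] = back[move]
        cur[i] = i
        first[i] = cur

    tang = np.roll(points, -1, axis=0) - np.roll(points, 1, axis=0)
    tangents = np.arctan2(tang[:, 0], tang[:, 1])
    step = points[first] - points[:, None, :]
    ang = np.arctan2(step[..., 0], step[..., 1])
    inner_angle = np.mod(ang - tangents[:, None], 2.0 * np.pi)
    np.fill_diagonal(inner_angle, 0.0)

    dist = np.asarray(dist)
    dist = 0.5 * (dist + dist.T)
    return ShapeSample(points=points, inner_dist=dist, inner_angle=inner_angle,
                       tangents=tangents)


def idsc_histograms(
    shape: ShapeSample,
    n_dist_bins: int = DEFAULT_DIST_BINS,
    n_angle_bins: int = DEFAULT_ANGLE_BINS,
) -> np.ndarray:
    """Per-point log-polar histograms, shape (n, n_dist_bins*n_angle_bins).

    Inner distances are normalized by their off-diagonal mean (scale
    invariance); log-distance bins cover 0.125–2× the mean with clamped
    tails, so every one of the other n−1 points falls in exactly one bin.
    """
    n = shape.n
    off = ~np.eye(n, dtype=bool)
    mean_d = shape.inner_dist[off].mean()
    rel = shape.inner_dist / max(mean_d, 1e-12)
    edges = np.logspace(
        np.log10(_REL_DIST_RANGE[0]), np.log10(_REL_DIST_RANGE[1]), n_dist_bins + 1
    )
    dbin = np.clip(np.searchsorted(edges[1:-1], rel, side="right"), 0, n_dist_bins - 1)
    abin = np.minimum(
        (shape.inner_angle / (2.0 * np.pi / n_angle_bins)).astype(int),
        n_angle_bins - 1,
    )
    code = dbin * n_angle_bins + abin
    k = n_dist_bins * n_angle_bins
    hists = np.zeros((n, k))
    for i in range(n):
        hists[i] = np.bincount(code[i][off[i]], minlength=k)
    return hists


def match_cost(h_i: np.ndarray, h_j: np.ndarray) -> float:
    """χ²/2 cost between two context histograms; empty bins contribute 0."""
    h_i = np.asarray(h_i, dtype=float)
    h_j = np.asarray(h_j, dtype=float)
    if h_i.shape != h_j.shape:
        raise ValueError("histogram length mismatch")
    den = h_i + h_j
    num = (h_i - h_j) ** 2
    with np.errstate(invalid="ignore", divide="ignore"):
        terms = np.where(den > 0, num / np.maximum(den, 1e-300), 0.0)
    return float(0.5 * terms.sum())


def cost_matrix(hists_a: np.ndarray, hists_b: np.ndarray) -> np.ndarray:
    """All-pairs χ²/2 costs between two histogram sets, shape (na, nb)."""
    a = hists_a[:, None, :]
    b = hists_b[None, :, :]
    den = a + b
    with np.errstate(invalid="ignore", divide="ignore"):
        terms = np.where(den > 0, (a - b) ** 2 / np.maximum(den, 1e-300), 0.0)
    return 0.5 * terms.sum(axis=2)


@njit(cache=True)
def _circular_dp(cost: np.ndarray, penalty: float) -> float:  # pragma: no cover
    n, m = cost.shape
    best = np.inf
    dp = np.empty((n + 1, m + 1))
    for s in range(m):
        dp[0, 0] = 0.0
        for j in range(1, m + 1):
            dp[0, j] = j * penalty
        for i in range(1, n + 1):
            dp[i, 0] = i * penalty
            for j in range(1, m + 1):
                c = cost[i - 1, (j - 1 + s) % m]
                v = dp[i - 1, j - 1] + c
                a = dp[i - 1, j] + penalty
                if a < v:
                    v = a
                b = dp[i, j - 1] + penalty
                if b < v:
                    v = b
                dp[i, j] = v
        if dp[n, m] < best:
            best = dp[n, m]
    return best


def shape_distance(
    a: ShapeSample,
    b: ShapeSample,
    n_dist_bins: int = DEFAULT_DIST_BINS,
    n_angle_bins: int = DEFAULT_ANGLE_BINS,
    penalty: float = DEFAULT_PENALTY,
    hists_a: np.ndarray | None = None,
    hists_b: np.ndarray | None = None,
) -> float:
    """Minimal circular order-preserving matching cost between two shapes.

    Dynamic programming runs over every circular start offset of ``b``;
    skipped points on either side pay the fixed occlusion ``penalty``.
    Precomputed histograms may be passed to amortize repeated matching.
    """
    if hists_a is None:
        hists_a = idsc_histograms(a, n_dist_bins, n_angle_bins)
    if hists_b is None:
        hists_b = idsc_histograms(b, n_dist_bins, n_angle_bins)
    # matching uses probability-normalized histograms so per-pair costs lie
    # in [0, 1] and the occlusion penalty has a fixed scale
    na = hists_a / np.maximum(hists_a.sum(axis=1, keepdims=True), 1e-300)
    nb = hists_b / np.maximum(hists_b.sum(axis=1, keepdims=True), 1e-300)
    cost = cost_matrix(na, nb)
    return float(_circular_dp(cost, penalty))


@dataclass
class TemplateLibrary:
    """Three template shapes per category, used as shape-feature anchors."""

    templates: dict[str, list[ShapeSample]]
    n_dist_bins: int = DEFAULT_DIST_BINS
    n_angle_bins: int = DEFAULT_ANGLE_BINS
    _hists: dict[str, list[np.ndarray]] = field(default_factory=dict, repr=False)

    def __post_init__(self) -> None:
        if not self.templates:
            raise ValueError("template library needs at least one category")
        for cat, shapes in self.templates.items():
            if len(shapes) != 3:
                raise ValueError(f"category {cat!r} must have exactly 3 templates")

    @classmethod
    def from_masks(
        cls, masks_by_category: dict[str, list[np.ndarray]], n_points: int = DEFAULT_N_POINTS,
        **kwargs,
    ) -> "TemplateLibrary":
        shapes = {
            cat: [sample_boundary(m, n=n_points) for m in masks]
            for cat, masks in masks_by_category.items()
        }
        return cls(templates=shapes, **kwargs)

    @property
    def categories(self) -> list[str]:
        return sorted(self.templates)

    def histograms(self, cat: str) -> list[np.ndarray]:
        if cat not in self._hists:
            self._hists[cat] = [
                idsc_histograms(s, self.n_dist_bins, self.n_angle_bins)
                for s in self.templates[cat]
            ]
        return self._hists[cat]


def idsc_features(
    image: np.ndarray,
    mask: np.ndarray,
    templates: TemplateLibrary,
    n_points: int = DEFAULT_N_POINTS,
    penalty: float = DEFAULT_PENALTY,
) -> FeatureVector:
    """Shape distances to every template, category-major (3 per category)."""
    shape = sample_boundary(mask, n=n_points)
    hists = idsc_histograms(shape, templates.n_dist_bins, templates.n_angle_bins)
    values, names = [], []
    for cat in templates.categories:
        for t_idx, (tmpl, thist) in enumerate(
            zip(templates.templates[cat], templates.histograms(cat))
        ):
            d = shape_distance(
                shape,
                tmpl,
                templates.n_dist_bins,
                templates.n_angle_bins,
                penalty,
                hists_a=hists,
                hists_b=thist,
            )
            values.append(d)
            names.append(f"{cat}_t{t_idx}")
    return FeatureVector(np.asarray(values), "idsc", names)
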