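import itertools

import numpy as np
import pytest
from skimage.draw import disk as draw_disk

from planktovision import shapecontext as sc
from planktovision.shapecontext import (
    ShapeSample,
    TemplateLibrary,
    idsc_features,
    idsc_histograms,
    match_cost,
    sample_boundary,
    shape_distance,
)


def square_mask(side=40, canvas=50):
    m = np.zeros((canvas, canvas), bool)
    off = (canvas - side) // 2
    m[off : off + side, off : off + side] = True
    return m


def disk_mask(radius, canvas=80):
    m = np.zeros((canvas, canvas), bool)
    rr, cc = draw_disk((canvas // 2, canvas // 2), radius)
    m[rr, cc] = True
    return m


def star_mask(canvas=100, R=32, k=6, amp=0.45):
    yy, xx = np.mgrid[0:canvas, 0:canvas] - canvas / 2.0
    rho = np.hypot(xx, yy)
    th = np.arctan2(yy, xx)
    return rho <= R * (1 + amp * np.cos(k * th)) / (1 + amp)


class TestSampleBoundary:
    def test_square_corners_and_midpoints(self):
        """8 arclength-uniform samples of a square land on its corners and
        edge midpoints (within raster tolerance), cross-checked with an
        explicit arclength partition of the traced contour."""
        from skimage import measure

        mask = square_mask()
        s = sample_boundary(mask, n=8)
        corners = [(4.5, 4.5), (4.5, 44.5), (44.5, 44.5), (44.5, 4.5)]
        mids = [(4.5, 24.5), (24.5, 44.5), (44.5, 24.5), (24.5, 4.5)]
        expected = np.array(corners + mids)
        for p in s.points:
            assert np.sqrt(((expected - p) ** 2).sum(axis=1)).min() <= 1.0
        # independent oracle: cumulative-arclength partition of the contour
        contour = max(measure.find_contours(mask.astype(float), 0.5), key=len)
        seg = np.sqrt((np.diff(contour, axis=0) ** 2).sum(axis=1))
        total = seg.sum()
        assert total == pytest.approx(4 * 40, rel=0.05)

    def test_convex_inner_equals_euclidean(self):
        s = sample_boundary(disk_mask(20), n=24)
        eu = np.sqrt(((s.points[:, None] - s.points[None]) ** 2).sum(-1))
        assert np.abs(s.inner_dist - eu).max() <= 1.0

    def test_inner_distance_structure(self):
        s = sample_boundary(star_mask(), n=32)
        assert np.allclose(np.diag(s.inner_dist), 0.0)
        assert np.allclose(s.inner_dist, s.inner_dist.T)
        eu = np.sqrt(((s.points[:, None] - s.points[None]) ** 2).sum(-1))
        assert np.all(s.inner_dist >= eu - 1.0)

    def test_too_small_component_raises(self):
        m = np.zeros((10, 10), bool)
        m[4:6, 4:6] = True
        with pytest.raises(ValueError):
            sample_boundary(m, n=100)


class TestHistograms:
    def test_every_histogram_sums_to_n_minus_1(self):
        s = sample_boundary(star_mask(), n=30)
        h = idsc_histograms(s)
        assert np.all(h.sum(axis=1) == 29)

    def test_identical_shapes_identical_histograms(self):
        a = sample_boundary(disk_mask(15), n=20)
        b = sample_boundary(disk_mask(15), n=20)
        assert np.array_equal(idsc_histograms(a), idsc_histograms(b))

    def test_toy_square_hand_binned(self):
        """4 points of a unit square with hand-computed inner structure."""
        pts = np.array([[0.0, 0.0], [0.0, 1.0], [1.0, 1.0], [1.0, 0.0]])
        d = np.array(
            [
                [0, 1, np.sqrt(2), 1],
                [1, 0, 1, np.sqrt(2)],
                [np.sqrt(2), 1, 0, 1],
                [1, np.sqrt(2), 1, 0],
            ]
        )
        ang = np.full((4, 4), 0.1)  # all in the first angle bin
        shape = ShapeSample(points=pts, inner_dist=d, inner_angle=ang)
        h = idsc_histograms(shape, n_dist_bins=2, n_angle_bins=1)
        # mean distance = (8·1 + 4·√2)/12 ≈ 1.138; bin edge at √(0.125·2)=0.5
        # relative distances: 1/1.138≈0.879 and √2/1.138≈1.243 -> both in bin 2
        expected = np.tile([0.0, 3.0], (4, 1))
        assert np.array_equal(h, expected)


class TestMatchCost:
    def test_identical_histograms_zero_cost(self):
        h = np.array([3.0, 1.0, 5.0])
        assert match_cost(h, h) == 0.0

    def test_disjoint_bins_example(self):
        assert match_cost(np.array([2.0, 0.0]), np.array([0.0, 2.0])) == pytest.approx(2.0)

    def test_symmetric(self):
        rng = np.random.default_rng(0)
        a, b = rng.integers(0, 9, 12).astype(float), rng.integers(0, 9, 12).astype(float)
        assert match_cost(a, b) == pytest.approx(match_cost(b, a))

    def test_length_mismatch_raises(self):
        with pytest.raises(ValueError):
            match_cost(np.zeros(3), np.zeros(4))


def _exhaustive_circular_match(cost, penalty):
    """Enumerate every order-preserving circular correspondence with skips."""
    n, m = cost.shape
    best = np.inf
    for s in range(m):
        rolled = cost[:, np.mod(np.arange(m) + s, m)]
        for k in range(0, min(n, m) + 1):
            for rows in itertools.combinations(range(n), k):
                for cols in itertools.combinations(range(m), k):
                    tot = sum(rolled[r, c] for r, c in zip(rows, cols))
                    tot += penalty * ((n - k) + (m - k))
                    best = min(best, tot)
    return best


class TestShapeDistance:
    def test_self_distance_zero(self):
        s = sample_boundary(star_mask(), n=24)
        assert shape_distance(s, s) == pytest.approx(0.0, abs=1e-9)

    def test_square_rot90_distance_zero(self):
        m = square_mask()
        a = sample_boundary(m, n=16)
        b = sample_boundary(np.rot90(m).copy(), n=16)
        assert shape_distance(a, b) <= 1e-6

    def test_scale_and_translation_invariance(self):
        a = sample_boundary(square_mask(side=40, canvas=50), n=16)
        b = sample_boundary(square_mask(side=80, canvas=100), n=16)
        assert shape_distance(a, b) <= 1e-3

    def test_square_closer_to_disk_than_to_bar(self):
        sq = sample_boundary(square_mask(side=30, canvas=60), n=16)
        bar = np.zeros((60, 60), bool)
        bar[26:34, 6:54] = True
        circle = sample_boundary(disk_mask(17, canvas=60), n=16)
        assert shape_distance(sq, sample_boundary(bar, 16)) > shape_distance(sq, circle)

    @pytest.mark.parametrize("n", [4, 6])
    def test_dp_equals_exhaustive_enumeration(self, n):
        rng = np.random.default_rng(42)
        for _ in range(3):
            cost = rng.uniform(0, 1, (n, n))
            dp = float(sc._circular_dp(cost, 0.3))
            assert dp == pytest.approx(_exhaustive_circular_match(cost, 0.3), abs=1e-12)


class TestTemplateFeatures:
    def _library(self):
        stars = [sample_boundary(star_mask(R=r, amp=a), n=40)
                 for r, a in ((30, 0.45), (32, 0.4), (34, 0.5))]
        disks = [sample_boundary(disk_mask(r, canvas=90), n=40) for r in (22, 26, 30)]
        return TemplateLibrary(templates={"star": stars, "disk": disks})

    def test_two_categories_give_six_distances(self):
        lib = self._library()
        mask = star_mask(R=28)
        fv = idsc_features(np.zeros(mask.shape), mask, lib, n_points=40)
        assert len(fv) == 6

    def test_star_is_closer_to_star_templates(self):
        lib = self._library()
        mask = star_mask(R=29, amp=0.42, k=6)
        fv = idsc_features(np.zeros(mask.shape), mask, lib, n_points=40)
        by_cat = fv.values.reshape(2, 3)  # categories sorted: disk, star
        assert by_cat[1].mean() < by_cat[0].mean()

    def test_template_identical_image_scores_zero(self):
        lib = self._library()
        mask = star_mask(R=30, amp=0.45)  # equals the first star template
        fv = idsc_features(np.zeros(mask.shape), mask, lib, n_points=40)
        assert fv.values[fv.names.index("star_t0")] == pytest.approx(0.0, abs=1e-9)

    def test_library_requires_three_templates(self):
        s = sample_boundary(disk_mask(20), n=16)
        with pytest.raises(ValueError):
            TemplateLibrary(templates={"disk": [s, s]})
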