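import numpy as np
import pytest

from planktovision.synthetic import ClassSpec, generate_image


@pytest.fixture(scope="session")
def star_image():
    """One synthetic star-class image with its ground-truth mask."""
    return generate_image(ClassSpec("s", "star", "striped"), seed=11)


@pytest.fixture(scope="session")
def blob_mask():
    """A mid-sized irregular blob mask for morphology properties."""
    rng = np.random.default_rng(5)
    yy, xx = np.mgrid[0:72, 0:72] - 36.0
    rho = np.hypot(xx, yy)
    th = np.arctan2(yy, xx)
    r = 22 + 6 * np.cos(3 * th + rng.uniform(0, 2 * np.pi))
    return rho <= r


def flood_fill_areas(mask: np.ndarray) -> list[int]:
    """Independent 8-connected component areas via explicit BFS."""
    mask = np.asarray(mask, bool)
    seen = np.zeros_like(mask)
    areas = []
    h, w = mask.shape
    for r0 in range(h):
        for c0 in range(w):
            if mask[r0, c0] and not seen[r0, c0]:
                stack = [(r0, c0)]
                seen[r0, c0] = True
                area = 0
                while stack:
                    r, c = stack.pop()
                    area += 1
                    for dr in (-1, 0, 1):
                        for dc in (-1, 0, 1):
                            rr, cc = r + dr, c + dc
                            if 0 <= rr < h and 0 <= cc < w and mask[rr, cc] and not seen[rr, cc]:
                                seen[rr, cc] = True
                                stack.append((rr, cc))
                areas.append(area)
    return areas
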