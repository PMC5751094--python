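"""Deterministic generator of labelled plankton-like image datasets.

Real plankton silhouettes span elongated diatom chains, disks, spiny
radiolarian-like stars, appendaged copepod-like blobs and ring-shaped
colonies; devices add marine snow (tiny detrital speckles) and sensor
noise.  The generator emulates those properties so every pipeline stage is
testable without external downloads:

* five silhouette families (ellipse, chain-of-disks, star, appendaged
  blob, ring) crossed with three texture families (smooth, striped,
  granular) define up to 15 distinct classes;
* dark organisms on a bright background (the pre-processing polarity rule
  is exercised, never assumed), with no object touching the image border;
* marine-snow speckles are connected components of area 1–4 px — strictly
  below the 5-px denoising threshold — placed clear of the organism;
* Gaussian pixel noise (σ = 3 intensity levels) on top;
* image sides vary per sample; every image is reproducible bit-for-bit
  from the dataset seed.

The first three images of each class are designated shape templates.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
from scipy import ndimage

__all__ = ["ClassSpec", "SyntheticDataset", "generate_image", "generate_dataset", "CLASS_ROSTER"]

SILHOUETTES = ("ellipse", "chain", "star", "blob", "ring")
TEXTURES = ("smooth", "striped", "granular")

#: fixed pairing order used to assign distinct (silhouette, texture) classes
CLASS_ROSTER = [
    ("ellipse", "smooth"),
    ("chain", "granular"),
    ("star", "striped"),
    ("blob", "smooth"),
    ("ring", "granular"),
    ("ellipse", "striped"),
    ("chain", "smooth"),
    ("star", "granular"),
    ("blob", "striped"),
    ("ring", "smooth"),
    ("ellipse", "granular"),
    ("chain", "striped"),
    ("star", "smooth"),
    ("blob", "granular"),
    ("ring", "striped"),
]

_MARGIN = 8  # px kept clear around the frame so border polarity detection holds

# connected speckle patterns of area 1..4 (offsets from anchor)
_SPECKLE_PATTERNS = (
    ((0, 0),),
    ((0, 0), (0, 1)),
    ((0, 0), (1, 0)),
    ((0, 0), (0, 1), (1, 0)),
    ((0, 0), (0, 1), (0, 2)),
    ((0, 0), (0, 1), (1, 0), (1, 1)),
    ((0, 0), (0, 1), (0, 2), (1, 1)),
)


@dataclass(frozen=True)
class ClassSpec:
    """Recipe for one synthetic class."""

    name: str
    silhouette: str
    texture: str
    size_range: tuple[int, int] = (44, 72)     # object max extent, px
    contrast: float = 30.0                     # texture modulation amplitude
    side_range: tuple[int, int] = (96, 160)    # image side lengths, px
    aspect: float | None = None                # fixed minor/major ratio (ellipse)

    def __post_init__(self) -> None:
        if self.silhouette not in SILHOUETTES:
            raise ValueError(f"unknown silhouette {self.silhouette!r}")
        if self.texture not in TEXTURES:
            raise ValueError(f"unknown texture {self.texture!r}")
        if self.size_range[0] > self.size_range[1]:
            raise ValueError("empty size range")


def _render_silhouette(spec: ClassSpec, rng: np.random.Generator, side: int) -> np.ndarray:
    """Boolean mask of the organism, centered, clear of the border margin."""
    extent = rng.uniform(*spec.size_range)
    extent = min(extent, side - 2 * _MARGIN - 4)
    radius = extent / 2.0
    cy = side / 2.0 + rng.uniform(-4, 4)
    cx = side / 2.0 + rng.uniform(-4, 4)
    yy, xx = np.mgrid[0:side, 0:side].astype(float)
    y, x = yy - cy, xx - cx
    phi = rng.uniform(0, np.pi)
    xr = x * np.cos(phi) + y * np.sin(phi)
    yr = -x * np.sin(phi) + y * np.cos(phi)

    if spec.silhouette == "ellipse":
        ratio = spec.aspect if spec.aspect is not None else rng.uniform(0.35, 0.55)
        a, b = radius, max(radius * ratio, 4.0)
        mask = (xr / a) ** 2 + (yr / b) ** 2 <= 1.0
    elif spec.silhouette == "chain":
        k = int(rng.integers(4, 7))
        r = max(extent / (1.0 + 0.75 * (k - 1)) / 2.0, 3.5)
        step = 1.5 * r
        mask = np.zeros((side, side), dtype=bool)
        for i in range(k):
            off = (i - (k - 1) / 2.0) * step
            wob = rng.uniform(-0.25, 0.25) * r
            mask |= (xr - off) ** 2 + (yr - wob) ** 2 <= r**2
    elif spec.silhouette == "star":
        k = int(rng.integers(5, 8))
        amp = rng.uniform(0.35, 0.5)
        phase = rng.uniform(0, 2 * np.pi)
        rho = np.sqrt(x**2 + y**2)
        theta = np.arctan2(y, x)
        rmax = radius * (1.0 + amp * np.cos(k * theta + phase)) / (1.0 + amp)
        mask = rho <= rmax
    elif spec.silhouette == "blob":
        ratio = rng.uniform(0.5, 0.7)
        a, b = radius * 0.7, radius * 0.7 * ratio
        mask = (xr / a) ** 2 + (yr / b) ** 2 <= 1.0
        n_app = int(rng.integers(3, 5))
        rho = np.sqrt(x**2 + y**2)
        theta = np.arctan2(yr, xr)
        for _ in range(n_app):
            ang = rng.uniform(0, 2 * np.pi)
            length = radius * rng.uniform(0.8, 1.0)
            width = rng.uniform(0.06, 0.10)
            dang = np.mod(theta - ang + np.pi, 2 * np.pi) - np.pi
            mask |= (np.abs(dang) < width) & (rho <= length)
    else:  # ring
        inner = rng.uniform(0.5, 0.62)
        rho2 = x**2 + y**2
        mask = (rho2 <= radius**2) & (rho2 >= (inner * radius) ** 2)

    # enforce the clear border frame
    mask[:_MARGIN, :] = False
    mask[-_MARGIN:, :] = False
    mask[:, :_MARGIN] = False
    mask[:, -_MARGIN:] = False
    return mask


def _texture_field(
    spec: ClassSpec, rng: np.random.Generator, side: int, base: float
) -> np.ndarray:
    yy, xx = np.mgrid[0:side, 0:side].astype(float)
    if spec.texture == "smooth":
        psi = rng.uniform(0, np.pi)
        g = (xx * np.cos(psi) + yy * np.sin(psi)) / side
        return base + 0.4 * spec.contrast * (g - g.mean())
    if spec.texture == "striped":
        psi = rng.uniform(0, np.pi)
        period = rng.uniform(5.0, 9.0)
        phase = rng.uniform(0, 2 * np.pi)
        proj = xx * np.cos(psi) + yy * np.sin(psi)
        return base + spec.contrast * np.sin(2 * np.pi * proj / period + phase)
    # granular
    noise = rng.standard_normal((side, side))
    smooth = ndimage.gaussian_filter(noise, sigma=1.6)
    smooth /= max(np.abs(smooth).max(), 1e-9)
    return base + spec.contrast * smooth


def _add_marine_snow(
    image: np.ndarray, object_mask: np.ndarray, rng: np.random.Generator
) -> None:
    """Scatter dark speckle components of area 1–4 px, clear of the organism."""
    side = image.shape[0]
    occupied = ndimage.binary_dilation(object_mask, iterations=3)
    n = int(rng.integers(12, 28))
    for _ in range(n):
        pattern = _SPECKLE_PATTERNS[rng.integers(len(_SPECKLE_PATTERNS))]
        for _attempt in range(10):
            r = int(rng.integers(2, side - 5))
            c = int(rng.integers(2, side - 5))
            cells = [(r + dr, c + dc) for dr, dc in pattern]
            region = occupied[r - 2 : r + 5, c - 2 : c + 5]
            if region.any():
                continue
            level = rng.uniform(40, 90)
            for rr, cc in cells:
                image[rr, cc] = level
                occupied[max(rr - 2, 0) : rr + 3, max(cc - 2, 0) : cc + 3] = True
            break


def generate_image(
    spec: ClassSpec, seed: int | np.random.SeedSequence
) -> tuple[np.ndarray, np.ndarray]:
    """Render one image; returns (uint8 grayscale, clean ground-truth mask)."""
    rng = np.random.default_rng(seed)
    side = int(rng.integers(spec.side_range[0], spec.side_range[1] + 1))
    mask = _render_silhouette(spec, rng, side)

    bg_level = rng.uniform(195, 215)
    yy, xx = np.mgrid[0:side, 0:side].astype(float)
    image = bg_level + 6.0 * (xx / side - 0.5)  # mild illumination gradient

    base = rng.uniform(70, 105)
    texture = _texture_field(spec, rng, side, base)
    image[mask] = texture[mask]

    _add_marine_snow(image, mask, rng)

    image += 3.0 * rng.standard_normal(image.shape)
    image = np.clip(np.round(image), 0, 255).astype(np.uint8)
    return image, mask


@dataclass
class SyntheticDataset:
    """In-memory labelled image collection with designated shape templates."""

    images: list[np.ndarray]
    masks: list[np.ndarray]
    labels: list[str]
    class_names: list[str]
    template_indices: dict[str, list[int]]
    specs: dict[str, ClassSpec]
    seed: int
    sample_ids: list[str] = field(default_factory=list)

    def __len__(self) -> int:
        return len(self.images)

    def template_masks(self) -> dict[str, list[np.ndarray]]:
        return {
            cls: [self.masks[i] for i in idxs]
            for cls, idxs in self.template_indices.items()
        }

    def save(self, root: str | Path) -> Path:
        """Write ``<root>/<class>/<id>.png`` (+ ``_mask.png``) and a manifest."""
        import imageio.v3 as iio

        root = Path(root)
        for i, (img, msk, lab) in enumerate(zip(self.images, self.masks, self.labels)):
            d = root / lab
            d.mkdir(parents=True, exist_ok=True)
            sid = self.sample_ids[i] if self.sample_ids else f"{i:04d}"
            iio.imwrite(d / f"{sid}.png", img)
            iio.imwrite(d / f"{sid}_mask.png", (msk.astype(np.uint8) * 255))
        manifest = {
            "seed": self.seed,
            "classes": self.class_names,
            "templates": {
                cls: [
                    f"{cls}/{self.sample_ids[i] if self.sample_ids else f'{i:04d}'}_mask.png"
                    for i in idxs
                ]
                for cls, idxs in self.template_indices.items()
            },
            "specs": {
                cls: {"silhouette": s.silhouette, "texture": s.texture}
                for cls, s in self.specs.items()
            },
        }
        (root / "manifest.json").write_text(json.dumps(manifest, indent=2))
        return root


def generate_dataset(
    n_classes: int = 5,
    n_per_class: int = 60,
    seed: int = 7,
    size_range: tuple[int, int] = (44, 72),
    side_range: tuple[int, int] = (96, 160),
) -> SyntheticDataset:
    """Generate ``n_classes × n_per_class`` images with distinct class recipes.

    The first three images of every class are designated templates.  The
    same (arguments, seed) always regenerates the identical dataset.
    """
    if n_classes < 2:
        raise ValueError("need at least 2 classes")
    if n_per_class < 6:
        raise ValueError("need at least 6 images per class")
    if n_classes > len(CLASS_ROSTER):
        raise ValueError(
            f"only {len(CLASS_ROSTER)} distinct silhouette/texture pairings exist"
        )
    specs = {}
    for silhouette, texture in CLASS_ROSTER[:n_classes]:
        name = f"{silhouette}_{texture}"
        specs[name] = ClassSpec(
            name=name, silhouette=silhouette, texture=texture,
            size_range=size_range, side_range=side_range,
        )
    class_names = sorted(specs)

    root_ss = np.random.SeedSequence(seed)
    children = root_ss.spawn(len(class_names) * n_per_class)
    images, masks, labels, sample_ids = [], [], [], []
    template_indices: dict[str, list[int]] = {c: [] for c in class_names}
    idx = 0
    for ci, cls in enumerate(class_names):
        for j in range(n_per_class):
            img, msk = generate_image(specs[cls], children[ci * n_per_class + j])
            images.append(img)
            masks.append(msk)
            labels.append(cls)
            sample_ids.append(f"{j:04d}")
            if j < 3:
                template_indices[cls].append(idx)
            idx += 1
    return SyntheticDataset(
        images=images, masks=masks, labels=labels, class_names=class_names,
        template_indices=template_indices, specs=specs, seed=seed,
        sample_ids=sample_ids,
    )
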