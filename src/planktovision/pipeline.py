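"""End-to-end orchestration: preprocess → extract → select → train → evaluate.

Per cross-validation fold, every data-dependent stage is fitted on the
training split only: the SIFT codebook is clustered from training
keypoints, the IDSC template library takes the first three training
silhouettes of each class, and wrapper selection scores candidate features
by training-fold CV.  Per-image quantities that do not depend on the split
(preprocessing, the eight static feature groups, SIFT descriptors, shape
samples) are computed once and cached by image content hash.

The benchmark entry point evaluates several systems — single-kernel SVMs
on the concatenated features, single-family NLMKL, and three-family
NLMKL — on shared folds, features and selections, mirroring the paper-style
system comparison at synthetic-desk scale.
"""

from __future__ import annotations

import hashlib
import json
import logging
from dataclasses import asdict, dataclass, field
from pathlib import Path

import numpy as np

from planktovision import evaluate as ev
from planktovision import mkl as mkl_mod
from planktovision import shapecontext as sc
from planktovision.features import (
    SETUP1,
    SETUP2,
    GaborBank,
    bgc1_features,
    build_codebook,
    gabor_features,
    geometric_grayscale_features,
    granulometry_curve,
    hog_features,
    lbp_features,
    sift_descriptors,
    variogram_features,
)
from planktovision.preprocess import preprocess_image
from planktovision.selection import (
    FeatureGroupSet,
    apply_selection,
    select_all_groups,
)
from planktovision.synthetic import SyntheticDataset

logger = logging.getLogger("planktovision")

__all__ = ["PipelineConfig", "load_dataset", "PipelineRunner", "run_benchmark", "run_pipeline"]

IMAGE_SUFFIXES = {".png", ".tif", ".tiff", ".jpg", ".jpeg"}

STATIC_GROUPS = (
    "geometric-grayscale",
    "gabor",
    "variogram",
    "lbp",
    "bgc",
    "granulometry1",
    "granulometry2",
    "hog",
)


@dataclass
class PipelineConfig:
    """Every tunable of the end-to-end system, with defaults echoed in reports."""

    seed: int = 0
    min_region_size: int = 5
    groups: tuple[str, ...] = STATIC_GROUPS + ("sift", "idsc")
    lbp_grid: int = 4
    codebook_k: int = 100
    idsc_points: int = 100
    idsc_penalty: float = 0.3
    selection_folds: int = 3
    selection_max_features: int = 20
    selection_candidate_cap: int = 60
    families: tuple[str, ...] = ("gaussian", "polynomial", "linear")
    c_grid: tuple[float, ...] = (1.0, 10.0, 100.0)
    mkl_degree: int = 2
    mkl_lambda: float = 1.0
    mkl_max_iter: int = 50
    cv_protocol: str = "k-fold"
    cv_folds: int = 2
    output_dir: str | None = None

    @classmethod
    def from_file(cls, path: str | Path) -> "PipelineConfig":
        import yaml

        data = yaml.safe_load(Path(path).read_text()) or {}
        for key in ("groups", "families", "c_grid"):
            if key in data and isinstance(data[key], list):
                data[key] = tuple(data[key])
        return cls(**data)

    def to_dict(self) -> dict:
        return asdict(self)


def load_dataset(root: str | Path):
    """Load a directory-per-class image tree.

    Returns ``(images, gt_masks, labels)`` with a stable alphabetical class
    roster and deterministic per-class file ordering.  ``<id>_mask.png``
    files are paired as ground-truth masks when present (else None entries).
    Non-image files are skipped with a logged warning.
    """
    from planktovision.preprocess import load_gray_image

    root = Path(root)
    class_dirs = sorted(d for d in root.iterdir() if d.is_dir())
    if len(class_dirs) < 2:
        raise ValueError(f"dataset root {root} needs >= 2 class directories")
    images, gt_masks, labels = [], [], []
    for d in class_dirs:
        files = sorted(p for p in d.iterdir() if p.is_file())
        kept = 0
        for p in files:
            if p.suffix.lower() not in IMAGE_SUFFIXES:
                logger.warning("ignoring non-image file %s", p)
                continue
            if p.stem.endswith("_mask"):
                continue
            img = load_gray_image(p)
            mpath = p.with_name(p.stem + "_mask" + p.suffix)
            msk = load_gray_image(mpath) > 127 if mpath.exists() else None
            images.append(img)
            gt_masks.append(msk)
            labels.append(d.name)
            kept += 1
        if kept == 0:
            raise ValueError(f"class directory {d} contains no images")
    return images, gt_masks, labels


def _content_key(image: np.ndarray) -> str:
    h = hashlib.sha1()
    h.update(str(image.shape).encode())
    h.update(np.ascontiguousarray(image).tobytes())
    return h.hexdigest()


@dataclass
class SystemSpec:
    """One classifier configuration in the comparison experiment."""

    name: str
    kind: str                      # "svm" or "mkl"
    families: tuple[str, ...]
    C: float


class PipelineRunner:
    """Shared-state executor: features are extracted once, reused across folds."""

    def __init__(self, images, labels, config: PipelineConfig, gt_masks=None):
        self.images = list(images)
        self.labels = list(labels)
        self.config = config
        self.gt_masks = list(gt_masks) if gt_masks is not None else [None] * len(images)
        self._cells = None
        self._masks = None
        self._static: dict[str, np.ndarray] | None = None
        self._descriptors: list[np.ndarray] | None = None
        self._shape_hists: list[np.ndarray] | None = None
        self._template_shapes: dict[str, sc.ShapeSample] = {}
        self._gabor_bank = GaborBank()
        self.consumed_seeds: list[int] = []

    # ------------------------------------------------------------------
    # per-image, split-independent computations
    # ------------------------------------------------------------------

    def _ensure_preprocessed(self) -> None:
        if self._cells is not None:
            return
        cells, masks = [], []
        for img in self.images:
            cell, mask = preprocess_image(img, min_size=self.config.min_region_size)
            if not mask.any():
                # degenerate segmentation: keep the whole frame as object
                mask = np.ones_like(mask)
                cell = img.copy()
                logger.warning("empty mask after preprocessing; using full frame")
            cells.append(cell)
            masks.append(mask)
        self._cells, self._masks = cells, masks

    def static_features(self) -> dict[str, np.ndarray]:
        """The eight split-independent feature-group tables."""
        if self._static is not None:
            return self._static
        self._ensure_preprocessed()
        cfg = self.config
        rows: dict[str, list[np.ndarray]] = {g: [] for g in STATIC_GROUPS}
        for cell, mask in zip(self._cells, self._masks):
            rows["geometric-grayscale"].append(
                geometric_grayscale_features(cell, mask).values
            )
            rows["gabor"].append(gabor_features(cell, self._gabor_bank).values)
            rows["variogram"].append(variogram_features(cell, mask).values)
            rows["lbp"].append(lbp_features(cell, grid=cfg.lbp_grid).values)
            rows["bgc"].append(bgc1_features(cell).values)
            rows["granulometry1"].append(
                granulometry_curve(mask, SETUP1, "granulometry1").values
            )
            rows["granulometry2"].append(
                granulometry_curve(mask, SETUP2, "granulometry2").values
            )
            rows["hog"].append(hog_features(cell).values)
        self._static = {g: np.vstack(v) for g, v in rows.items() if g in cfg.groups}
        return self._static

    def descriptors(self) -> list[np.ndarray]:
        if self._descriptors is None:
            self._ensure_preprocessed()
            self._descriptors = [sift_descriptors(c) for c in self._cells]
        return self._descriptors

    def shape_histograms(self) -> list[np.ndarray]:
        """Per-image IDSC histograms (split independent)."""
        if self._shape_hists is None:
            self._ensure_preprocessed()
            hists = []
            for mask in self._masks:
                shape = self._sample_shape(mask)
                hists.append(sc.idsc_histograms(shape))
            self._shape_hists = hists
        return self._shape_hists

    def _sample_shape(self, mask: np.ndarray) -> sc.ShapeSample:
        n = self.config.idsc_points
        while True:
            try:
                return sc.sample_boundary(mask, n=n)
            except ValueError:
                if n <= 16:
                    raise
                n = max(16, n // 2)

    # ------------------------------------------------------------------
    # fold-dependent features
    # ------------------------------------------------------------------

    def _template_library(self, train_idx: np.ndarray) -> sc.TemplateLibrary:
        by_class: dict[str, list[sc.ShapeSample]] = {}
        for cls in sorted(set(self.labels)):
            picks = [i for i in train_idx if self.labels[i] == cls][:3]
            if len(picks) < 3:
                raise ValueError(f"class {cls!r} has fewer than 3 training images")
            shapes = []
            for i in picks:
                key = _content_key(self.images[i])
                if key not in self._template_shapes:
                    mask = self.gt_masks[i]
                    if mask is None:
                        self._ensure_preprocessed()
                        mask = self._masks[i]
                    self._template_shapes[key] = self._sample_shape(mask)
                shapes.append(self._template_shapes[key])
            by_class[cls] = shapes
        return sc.TemplateLibrary(templates=by_class)

    def fold_features(self, train_idx: np.ndarray) -> FeatureGroupSet:
        """All-sample feature tables with split-dependent stages fitted on train."""
        cfg = self.config
        groups = dict(self.static_features())

        if "sift" in cfg.groups:
            desc = self.descriptors()
            train_desc = [desc[i] for i in train_idx if len(desc[i])]
            stack = (
                np.vstack(train_desc) if train_desc else np.zeros((0, 128))
            )
            k = min(cfg.codebook_k, len(stack))
            if k >= 1:
                codebook = build_codebook(stack, k=k, seed=cfg.seed)
                bows = []
                for i in range(len(self.images)):
                    hist = np.zeros(cfg.codebook_k)
                    if len(desc[i]):
                        d2 = (
                            (desc[i][:, None, :] - codebook.centers[None, :, :]) ** 2
                        ).sum(axis=2)
                        hist[: codebook.k] = np.bincount(
                            d2.argmin(axis=1), minlength=codebook.k
                        )
                    bows.append(hist)
                groups["sift"] = np.vstack(bows)
            else:
                groups["sift"] = np.zeros((len(self.images), cfg.codebook_k))

        if "idsc" in cfg.groups:
            lib = self._template_library(np.asarray(train_idx))
            hists = self.shape_histograms()
            cats = lib.categories
            rows = []
            for hist in hists:
                vals = []
                for cat in cats:
                    for thist in lib.histograms(cat):
                        d = sc.shape_distance(
                            None, None, penalty=self.config.idsc_penalty,
                            hists_a=hist, hists_b=thist,
                        )
                        vals.append(d)
                rows.append(vals)
            groups["idsc"] = np.asarray(rows, dtype=float)

        groups = {g: t for g, t in groups.items() if g in cfg.groups}
        return FeatureGroupSet(groups=groups, labels=self.labels)

    # ------------------------------------------------------------------
    # experiments
    # ------------------------------------------------------------------

    def evaluate_systems(
        self, systems: list[SystemSpec]
    ) -> tuple[dict[str, ev.CVResult], dict]:
        """Shared-fold comparison of several classifier configurations.

        Returns per-system CV results plus a report of selected dimensions.
        """
        cfg = self.config
        y = np.asarray(self.labels)
        from sklearn.model_selection import StratifiedKFold, train_test_split

        if cfg.cv_protocol == "k-fold":
            splitter = StratifiedKFold(
                n_splits=cfg.cv_folds, shuffle=True, random_state=cfg.seed
            )
            splits = list(splitter.split(np.zeros(len(y)), y))
        else:
            tr, te = train_test_split(
                np.arange(len(y)), test_size=0.5, stratify=y, random_state=cfg.seed
            )
            splits = [(np.sort(tr), np.sort(te))]
        self.consumed_seeds.append(cfg.seed)

        roster = sorted(set(self.labels))
        confusions: dict[str, list[ev.ConfusionMatrix]] = {s.name: [] for s in systems}
        selected_dims: list[dict[str, int]] = []
        for fold, (tr, te) in enumerate(splits):
            feats = self.fold_features(tr)
            train_set = feats.subset(tr)
            test_set = feats.subset(te)
            sel = select_all_groups(
                train_set,
                y[tr],
                folds=cfg.selection_folds,
                seed=cfg.seed,
                max_features=cfg.selection_max_features,
                candidate_cap=cfg.selection_candidate_cap,
            )
            selected_dims.append({g: int(len(ix)) for g, ix in sel.indices.items()})
            train_sel = apply_selection(train_set, sel)
            test_sel = apply_selection(test_set, sel)
            for system in systems:
                if system.kind == "svm":
                    model = mkl_mod.train_svm_single(
                        train_sel.concatenated(), y[tr],
                        family=system.families[0], C=system.C, seed=cfg.seed,
                    )
                    pred = mkl_mod.predict(
                        model,
                        FeatureGroupSet(groups={"all": test_sel.concatenated()}),
                    )
                else:
                    model = mkl_mod.train_nlmkl(
                        train_sel, y[tr], families=system.families, C=system.C,
                        degree=cfg.mkl_degree, seed=cfg.seed, lam=cfg.mkl_lambda,
                        max_iter=cfg.mkl_max_iter,
                    )
                    pred = mkl_mod.predict(model, test_sel)
                confusions[system.name].append(
                    ev.confusion_matrix(y[te].tolist(), pred, classes=roster)
                )
        results = {}
        for system in systems:
            cms = confusions[system.name]
            pooled = cms[0]
            for cm in cms[1:]:
                pooled = pooled + cm
            results[system.name] = ev.CVResult(
                fold_metrics=[ev.metrics(c) for c in cms],
                fold_confusions=cms,
                pooled_confusion=pooled,
            )
        report = {
            "selected_dimensions": selected_dims,
            "config": cfg.to_dict(),
            "n_samples": len(self.images),
        }
        return results, report


def default_systems(config: PipelineConfig) -> list[SystemSpec]:
    """The paper-style comparison grid: SVM, 1-family MKL, 3-family MKL."""
    systems = []
    for fam in config.families:
        for C in config.c_grid:
            systems.append(SystemSpec(f"svm_{fam}_C{C:g}", "svm", (fam,), C))
            systems.append(SystemSpec(f"mkl_{fam}_C{C:g}", "mkl", (fam,), C))
    for C in config.c_grid:
        systems.append(SystemSpec(f"mkl_all_C{C:g}", "mkl", tuple(config.families), C))
    return systems


def run_benchmark(
    dataset: SyntheticDataset, config: PipelineConfig, systems=None
):
    """Evaluate the comparison grid on an in-memory dataset."""
    runner = PipelineRunner(
        dataset.images, dataset.labels, config, gt_masks=dataset.masks
    )
    if systems is None:
        systems = default_systems(config)
    return runner.evaluate_systems(systems)


def run_pipeline(config: PipelineConfig, dataset_root: str | Path):
    """CLI entry: load a dataset directory, run the comparison, write reports."""
    images, gt_masks, labels = load_dataset(dataset_root)
    runner = PipelineRunner(images, labels, config, gt_masks=gt_masks)
    results, report = runner.evaluate_systems(default_systems(config))

    summary_rows = []
    for name, res in results.items():
        m = res.pooled_metrics
        summary_rows.append(
            {
                "system": name,
                "macro_recall": m.macro_recall,
                "macro_error": m.macro_error,
                "macro_f": m.macro_f,
                "micro_recall": m.micro_recall,
            }
        )
    if config.output_dir:
        out = Path(config.output_dir)
        out.mkdir(parents=True, exist_ok=True)
        import pandas as pd

        pd.DataFrame(summary_rows).to_csv(out / "metrics.csv", index=False)
        for name, res in results.items():
            pd.DataFrame(
                res.pooled_confusion.counts,
                index=res.pooled_confusion.classes,
                columns=res.pooled_confusion.classes,
            ).to_csv(out / f"confusion_{name}.csv")
        (out / "report.json").write_text(json.dumps(report, indent=2, default=str))
    return results, report
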