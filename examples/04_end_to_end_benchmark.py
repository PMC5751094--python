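"""A small end-to-end run: synthetic dataset → pipeline → metrics.

Uses a reduced dataset (3 classes × 12 images) and a trimmed feature roster
so the whole thing runs in about a minute; prints macro recall, error rate
(1 − precision) and F-measure for an SVM and the three-family NLMKL system.
For the full-size benchmark (5 × 60, all ten groups, full C grid) see
scripts/acceptance.py.
"""

from planktovision.pipeline import PipelineConfig, SystemSpec, run_benchmark
from planktovision.synthetic import generate_dataset

dataset = generate_dataset(n_classes=3, n_per_class=12, seed=7)
config = PipelineConfig(
    seed=7,
    groups=("geometric-grayscale", "granulometry1", "variogram", "bgc", "idsc"),
    cv_folds=2,
)
systems = [
    SystemSpec("svm_gaussian_C10", "svm", ("gaussian",), 10.0),
    SystemSpec("mkl_all_C10", "mkl", ("gaussian", "polynomial", "linear"), 10.0),
]
results, report = run_benchmark(dataset, config, systems)

print(f"{len(dataset)} images, classes: {dataset.class_names}")
print("selected dims per fold:", report["selected_dimensions"])
for name, res in results.items():
    m = res.pooled_metrics
    print(f"{name:>18}: R={m.macro_recall:.3f}  1-P={m.macro_error:.3f}  F={m.macro_f:.3f}")
# R is macro recall (mean per-class sensitivity), 1-P the macro error rate,
# F the macro F-measure; MKL combines one kernel per (group, family) pair.
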