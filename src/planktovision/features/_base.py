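"""Shared feature-vector container and the canonical group roster."""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

#: the ten canonical feature-group names, in pipeline order
GROUP_NAMES = (
    "geometric-grayscale",
    "gabor",
    "variogram",
    "lbp",
    "bgc",
    "granulometry1",
    "granulometry2",
    "sift",
    "hog",
    "idsc",
)


@dataclass
class FeatureVector:
    """An ordered list of real-valued features belonging to one group.

    ``names`` labels every element; all values are finite floats.
    """

    values: np.ndarray
    group: str
    names: list[str] = field(default_factory=list)

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=float).ravel()
        if self.names and len(self.names) != self.values.size:
            raise ValueError("names and values length mismatch")
        if not np.all(np.isfinite(self.values)):
            raise ValueError(f"non-finite value in {self.group} features")

    def __len__(self) -> int:
        return int(self.values.size)
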