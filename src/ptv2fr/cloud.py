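"""Labeled point-cloud container and the class color palette.

A cloud is N points with XYZ coordinates in meters, 8-bit RGB colors and a
per-point semantic label: 0 = leaf, 1 = stem, 2 = pot, -1 = ignore.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

import numpy as np

LEAF, STEM, POT, IGNORE = 0, 1, 2, -1
CLASS_NAMES = {LEAF: "leaf", STEM: "stem", POT: "pot"}
VALID_LABELS = frozenset({LEAF, STEM, POT, IGNORE})


@dataclass
class ClassPalette:
    """Bijective class -> RGB mapping used for label/color round-trips."""

    mapping: dict[int, tuple[int, int, int]] = field(default_factory=lambda: {
        LEAF: (255, 0, 0),
        STEM: (0, 255, 0),
        POT: (255, 255, 0),
    })

    def __post_init__(self):
        colors = list(self.mapping.values())
        if len(set(colors)) != len(colors):
            raise ValueError("palette colors must be distinct (bijective mapping)")

    def color_of(self, label: int) -> tuple[int, int, int]:
        return self.mapping[label]

    def label_of(self, color: tuple[int, int, int]) -> int:
        for lab, c in self.mapping.items():
            if tuple(c) == tuple(color):
                return lab
        return IGNORE


@dataclass
class LabeledCloud:
    points: np.ndarray            # (N, 3) float64, meters
    colors: np.ndarray | None = None   # (N, 3) uint8
    labels: np.ndarray | None = None   # (N,) int, in {-1, 0, 1, 2}
    pot_id: str = ""
    timepoint: str | None = None

    def __post_init__(self):
        self.points = np.asarray(self.points, dtype=np.float64)
        if self.points.ndim != 2 or self.points.shape[1] != 3 or len(self.points) < 1:
            raise ValueError("points must be a non-empty (N, 3) array")
        if not np.isfinite(self.points).all():
            raise ValueError("points must be finite")
        n = len(self.points)
        if self.colors is None:
            self.colors = np.zeros((n, 3), dtype=np.uint8)
        else:
            colors = np.asarray(self.colors)
            if colors.shape != (n, 3):
                raise ValueError("colors must be (N, 3)")
            if colors.min() < 0 or colors.max() > 255:
                raise ValueError("colors must lie in [0, 255]")
            self.colors = colors.astype(np.uint8)
        if self.labels is None:
            self.labels = np.full(n, IGNORE, dtype=np.int64)
        else:
            labels = np.asarray(self.labels, dtype=np.int64)
            if labels.shape != (n,):
                raise ValueError("labels must be (N,)")
            if not np.isin(labels, list(VALID_LABELS)).all():
                raise ValueError(f"labels must be in {sorted(VALID_LABELS)}")
            self.labels = labels

    def __len__(self) -> int:
        return len(self.points)

    def select(self, index) -> "LabeledCloud":
        return replace(self, points=self.points[index], colors=self.colors[index],
                       labels=self.labels[index])


def labels_to_colors(cloud: LabeledCloud, palette: ClassPalette | None = None) -> LabeledCloud:
    """Paint each labeled point with its class palette color (ignore -> black)."""
    palette = palette or ClassPalette()
    colors = np.zeros((len(cloud), 3), dtype=np.uint8)
    for lab, rgb in palette.mapping.items():
        colors[cloud.labels == lab] = rgb
    return replace(cloud, colors=colors)


def colors_to_labels(cloud: LabeledCloud, palette: ClassPalette | None = None) -> LabeledCloud:
    """Recover labels by exact RGB match against the palette; non-matches -> ignore."""
    palette = palette or ClassPalette()
    labels = np.full(len(cloud), IGNORE, dtype=np.int64)
    for lab, rgb in palette.mapping.items():
        labels[(cloud.colors == np.asarray(rgb, dtype=np.uint8)).all(axis=1)] = lab
    return replace(cloud, labels=labels)
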