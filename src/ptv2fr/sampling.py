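"""Furthest-point sampling, pot-level dataset splitting and training
augmentations (random scale / flip / jitter / elastic distortion / sphere crop).
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy.ndimage import gaussian_filter

from .cloud import LabeledCloud


def fps_downsample(cloud: LabeledCloud, m: int, seed: int = 0) -> LabeledCloud:
    """Greedy furthest-point sampling down to ``m`` points.

    The start point is chosen by a seeded draw; every subsequent pick is the
    point maximizing the minimum distance to the already-selected set, ties
    broken toward the lowest index.  If the cloud already has <= m points it
    is returned unchanged.
    """
    if m < 1:
        raise ValueError("m must be >= 1")
    n = len(cloud)
    if n <= m:
        return cloud
    idx = fps_indices(cloud.points, m, seed)
    return cloud.select(idx)


def fps_indices(points: np.ndarray, m: int, seed: int = 0,
                start: int | None = None) -> np.ndarray:
    n = len(points)
    if start is None:
        start = int(np.random.default_rng(seed).integers(n))
    selected = np.empty(m, dtype=np.int64)
    selected[0] = start
    # min distance of every point to the selected set; argmax ties -> lowest index
    d2 = ((points - points[start]) ** 2).sum(axis=1)
    for i in range(1, m):
        nxt = int(np.argmax(d2))
        selected[i] = nxt
        np.minimum(d2, ((points - points[nxt]) ** 2).sum(axis=1), out=d2)
    return selected


@dataclass
class PotSplit:
    assignment: dict[str, str]           # pot_id -> "train" | "val" | "test"
    ratio: tuple[int, int, int] = (7, 2, 1)
    seed: int = 0

    def subset(self, name: str) -> list[str]:
        return sorted(p for p, s in self.assignment.items() if s == name)


def pot_level_split(pot_ids, ratio: tuple[int, int, int] = (7, 2, 1),
                    seed: int = 0) -> PotSplit:
    """Partition pots into train/val/test so no pot crosses subsets.

    Subset sizes follow the ratio with floor rounding for val and test and
    the remainder going to train (50 pots at 7:2:1 -> 35/10/5).
    """
    pots = sorted(set(pot_ids))
    if len(pots) < 3:
        raise ValueError("need at least 3 distinct pots to split")
    n = len(pots)
    total = sum(ratio)
    n_val = int(n * ratio[1] / total)
    n_test = int(n * ratio[2] / total)
    n_train = n - n_val - n_test
    order = np.random.default_rng(seed).permutation(n)
    assignment = {}
    for rank, j in enumerate(order):
        if rank < n_train:
            assignment[pots[j]] = "train"
        elif rank < n_train + n_val:
            assignment[pots[j]] = "val"
        else:
            assignment[pots[j]] = "test"
    return PotSplit(assignment=assignment, ratio=tuple(ratio), seed=seed)


@dataclass
class AugmentConfig:
    scale_range: tuple[float, float] = (0.9, 1.1)
    flip_prob: float = 0.5
    jitter_sigma: float = 0.005
    jitter_clip: float = 0.02
    elastic_params: list[list[float]] = field(
        default_factory=lambda: [[0.2, 0.4], [0.8, 1.6]])
    sphere_crop_max: int = 80_000
    enabled: tuple[str, ...] = ("scale", "flip", "jitter", "elastic", "crop")

    def __post_init__(self):
        if not (0.0 <= self.flip_prob <= 1.0):
            raise ValueError("flip_prob must lie in [0, 1]")
        if self.scale_range[0] <= 0 or self.jitter_sigma < 0 or self.jitter_clip < 0:
            raise ValueError("augmentation ranges must be positive")


def _elastic_distortion(points: np.ndarray, granularity: float, magnitude: float,
                        rng: np.random.Generator) -> np.ndarray:
    """One smoothed random displacement field, trilinearly interpolated."""
    lo = points.min(axis=0) - granularity
    dims = np.maximum(((points.max(axis=0) - lo) / granularity).astype(int) + 3, 3)
    noise = rng.standard_normal(size=(*dims, 3))
    noise = gaussian_filter(noise, sigma=(1.0, 1.0, 1.0, 0.0), mode="constant")
    # trilinear interpolation of the displacement grid at each point
    u = (points - lo) / granularity
    i0 = np.clip(u.astype(int), 0, np.asarray(dims) - 2)
    f = u - i0
    disp = np.zeros_like(points)
    for dx in (0, 1):
        for dy in (0, 1):
            for dz in (0, 1):
                w = (np.where(dx, f[:, 0], 1 - f[:, 0])
                     * np.where(dy, f[:, 1], 1 - f[:, 1])
                     * np.where(dz, f[:, 2], 1 - f[:, 2]))
                disp += w[:, None] * noise[i0[:, 0] + dx, i0[:, 1] + dy, i0[:, 2] + dz]
    return points + disp * magnitude


def augment(cloud: LabeledCloud, config: AugmentConfig,
            rng: np.random.Generator) -> LabeledCloud:
    """Apply the training augmentation chain.

    Order: random scale -> random flip (x and/or y, never z) -> jitter
    (clipped Gaussian) -> elastic distortion -> sphere crop.  Labels and
    colors ride along with surviving points.
    """
    pts = cloud.points.copy()
    out = cloud
    if "scale" in config.enabled:
        s = rng.uniform(*config.scale_range)
        pts = pts * s
    if "flip" in config.enabled:
        for axis in (0, 1):  # plants are gravity-oriented: never flip z
            if rng.random() < config.flip_prob:
                pts[:, axis] = -pts[:, axis]
    if "jitter" in config.enabled and config.jitter_sigma > 0:
        noise = np.clip(rng.normal(0.0, config.jitter_sigma, size=pts.shape),
                        -config.jitter_clip, config.jitter_clip)
        pts = pts + noise
    if "elastic" in config.enabled:
        for granularity, magnitude in config.elastic_params:
            pts = _elastic_distortion(pts, granularity, magnitude, rng)
    out = out.select(slice(None))
    out.points = pts
    if "crop" in config.enabled and len(out) > config.sphere_crop_max:
        center = pts[rng.integers(len(pts))]
        d2 = ((pts - center) ** 2).sum(axis=1)
        keep = np.argsort(d2, kind="stable")[: config.sphere_crop_max]
        out = out.select(np.sort(keep))
    return out
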