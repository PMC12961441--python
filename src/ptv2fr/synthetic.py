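"""Procedural sorghum-seedling pot clouds with analytically known traits.

Each pot emulates the structure of the real dataset: an acrylic tray
(25 x 25 x 5 cm) carrying 15-25 seedlings on a jittered 5 x 5 grid.  A
seedling is a thin, slightly tilted stem (cylinder surface) with two
alternate leaves modeled as cylinder-section ribbons — developable
surfaces, so the surface area has the closed form arc_length x width and
the chord length 2R sin(arc / 2R) is known exactly.  Optional Gaussian
surface noise, a vertical density gradient and occlusion sectors emulate
multi-view reconstruction artifacts.  Stem points are a small minority of
the cloud, matching the class imbalance that motivates the weighted loss.

Every generated cloud satisfies the LabeledCloud invariants and ships with
a ground-truth TraitRecord plus per-point plant/leaf instance ids.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from .cloud import LEAF, POT, STEM, LabeledCloud
from .ply import write_ply
from .sampling import pot_level_split
from .traits import TRAY_AREA_CM2, TraitRecord

TRAY = (0.25, 0.25, 0.05)  # meters


@dataclass
class LeafSpec:
    attach_frac: float       # attachment height as fraction of stem length
    azimuth: float           # radians
    elevation: float         # radians above horizontal
    arc_length: float        # meters along the midrib
    width: float             # meters
    bend_radius: float       # meters (constant-curvature midrib)

    @property
    def area_m2(self) -> float:
        return self.arc_length * self.width       # developable ribbon

    @property
    def chord_m(self) -> float:
        r, s = self.bend_radius, self.arc_length
        return 2.0 * r * np.sin(s / (2.0 * r))


@dataclass
class SeedlingSpec:
    base_xy: tuple[float, float]
    stem_length: float       # meters
    stem_radius: float       # meters
    tilt: float              # radians from vertical
    tilt_azimuth: float
    leaves: list[LeafSpec] = field(default_factory=list)

    @property
    def stem_axis(self) -> np.ndarray:
        s, c = np.sin(self.tilt), np.cos(self.tilt)
        return np.array([s * np.cos(self.tilt_azimuth),
                         s * np.sin(self.tilt_azimuth), c])


@dataclass
class PotSpec:
    n_plants: int | None = None      # None: draw 15-25
    grid_jitter: float = 0.003       # meters
    tray_points: int = 3000
    stem_points: int = 60            # per plant
    leaf_points: int = 250           # per leaf
    noise_sigma: float = 0.0005      # meters, surface noise
    density_gradient: bool = True    # thinner sampling away from the tray
    occlusion: bool = True           # thinned random angular sector
    target_points: int | None = 4096  # FPS target; None keeps the raw cloud

    @classmethod
    def dense_traits(cls) -> "PotSpec":
        """Noise-free, densely sampled preset for trait-recovery studies."""
        return cls(tray_points=1500, stem_points=400, leaf_points=900,
                   noise_sigma=0.0, density_gradient=False, occlusion=False,
                   target_points=None)


def _random_seedling(rng: np.random.Generator, base_xy, dense: bool) -> SeedlingSpec:
    stem_length = rng.uniform(0.03, 0.05)
    leaves = []
    n_leaves = 2
    base_azimuth = rng.uniform(0, 2 * np.pi)
    for li in range(n_leaves):
        # the dense (trait-oracle) preset keeps leaves short and shallow so
        # leaf instances stay separable at the 1 cm clustering radius
        arc = rng.uniform(0.012, 0.018) if dense else rng.uniform(0.02, 0.05)
        elev_hi = 38.0 if dense else 55.0
        leaves.append(LeafSpec(
            attach_frac=(0.40, 0.95)[li] + rng.uniform(-0.015, 0.015),
            azimuth=base_azimuth + li * np.pi + rng.uniform(-0.2, 0.2),
            elevation=rng.uniform(np.deg2rad(20), np.deg2rad(elev_hi)),
            arc_length=arc,
            width=rng.uniform(0.005, min(0.009, 0.45 * arc)),
            bend_radius=rng.uniform(0.04, 0.08),
        ))
    return SeedlingSpec(
        base_xy=tuple(base_xy),
        stem_length=stem_length,
        stem_radius=rng.uniform(0.0008, 0.0015),
        tilt=rng.uniform(0, np.deg2rad(4)),
        tilt_azimuth=rng.uniform(0, 2 * np.pi),
        leaves=leaves,
    )


def _leaf_frame(seedling: SeedlingSpec, leaf: LeafSpec):
    attach = (np.array([*seedling.base_xy, 0.0])
              + leaf.attach_frac * seedling.stem_length * seedling.stem_axis)
    az = np.array([np.cos(leaf.azimuth), np.sin(leaf.azimuth), 0.0])
    d1 = np.cos(leaf.elevation) * az + np.sin(leaf.elevation) * np.array([0, 0, 1.0])
    w_dir = np.array([-np.sin(leaf.azimuth), np.cos(leaf.azimuth), 0.0])
    d2 = np.cross(w_dir, d1)          # bending direction (droop)
    return attach, d1, -d2, w_dir


def _sample_leaf(seedling: SeedlingSpec, leaf: LeafSpec, n: int,
                 rng: np.random.Generator) -> np.ndarray:
    attach, d1, d2, w_dir = _leaf_frame(seedling, leaf)
    s = rng.uniform(0, leaf.arc_length, n)
    t = rng.uniform(-leaf.width / 2, leaf.width / 2, n)
    theta = s / leaf.bend_radius
    r = leaf.bend_radius
    return (attach[None]
            + np.outer(r * np.sin(theta), d1)
            + np.outer(r * (1 - np.cos(theta)), d2)
            + np.outer(t, w_dir))


def _sample_stem(seedling: SeedlingSpec, n: int, rng: np.random.Generator) -> np.ndarray:
    a = seedling.stem_axis
    ref = np.array([1.0, 0, 0]) if abs(a[0]) < 0.9 else np.array([0, 1.0, 0])
    e1 = np.cross(a, ref)
    e1 /= np.linalg.norm(e1)
    e2 = np.cross(a, e1)
    t = rng.uniform(0, seedling.stem_length, n)
    phi = rng.uniform(0, 2 * np.pi, n)
    base = np.array([*seedling.base_xy, 0.0])
    return (base[None] + np.outer(t, a)
            + seedling.stem_radius * (np.outer(np.cos(phi), e1)
                                      + np.outer(np.sin(phi), e2)))


def _sample_tray(n: int, rng: np.random.Generator) -> np.ndarray:
    lx, ly, h = TRAY
    top_area = lx * ly
    wall_area = 2 * (lx + ly) * h
    n_top = int(n * top_area / (top_area + wall_area))
    top = np.column_stack([rng.uniform(-lx / 2, lx / 2, n_top),
                           rng.uniform(-ly / 2, ly / 2, n_top),
                           np.zeros(n_top)])
    n_wall = n - n_top
    perim = rng.uniform(0, 2 * (lx + ly), n_wall)
    z = rng.uniform(-h, 0, n_wall)
    x = np.empty(n_wall)
    y = np.empty(n_wall)
    for lo, hi, fx, fy in [(0, lx, lambda u: u - lx / 2, lambda u: -ly / 2),
                           (lx, lx + ly, lambda u: lx / 2, lambda u: u - lx - ly / 2),
                           (lx + ly, 2 * lx + ly, lambda u: u - lx - ly - lx / 2,
                            lambda u: ly / 2),
                           (2 * lx + ly, 2 * (lx + ly), lambda u: -lx / 2,
                            lambda u: u - 2 * lx - ly - ly / 2)]:
        m = (perim >= lo) & (perim < hi)
        x[m] = fx(perim[m])
        y[m] = fy(perim[m])
    return np.vstack([top, np.column_stack([x, y, z])])


# leaves deep green, stems the paler yellow-green of young sorghum culms,
# tray a neutral acrylic gray; overlapping noise keeps classes non-separable
# by color alone
_COLOR_MEANS = {LEAF: (40, 120, 35), STEM: (90, 140, 55), POT: (150, 145, 135)}


def _colorize(labels: np.ndarray, rng: np.random.Generator) -> np.ndarray:
    colors = np.zeros((len(labels), 3))
    for lab, mean in _COLOR_MEANS.items():
        m = labels == lab
        colors[m] = np.asarray(mean) + rng.normal(0, 18, size=(int(m.sum()), 3))
    return np.clip(colors, 0, 255).astype(np.uint8)


def analytic_traits(seedlings: list[SeedlingSpec]) -> TraitRecord:
    """Closed-form trait record for a pot (the trait-module oracle)."""
    record = TraitRecord()
    for i, s in enumerate(sorted(seedlings, key=lambda s: s.base_xy)):
        record.plants.append({
            "plant_id": i,
            "stem_length_cm": s.stem_length * 100.0,
            "stem_diameter_mm": 2.0 * s.stem_radius * 1000.0,
            "centroid_x": s.base_xy[0], "centroid_y": s.base_xy[1],
        })
        for leaf in s.leaves:
            record.leaves.append({
                "plant_id": i,
                "length_cm": leaf.chord_m * 100.0,
                "width_cm": leaf.width * 100.0,
                "area_cm2": leaf.area_m2 * 1e4,
            })
    record.leaf_count = len(record.leaves)
    record.lai = sum(l["area_cm2"] for l in record.leaves) / TRAY_AREA_CM2
    if record.plants:
        record.mean_stem_length_cm = float(np.mean(
            [p["stem_length_cm"] for p in record.plants]))
        record.mean_stem_diameter_mm = float(np.mean(
            [p["stem_diameter_mm"] for p in record.plants]))
    return record


def generate_pot(spec: PotSpec | None = None, seed: int = 0,
                 pot_id: str = "pot") -> tuple[LabeledCloud, dict]:
    """One labeled pot cloud plus its ground truth.

    The ground truth dict holds the seedling specs, the analytic
    TraitRecord and per-point plant/leaf instance ids (-1 off-plant),
    aligned with the returned cloud.
    """
    spec = spec or PotSpec()
    rng = np.random.default_rng(seed)
    n_plants = spec.n_plants or int(rng.integers(15, 26))
    if n_plants > 25:
        raise ValueError("at most 25 grid positions per tray")
    cells = rng.permutation(25)[:n_plants]
    dense = spec.target_points is None
    seedlings = []
    for cell in cells:
        gx, gy = divmod(int(cell), 5)
        base = (np.array([gx, gy]) - 2.0) * 0.05 + rng.uniform(
            -spec.grid_jitter, spec.grid_jitter, 2)
        seedlings.append(_random_seedling(rng, base, dense))

    pts, labels, plant_ids, leaf_ids = [], [], [], []
    tray = _sample_tray(spec.tray_points, rng)
    pts.append(tray)
    labels.append(np.full(len(tray), POT))
    plant_ids.append(np.full(len(tray), -1))
    leaf_ids.append(np.full(len(tray), -1))
    leaf_counter = 0
    for pi, s in enumerate(seedlings):
        stem = _sample_stem(s, spec.stem_points, rng)
        pts.append(stem)
        labels.append(np.full(len(stem), STEM))
        plant_ids.append(np.full(len(stem), pi))
        leaf_ids.append(np.full(len(stem), -1))
        for leaf in s.leaves:
            lp = _sample_leaf(s, leaf, spec.leaf_points, rng)
            pts.append(lp)
            labels.append(np.full(len(lp), LEAF))
            plant_ids.append(np.full(len(lp), pi))
            leaf_ids.append(np.full(len(lp), leaf_counter))
            leaf_counter += 1
    points = np.vstack(pts)
    labels = np.concatenate(labels)
    plant_ids = np.concatenate(plant_ids)
    leaf_ids = np.concatenate(leaf_ids)

    if spec.noise_sigma > 0:
        points = points + rng.normal(0, spec.noise_sigma, points.shape)
    keep = np.ones(len(points), dtype=bool)
    if spec.density_gradient:
        zmax = max(points[:, 2].max(), 1e-9)
        rel = np.clip(points[:, 2], 0, None) / zmax
        keep &= rng.random(len(points)) > 0.25 * rel
    if spec.occlusion:
        ang = np.arctan2(points[:, 1], points[:, 0])
        a0 = rng.uniform(-np.pi, np.pi)
        width = rng.uniform(np.pi / 8, np.pi / 4)
        in_sector = np.abs((ang - a0 + np.pi) % (2 * np.pi) - np.pi) < width / 2
        keep &= ~(in_sector & (rng.random(len(points)) < 0.5))
    points, labels = points[keep], labels[keep]
    plant_ids, leaf_ids = plant_ids[keep], leaf_ids[keep]

    cloud = LabeledCloud(points=points, colors=_colorize(labels, rng),
                         labels=labels, pot_id=pot_id)
    gt = {"seedlings": seedlings, "traits": analytic_traits(seedlings),
          "plant_ids": plant_ids, "leaf_ids": leaf_ids,
          "n_plants": n_plants}
    if spec.target_points is not None and len(cloud) > spec.target_points:
        from .sampling import fps_indices
        idx = np.sort(fps_indices(cloud.points, spec.target_points,
                                  seed=int(rng.integers(2 ** 31))))
        cloud = cloud.select(idx)
        gt["plant_ids"] = plant_ids[idx]
        gt["leaf_ids"] = leaf_ids[idx]
    return cloud, gt


def generate_dataset(n_pots: int, seed: int = 0,
                     spec: PotSpec | None = None) -> list[tuple[LabeledCloud, dict]]:
    base = np.random.default_rng(seed).integers(2 ** 31, size=n_pots)
    return [generate_pot(spec, seed=int(base[i]), pot_id=f"pot_{i:03d}")
            for i in range(n_pots)]


def generate_benchmark(n_pots: int, out_dir, split_ratio=(7, 2, 1), seed: int = 0,
                       spec: PotSpec | None = None) -> dict:
    """Write PLY files, a ground-truth CSV and a pot-level split manifest."""
    if n_pots < 3:
        raise ValueError("need at least 3 pots")
    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    rows = []
    pot_ids = []
    for cloud, gt in generate_dataset(n_pots, seed=seed, spec=spec):
        write_ply(cloud, out_dir / f"{cloud.pot_id}.ply")
        pot_ids.append(cloud.pot_id)
        tr = gt["traits"]
        for p in tr.plants:
            rows.append({"pot_id": cloud.pot_id, "kind": "plant", **p})
        for l in tr.leaves:
            rows.append({"pot_id": cloud.pot_id, "kind": "leaf", **l})
        rows.append({"pot_id": cloud.pot_id, "kind": "pot",
                     "leaf_count": tr.leaf_count, "lai": tr.lai,
                     "mean_stem_length_cm": tr.mean_stem_length_cm,
                     "mean_stem_diameter_mm": tr.mean_stem_diameter_mm})
    pd.DataFrame(rows).to_csv(out_dir / "ground_truth.csv", index=False)
    split = pot_level_split(pot_ids, split_ratio, seed=seed)
    manifest = pd.DataFrame(sorted(split.assignment.items()),
                            columns=["pot_id", "subset"])
    manifest.to_csv(out_dir / "split.csv", index=False)
    return {"pot_ids": pot_ids, "split": split, "dir": out_dir}
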