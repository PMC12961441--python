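"""Phenotypic trait extraction from a semantically segmented cloud.

Pipeline: rescale to real-world meters, split points by class, cluster
stem points into plants (DBSCAN on the xy projection), fit each stem's
axis (RANSAC line consensus refined by PCA/SVD with the upward sign
convention), assign leaf points to the nearest stem centroid, split each
plant's leaf points into individual leaves (3-D DBSCAN), then measure leaf
length/width (PCA extents), leaf surface area (Delaunay triangulation of
the PCA-plane projection with 3-D triangle areas), stem length (axial
extent) and basal stem diameter.  Pot-level LAI is total leaf area over
the 625 cm^2 tray footprint.

Units: coordinates are meters; reported lengths and areas are cm and cm^2,
stem diameters mm.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
from scipy.spatial import Delaunay, QhullError
from sklearn.cluster import DBSCAN

from .cloud import LEAF, POT, STEM, LabeledCloud

M_TO_CM = 100.0
M_TO_MM = 1000.0
TRAY_AREA_CM2 = 625.0


@dataclass
class ClusterConfig:
    eps: float = 0.03            # meters (s_stem = 3 cm)
    min_pts: int = 80
    leaf_eps: float = 0.01       # 3-D leaf-instance clustering
    leaf_min_pts: int = 20

    def __post_init__(self):
        if self.eps <= 0 or self.leaf_eps <= 0:
            raise ValueError("eps must be positive")
        if self.min_pts < 1 or self.leaf_min_pts < 1:
            raise ValueError("minPts must be >= 1")


@dataclass
class RansacConfig:
    threshold: float = 0.01      # meters (inlier distance to the line)
    iterations: int = 120
    seed: int = 0

    def __post_init__(self):
        if self.threshold <= 0 or self.iterations < 1:
            raise ValueError("invalid RANSAC configuration")


@dataclass
class PlantInstance:
    plant_id: int
    stem_points: np.ndarray                 # (M, 3) meters
    centroid: np.ndarray                    # (2,) xy centroid of the stem
    axis: np.ndarray | None = None          # unit 3-vector, z >= 0
    anchor: np.ndarray | None = None        # mean stem point


@dataclass
class LeafInstance:
    plant_id: int
    points: np.ndarray
    length_cm: float = 0.0
    width_cm: float = 0.0
    area_cm2: float = 0.0


@dataclass
class TraitRecord:
    plants: list[dict] = field(default_factory=list)     # stem traits per plant
    leaves: list[dict] = field(default_factory=list)     # per-leaf L/W/A
    leaf_count: int = 0
    lai: float = 0.0
    mean_stem_length_cm: float = 0.0
    mean_stem_diameter_mm: float = 0.0


def rescale_cloud(cloud: LabeledCloud, scale: float) -> LabeledCloud:
    """Multiply coordinates by a constant factor (to real-world meters)."""
    if scale <= 0:
        raise ValueError("scale must be positive")
    out = cloud.select(slice(None))
    out.points = cloud.points * scale
    return out


def split_by_label(cloud: LabeledCloud) -> dict[str, np.ndarray]:
    """Disjoint stem/leaf/pot coordinate subsets; ignore points in none."""
    subsets = {
        "stem": cloud.points[cloud.labels == STEM],
        "leaf": cloud.points[cloud.labels == LEAF],
        "pot": cloud.points[cloud.labels == POT],
    }
    if len(subsets["stem"]) == 0:
        warnings.warn("no stem points in cloud; trait record will be empty")
    return subsets


def cluster_stems(stem_points: np.ndarray,
                  config: ClusterConfig | None = None) -> list[PlantInstance]:
    """DBSCAN on the xy projection; noise discarded; one plant per cluster.

    Plant ids are assigned in order of increasing cluster centroid (x, then
    y) so the numbering is stable under point permutation.
    """
    config = config or ClusterConfig()
    if len(stem_points) == 0:
        return []
    xy = stem_points[:, :2]
    labels = DBSCAN(eps=config.eps, min_samples=config.min_pts).fit_predict(xy)
    plants = []
    for c in sorted(set(labels) - {-1}):
        pts = stem_points[labels == c]
        plants.append(PlantInstance(plant_id=0, stem_points=pts,
                                    centroid=pts[:, :2].mean(axis=0)))
    plants.sort(key=lambda p: (round(p.centroid[0], 9), round(p.centroid[1], 9)))
    for i, p in enumerate(plants):
        p.plant_id = i
    return plants


def fit_stem_axis(plant: PlantInstance,
                  config: RansacConfig | None = None) -> PlantInstance:
    """RANSAC 2-point line consensus refined by SVD on the inlier set.

    The consensus model is the hypothesis with the largest inlier count
    (ties: earliest iteration); the first principal component of the
    centered inliers gives the axis, sign-fixed to a_z >= 0.
    """
    config = config or RansacConfig()
    pts = plant.stem_points
    if len(pts) < 2:
        raise ValueError("need at least 2 stem points to fit an axis")
    if np.allclose(pts, pts[0]):
        raise ValueError("degenerate stem: all points coincident")
    rng = np.random.default_rng(config.seed + plant.plant_id)
    best_count, best_inliers = -1, None
    for _ in range(config.iterations):
        i, j = rng.choice(len(pts), size=2, replace=False)
        v = pts[j] - pts[i]
        nv = np.linalg.norm(v)
        if nv == 0:
            continue
        vhat = v / nv
        d = np.linalg.norm(np.cross(pts - pts[i], vhat), axis=1)
        inliers = d <= config.threshold
        count = int(inliers.sum())
        if count > best_count:
            best_count, best_inliers = count, inliers
    inlier_pts = pts[best_inliers] if best_inliers is not None else pts
    if len(inlier_pts) < 2:
        inlier_pts = pts
    anchor = inlier_pts.mean(axis=0)
    _, _, vt = np.linalg.svd(inlier_pts - anchor, full_matrices=False)
    axis = vt[0]
    if axis[2] < 0:
        axis = -axis
    plant.axis = axis
    plant.anchor = anchor
    return plant


def assign_leaves(leaf_points: np.ndarray,
                  plants: list[PlantInstance]) -> dict[int, np.ndarray]:
    """Assign each leaf point to the plant with the nearest stem centroid
    in xy (ties: lowest plant id).  With no plants, everything lands under
    key -1 (unassigned)."""
    if not plants:
        return {-1: leaf_points}
    cents = np.stack([p.centroid for p in plants])
    d2 = ((leaf_points[:, None, :2] - cents[None]) ** 2).sum(axis=2)
    owner = d2.argmin(axis=1)                   # argmin -> lowest index on ties
    return {p.plant_id: leaf_points[owner == i] for i, p in enumerate(plants)}


def segment_leaves(plant_leaf_points: np.ndarray, plant_id: int = -1,
                   config: ClusterConfig | None = None) -> list[LeafInstance]:
    """3-D DBSCAN separating a plant's leaf points into individual leaves.

    Leaves closer than ``leaf_eps`` merge into one instance — a documented
    limitation of density-based instancing."""
    config = config or ClusterConfig()
    if len(plant_leaf_points) == 0:
        return []
    labels = DBSCAN(eps=config.leaf_eps,
                    min_samples=config.leaf_min_pts).fit_predict(plant_leaf_points)
    return [LeafInstance(plant_id=plant_id, points=plant_leaf_points[labels == c])
            for c in sorted(set(labels) - {-1})]


def _leaf_pca(points: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    centered = points - points.mean(axis=0)
    _, _, vt = np.linalg.svd(centered, full_matrices=False)
    return centered, vt


def leaf_dimensions(points: np.ndarray, use_third_component: bool = False
                    ) -> tuple[float, float]:
    """(L, W) in cm: extents along the first and second principal axes.

    The third-component variant (W along u3) is available behind a flag;
    the default ordering guarantees L >= W.
    """
    if len(points) < 3:
        raise ValueError("need at least 3 points")
    centered, vt = _leaf_pca(points)
    if np.linalg.matrix_rank(centered, tol=1e-12) < 2:
        raise ValueError("points are collinear")
    u1 = vt[0]
    u2 = vt[2] if use_third_component else vt[1]
    proj1 = centered @ u1
    proj2 = centered @ u2
    length = float(proj1.max() - proj1.min()) * M_TO_CM
    width = float(proj2.max() - proj2.min()) * M_TO_CM
    return length, width


def leaf_area(points: np.ndarray, tilt_cap: float = 5.0) -> float:
    """Surface area in cm^2: Delaunay triangulation of the (u1, u2) PCA
    projection, summing each triangle's 3-D area
    1/2 ||(p_j - p_i) x (p_k - p_i)||.

    ``tilt_cap`` bounds each triangle's 3-D-to-projected area ratio.
    Irregularly sampled curved surfaces produce sliver triangles whose
    interpolated facet is nearly perpendicular to the leaf plane; their
    inflated 3-D area would otherwise bias the estimate upward, so facets
    steeper than the cap are clamped (a leaf surface is never near-vertical
    relative to its own principal plane).
    """
    if len(points) < 3:
        raise ValueError("need at least 3 points")
    centered, vt = _leaf_pca(points)
    plane = centered @ vt[:2].T
    try:
        tri = Delaunay(plane)
    except QhullError:
        warnings.warn("degenerate (collinear) leaf points; area = 0")
        return 0.0
    p = points[tri.simplices]                       # (T, 3, 3)
    cross = np.cross(p[:, 1] - p[:, 0], p[:, 2] - p[:, 0])
    area3d = 0.5 * np.linalg.norm(cross, axis=1)
    q = plane[tri.simplices]
    d1, d2 = q[:, 1] - q[:, 0], q[:, 2] - q[:, 0]
    area2d = 0.5 * np.abs(d1[:, 0] * d2[:, 1] - d1[:, 1] * d2[:, 0])
    area3d = np.minimum(area3d, tilt_cap * area2d)
    return float(area3d.sum()) * M_TO_CM ** 2


def stem_traits(plant: PlantInstance,
                basal_fraction: float = 0.2) -> tuple[float, float]:
    """(stem length cm, stem diameter mm).

    Length is the extent of the stem points projected on the fitted axis.
    Diameter is twice the median perpendicular distance to the axis among
    points in the basal (lowest) fraction of the axial extent.
    """
    if plant.axis is None:
        raise ValueError("fit the stem axis first")
    pts = plant.stem_points
    if len(pts) < 2:
        raise ValueError("need at least 2 stem points")
    t = (pts - plant.anchor) @ plant.axis
    length = float(t.max() - t.min()) * M_TO_CM
    basal = t <= t.min() + basal_fraction * max(t.max() - t.min(), 1e-12)
    radial = np.linalg.norm(
        pts[basal] - plant.anchor - np.outer(t[basal], plant.axis), axis=1)
    diameter = float(2.0 * np.median(radial)) * M_TO_MM if basal.any() else 0.0
    return length, diameter


def pot_summary(record: TraitRecord, unit_area_cm2: float = TRAY_AREA_CM2) -> TraitRecord:
    """Fill pot-level aggregates: leaf count, LAI, mean stem height/diameter."""
    record.leaf_count = len(record.leaves)
    record.lai = sum(l["area_cm2"] for l in record.leaves) / unit_area_cm2
    if record.plants:
        record.mean_stem_length_cm = float(
            np.mean([p["stem_length_cm"] for p in record.plants]))
        record.mean_stem_diameter_mm = float(
            np.mean([p["stem_diameter_mm"] for p in record.plants]))
    return record


def extract_traits(cloud: LabeledCloud, scale: float = 1.0,
                   cluster_config: ClusterConfig | None = None,
                   ransac_config: RansacConfig | None = None) -> TraitRecord:
    """Full pipeline from a labeled cloud to a TraitRecord."""
    cluster_config = cluster_config or ClusterConfig()
    cloud = rescale_cloud(cloud, scale)
    subsets = split_by_label(cloud)
    record = TraitRecord()
    plants = cluster_stems(subsets["stem"], cluster_config)
    for plant in plants:
        fit_stem_axis(plant, ransac_config)
        length, diameter = stem_traits(plant)
        record.plants.append({"plant_id": plant.plant_id,
                              "stem_length_cm": length,
                              "stem_diameter_mm": diameter,
                              "centroid_x": float(plant.centroid[0]),
                              "centroid_y": float(plant.centroid[1])})
    for plant_id, pts in assign_leaves(subsets["leaf"], plants).items():
        if plant_id < 0 or len(pts) == 0:
            continue
        for leaf in segment_leaves(pts, plant_id, cluster_config):
            try:
                length, width = leaf_dimensions(leaf.points)
                area = leaf_area(leaf.points)
            except ValueError:
                continue
            record.leaves.append({"plant_id": plant_id, "length_cm": length,
                                  "width_cm": width, "area_cm2": area})
    return pot_summary(record)
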