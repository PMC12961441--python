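"""Trait extraction: clustering, axis fitting, leaf geometry, pot summary."""

import numpy as np
import pytest

from ptv2fr import (ClusterConfig, LabeledCloud, RansacConfig, TraitRecord,
                    assign_leaves, cluster_stems, extract_traits, fit_stem_axis,
                    leaf_area, leaf_dimensions, pot_summary, rescale_cloud,
                    split_by_label, stem_traits)
from ptv2fr.traits import PlantInstance


def textbook_dbscan(points, eps, min_pts):
    """From-scratch core/border/noise DBSCAN for cross-checking."""
    n = len(points)
    d = np.linalg.norm(points[:, None] - points[None], axis=-1)
    neighbors = [np.flatnonzero(d[i] <= eps) for i in range(n)]
    core = np.array([len(nb) >= min_pts for nb in neighbors])
    labels = np.full(n, -1)
    cid = 0
    for i in range(n):
        if labels[i] != -1 or not core[i]:
            continue
        stack = [i]
        labels[i] = cid
        while stack:
            j = stack.pop()
            if not core[j]:
                continue
            for q in neighbors[j]:
                if labels[q] == -1:
                    labels[q] = cid
                    stack.append(q)
        cid += 1
    return labels


def make_cylinder(n, height, radius, rng, axis=None, base=None, noise=0.0):
    axis = np.array([0, 0, 1.0]) if axis is None else np.asarray(axis, float)
    axis = axis / np.linalg.norm(axis)
    ref = np.array([1.0, 0, 0]) if abs(axis[0]) < 0.9 else np.array([0, 1.0, 0])
    e1 = np.cross(axis, ref)
    e1 /= np.linalg.norm(e1)
    e2 = np.cross(axis, e1)
    t = rng.uniform(0, height, n)
    phi = rng.uniform(0, 2 * np.pi, n)
    pts = (np.outer(t, axis) + radius * (np.outer(np.cos(phi), e1)
                                         + np.outer(np.sin(phi), e2)))
    if base is not None:
        pts = pts + np.asarray(base)
    if noise:
        pts = pts + rng.normal(0, noise, pts.shape)
    return pts


class TestRescaleAndSplit:
    def test_rescale_arithmetic_and_identity(self):
        c = LabeledCloud(points=np.array([[100.0, 0, 0]]))
        assert rescale_cloud(c, 1.0).points[0, 0] == 100.0
        assert rescale_cloud(c, 0.01).points[0, 0] == pytest.approx(1.0)
        with pytest.raises(ValueError):
            rescale_cloud(c, 0.0)

    def test_split_sizes_and_ignore_exclusion(self):
        labels = np.repeat([1, 0, 2, -1], [10, 20, 30, 5])
        c = LabeledCloud(points=np.zeros((65, 3)), labels=labels)
        subs = split_by_label(c)
        assert [len(subs[k]) for k in ("stem", "leaf", "pot")] == [10, 20, 30]

    def test_no_stem_warns(self):
        c = LabeledCloud(points=np.zeros((4, 3)), labels=np.zeros(4, int))
        with pytest.warns(UserWarning):
            split_by_label(c)

    def test_rescale_commutes_with_pipeline(self, rng):
        stem = make_cylinder(300, 0.04, 0.001, rng, base=(0.0, 0.0, 0.0))
        cloud = LabeledCloud(points=stem * 100.0,    # decimeters, say
                             labels=np.full(len(stem), 1))
        a = extract_traits(cloud, scale=0.01)
        b = extract_traits(rescale_cloud(cloud, 0.01), scale=1.0)
        assert a.mean_stem_length_cm == pytest.approx(b.mean_stem_length_cm)


class TestClusterStems:
    def test_two_blobs_two_plants(self, rng):
        a = rng.normal([0, 0, 0.02], 0.002, (100, 3))
        b = rng.normal([0.10, 0, 0.02], 0.002, (100, 3))
        plants = cluster_stems(np.vstack([a, b]), ClusterConfig(min_pts=50))
        assert len(plants) == 2
        assert plants[0].centroid[0] < plants[1].centroid[0]   # stable ids

    def test_min_pts_makes_small_blob_noise(self, rng):
        pts = rng.normal(0, 0.002, (50, 3))
        assert cluster_stems(pts, ClusterConfig(min_pts=80)) == []

    def test_matches_textbook_dbscan(self, rng):
        pts = np.vstack([rng.normal([0, 0, 0], 0.01, (60, 3)),
                         rng.normal([0.2, 0.1, 0], 0.01, (50, 3)),
                         rng.uniform(-0.5, 0.5, (30, 3))])
        cfg = ClusterConfig(eps=0.03, min_pts=10)
        plants = cluster_stems(pts, cfg)
        ref = textbook_dbscan(pts[:, :2], cfg.eps, cfg.min_pts)
        got_partition = sorted(
            (sorted(map(tuple, p.stem_points.round(9))) for p in plants))
        ref_partition = sorted(
            sorted(map(tuple, pts[ref == c].round(9)))
            for c in set(ref) - {-1})
        assert got_partition == ref_partition


class TestStemAxis:
    def test_vertical_stem_axis(self, rng):
        plant = PlantInstance(0, make_cylinder(400, 0.04, 0.001, rng),
                              np.zeros(2))
        fit_stem_axis(plant)
        np.testing.assert_allclose(plant.axis, [0, 0, 1], atol=1e-2)
        assert plant.axis[2] > 0.9999

    def test_outliers_rejected_within_one_degree(self, rng):
        stem = make_cylinder(360, 0.05, 0.0008, rng)
        outliers = rng.uniform(-0.05, 0.05, (40, 3)) + [0.03, 0.03, 0.02]
        plant = PlantInstance(0, np.vstack([stem, outliers]), np.zeros(2))
        fit_stem_axis(plant, RansacConfig(threshold=0.003, seed=1))
        angle = np.degrees(np.arccos(min(plant.axis[2], 1.0)))
        assert angle < 1.0

    def test_downward_axis_flipped_up(self, rng):
        pts = np.outer(np.linspace(0, 1, 50), [0.2, 0.0, -1.0]) * 0.05
        pts += rng.normal(0, 1e-5, pts.shape)
        plant = PlantInstance(0, pts, np.zeros(2))
        fit_stem_axis(plant)
        assert plant.axis[2] >= 0

    def test_degenerate_inputs(self):
        with pytest.raises(ValueError):
            fit_stem_axis(PlantInstance(0, np.zeros((1, 3)), np.zeros(2)))
        with pytest.raises(ValueError):
            fit_stem_axis(PlantInstance(0, np.zeros((5, 3)), np.zeros(2)))


class TestAssignLeaves:
    def test_nearest_and_tie_break(self):
        plants = [PlantInstance(0, np.zeros((1, 3)), np.array([0.0, 0.0])),
                  PlantInstance(1, np.zeros((1, 3)), np.array([0.06, 0.0]))]
        leaves = np.array([[0.01, 0, 0.02],      # 1 cm from A, 5 cm from B
                           [0.03, 0, 0.02]])     # equidistant -> plant 0
        out = assign_leaves(leaves, plants)
        assert len(out[0]) == 2 and len(out[1]) == 0

    def test_matches_brute_force(self, rng):
        plants = [PlantInstance(i, np.zeros((1, 3)),
                                rng.uniform(-0.1, 0.1, 2)) for i in range(6)]
        leaves = rng.uniform(-0.12, 0.12, (200, 3))
        out = assign_leaves(leaves, plants)
        cents = np.stack([p.centroid for p in plants])
        for pid, pts in out.items():
            for q in pts:
                d = np.linalg.norm(cents - q[:2], axis=1)
                assert d[pid] == pytest.approx(d.min())

    def test_no_plants(self):
        out = assign_leaves(np.zeros((3, 3)), [])
        assert len(out[-1]) == 3


class TestLeafGeometry:
    def _grid(self, lx, ly, n=25):
        u, v = np.meshgrid(np.linspace(0, lx, n), np.linspace(0, ly, n))
        return np.column_stack([u.ravel(), v.ravel(), np.zeros(u.size)])

    def test_rectangle_extents(self):
        pts = self._grid(0.04, 0.01)
        length, width = leaf_dimensions(pts)
        assert length == pytest.approx(4.0, abs=1e-9)
        assert width == pytest.approx(1.0, abs=1e-9)

    def test_rotation_invariance(self, rng):
        pts = self._grid(0.04, 0.01)
        q, _ = np.linalg.qr(rng.standard_normal((3, 3)))
        rotated = pts @ q.T + rng.uniform(-1, 1, 3)
        l0, w0 = leaf_dimensions(pts)
        l1, w1 = leaf_dimensions(rotated)
        assert l1 == pytest.approx(l0, abs=1e-6)
        assert w1 == pytest.approx(w0, abs=1e-6)

    def test_single_triangle_area(self):
        pts = np.array([[0, 0, 0], [2, 0, 0], [0, 2, 0.]])
        assert leaf_area(pts) == pytest.approx(2.0 * 1e4)   # m^2 -> cm^2

    def test_flat_unit_square_area(self):
        pts = self._grid(1.0, 1.0, n=11)
        assert leaf_area(pts) == pytest.approx(1e4, abs=1e-5)

    def test_cylinder_section_area_within_2_percent(self, rng):
        # ribbon on a cylinder of radius R: developable, area = arc * width
        r, arc, width = 0.05, 0.03, 0.01
        s = rng.uniform(0, arc, 2000)
        t = rng.uniform(0, width, 2000)
        theta = s / r
        pts = np.column_stack([r * np.sin(theta), t, r * (1 - np.cos(theta))])
        expect = arc * width * 1e4
        assert abs(leaf_area(pts) - expect) / expect < 0.02

    def test_curved_ribbon_length_within_5_percent(self, rng):
        r, arc, width = 0.06, 0.04, 0.008
        s = rng.uniform(0, arc, 1500)
        t = rng.uniform(0, width, 1500)
        theta = s / r
        pts = np.column_stack([r * np.sin(theta), t, r * (1 - np.cos(theta))])
        chord = 2 * r * np.sin(arc / (2 * r)) * 100.0
        length, _ = leaf_dimensions(pts)
        assert abs(length - chord) / chord < 0.05

    def test_too_few_or_collinear(self):
        with pytest.raises(ValueError):
            leaf_dimensions(np.zeros((2, 3)))
        line = np.outer(np.linspace(0, 1, 10), [1.0, 0, 0])
        with pytest.raises(ValueError):
            leaf_dimensions(line)


class TestStemTraits:
    def test_ideal_cylinder(self, rng):
        plant = PlantInstance(0, make_cylinder(2000, 0.04, 0.001, rng), np.zeros(2))
        fit_stem_axis(plant)
        length, diameter = stem_traits(plant)
        assert length == pytest.approx(4.0, rel=0.02)
        assert diameter == pytest.approx(2.0, rel=0.02)

    def test_noisy_cylinder_diameter_within_10_percent(self, rng):
        plant = PlantInstance(0, make_cylinder(2000, 0.04, 0.001, rng,
                                               noise=1e-4), np.zeros(2))
        fit_stem_axis(plant)
        _, diameter = stem_traits(plant)
        assert abs(diameter - 2.0) / 2.0 < 0.10

    def test_two_point_degenerate_stem(self):
        plant = PlantInstance(0, np.array([[0, 0, 0], [0, 0, 0.03]]), np.zeros(2))
        fit_stem_axis(plant)
        length, diameter = stem_traits(plant)
        assert length == pytest.approx(3.0)
        assert diameter == pytest.approx(0.0, abs=1e-9)


class TestPotSummary:
    def _record(self, areas):
        rec = TraitRecord()
        rec.leaves = [{"plant_id": 0, "length_cm": 1, "width_cm": 1,
                       "area_cm2": a} for a in areas]
        rec.plants = [{"plant_id": 0, "stem_length_cm": 4.0,
                       "stem_diameter_mm": 2.0}]
        return rec

    def test_lai_definition(self):
        assert pot_summary(self._record([625.0])).lai == pytest.approx(1.0)

    def test_lai_arithmetic(self):
        rec = pot_summary(self._record([1000.0, 831.25]))
        assert rec.lai == pytest.approx(1831.25 / 625)
        assert rec.leaf_count == 2

    def test_zero_leaves(self):
        rec = pot_summary(self._record([]))
        assert rec.lai == 0.0 and rec.leaf_count == 0


class TestRigidInvariance:
    def test_traits_invariant_to_z_rotation_and_translation(self, rng):
        from ptv2fr.synthetic import PotSpec, generate_pot
        cloud, _ = generate_pot(PotSpec.dense_traits(), seed=2)
        rec0 = extract_traits(cloud)
        ang = 0.7
        rot = np.array([[np.cos(ang), -np.sin(ang), 0],
                        [np.sin(ang), np.cos(ang), 0], [0, 0, 1.0]])
        moved = cloud.select(slice(None))
        moved.points = cloud.points @ rot.T + np.array([0.3, -0.2, 0.1])
        rec1 = extract_traits(moved)
        assert len(rec1.plants) == len(rec0.plants)
        assert rec1.leaf_count == rec0.leaf_count
        assert rec1.mean_stem_length_cm == pytest.approx(
            rec0.mean_stem_length_cm, rel=1e-3)
        assert rec1.lai == pytest.approx(rec0.lai, rel=1e-3)
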