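"""Side alignment, stems, curvature features and fruit segmentation."""

import numpy as np
import pytest
from scipy.spatial.transform import Rotation

from thermocloud.geometry import RigidTransform
from thermocloud.io import PointCloud
from thermocloud.orchard import (
    FruitSegment,
    align_tree_sides,
    categorize_side,
    curvature_features,
    detect_stems,
    estimate_thresholds,
    segment_fruits,
    segment_tree,
)


# ---------------------------------------------------------------------------
# side alignment
# ---------------------------------------------------------------------------


def test_alignment_recovers_known_displacement(orchard_scene):
    # side_b: a displaced copy of side_a, init near the truth
    (east, _), _, _ = orchard_scene
    true = RigidTransform(
        Rotation.from_rotvec([0.0, 0.0, 0.03]).as_matrix(), [0.02, -0.015, 0.01]
    )
    side_b = PointCloud(true.inverse().apply(east.points))
    init = RigidTransform(
        Rotation.from_rotvec([0.0, 0.0, 0.022]).as_matrix(), [0.012, -0.02, 0.006]
    )
    merged, icp = align_tree_sides(east, side_b, init)
    moved = icp.T_final.apply(side_b.points)
    rms = np.sqrt(np.mean(np.sum((moved - east.points) ** 2, axis=1)))
    assert rms < 0.005  # < 5 mm
    assert len(merged) == 2 * len(east)


def test_fixture_alignment_good_enough_for_fruit_merging(orchard_pipeline, orchard_scene):
    (east, west), _, truth = orchard_scene
    icp = orchard_pipeline["icp"]
    ideal = truth.info["row_from_west"].apply(west.points)
    moved = icp.T_final.apply(west.points)
    rms = np.sqrt(np.mean(np.sum((moved - ideal) ** 2, axis=1)))
    assert rms < 0.010  # inside the 20 mm clustering linkage


def test_alignment_identity_for_identical_clouds():
    rng = np.random.default_rng(0)
    cloud = PointCloud(rng.uniform(-1, 1, (2000, 3)))
    merged, icp = align_tree_sides(cloud, cloud, RigidTransform.identity())
    assert icp.T_corr.is_identity(atol=1e-9)
    assert len(merged) == 2 * len(cloud)
    assert (merged.extra["side"] == 0).sum() == len(cloud)


# ---------------------------------------------------------------------------
# stems and trees
# ---------------------------------------------------------------------------


def test_five_stems_within_half_bin(orchard_pipeline):
    stems = orchard_pipeline["stems"]
    truth = orchard_pipeline["truth"].info["stems"]
    assert len(stems) == 5
    for (sx, sy), (tx, ty) in zip(stems, truth):
        assert abs(sx - tx) <= 0.025 and abs(sy - ty) <= 0.025  # half of 50 mm bin


def test_single_trunk_single_peak():
    rng = np.random.default_rng(1)
    th = rng.uniform(0, 2 * np.pi, 3000)
    z = rng.uniform(0.0, 1.5, 3000)
    pts = np.column_stack([0.3 + 0.03 * np.cos(th), -0.2 + 0.03 * np.sin(th), z])
    stems = detect_stems(PointCloud(pts))
    assert len(stems) == 1
    assert stems[0] == pytest.approx((0.3, -0.2), abs=0.03)


def test_peak_count_matches_bruteforce_histogram_scan(orchard_pipeline):
    """Recount peaks with an exhaustive neighbourhood scan of the histogram."""
    merged = orchard_pipeline["merged"]
    z = merged.points[:, 2]
    band = merged.points[(z >= 0.2) & (z <= 0.8)]
    bs = 0.05
    xe = np.arange(band[:, 0].min() - bs, band[:, 0].max() + 2 * bs, bs)
    ye = np.arange(band[:, 1].min() - bs, band[:, 1].max() + 2 * bs, bs)
    H, _, _ = np.histogram2d(band[:, 0], band[:, 1], bins=(xe, ye))
    floor = np.percentile(H[H > 0], 50.0)
    win = 5  # 0.5 m suppression / 0.05 m bin / 2
    count = 0
    for i in range(H.shape[0]):
        for j in range(H.shape[1]):
            if H[i, j] < floor:
                continue
            lo_i, hi_i = max(0, i - win), min(H.shape[0], i + win + 1)
            lo_j, hi_j = max(0, j - win), min(H.shape[1], j + win + 1)
            if H[i, j] == H[lo_i:hi_i, lo_j:hi_j].max():
                count += 1
    assert len(orchard_pipeline["stems"]) == 5 <= count


def test_tree_cylinder_membership():
    rng = np.random.default_rng(2)
    cloud = PointCloud(rng.uniform([-1, -1, 0], [1, 3, 2], size=(5000, 3)))
    seg = segment_tree(cloud, (0.1, 1.0), radius=0.45)
    d = np.hypot(cloud.points[:, 0] - 0.1, cloud.points[:, 1] - 1.0)
    np.testing.assert_array_equal(np.sort(seg.indices), np.flatnonzero(d <= 0.45))
    whole = segment_tree(cloud, (0.0, 1.0), radius=10.0)
    assert len(whole.indices) == len(cloud)


def test_adjacent_trees_disjoint_at_default_radius():
    rng = np.random.default_rng(3)
    t1 = rng.normal([0, 0, 1], [0.1, 0.1, 0.3], size=(1000, 3))
    t2 = rng.normal([0, 0.95, 1], [0.1, 0.1, 0.3], size=(1000, 3))
    cloud = PointCloud(np.vstack([t1, t2]))
    a = segment_tree(cloud, (0.0, 0.0), 0.45)
    b = segment_tree(cloud, (0.0, 0.95), 0.45)
    assert len(np.intersect1d(a.indices, b.indices)) == 0


# ---------------------------------------------------------------------------
# curvature
# ---------------------------------------------------------------------------


def test_plane_has_zero_raw_curvature():
    rng = np.random.default_rng(4)
    uv = rng.uniform(-1, 1, (2000, 2))
    cloud = PointCloud(np.column_stack([uv, np.zeros(2000)]))
    field = curvature_features(cloud, k=30)
    np.testing.assert_allclose(field.raw_curvature, 0.0, atol=1e-12)


def test_sphere_curvature_exceeds_plane_under_identical_sampling():
    rng = np.random.default_rng(5)
    n = 3000
    v = rng.normal(size=(n, 3))
    v /= np.linalg.norm(v, axis=1, keepdims=True)
    sphere = PointCloud(0.04 * v)
    uv = rng.uniform(-0.04, 0.04, (n, 2))
    plane = PointCloud(np.column_stack([uv, np.zeros(n)]))
    c_sphere = curvature_features(sphere, k=30).raw_curvature
    c_plane = curvature_features(plane, k=30).raw_curvature
    assert np.median(c_plane) == 0.0
    assert np.median(c_sphere) > 1e-3  # curvature of the 40 mm sphere patch


def test_eigenvalues_match_dense_per_neighbourhood_oracle():
    from scipy.spatial import cKDTree

    rng = np.random.default_rng(6)
    pts = rng.normal(size=(500, 3))
    cloud = PointCloud(pts)
    k = 12
    field = curvature_features(cloud, k=k)
    tree = cKDTree(pts)
    check = rng.choice(500, size=100, replace=False)
    for i in check:
        _, idx = tree.query(pts[i], k=k + 1)
        nb = pts[idx] - pts[idx].mean(axis=0)
        cov = nb.T @ nb / (k + 1)
        evals = np.sort(np.linalg.eigh(cov)[0])[::-1]
        np.testing.assert_allclose(field.eigenvalues[i], evals, atol=1e-9)


def test_scaled_curvature_attains_bounds_and_duplicates_flagged():
    rng = np.random.default_rng(7)
    pts = np.vstack([rng.normal(size=(500, 3)), np.tile([[5.0, 5.0, 5.0]], (10, 1))])
    field = curvature_features(PointCloud(pts), k=6)
    assert field.curvature.min() == 0.0
    assert field.curvature.max() == 100.0
    assert field.degenerate[-10:].all()
    assert np.all(field.curvature[field.degenerate] == 0.0)


def test_curvature_invariant_under_rigid_motion():
    rng = np.random.default_rng(8)
    v = rng.normal(size=(2000, 3))
    v /= np.linalg.norm(v, axis=1, keepdims=True)
    pts = 0.04 * v + rng.normal(0, 1e-4, (2000, 3))
    T = RigidTransform(Rotation.from_rotvec([0.4, -0.8, 0.2]).as_matrix(), [1.0, -2.0, 3.0])
    a = curvature_features(PointCloud(pts), k=20).curvature
    b = curvature_features(PointCloud(T.apply(pts)), k=20).curvature
    np.testing.assert_allclose(a, b, atol=1e-6)


# ---------------------------------------------------------------------------
# thresholds
# ---------------------------------------------------------------------------


def _field_with(curv, refl):
    from thermocloud.orchard import FeatureField

    return FeatureField(
        curvature=np.asarray(curv, float),
        raw_curvature=np.asarray(curv, float),
        eigenvalues=np.zeros((len(curv), 3)),
        reflectance=np.asarray(refl, float),
        k=30,
        degenerate=np.zeros(len(curv), bool),
    )


def test_kde_valley_between_two_modes():
    rng = np.random.default_rng(9)
    curv = np.concatenate([rng.normal(20, 5, 4000), rng.normal(80, 5, 2000)])
    refl = np.concatenate([rng.normal(0.3, 0.03, 4000), rng.normal(0.8, 0.03, 2000)])
    c_th, r_th = estimate_thresholds(_field_with(curv, refl), method="kde_valley")
    assert 40.0 <= c_th <= 60.0
    assert 0.45 <= r_th <= 0.65


def test_percentile_matches_quantile_oracle():
    rng = np.random.default_rng(10)
    curv = rng.gamma(2.0, 10.0, 5000)
    refl = rng.uniform(0, 1, 5000)
    c_th, r_th = estimate_thresholds(_field_with(curv, refl), method="percentile", percentile=90)
    assert c_th == pytest.approx(np.quantile(curv, 0.9), abs=1e-12)
    assert r_th == pytest.approx(np.quantile(refl, 0.9), abs=1e-12)


def test_constant_feature_raises_naming_it():
    rng = np.random.default_rng(11)
    with pytest.raises(ValueError, match="reflectance"):
        estimate_thresholds(_field_with(rng.uniform(0, 100, 100), np.full(100, 0.5)))


# ---------------------------------------------------------------------------
# fruit segmentation
# ---------------------------------------------------------------------------


def test_fruit_detection_on_standard_fixture(orchard_pipeline):
    from thermocloud.evaluate import detection_f1

    fruits = orchard_pipeline["fruits"]
    truth = orchard_pipeline["truth"].info["fruits"]
    rep = detection_f1([f.centroid for f in fruits], [t["center"] for t in truth], 0.06)
    assert rep.f1 >= 0.9


def test_recovered_fst_within_tolerance(orchard_pipeline):
    from thermocloud.evaluate import detection_f1

    fruits = orchard_pipeline["fruits"]
    truth = orchard_pipeline["truth"].info["fruits"]
    rep = detection_f1([f.centroid for f in fruits], [t["center"] for t in truth], 0.06)
    for di, tj, _ in rep.matches:
        assert abs(fruits[di].fst_mean - truth[tj]["fst_mean"]) < 0.2


def test_thresholds_above_all_features_yield_empty(orchard_pipeline):
    import copy

    field = copy.copy(orchard_pipeline["field"])
    field.curvature_threshold = 101.0
    field.reflectance_threshold = 2.0
    merged = orchard_pipeline["merged"]
    seg = segment_tree(merged, orchard_pipeline["stems"][0], 0.45)
    assert segment_fruits(seg, merged, field) == []


def test_constant_temperature_fruit_stats():
    rng = np.random.default_rng(12)
    v = rng.normal(size=(400, 3))
    v /= np.linalg.norm(v, axis=1, keepdims=True)
    pts = 0.035 * v + [0.1, 0.2, 1.5]
    cloud = PointCloud(pts, np.full(400, 0.9), np.full(400, 18.5))
    field = _field_with(np.full(400, 50.0), cloud.reflectance)
    field.curvature_threshold = 10.0
    field.reflectance_threshold = 0.5
    seg = segment_tree(cloud, (0.1, 0.2), 1.0)
    (fruit,) = segment_fruits(seg, cloud, field)
    assert fruit.fst_mean == 18.5 and fruit.fst_sd == 0.0
    assert fruit.radius == pytest.approx(0.035, rel=0.05)


def test_sentinel_temperatures_excluded_from_fst():
    rng = np.random.default_rng(13)
    v = rng.normal(size=(200, 3))
    v /= np.linalg.norm(v, axis=1, keepdims=True)
    temps = np.full(200, 21.0)
    temps[:50] = -10.0
    cloud = PointCloud(0.03 * v, np.full(200, 0.9), temps)
    field = _field_with(np.full(200, 50.0), cloud.reflectance)
    field.curvature_threshold = 0.0
    field.reflectance_threshold = 0.0
    seg = segment_tree(cloud, (0.0, 0.0), 1.0)
    (fruit,) = segment_fruits(seg, cloud, field)
    assert fruit.fst_mean == 21.0 and fruit.n_temperature == 150


# ---------------------------------------------------------------------------
# side labels
# ---------------------------------------------------------------------------


def _fruit_at(x):
    return FruitSegment(
        indices=np.arange(3), centroid=np.array([x, 0.0, 1.0]), radius=0.03,
        fst_mean=18.0, fst_min=17.0, fst_max=19.0, fst_sd=0.2, n_temperature=3,
    )


def test_side_labels_sign_symmetry_and_partition():
    fruits = [_fruit_at(0.2), _fruit_at(-0.15), _fruit_at(0.0)]
    labelled = categorize_side(fruits)
    assert [f.side for f in labelled] == ["east", "west", "east"]  # 0 ties to east
    mirrored = [_fruit_at(-0.2), _fruit_at(0.15)]
    assert [f.side for f in categorize_side(mirrored)] == ["west", "east"]
    assert sum(f.side == "east" for f in labelled) + sum(f.side == "west" for f in labelled) == 3
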