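"""Board localisation, pose refinement and the extrinsic solve."""

import numpy as np
import pytest
from scipy.spatial.transform import Rotation

from thermocloud.extrinsics import (
    DegenerateGeometryError,
    DimensionMismatchError,
    FeaturePair,
    bulb_positions,
    crop_box,
    cross_scan_rmse,
    initial_pose_pca,
    locate_pattern_plane,
    refine_pose_icp,
    reprojection_rmse,
    sample_pattern_model,
    solve_extrinsics,
)
from thermocloud.geometry import RigidTransform, rotation_between
from thermocloud.intrinsics import CameraIntrinsics, InsufficientDataError, pattern_grid
from thermocloud.io import PointCloud


CAM = CameraIntrinsics(570.0, 570.0, 320.0, 240.0, k1=-0.05)


def _board_cloud(pattern, pose=RigidTransform.identity(), n=4000, noise=0.0, seed=0):
    rng = np.random.default_rng(seed)
    uv = rng.uniform(
        [-pattern.board_width / 2, -pattern.board_height / 2],
        [pattern.board_width / 2, pattern.board_height / 2],
        size=(n, 2),
    )
    pts = np.column_stack([uv, np.zeros(n)])
    if noise:
        pts[:, 2] += rng.normal(0, noise, n)
    return PointCloud(pose.apply(pts))


# ---------------------------------------------------------------------------
# crop
# ---------------------------------------------------------------------------


def test_crop_box_identity_and_empty():
    cloud = PointCloud(np.random.default_rng(0).uniform(-1, 1, (500, 3)))
    assert len(crop_box(cloud, ([-2, -2, -2], [2, 2, 2]))) == 500
    big = PointCloud(np.full((10, 3), 2.0))
    assert len(crop_box(big, ([-0.5, -0.5, -0.5], [0.5, 0.5, 0.5]))) == 0


def test_crop_box_matches_membership_oracle():
    rng = np.random.default_rng(1)
    cloud = PointCloud(rng.uniform(-2, 2, (1000, 3)), rng.uniform(0, 1, 1000))
    lo, hi = np.array([-0.7, -1.2, 0.1]), np.array([1.1, 0.4, 1.9])
    kept = crop_box(cloud, (lo, hi))
    expected = [i for i, p in enumerate(cloud.points) if np.all(p > lo) and np.all(p < hi)]
    assert len(kept) == len(expected)
    np.testing.assert_allclose(kept.points, cloud.points[expected])
    np.testing.assert_allclose(kept.reflectance, cloud.reflectance[expected])


# ---------------------------------------------------------------------------
# plane extraction
# ---------------------------------------------------------------------------


def test_plane_recovered_among_outliers(pattern):
    # 20 % clutter in front of and behind the board, within its footprint
    rng = np.random.default_rng(2)
    pose = RigidTransform(Rotation.from_rotvec([0.2, 0.1, 0.0]).as_matrix(), [1.5, 0.2, 0.0])
    board = _board_cloud(pattern, pose, n=4000, noise=0.002, seed=3)
    # clutter above/below the (near-horizontal) board, inside its footprint
    outliers = rng.uniform([1.3, 0.0, -0.2], [1.7, 0.4, 0.2], size=(1000, 3))
    cloud = PointCloud(np.vstack([board.points, outliers]))
    inliers, plane = locate_pattern_plane(cloud, pattern, ransac_threshold=0.010, rng=0)
    # membership against generating labels: board points are the first 4000
    sel = plane.distance(board.points) <= 0.010
    assert sel.mean() >= 0.99


def test_noiseless_plane_normal_exact(pattern):
    pose = RigidTransform(Rotation.from_rotvec([0.3, 0.0, 0.1]).as_matrix(), [1.5, 0.0, 0.0])
    board = _board_cloud(pattern, pose, n=2000, seed=4)
    _, plane = locate_pattern_plane(board, pattern, rng=0)
    true_normal = pose.R[:, 2]
    angle = np.arccos(min(1.0, abs(plane.normal @ true_normal)))
    assert angle < 1e-6


def test_cut_off_board_fails_dimension_check(pattern):
    pose = RigidTransform(np.eye(3), [0.0, 0.0, 0.0])
    board = _board_cloud(pattern, pose, n=3000, seed=5)
    half = PointCloud(board.points[board.points[:, 0] > 0])  # half the width cut away
    with pytest.raises(DimensionMismatchError):
        locate_pattern_plane(half, pattern, rng=0)


# ---------------------------------------------------------------------------
# PCA initial pose
# ---------------------------------------------------------------------------


def test_axis_aligned_board_pose(pattern):
    pose = RigidTransform(
        np.column_stack([[1, 0, 0], [0, 0, 1], [0, -1, 0]]).astype(float), [0.0, 2.0, 1.0]
    )  # board normal -y, long axis +z, sensor at origin
    board = _board_cloud(pattern, pose, n=6000, seed=6)
    T = initial_pose_pca(board, sensor_origin=(0, 0, 0), up_vector=(0, 0, 1))
    np.testing.assert_allclose(T.t, [0.0, 2.0, 1.0], atol=0.01)
    assert rotation_between(T, pose) < 2.0


def test_rotated_board_recovered_within_2deg(pattern):
    R0 = Rotation.from_rotvec([0.15, 0.1, 0.2]).as_matrix()
    base = np.column_stack([[0, -1, 0], [0, 0, 1], [-1, 0, 0]]).astype(float)
    pose = RigidTransform(R0 @ base, [1.5, 0.3, 0.1])
    board = _board_cloud(pattern, pose, n=8000, noise=0.001, seed=7)
    T = initial_pose_pca(board)
    assert rotation_between(T, pose) < 2.0
    np.testing.assert_allclose(T.t, pose.t, atol=0.01)


def test_pca_eigenvalues_match_dense_oracle():
    rng = np.random.default_rng(8)
    pts = rng.normal(size=(800, 3)) * [2.0, 1.0, 0.05]
    cloud = PointCloud(pts)
    T = initial_pose_pca(cloud, voxel=0.0)
    cov = np.cov((pts - pts.mean(axis=0)).T)
    evals, evecs = np.linalg.eigh(cov)
    # long axis aligns with the largest-eigenvalue vector, normal with smallest
    assert abs(T.R[:, 1] @ evecs[:, 2]) > 0.999
    assert abs(T.R[:, 2] @ evecs[:, 0]) > 0.999


def test_collinear_points_degenerate():
    pts = np.outer(np.linspace(0, 1, 100), [1.0, 2.0, 3.0])
    with pytest.raises(DegenerateGeometryError):
        initial_pose_pca(PointCloud(pts), voxel=0.0)


# ---------------------------------------------------------------------------
# model sampling
# ---------------------------------------------------------------------------


def test_model_grid_count_planarity_and_extent(pattern):
    model = sample_pattern_model(pattern, resolution=0.005)
    assert len(model) == 101 * 121 == 12221
    assert np.all(model.points[:, 2] == 0.0)
    ext = model.points.max(axis=0) - model.points.min(axis=0)
    np.testing.assert_allclose(ext[:2], [pattern.board_width, pattern.board_height], atol=1e-12)


# ---------------------------------------------------------------------------
# ICP
# ---------------------------------------------------------------------------


def test_icp_recovers_known_displacement(pattern):
    # data is the displaced model itself; the guess is inside capture range
    model = sample_pattern_model(pattern, resolution=0.005)
    true = RigidTransform(
        Rotation.from_rotvec([0.03, -0.02, 0.05]).as_matrix(), [1.5, 0.2, -0.1]
    )
    data = PointCloud(true.apply(model.points))
    guess = RigidTransform(
        Rotation.from_rotvec([0.027, -0.018, 0.047]).as_matrix(), [1.502, 0.198, -0.101]
    )
    res = refine_pose_icp(model, data, guess, max_iter=80)
    assert rotation_between(res.T_final, true) < 0.1
    assert np.linalg.norm(res.T_final.t - true.t) < 0.001


def test_icp_identity_when_already_aligned(pattern):
    model = sample_pattern_model(pattern, resolution=0.01)
    res = refine_pose_icp(model, model, RigidTransform.identity())
    assert res.T_corr.is_identity(atol=1e-9)


def test_icp_rms_distance_non_increasing(pattern):
    model = sample_pattern_model(pattern, resolution=0.01)
    true = RigidTransform(Rotation.from_rotvec([0.0, 0.0, 0.08]).as_matrix(), [0.02, 0.01, 0.0])
    data = PointCloud(true.apply(_board_cloud(pattern, n=15000, seed=21).points))
    res = refine_pose_icp(model, data, RigidTransform.identity(), max_iter=40)
    d = np.array(res.rms_distances)
    assert np.all(np.diff(d) <= 1e-12)


def test_composition_convention_initial_then_corr(pattern):
    """T_final applied once equals T_initial applied after T_corr."""
    model = sample_pattern_model(pattern, resolution=0.01)
    true = RigidTransform(Rotation.from_rotvec([0.05, 0.02, -0.04]).as_matrix(), [1.2, 0.1, 0.3])
    data = PointCloud(true.apply(model.points))
    init = RigidTransform(Rotation.from_rotvec([0.04, 0.01, -0.02]).as_matrix(), [1.21, 0.08, 0.29])
    res = refine_pose_icp(model, data, init)
    via_two = init.apply(res.T_corr.apply(model.points))
    via_one = res.T_final.apply(model.points)
    np.testing.assert_allclose(via_two, via_one, atol=1e-9)


# ---------------------------------------------------------------------------
# bulb positions
# ---------------------------------------------------------------------------


def test_bulb_positions_identity_translation_and_spacing(pattern):
    grid = pattern_grid(pattern)
    np.testing.assert_allclose(bulb_positions(RigidTransform.identity(), pattern), grid)
    shifted = bulb_positions(RigidTransform(np.eye(3), [1.0, 0.0, 0.0]), pattern)
    np.testing.assert_allclose(shifted, grid + [1.0, 0.0, 0.0])
    T = RigidTransform(Rotation.from_rotvec([0.4, -0.2, 0.9]).as_matrix(), [2.0, -1.0, 0.5])
    moved = bulb_positions(T, pattern)
    for r in range(pattern.rows):
        row = moved[r * pattern.cols : (r + 1) * pattern.cols]
        gaps = np.linalg.norm(np.diff(row, axis=0), axis=1)
        np.testing.assert_allclose(gaps, pattern.spacing, atol=1e-12)


# ---------------------------------------------------------------------------
# extrinsic solve
# ---------------------------------------------------------------------------


def _pairs_from_pose(T, pts, cam, noise=0.0, rng=None):
    px = cam.project(T.apply(pts))
    if noise:
        px = px + rng.normal(0, noise, px.shape)
    return [FeaturePair(tuple(p), tuple(L)) for p, L in zip(px, pts)]


def test_exact_pairs_recover_pose(pattern):
    true = RigidTransform(
        Rotation.from_rotvec([0.1, -1.5, 0.2]).as_matrix(), [0.3, 0.25, 0.1]
    )
    bulbs = RigidTransform(
        Rotation.from_rotvec([0.0, 1.45, 0.0]).as_matrix(), [1.4, 0.0, 0.0]
    ).apply(pattern_grid(pattern))
    pairs = _pairs_from_pose(true, bulbs, CAM)
    T = solve_extrinsics(pairs, CAM)
    assert rotation_between(T, true) < 0.05
    assert np.linalg.norm(T.t - true.t) < 0.001


def test_noisy_pairs_translation_error_bounded():
    rng = np.random.default_rng(12)
    true = RigidTransform(Rotation.from_rotvec([0.05, -1.5, 0.1]).as_matrix(), [0.1, 0.2, 0.05])
    errors = []
    for _ in range(40):
        pts = RigidTransform(np.eye(3), [1.0, 0.0, 0.0]).apply(
            rng.uniform([-0.3, -0.3, -0.3], [0.3, 0.3, 0.3], size=(30, 3))
        )
        pairs = _pairs_from_pose(true, pts, CAM, noise=0.5, rng=rng)
        T = solve_extrinsics(pairs, CAM)
        errors.append(np.linalg.norm(T.t - true.t))
    assert np.median(errors) < 0.010  # < 10 mm at ~1 m range


def test_too_few_or_collinear_pairs_rejected():
    true = RigidTransform(Rotation.from_rotvec([0.0, -1.5, 0.0]).as_matrix(), [0.0, 0.0, 0.0])
    pts3 = np.array([[1.0, 0, 0], [1.0, 0.1, 0], [1.0, 0, 0.1]])
    with pytest.raises(InsufficientDataError):
        solve_extrinsics(_pairs_from_pose(true, pts3, CAM), CAM)
    line = np.column_stack([np.full(8, 1.0), np.linspace(-0.2, 0.2, 8), np.zeros(8)])
    with pytest.raises(DegenerateGeometryError):
        solve_extrinsics(_pairs_from_pose(true, line, CAM), CAM)


# ---------------------------------------------------------------------------
# cross-scan RMSE
# ---------------------------------------------------------------------------


def test_eq_style_rmse_matches_explicit_summation():
    T = RigidTransform(Rotation.from_rotvec([0.0, -1.5, 0.0]).as_matrix(), [0.0, 0.0, 0.0])
    rng = np.random.default_rng(13)
    scans = []
    for _ in range(2):
        pts = RigidTransform(np.eye(3), [1.2, 0, 0]).apply(rng.uniform(-0.2, 0.2, (4, 3)))
        px = CAM.project(T.apply(pts)) + rng.normal(0, 2.0, (4, 2))
        scans.append([FeaturePair(tuple(p), tuple(L)) for p, L in zip(px, pts)])
    # explicit double summation over N scans and M points
    total = 0.0
    for scan in scans:
        for fp in scan:
            proj = CAM.project(T.apply(np.array(fp.point))[None, :])[0]
            total += np.sum((proj - np.array(fp.pixel)) ** 2)
    expected = np.sqrt(total / (2 * 4))
    assert reprojection_rmse(T, scans, CAM) == pytest.approx(expected, abs=1e-12)


def test_perfect_candidate_scores_zero_and_single_candidate_selected(pattern):
    true = RigidTransform(Rotation.from_rotvec([0.0, -1.5, 0.0]).as_matrix(), [0.0, 0.1, 0.0])
    bulbs = RigidTransform(np.eye(3), [1.3, 0.0, 0.0]).apply(pattern_grid(pattern))
    scans = [_pairs_from_pose(true, bulbs, CAM)]
    sol = cross_scan_rmse([true], scans, CAM)
    assert sol.rmse == pytest.approx(0.0, abs=1e-9)
    assert sol.selected and sol.transform is not None
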