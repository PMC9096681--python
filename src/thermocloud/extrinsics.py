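"""LiDAR <-> thermal-camera extrinsic calibration.

The bulb board is located in the assembled 3D cloud (box crop -> RANSAC
plane -> dimension check), its pose estimated by PCA on a voxel-downsampled
copy and refined by registering a synthetically sampled board model with
ICP (``T_final = T_initial o T_corr``).  The 30 bulb grid positions mapped
through ``T_final`` give 3D features in the LiDAR frame; paired with the
sorted blob pixels they feed a perspective-n-point solve of the
camera-from-LiDAR rotation and translation.  With several board placements
each scan yields a candidate parameter set; every candidate (and their
element-wise mean) is scored by the cross-scan reprojection RMSE and the
minimum wins.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import List, Optional, Sequence, Tuple

import numpy as np
from scipy.optimize import least_squares
from scipy.spatial import cKDTree
from scipy.spatial.transform import Rotation

from .geometry import RigidTransform
from .intrinsics import (
    CameraIntrinsics,
    InsufficientDataError,
    PatternSpec,
    pattern_grid,
)
from .io import PointCloud

__all__ = [
    "FeaturePair",
    "PlaneModel",
    "ExtrinsicSolution",
    "PlaneNotFoundError",
    "DimensionMismatchError",
    "DegenerateGeometryError",
    "calibrate_from_scans",
    "crop_box",
    "locate_pattern_plane",
    "initial_pose_pca",
    "sample_pattern_model",
    "refine_pose_icp",
    "bulb_positions",
    "solve_extrinsics",
    "cross_scan_rmse",
]


class PlaneNotFoundError(RuntimeError):
    """RANSAC found no plane with enough inliers."""


class DimensionMismatchError(RuntimeError):
    """The extracted plane does not match the board dimensions."""

    def __init__(self, msg: str, extents: Tuple[float, float]):
        super().__init__(msg)
        self.extents = extents


class DegenerateGeometryError(ValueError):
    """Feature geometry insufficient for a pose solve (e.g. collinear)."""


@dataclass(frozen=True)
class FeaturePair:
    """One 2D blob centre with its corresponding 3D bulb position."""

    pixel: Tuple[float, float]
    point: Tuple[float, float, float]


@dataclass(frozen=True)
class PlaneModel:
    """Plane n . p = d with unit normal."""

    normal: np.ndarray
    d: float

    def distance(self, points: np.ndarray) -> np.ndarray:
        return np.abs(np.asarray(points) @ self.normal - self.d)


@dataclass
class ExtrinsicSolution:
    """Outcome of cross-scan candidate evaluation.

    ``candidate_rmse[i]`` is the Eq-style cross-scan reprojection RMSE of
    candidate ``i``; ``mean_rmse`` scores the element-wise mean of all
    candidate parameters.  ``transform`` is the selected (minimum-RMSE)
    solution.
    """

    transform: RigidTransform
    candidate_rmse: np.ndarray
    mean_rmse: float
    mean_transform: RigidTransform
    selected_index: int  # -1 when the mean candidate wins
    per_scan_rmse: np.ndarray = field(default_factory=lambda: np.zeros(0))
    selected: bool = True

    @property
    def rmse(self) -> float:
        if self.selected_index < 0:
            return float(self.mean_rmse)
        return float(self.candidate_rmse[self.selected_index])


# ---------------------------------------------------------------------------
# board localisation
# ---------------------------------------------------------------------------


def crop_box(cloud: PointCloud, bounds) -> PointCloud:
    """Keep points strictly inside an axis-aligned box ((3,) mins, (3,) maxs)."""
    lo, hi = (np.asarray(b, dtype=float).reshape(3) for b in bounds)
    if np.any(lo >= hi):
        raise ValueError("box bounds require min < max on every axis")
    inside = np.all((cloud.points > lo) & (cloud.points < hi), axis=1)
    return cloud.select(inside)


def fit_plane(points: np.ndarray) -> PlaneModel:
    """Total-least-squares plane through points (SVD of the centred cloud)."""
    pts = np.asarray(points, dtype=float)
    centroid = pts.mean(axis=0)
    _, _, Vt = np.linalg.svd(pts - centroid, full_matrices=False)
    normal = Vt[-1]
    return PlaneModel(normal=normal, d=float(normal @ centroid))


def locate_pattern_plane(
    cloud: PointCloud,
    pattern: PatternSpec,
    ransac_threshold: float = 0.010,
    dim_tolerance: float = 0.10,
    iterations: int = 1000,
    min_inliers: int = 500,
    rng=None,
) -> Tuple[PointCloud, PlaneModel]:
    """Extract the dominant plane by RANSAC and verify it is the board.

    The input is assumed pre-cropped so the largest plane IS the
    calibration pattern.  The inlier set's in-plane oriented extents must
    match ``board_width x board_height`` within ``dim_tolerance``
    (fractional), otherwise the scan is rejected — this catches boards cut
    off at the edge of the scan area.
    """
    rng = np.random.default_rng(rng)
    pts = cloud.points
    n = len(pts)
    if n < max(3, min_inliers):
        raise PlaneNotFoundError(f"only {n} points available")
    best_count, best_inliers = 0, None
    for _ in range(iterations):
        sample = pts[rng.choice(n, size=3, replace=False)]
        normal = np.cross(sample[1] - sample[0], sample[2] - sample[0])
        norm = np.linalg.norm(normal)
        if norm < 1e-12:
            continue
        normal = normal / norm
        dist = np.abs((pts - sample[0]) @ normal)
        mask = dist <= ransac_threshold
        count = int(mask.sum())
        if count > best_count:
            best_count, best_inliers = count, mask
    if best_inliers is None or best_count < min_inliers:
        raise PlaneNotFoundError(
            f"no plane with >= {min_inliers} inliers (best {best_count})"
        )
    # refine on the consensus set, then re-select inliers once
    plane = fit_plane(pts[best_inliers])
    mask = plane.distance(pts) <= ransac_threshold
    plane = fit_plane(pts[mask])
    inlier_cloud = cloud.select(mask)

    # oriented in-plane extents via 2D PCA
    p = inlier_cloud.points - inlier_cloud.points.mean(axis=0)
    basis = _plane_basis(plane.normal)
    uv = p @ basis.T
    _, _, Vt = np.linalg.svd(uv - uv.mean(axis=0), full_matrices=False)
    uv_r = uv @ Vt.T
    extents = uv_r.max(axis=0) - uv_r.min(axis=0)
    want = sorted((pattern.board_width, pattern.board_height))
    got = sorted(extents.tolist())
    for g, w in zip(got, want):
        if abs(g - w) > dim_tolerance * w:
            raise DimensionMismatchError(
                f"plane extents {got[0]:.3f} x {got[1]:.3f} m do not match "
                f"board {want[0]:.3f} x {want[1]:.3f} m",
                extents=(float(got[0]), float(got[1])),
            )
    return inlier_cloud, plane


def _plane_basis(normal: np.ndarray) -> np.ndarray:
    """Two orthonormal in-plane directions (2, 3) for a unit normal."""
    a = np.array([1.0, 0.0, 0.0])
    if abs(normal @ a) > 0.9:
        a = np.array([0.0, 1.0, 0.0])
    u = np.cross(normal, a)
    u /= np.linalg.norm(u)
    v = np.cross(normal, u)
    return np.stack([u, v])


def voxel_downsample(cloud: PointCloud, voxel: float) -> PointCloud:
    """Average points per occupied voxel (attributes averaged alongside)."""
    if voxel <= 0:
        raise ValueError("voxel size must be positive")
    keys = np.floor(cloud.points / voxel).astype(np.int64)
    _, inverse, counts = np.unique(keys, axis=0, return_inverse=True, return_counts=True)

    def pool(arr):
        out = np.zeros((len(counts),) + arr.shape[1:])
        np.add.at(out, inverse, arr)
        return out / counts.reshape(-1, *([1] * (arr.ndim - 1)))

    return PointCloud(
        pool(cloud.points),
        None if cloud.reflectance is None else pool(cloud.reflectance[:, None])[:, 0],
        None if cloud.temperature is None else pool(cloud.temperature[:, None])[:, 0],
        cloud.frame_label,
    )


def initial_pose_pca(
    plane_points: PointCloud,
    voxel: float = 0.010,
    sensor_origin=(0.0, 0.0, 0.0),
    up_vector=(0.0, 0.0, 1.0),
) -> RigidTransform:
    """Initial board pose from PCA of the voxel-downsampled plane points.

    Eigenvectors of the centred covariance give the board axes: the largest
    eigenvalue is the board's long axis (its height), the smallest its
    normal; the centroid is the origin.  Signs follow a fixed convention the
    optimiser cannot recover on its own: the normal faces the sensor origin
    and the long axis has positive dot with ``up_vector``; the short axis
    completes a right-handed frame.
    """
    down = voxel_downsample(plane_points, voxel) if voxel else plane_points
    pts = down.points
    centroid = pts.mean(axis=0)
    cov = np.cov((pts - centroid).T)
    evals, evecs = np.linalg.eigh(cov)  # ascending
    if evals[1] < 1e-12 * max(evals[2], 1e-300):
        raise DegenerateGeometryError("points are collinear; no board frame")
    normal = evecs[:, 0]
    long_axis = evecs[:, 2]
    if normal @ (np.asarray(sensor_origin, dtype=float) - centroid) < 0:
        normal = -normal
    if long_axis @ np.asarray(up_vector, dtype=float) < 0:
        long_axis = -long_axis
    short_axis = np.cross(long_axis, normal)
    R = np.column_stack([short_axis, long_axis, normal])
    return RigidTransform(R, centroid)


def sample_pattern_model(pattern: PatternSpec, resolution: float = 0.005) -> PointCloud:
    """Uniform board-frame grid over the board rectangle (Z = 0)."""
    if resolution <= 0:
        raise ValueError("resolution must be positive")
    nx = int(round(pattern.board_width / resolution)) + 1
    ny = int(round(pattern.board_height / resolution)) + 1
    xs = np.linspace(-pattern.board_width / 2.0, pattern.board_width / 2.0, nx)
    ys = np.linspace(-pattern.board_height / 2.0, pattern.board_height / 2.0, ny)
    X, Y = np.meshgrid(xs, ys)
    pts = np.column_stack([X.ravel(), Y.ravel(), np.zeros(X.size)])
    return PointCloud(pts, frame_label="pattern-model")


# ---------------------------------------------------------------------------
# ICP
# ---------------------------------------------------------------------------


def _umeyama_rigid(src: np.ndarray, dst: np.ndarray) -> RigidTransform:
    """Least-squares rigid transform aligning src onto dst (no scale)."""
    mu_s, mu_d = src.mean(axis=0), dst.mean(axis=0)
    H = (src - mu_s).T @ (dst - mu_d)
    U, _, Vt = np.linalg.svd(H)
    S = np.eye(3)
    if np.linalg.det(U @ Vt) < 0:
        S[2, 2] = -1.0
    R = Vt.T @ S @ U.T
    return RigidTransform(R, mu_d - R @ mu_s)


@dataclass
class ICPResult:
    T_corr: RigidTransform
    T_final: RigidTransform
    mean_distances: List[float]
    rms_distances: List[float]
    converged: bool


def refine_pose_icp(
    model: PointCloud,
    data: PointCloud,
    T_initial: RigidTransform,
    max_iter: int = 50,
    tol: float = 1e-7,
    max_correspondence: Optional[float] = None,
) -> ICPResult:
    """Point-to-point ICP of the board model onto the measured plane points.

    The model (board frame) is first placed by ``T_initial``; each
    iteration matches every model point to its nearest data point and
    applies the closed-form rigid correction; with ``max_correspondence``
    set, pairs farther apart are dropped from the update (trimmed ICP for
    partially overlapping clouds).  The accumulated pose
    satisfies ``T_final = T_initial o T_corr`` with ``T_corr`` expressed in
    the board frame, so applying ``T_initial`` after ``T_corr`` to the
    model equals applying ``T_final`` once.  Non-convergence returns the
    last iterate flagged, never raises.
    """
    tree = cKDTree(data.points)
    T_cur = T_initial
    mean_distances: List[float] = []
    rms_distances: List[float] = []
    converged = False
    prev = np.inf
    for _ in range(max_iter):
        moved = T_cur.apply(model.points)
        dists, idx = tree.query(moved)
        if max_correspondence is not None:
            keep = dists <= max_correspondence
            if keep.sum() < 3:
                break
            moved_k, idx_k, dists_k = moved[keep], idx[keep], dists[keep]
        else:
            moved_k, idx_k, dists_k = moved, idx, dists
        mean_distances.append(float(np.mean(dists_k)))
        rms_d = float(np.sqrt(np.mean(dists_k**2)))
        rms_distances.append(rms_d)
        delta = _umeyama_rigid(moved_k, data.points[idx_k])
        T_cur = delta @ T_cur
        if abs(prev - rms_d) < tol:
            converged = True
            break
        prev = rms_d
    T_corr = T_initial.inverse() @ T_cur
    return ICPResult(
        T_corr=T_corr,
        T_final=T_cur,
        mean_distances=mean_distances,
        rms_distances=rms_distances,
        converged=converged,
    )


def bulb_positions(T_final: RigidTransform, pattern: PatternSpec) -> np.ndarray:
    """The m bulb grid points mapped into the LiDAR frame, canonical order."""
    return T_final.apply(pattern_grid(pattern))


# ---------------------------------------------------------------------------
# pose solve (PnP) and candidate selection
# ---------------------------------------------------------------------------


def _reprojection_residuals(x, pts, obs, intrinsics):
    T = RigidTransform(Rotation.from_rotvec(x[:3]).as_matrix(), x[3:6])
    proj = intrinsics.project(T.apply(pts))
    return (proj - obs).ravel()


def _init_pose_planar(pts: np.ndarray, obs_norm: np.ndarray) -> RigidTransform:
    """Pose from a plane homography on undistorted normalised observations."""
    from .intrinsics import _dlt_homography, _pose_from_homography

    centroid = pts.mean(axis=0)
    _, _, Vt = np.linalg.svd(pts - centroid, full_matrices=False)
    # board-plane frame: rows of Vt; third axis is the plane normal
    basis = Vt
    uv = (pts - centroid) @ basis.T
    H = _dlt_homography(uv[:, :2], obs_norm)
    T_cam_from_plane = _pose_from_homography(H, np.eye(3))
    R_plane = np.column_stack([basis[0], basis[1], np.cross(basis[0], basis[1])])
    # plane frame: p_plane = R_plane^T (p - centroid)
    T_plane_from_lidar = RigidTransform(R_plane.T, -(R_plane.T @ centroid))
    return T_cam_from_plane @ T_plane_from_lidar


def _init_pose_dlt(pts: np.ndarray, obs_norm: np.ndarray) -> RigidTransform:
    """11-parameter DLT for non-coplanar points on normalised observations."""
    n = len(pts)
    M = np.zeros((2 * n, 12))
    M[0::2, 0:3] = pts
    M[0::2, 3] = 1.0
    M[0::2, 8:11] = -pts * obs_norm[:, :1]
    M[0::2, 11] = -obs_norm[:, 0]
    M[1::2, 4:7] = pts
    M[1::2, 7] = 1.0
    M[1::2, 8:11] = -pts * obs_norm[:, 1:2]
    M[1::2, 11] = -obs_norm[:, 1]
    _, _, Vt = np.linalg.svd(M)
    P = Vt[-1].reshape(3, 4)
    # scale/sign so that R is orthonormal with points in front
    scale = np.linalg.norm(P[2, :3])
    P = P / scale
    if np.mean(pts @ P[2, :3] + P[2, 3]) < 0:
        P = -P
    U, _, Vt3 = np.linalg.svd(P[:, :3])
    R = U @ Vt3
    if np.linalg.det(R) < 0:
        R = U @ np.diag([1.0, 1.0, -1.0]) @ Vt3
    return RigidTransform(R, P[:, 3])


def solve_extrinsics(
    pairs: Sequence[FeaturePair],
    intrinsics: CameraIntrinsics,
) -> RigidTransform:
    """Camera-from-LiDAR pose from >= 6 pixel/3D feature pairs.

    Pixels are undistorted to normalised coordinates; an algebraic
    initial pose (plane homography for the coplanar board, DLT otherwise)
    is refined by minimising the full distorted-model reprojection error.
    """
    if len(pairs) < 6:
        raise InsufficientDataError(f"extrinsic solve needs >= 6 pairs, got {len(pairs)}")
    pts = np.array([p.point for p in pairs], dtype=float)
    obs = np.array([p.pixel for p in pairs], dtype=float)
    centered = pts - pts.mean(axis=0)
    svals = np.linalg.svd(centered, compute_uv=False)
    if svals[1] < 1e-9 * max(svals[0], 1e-300):
        raise DegenerateGeometryError("feature points are collinear")
    K = intrinsics.matrix
    obs_norm = intrinsics.undistort(
        np.column_stack([(obs[:, 0] - intrinsics.cx) / intrinsics.fx,
                         (obs[:, 1] - intrinsics.cy) / intrinsics.fy])
    )
    coplanar = svals[2] < 1e-6 * svals[0]
    T0 = _init_pose_planar(pts, obs_norm) if coplanar else _init_pose_dlt(pts, obs_norm)
    x0 = np.concatenate([T0.rotvec(), T0.t])
    sol = least_squares(
        _reprojection_residuals, x0, args=(pts, obs, intrinsics), method="lm"
    )
    return RigidTransform(Rotation.from_rotvec(sol.x[:3]).as_matrix(), sol.x[3:6])


def reprojection_rmse(
    transform: RigidTransform,
    scans: Sequence[Sequence[FeaturePair]],
    intrinsics: CameraIntrinsics,
) -> float:
    """Cross-scan RMSE: sqrt( sum_i sum_j ||m'_ij - m_ij||^2 / (N M) ).

    N is the number of valid scans and M the features per scan; ``m'`` is
    the reprojection of the 3D feature through ``transform`` and the
    camera model, ``m`` the measured pixel.
    """
    total, count = 0.0, 0
    for scan in scans:
        pts = np.array([p.point for p in scan], dtype=float)
        obs = np.array([p.pixel for p in scan], dtype=float)
        proj = intrinsics.project(transform.apply(pts))
        total += float(np.sum((proj - obs) ** 2))
        count += len(scan)
    return float(np.sqrt(total / count))


def mean_transform(transforms: Sequence[RigidTransform]) -> RigidTransform:
    """Element-wise mean of rotation matrices (re-projected onto SO(3)) and t."""
    Rm = np.mean([T.R for T in transforms], axis=0)
    U, _, Vt = np.linalg.svd(Rm)
    R = U @ Vt
    if np.linalg.det(R) < 0:
        R = U @ np.diag([1.0, 1.0, -1.0]) @ Vt
    return RigidTransform(R, np.mean([T.t for T in transforms], axis=0))


def calibrate_from_scans(
    scans,
    camera: CameraIntrinsics,
    pattern: PatternSpec,
    crop_bounds=((0.3, -0.1, -0.65), (2.5, 0.9, 0.9)),
    ransac_seed: int = 0,
    model_resolution: float = 0.005,
) -> Tuple[ExtrinsicSolution, List[dict]]:
    """Full extrinsic calibration from (cloud, image) scan pairs.

    Per scan: crop -> RANSAC plane + dimension check -> PCA pose -> ICP
    against the sampled board model -> bulb positions -> staged blob
    detection -> pose solve.  Scans failing any stage are recorded as
    invalid, mirroring field practice where badly placed boards are
    discarded.  All surviving candidates (and their element-wise mean) are
    scored by cross-scan RMSE and the minimum selected.
    """
    from .intrinsics import staged_blob_detection

    model = sample_pattern_model(pattern, model_resolution)
    candidates, pairs_per_scan, log = [], [], []
    for i, (cloud, image) in enumerate(scans):
        entry = {"scan": i, "valid": False}
        log.append(entry)
        try:
            cropped = crop_box(cloud, crop_bounds)
            inliers, _ = locate_pattern_plane(cropped, pattern, rng=ransac_seed)
            icp = refine_pose_icp(model, inliers, initial_pose_pca(inliers))
            bulbs = bulb_positions(icp.T_final, pattern)
            view = staged_blob_detection(image, pattern)
            if view.status != "ok":
                entry["error"] = "blob detection failed"
                continue
            pairs = [FeaturePair(tuple(px), tuple(L)) for px, L in zip(view.features, bulbs)]
            candidates.append(solve_extrinsics(pairs, camera))
            pairs_per_scan.append(pairs)
            entry["valid"] = True
        except (PlaneNotFoundError, DimensionMismatchError, DegenerateGeometryError) as exc:
            entry["error"] = str(exc)
    if not candidates:
        raise PlaneNotFoundError("no scan could be processed")
    solution = cross_scan_rmse(candidates, pairs_per_scan, camera)
    return solution, log


def cross_scan_rmse(
    candidates: Sequence[RigidTransform],
    scans: Sequence[Sequence[FeaturePair]],
    intrinsics: CameraIntrinsics,
) -> ExtrinsicSolution:
    """Score every candidate (and their element-wise mean) across all scans.

    Returns the minimum-RMSE solution marked selected; the per-candidate
    table and the mean candidate's score are kept for reporting.
    """
    if not candidates or not scans:
        raise ValueError("need at least one candidate and one scan")
    cand_rmse = np.array([reprojection_rmse(T, scans, intrinsics) for T in candidates])
    T_mean = mean_transform(candidates)
    rmse_mean = reprojection_rmse(T_mean, scans, intrinsics)
    best = int(np.argmin(cand_rmse))
    if rmse_mean < cand_rmse[best]:
        chosen, chosen_idx = T_mean, -1
    else:
        chosen, chosen_idx = candidates[best], best
    per_scan = np.array(
        [reprojection_rmse(chosen, [scan], intrinsics) for scan in scans]
    )
    return ExtrinsicSolution(
        transform=chosen,
        candidate_rmse=cand_rmse,
        mean_rmse=float(rmse_mean),
        mean_transform=T_mean,
        selected_index=chosen_idx,
        per_scan_rmse=per_scan,
    )
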