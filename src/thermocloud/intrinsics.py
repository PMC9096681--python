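"""Thermal-camera intrinsic calibration from an actively heated blob board.

Chessboard corners are invisible to a thermal camera, so the calibration
target is a board of hot 12 V lightbulbs on a regular grid (default
5 rows x 6 cols, 100 mm pitch).  The pipeline:

1. scale the radiometric image to a temperature range and quantise to 8 bit;
2. detect bright blobs with a multi-threshold connected-component sweep
   (three sensitivity presets of increasing permissiveness);
3. if not exactly ``m = rows*cols`` blobs are found, raise the lower bound
   of the temperature range by 5 °C and retry — after 4 ranges x 3 presets
   the image is discarded;
4. sort the blob centres into canonical row-major grid order;
5. jointly estimate the camera matrix ``A = [[fx,0,cx],[0,fy,cy],[0,0,1]]``,
   the distortion ``D = (k1,k2,k3,p1,p2)`` and per-view board poses by
   minimising the total squared reprojection error.

The distortion model is radial+tangential:
``x_d = x(1 + k1 r^2 + k2 r^4 + k3 r^6) + 2 p1 x y + p2 (r^2 + 2 x^2)`` and
symmetrically for ``y_d``, with ``r^2 = x^2 + y^2`` on normalised image
coordinates.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import List, Optional, Sequence, Tuple

import numpy as np
from scipy.optimize import least_squares
from scipy.spatial.transform import Rotation
from skimage.measure import label, regionprops

from .geometry import RigidTransform
from .io import ThermalImage

__all__ = [
    "PatternSpec",
    "TemperatureRange",
    "SensitivityPreset",
    "Blob",
    "CalibrationView",
    "CameraIntrinsics",
    "IntrinsicsResult",
    "DEFAULT_PRESETS",
    "BehindCameraError",
    "OrderingError",
    "DegenerateViewsError",
    "InsufficientDataError",
    "scale_to_8bit",
    "detect_blobs",
    "staged_blob_detection",
    "sort_blobs_grid",
    "pattern_grid",
    "project_point",
    "calibrate_intrinsics",
]


class BehindCameraError(ValueError):
    """Projection requested for a point at or behind the camera plane."""


class OrderingError(ValueError):
    """Blob constellation could not be arranged into the expected grid."""


class DegenerateViewsError(ValueError):
    """View geometry does not constrain the intrinsics (e.g. identical poses)."""


class InsufficientDataError(ValueError):
    """Too few views or feature pairs for the requested estimation."""


# ---------------------------------------------------------------------------
# domain types
# ---------------------------------------------------------------------------


@dataclass(frozen=True)
class PatternSpec:
    """Geometry of the heated-bulb calibration board (metres)."""

    rows: int = 5
    cols: int = 6
    spacing: float = 0.100
    board_width: float = 0.500
    board_height: float = 0.600
    bulb_diameter: float = 0.004

    def __post_init__(self) -> None:
        if self.rows < 2 or self.cols < 2:
            raise ValueError("pattern needs at least a 2x2 grid")
        if self.spacing <= 0:
            raise ValueError("spacing must be positive")
        if (self.cols - 1) * self.spacing > self.board_width + 1e-12 or (
            self.rows - 1
        ) * self.spacing > self.board_height + 1e-12:
            raise ValueError("bulb grid does not fit inside the board")

    @property
    def m(self) -> int:
        """Expected feature count."""
        return self.rows * self.cols


@dataclass(frozen=True)
class TemperatureRange:
    low: float
    high: float

    def __post_init__(self) -> None:
        if not self.low < self.high:
            raise ValueError("temperature range requires low < high")


@dataclass(frozen=True)
class SensitivityPreset:
    """Blob-detector sensitivity: threshold sweep bounds and area gates.

    Preset 1 follows the published operating point for this camera/board
    combination; presets 2 and 3 are progressively more permissive package
    defaults (wider threshold sweep, looser area gate) and are fully
    configurable.
    """

    id: int
    minThreshold: int
    maxThreshold: int
    thresholdStep: int
    minArea: float
    maxArea: float

    def __post_init__(self) -> None:
        if not 0 <= self.minThreshold < self.maxThreshold <= 255:
            raise ValueError("need 0 <= minThreshold < maxThreshold <= 255")
        if self.thresholdStep < 1:
            raise ValueError("thresholdStep must be >= 1")
        if not 0 < self.minArea <= self.maxArea:
            raise ValueError("need 0 < minArea <= maxArea")


DEFAULT_PRESETS: Tuple[SensitivityPreset, ...] = (
    SensitivityPreset(1, 20, 220, 15, 160, 230),
    SensitivityPreset(2, 20, 220, 10, 80, 400),
    SensitivityPreset(3, 10, 240, 5, 30, 800),
)


@dataclass(frozen=True)
class Blob:
    """A detected bright region: sub-pixel centre, mean radius, area (px^2)."""

    center: Tuple[float, float]
    radius: float
    area: float


@dataclass
class CalibrationView:
    """One board image with its detection outcome.

    ``features`` holds the ``m`` blob centres in canonical grid order when
    ``status == "ok"``; ``pose`` is filled by :func:`calibrate_intrinsics`.
    """

    image: Optional[ThermalImage]
    features: Optional[np.ndarray] = None
    pose: Optional[RigidTransform] = None
    status: str = "ok"
    attempts: int = 0
    used_range: Optional[TemperatureRange] = None
    used_sensitivity: Optional[int] = None


@dataclass(frozen=True)
class CameraIntrinsics:
    """Pinhole camera matrix and radial/tangential distortion."""

    fx: float
    fy: float
    cx: float
    cy: float
    k1: float = 0.0
    k2: float = 0.0
    k3: float = 0.0
    p1: float = 0.0
    p2: float = 0.0

    def __post_init__(self) -> None:
        if self.fx <= 0 or self.fy <= 0:
            raise ValueError("focal lengths must be positive")

    @property
    def matrix(self) -> np.ndarray:
        return np.array(
            [[self.fx, 0.0, self.cx], [0.0, self.fy, self.cy], [0.0, 0.0, 1.0]]
        )

    @property
    def distortion(self) -> np.ndarray:
        return np.array([self.k1, self.k2, self.k3, self.p1, self.p2])

    # -- projection ---------------------------------------------------
    def distort(self, xy: np.ndarray) -> np.ndarray:
        """Apply the distortion model on normalised coordinates (N, 2)."""
        xy = np.asarray(xy, dtype=float)
        x, y = xy[..., 0], xy[..., 1]
        r2 = x * x + y * y
        radial = 1.0 + self.k1 * r2 + self.k2 * r2**2 + self.k3 * r2**3
        xd = x * radial + 2.0 * self.p1 * x * y + self.p2 * (r2 + 2.0 * x * x)
        yd = y * radial + self.p1 * (r2 + 2.0 * y * y) + 2.0 * self.p2 * x * y
        return np.stack([xd, yd], axis=-1)

    def undistort(self, xy_d: np.ndarray, iterations: int = 20) -> np.ndarray:
        """Invert :meth:`distort` by fixed-point iteration."""
        xy_d = np.asarray(xy_d, dtype=float)
        xy = xy_d.copy()
        for _ in range(iterations):
            delta = self.distort(xy) - xy
            xy = xy_d - delta
        return xy

    def project(self, points_cam: np.ndarray, allow_behind: bool = False):
        """Project camera-frame points (N, 3) to pixels (N, 2).

        With ``allow_behind`` a validity mask is returned alongside; points
        at or behind the camera plane get NaN pixels and ``False`` in the
        mask instead of raising.
        """
        pts = np.asarray(points_cam, dtype=float).reshape(-1, 3)
        z = pts[:, 2]
        ok = z > 0
        if not allow_behind and not np.all(ok):
            raise BehindCameraError("point with Z <= 0 cannot be projected")
        with np.errstate(divide="ignore", invalid="ignore"):
            norm = pts[:, :2] / z[:, None]
        dist = self.distort(norm)
        px = np.empty_like(dist)
        px[:, 0] = self.fx * dist[:, 0] + self.cx
        px[:, 1] = self.fy * dist[:, 1] + self.cy
        px[~ok] = np.nan
        if allow_behind:
            return px, ok
        return px


def project_point(intrinsics: CameraIntrinsics, point_cam) -> Tuple[float, float]:
    """Project a single camera-frame 3D point (metres) to pixel coordinates."""
    px = intrinsics.project(np.asarray(point_cam, dtype=float).reshape(1, 3))
    return float(px[0, 0]), float(px[0, 1])


# ---------------------------------------------------------------------------
# image scaling and blob detection
# ---------------------------------------------------------------------------


def scale_to_8bit(image: ThermalImage, trange: TemperatureRange) -> np.ndarray:
    """Map °C values into [0, 255] linearly over ``trange`` (clipped).

    Rounding is half-up so the quantisation is deterministic across
    platforms.  Monotone in the input temperature.
    """
    span = trange.high - trange.low
    scaled = np.clip((image.values - trange.low) / span, 0.0, 1.0)
    return np.floor(scaled * 255.0 + 0.5).astype(np.uint8)


def detect_blobs(
    image8: np.ndarray,
    preset: SensitivityPreset,
    merge_distance: float = 10.0,
) -> List[Blob]:
    """Bright-blob detection by a multi-threshold connected-component sweep.

    The 8-bit image is binarised at thresholds ``minThreshold`` to
    ``maxThreshold`` in ``thresholdStep`` increments; per slice, bright
    8-connected components with area inside ``[minArea, maxArea]`` are kept;
    component centres within ``merge_distance`` px across slices are grouped
    into one blob whose centre/radius are the group means.
    """
    image8 = np.asarray(image8)
    if image8.dtype != np.uint8:
        raise ValueError("detect_blobs expects an 8-bit grayscale image")
    groups: List[dict] = []  # {'centers': [...], 'radii': [...]}
    thresholds = np.arange(preset.minThreshold, preset.maxThreshold + 1, preset.thresholdStep)
    for tau in thresholds:
        labels = label(image8 >= tau, connectivity=2)
        for region in regionprops(labels):
            area = float(region.area)
            if not preset.minArea <= area <= preset.maxArea:
                continue
            cy, cx = region.centroid
            center = np.array([cx, cy])
            radius = float(np.sqrt(area / np.pi))
            best, best_d = None, merge_distance
            for g in groups:
                d = float(np.linalg.norm(g["mean"] - center))
                if d < best_d:
                    best, best_d = g, d
            if best is None:
                groups.append({"centers": [center], "radii": [radius], "mean": center})
            else:
                best["centers"].append(center)
                best["radii"].append(radius)
                best["mean"] = np.mean(best["centers"], axis=0)
    blobs = []
    for g in groups:
        c = np.mean(g["centers"], axis=0)
        r = float(np.mean(g["radii"]))
        blobs.append(Blob(center=(float(c[0]), float(c[1])), radius=r, area=float(np.pi * r * r)))
    return blobs


def staged_blob_detection(
    image: ThermalImage,
    pattern: PatternSpec,
    presets: Sequence[SensitivityPreset] = DEFAULT_PRESETS,
    n_ranges: int = 4,
    range_step: float = 5.0,
    merge_distance: float = 10.0,
) -> CalibrationView:
    """Staged detection of exactly ``m`` bulbs with escalating settings.

    The first temperature range is the image's own [min, max]; every time
    all three presets fail, the lower bound is raised by ``range_step`` °C
    (increasing bulb/board contrast) and detection retried.  After
    ``n_ranges`` ranges x ``len(presets)`` presets without exactly ``m``
    blobs in a valid grid arrangement, the view is discarded — a status,
    not an exception, so batch calibration can log failures.
    """
    m = pattern.m
    lo0 = float(image.values.min())
    hi = float(image.values.max())
    attempts = 0
    for ridx in range(n_ranges):
        lo = lo0 + ridx * range_step
        if lo >= hi:
            break
        trange = TemperatureRange(lo, hi)
        image8 = scale_to_8bit(image, trange)
        for preset in presets:
            attempts += 1
            blobs = detect_blobs(image8, preset, merge_distance=merge_distance)
            if len(blobs) != m:
                continue
            try:
                features = sort_blobs_grid(blobs, pattern)
            except OrderingError:
                continue
            return CalibrationView(
                image=image,
                features=features,
                status="ok",
                attempts=attempts,
                used_range=trange,
                used_sensitivity=preset.id,
            )
    return CalibrationView(image=image, status="discarded", attempts=attempts)


def sort_blobs_grid(blobs: Sequence[Blob], pattern: PatternSpec) -> np.ndarray:
    """Arrange ``m`` blob centres into canonical row-major order, top-left first.

    Centres are projected onto the two principal axes of the constellation
    (which align with the grid axes of a regular pattern under any in-plane
    rotation); the axis admitting a clean partition into ``rows`` groups of
    ``cols`` is the row axis.  Axis signs are fixed against the image axes
    (x rightward, y downward), which is unambiguous for in-plane rotations
    up to +-30 degrees.
    """
    if len(blobs) != pattern.m:
        raise ValueError(f"expected exactly {pattern.m} blobs, got {len(blobs)}")
    centers = np.array([b.center for b in blobs], dtype=float)
    centered = centers - centers.mean(axis=0)
    _, _, Vt = np.linalg.svd(centered, full_matrices=False)
    axes = Vt  # rows: principal directions in pixel coords

    def try_split(row_axis: np.ndarray, col_axis: np.ndarray):
        # orient: rows increase with image y, columns with image x
        if np.dot(row_axis, [0.0, 1.0]) < 0:
            row_axis = -row_axis
        if np.dot(col_axis, [1.0, 0.0]) < 0:
            col_axis = -col_axis
        v = centered @ row_axis
        u = centered @ col_axis
        order = np.argsort(v)
        gaps = np.diff(v[order])
        if len(gaps) < pattern.rows - 1:
            return None
        cut_idx = np.sort(np.argsort(gaps)[::-1][: pattern.rows - 1])
        groups = np.split(order, cut_idx + 1)
        if any(len(g) != pattern.cols for g in groups):
            return None
        # groups are in ascending v (top row first); sort within row by u
        idx = np.concatenate([g[np.argsort(u[g])] for g in groups])
        return centers[idx]

    # try the minor axis as row axis first (grid wider than tall for cols>rows)
    candidates = [(axes[1], axes[0]), (axes[0], axes[1])]
    for row_axis, col_axis in candidates:
        result = try_split(row_axis, col_axis)
        if result is not None:
            return result
    # strong perspective keystone defeats the axis partition; fall back to a
    # projective ordering fitted on the four extreme corners
    result = _sort_by_homography(centers, pattern)
    if result is not None:
        return result
    raise OrderingError("could not partition blobs into the expected grid")


def _sort_by_homography(centers: np.ndarray, pattern: PatternSpec):
    """Order grid blobs by snapping through a corner-fitted homography."""
    from itertools import combinations

    from scipy.spatial import ConvexHull, QhullError

    try:
        hull = ConvexHull(centers)
    except QhullError:
        return None
    hv = hull.vertices  # counterclockwise in (x, y-down) = clockwise on screen
    if len(hv) < 4:
        return None
    # the 4 grid corners are the hull quadrilateral of maximum area
    best_quad, best_area = None, -1.0
    for quad in combinations(range(len(hv)), 4):
        p = centers[hv[list(quad)]]
        area = 0.5 * abs(
            np.dot(p[:, 0], np.roll(p[:, 1], -1)) - np.dot(p[:, 1], np.roll(p[:, 0], -1))
        )
        if area > best_area:
            best_area, best_quad = area, hv[list(quad)]
    corners = centers[best_quad]
    r_max, c_max = pattern.rows - 1, pattern.cols - 1
    corner_cycles = [
        [(0, 0), (0, c_max), (r_max, c_max), (r_max, 0)],
        [(0, 0), (r_max, 0), (r_max, c_max), (0, c_max)],
    ]
    for start in range(4):
        rolled = np.roll(corners, -start, axis=0)
        for cycle in corner_cycles:
            target = np.array([(c, r) for r, c in cycle], dtype=float)
            H = _dlt_homography(rolled, target)
            mapped = np.column_stack([centers, np.ones(len(centers))]) @ H.T
            mapped = mapped[:, :2] / mapped[:, 2:3]
            snapped = np.round(mapped).astype(int)
            if np.any(np.abs(mapped - snapped) > 0.3):
                continue
            cols_ok = (snapped[:, 0] >= 0) & (snapped[:, 0] <= c_max)
            rows_ok = (snapped[:, 1] >= 0) & (snapped[:, 1] <= r_max)
            if not np.all(cols_ok & rows_ok):
                continue
            flat = snapped[:, 1] * pattern.cols + snapped[:, 0]
            if len(np.unique(flat)) != pattern.m:
                continue
            order = np.argsort(flat)
            ordered = centers[order]
            # orientation gate: columns increase with image x, rows with image y
            du = ordered[1] - ordered[0]
            dv = ordered[pattern.cols] - ordered[0]
            if du[0] > 0 and dv[1] > 0:
                return ordered
    return None


# ---------------------------------------------------------------------------
# pattern geometry
# ---------------------------------------------------------------------------


def pattern_grid(pattern: PatternSpec) -> np.ndarray:
    """Bulb positions in the board frame, canonical row-major order (m, 3).

    Board frame: origin at the grid centre, X along the board width
    (columns), Y along the board height (rows, up-positive), Z the board
    normal (toward the sensors).  Row 0 is the TOP row, so its Y is
    largest; within a row columns run left to right (X increasing).  Seen
    by a camera facing the board this reproduces image row-major order.
    """
    pts = []
    for r in range(pattern.rows):
        y = ((pattern.rows - 1) / 2.0 - r) * pattern.spacing
        for c in range(pattern.cols):
            x = (c - (pattern.cols - 1) / 2.0) * pattern.spacing
            pts.append((x, y, 0.0))
    return np.array(pts)


# ---------------------------------------------------------------------------
# calibration
# ---------------------------------------------------------------------------


def _dlt_homography(src: np.ndarray, dst: np.ndarray) -> np.ndarray:
    """Normalised DLT homography mapping src (N,2) -> dst (N,2)."""

    def normalise(p):
        mean = p.mean(axis=0)
        scale = np.sqrt(2.0) / max(np.mean(np.linalg.norm(p - mean, axis=1)), 1e-300)
        T = np.array([[scale, 0, -scale * mean[0]], [0, scale, -scale * mean[1]], [0, 0, 1]])
        q = (p - mean) * scale
        return q, T

    s, Ts = normalise(src)
    d, Td = normalise(dst)
    n = len(src)
    Amat = np.zeros((2 * n, 9))
    Amat[0::2, 0:2] = s
    Amat[0::2, 2] = 1.0
    Amat[0::2, 6:8] = -s * d[:, :1]
    Amat[0::2, 8] = -d[:, 0]
    Amat[1::2, 3:5] = s
    Amat[1::2, 5] = 1.0
    Amat[1::2, 6:8] = -s * d[:, 1:2]
    Amat[1::2, 8] = -d[:, 1]
    _, _, Vt = np.linalg.svd(Amat)
    H = Vt[-1].reshape(3, 3)
    H = np.linalg.inv(Td) @ H @ Ts
    return H / H[2, 2]


def _zhang_init(homographies: Sequence[np.ndarray]) -> Tuple[float, float, float, float]:
    """Closed-form camera matrix from plane homographies."""

    def v_ij(H, i, j):
        return np.array(
            [
                H[0, i] * H[0, j],
                H[0, i] * H[1, j] + H[1, i] * H[0, j],
                H[1, i] * H[1, j],
                H[2, i] * H[0, j] + H[0, i] * H[2, j],
                H[2, i] * H[1, j] + H[1, i] * H[2, j],
                H[2, i] * H[2, j],
            ]
        )

    V = []
    for H in homographies:
        V.append(v_ij(H, 0, 1))
        V.append(v_ij(H, 0, 0) - v_ij(H, 1, 1))
    V = np.array(V)
    _, s, Vt = np.linalg.svd(V)
    if s[-2] < 1e-9 * s[0]:
        raise DegenerateViewsError("board poses do not constrain the camera matrix")
    b = Vt[-1]
    B11, B12, B22, B13, B23, B33 = b
    denom = B11 * B22 - B12**2
    try:
        cy = (B12 * B13 - B11 * B23) / denom
        lam = B33 - (B13**2 + cy * (B12 * B13 - B11 * B23)) / B11
        fx = np.sqrt(lam / B11)
        fy = np.sqrt(lam * B11 / denom)
        gamma = -B12 * fx * fx * fy / lam
        cx = gamma * cy / fy - B13 * fx * fx / lam
    except (ZeroDivisionError, FloatingPointError):
        raise DegenerateViewsError("camera-matrix extraction failed") from None
    if not (np.isfinite(fx) and np.isfinite(fy) and fx > 0 and fy > 0):
        raise DegenerateViewsError(
            "degenerate view configuration (identical or coplanar-equivalent poses)"
        )
    return float(fx), float(fy), float(cx), float(cy)


def _pose_from_homography(H: np.ndarray, K: np.ndarray) -> RigidTransform:
    Kinv = np.linalg.inv(K)
    h1, h2, h3 = H[:, 0], H[:, 1], H[:, 2]
    lam = 1.0 / np.linalg.norm(Kinv @ h1)
    if (Kinv @ h3)[2] < 0:  # board must sit in front of the camera
        lam = -lam
    r1 = lam * (Kinv @ h1)
    r2 = lam * (Kinv @ h2)
    r3 = np.cross(r1, r2)
    R = np.column_stack([r1, r2, r3])
    U, _, Vt = np.linalg.svd(R)
    R = U @ Vt
    if np.linalg.det(R) < 0:
        R = U @ np.diag([1.0, 1.0, -1.0]) @ Vt
    t = lam * (Kinv @ h3)
    return RigidTransform(R, t)


@dataclass
class IntrinsicsResult:
    intrinsics: CameraIntrinsics
    poses: List[RigidTransform]
    per_view_rmse: np.ndarray
    rmse: float
    converged: bool = True

    views: List[CalibrationView] = field(default_factory=list)


def calibrate_intrinsics(
    views: Sequence[CalibrationView],
    pattern: PatternSpec,
    max_nfev: int = 200,
) -> IntrinsicsResult:
    """Estimate camera matrix, distortion and per-view board poses.

    Only views with ``status == "ok"`` participate; at least three with
    distinct board orientations are required.  Initialisation is the
    classic closed-form plane-homography solution (zero distortion),
    followed by a joint nonlinear refinement of
    ``(fx, fy, cx, cy, k1, k2, k3, p1, p2)`` and the 6-dof pose of every
    view against the total squared reprojection error.  RMSE is reported
    in pixels, per view and globally.
    """
    usable = [v for v in views if v.status == "ok"]
    if len(usable) < 3:
        raise InsufficientDataError("intrinsic calibration needs >= 3 usable views")
    grid = pattern_grid(pattern)
    for v in usable:
        if v.features is None or len(v.features) != pattern.m:
            raise ValueError("ok view without a full canonical feature set")

    homographies = [_dlt_homography(grid[:, :2], np.asarray(v.features)) for v in usable]
    fx, fy, cx, cy = _zhang_init(homographies)
    K = np.array([[fx, 0, cx], [0, fy, cy], [0, 0, 1.0]])
    poses0 = [_pose_from_homography(H, K) for H in homographies]

    n_views = len(usable)
    x0 = np.zeros(9 + 6 * n_views)
    x0[:4] = (fx, fy, cx, cy)
    for i, pose in enumerate(poses0):
        x0[9 + 6 * i : 12 + 6 * i] = pose.rotvec()
        x0[12 + 6 * i : 15 + 6 * i] = pose.t

    observed = np.concatenate([np.asarray(v.features) for v in usable])

    def unpack(x):
        intr = CameraIntrinsics(
            fx=x[0], fy=x[1], cx=x[2], cy=x[3],
            k1=x[4], k2=x[5], k3=x[6], p1=x[7], p2=x[8],
        )
        poses = [
            RigidTransform(
                Rotation.from_rotvec(x[9 + 6 * i : 12 + 6 * i]).as_matrix(),
                x[12 + 6 * i : 15 + 6 * i],
            )
            for i in range(n_views)
        ]
        return intr, poses

    def residuals(x):
        intr, poses = unpack(x)
        proj = np.concatenate([intr.project(p.apply(grid)) for p in poses])
        return (proj - observed).ravel()

    sol = least_squares(residuals, x0, method="trf", x_scale="jac", max_nfev=max_nfev)
    intr, poses = unpack(sol.x)
    res = sol.fun.reshape(-1, 2)
    per_view = np.array(
        [
            float(np.sqrt(np.mean(np.sum(res[i * pattern.m : (i + 1) * pattern.m] ** 2, axis=1))))
            for i in range(n_views)
        ]
    )
    rmse = float(np.sqrt(np.mean(np.sum(res**2, axis=1))))
    for v, p in zip(usable, poses):
        v.pose = p
    return IntrinsicsResult(
        intrinsics=intr,
        poses=poses,
        per_view_rmse=per_view,
        rmse=rmse,
        converged=bool(sol.success),
        views=list(usable),
    )
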