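"""Ground-truth scene generators for every pipeline stage.

Three scene families make the whole tool chain testable without hardware:

* the heated bulb board for intrinsic/extrinsic calibration (ray-cast
  moving line scanner + rendered thermal frame),
* the metal evaluation tree with coated sphere targets,
* a two-sided apple-tree row with trunks, leaf disks and spherical fruits.

Sensor defaults mirror the instruments the method was designed around: a
2D LiDAR with 0.1667° angular resolution over a 180° fan at 25 Hz on a
platform moving 20 mm s⁻¹, and a 640 x 480 radiometric camera mounted
0.2 m above the scanner.  Every generator is fully deterministic in its
seed and returns a :class:`SceneTruth` that labels each emitted point, so
tests can compare any derived quantity against the generating model.

The calibration-board and metal-frame clouds are produced by ray casting
against analytic primitives (plane/sphere/cylinder intersections).  The
orchard row is sampled directly on the organ surfaces at scanner-scale
density: the fruit-segmentation stage consumes already-fused thermal
clouds with organ labels, for which occlusion realism adds nothing while
multiplying the run time.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Callable, List, Optional, Sequence, Tuple, Union

import numpy as np
from skimage.draw import disk as draw_disk
from skimage.draw import polygon as draw_polygon

from .geometry import RigidTransform
from .intrinsics import CameraIntrinsics, CalibrationView, PatternSpec, pattern_grid
from .io import PointCloud, ThermalImage

__all__ = [
    "LidarSpec",
    "SensorNoise",
    "SceneTruth",
    "Rectangle",
    "Sphere",
    "Cylinder",
    "default_camera",
    "default_extrinsics",
    "default_board_pose",
    "raycast",
    "lidar_scan",
    "sample_board_placements",
    "simulate_calibration_scene",
    "simulate_metal_frame",
    "simulate_orchard_row",
    "synthetic_views",
]


# ---------------------------------------------------------------------------
# sensor models
# ---------------------------------------------------------------------------


@dataclass(frozen=True)
class LidarSpec:
    """Moving 2D line scanner: vertical fan in the x–z plane, travel +y."""

    angular_resolution_deg: float = 0.1667
    span_deg: float = 180.0
    scan_rate_hz: float = 25.0
    speed_m_s: float = 0.020
    max_range: float = 40.0
    angle_start_deg: float = -90.0  # fan covers the forward (+x) half plane

    @property
    def angles(self) -> np.ndarray:
        n = int(round(self.span_deg / self.angular_resolution_deg)) + 1
        return np.radians(self.angle_start_deg + self.angular_resolution_deg * np.arange(n))

    @property
    def profile_step(self) -> float:
        return self.speed_m_s / self.scan_rate_hz


@dataclass(frozen=True)
class SensorNoise:
    """Noise model: LiDAR range σ (m), pixel temperature σ (°C), and the
    jitter of rendered bulb centres in pixels (emulating sub-pixel feature
    localisation error)."""

    range_sigma: float = 0.005
    temp_sigma: float = 0.05
    blob_sigma_px: float = 0.0


@dataclass
class SceneTruth:
    """Everything the generator knows: per-point labels + model parameters."""

    labels: np.ndarray
    label_names: dict
    camera: Optional[CameraIntrinsics] = None
    extrinsics: Optional[RigidTransform] = None
    seed: Optional[int] = None
    info: dict = field(default_factory=dict)


def default_camera() -> CameraIntrinsics:
    """640x480 camera with an 80° diagonal field of view and mild distortion."""
    f = 400.0 / np.tan(np.radians(40.0))  # half-diagonal 400 px
    return CameraIntrinsics(fx=f, fy=f, cx=320.0, cy=240.0, k1=-0.05)


def default_extrinsics(travel: float = 0.8, camera_height: float = 0.2) -> RigidTransform:
    """Camera-from-LiDAR pose: camera ``camera_height`` above the scanner at
    mid-travel, looking along +x (the scanner's forward direction)."""
    R = np.array([[0.0, -1.0, 0.0], [0.0, 0.0, -1.0], [1.0, 0.0, 0.0]])
    C = np.array([0.0, travel / 2.0, camera_height])
    return RigidTransform(R, -R @ C)


def default_board_pose(travel: float = 0.8, distance: float = 1.5) -> RigidTransform:
    """Board facing the sensors at ``distance`` ahead, centred on the traverse."""
    R = np.array([[0.0, 0.0, -1.0], [-1.0, 0.0, 0.0], [0.0, 1.0, 0.0]])
    return RigidTransform(R, [distance, travel / 2.0, 0.0])


def sample_board_placements(
    n: int,
    rng: np.random.Generator,
    pattern: PatternSpec = PatternSpec(),
    camera: Optional[CameraIntrinsics] = None,
    extrinsics: Optional[RigidTransform] = None,
    travel: float = 0.8,
    distance: Tuple[float, float] = (1.1, 1.9),
    tilt: float = 0.35,
    y_jitter: float = 0.04,
    z_offset: float = 0.25,
    margin_px: float = 10.0,
    z_limits: Tuple[float, float] = (-0.62, 0.85),
) -> List[RigidTransform]:
    """Board poses spread over the camera frame, all bulbs safely in view.

    Calibration practice positions the pattern to cover the whole frame at a
    variety of tilts; proposals whose bulbs would leave the image (or whose
    board leaves the scanner's vertical window) are rejected and redrawn, so
    every returned placement yields a processable scan.
    """
    from scipy.spatial.transform import Rotation

    camera = camera or default_camera()
    extrinsics = extrinsics or default_extrinsics(travel)
    grid = pattern_grid(pattern)
    corners = np.array(
        [
            [sx * pattern.board_width / 2, sy * pattern.board_height / 2, 0.0]
            for sx in (-1, 1)
            for sy in (-1, 1)
        ]
    )
    poses: List[RigidTransform] = []
    w, h = 2 * camera.cx, 2 * camera.cy
    while len(poses) < n:
        base = default_board_pose(travel, distance=rng.uniform(*distance))
        pose = RigidTransform(
            Rotation.from_rotvec(rng.uniform(-tilt, tilt, 3)).as_matrix() @ base.R,
            base.t
            + [0.0, rng.uniform(-y_jitter, y_jitter), rng.uniform(-z_offset, z_offset)],
        )
        cz = pose.apply(corners)[:, 2]
        if cz.min() < z_limits[0] or cz.max() > z_limits[1]:
            continue
        cam_pts = extrinsics.apply(pose.apply(grid))
        if np.any(cam_pts[:, 2] <= 0.2):
            continue
        px = camera.project(cam_pts)
        if np.any(
            (px[:, 0] < margin_px)
            | (px[:, 0] > w - margin_px)
            | (px[:, 1] < margin_px)
            | (px[:, 1] > h - margin_px)
        ):
            continue
        poses.append(pose)
    return poses


# ---------------------------------------------------------------------------
# analytic primitives and ray casting
# ---------------------------------------------------------------------------


@dataclass
class Rectangle:
    """Finite plane patch: centre, two orthonormal in-plane axes, half extents."""

    center: np.ndarray
    u: np.ndarray
    v: np.ndarray
    half_u: float
    half_v: float
    reflectance: float = 0.5
    temperature: Union[float, Callable] = 20.0
    label: int = 0

    def __post_init__(self) -> None:
        self.center = np.asarray(self.center, dtype=float)
        self.u = np.asarray(self.u, dtype=float) / np.linalg.norm(self.u)
        self.v = np.asarray(self.v, dtype=float) / np.linalg.norm(self.v)
        self.normal = np.cross(self.u, self.v)

    def intersect(self, origins: np.ndarray, dirs: np.ndarray) -> np.ndarray:
        denom = dirs @ self.normal
        with np.errstate(divide="ignore", invalid="ignore"):
            t = ((self.center - origins) @ self.normal) / denom
        p = origins + t[:, None] * dirs
        rel = p - self.center
        hit = (
            (np.abs(denom) > 1e-12)
            & (t > 1e-9)
            & (np.abs(rel @ self.u) <= self.half_u)
            & (np.abs(rel @ self.v) <= self.half_v)
        )
        return np.where(hit, t, np.inf)


@dataclass
class Sphere:
    center: np.ndarray
    radius: float
    reflectance: float = 0.5
    temperature: Union[float, Callable] = 20.0
    label: int = 0

    def __post_init__(self) -> None:
        self.center = np.asarray(self.center, dtype=float)

    def intersect(self, origins: np.ndarray, dirs: np.ndarray) -> np.ndarray:
        oc = origins - self.center
        b = np.einsum("ij,ij->i", oc, dirs)
        c = np.einsum("ij,ij->i", oc, oc) - self.radius**2
        disc = b * b - c
        with np.errstate(invalid="ignore"):
            sq = np.sqrt(disc)
        t = -b - sq
        hit = (disc >= 0) & (t > 1e-9)
        return np.where(hit, t, np.inf)


@dataclass
class Cylinder:
    """Finite open cylinder between two axis endpoints."""

    p0: np.ndarray
    p1: np.ndarray
    radius: float
    reflectance: float = 0.5
    temperature: Union[float, Callable] = 20.0
    label: int = 0

    def __post_init__(self) -> None:
        self.p0 = np.asarray(self.p0, dtype=float)
        self.p1 = np.asarray(self.p1, dtype=float)
        self.axis = (self.p1 - self.p0) / np.linalg.norm(self.p1 - self.p0)
        self.length = float(np.linalg.norm(self.p1 - self.p0))

    def intersect(self, origins: np.ndarray, dirs: np.ndarray) -> np.ndarray:
        oc = origins - self.p0
        d_perp = dirs - np.outer(dirs @ self.axis, self.axis)
        o_perp = oc - np.outer(oc @ self.axis, self.axis)
        a = np.einsum("ij,ij->i", d_perp, d_perp)
        b = np.einsum("ij,ij->i", o_perp, d_perp)
        c = np.einsum("ij,ij->i", o_perp, o_perp) - self.radius**2
        with np.errstate(invalid="ignore", divide="ignore"):
            disc = b * b - a * c
            sq = np.sqrt(disc)
            t = (-b - sq) / a
        axial = (oc @ self.axis) + t * (dirs @ self.axis)
        hit = (a > 1e-12) & (disc >= 0) & (t > 1e-9) & (axial >= 0) & (axial <= self.length)
        return np.where(hit, t, np.inf)


def raycast(primitives: Sequence, origins: np.ndarray, dirs: np.ndarray):
    """First-hit ranges (inf = miss) and primitive index (-1 = miss)."""
    n = len(origins)
    best_t = np.full(n, np.inf)
    best_i = np.full(n, -1, dtype=int)
    for i, prim in enumerate(primitives):
        t = prim.intersect(origins, dirs)
        closer = t < best_t
        best_t[closer] = t[closer]
        best_i[closer] = i
    return best_t, best_i


def _surface_temperature(prim, points: np.ndarray) -> np.ndarray:
    if callable(prim.temperature):
        return np.asarray(prim.temperature(points), dtype=float)
    return np.full(len(points), float(prim.temperature))


def lidar_scan(
    primitives: Sequence,
    lidar: LidarSpec,
    travel: float,
    range_sigma: float = 0.0,
    rng: Optional[np.random.Generator] = None,
    chunk: int = 200_000,
) -> Tuple[PointCloud, np.ndarray]:
    """Assemble the moving scanner's cloud against a primitive scene.

    Returns the cloud (points, reflectance) and the per-point primitive
    index.  Profile ``k`` originates at ``(0, k·v/f, 0)``; beams live in
    that profile's x–z plane.  Range noise perturbs ranges along the beam.
    """
    rng = rng or np.random.default_rng()
    angles = lidar.angles
    n_prof = int(round(travel / lidar.profile_step))
    dirs_one = np.column_stack([np.cos(angles), np.zeros(len(angles)), np.sin(angles)])
    pts_out, refl_out, lab_out = [], [], []
    prof_per_chunk = max(1, chunk // len(angles))
    for start in range(0, n_prof, prof_per_chunk):
        stop = min(start + prof_per_chunk, n_prof)
        ks = np.arange(start, stop)
        origins = np.zeros((len(ks), len(angles), 3))
        origins[:, :, 1] = (ks * lidar.profile_step)[:, None]
        origins = origins.reshape(-1, 3)
        dirs = np.tile(dirs_one, (len(ks), 1))
        t, idx = raycast(primitives, origins, dirs)
        hit = np.isfinite(t) & (t <= lidar.max_range)
        t = t[hit]
        if range_sigma > 0:
            t = t + rng.normal(0.0, range_sigma, size=len(t))
        p = origins[hit] + t[:, None] * dirs[hit]
        pts_out.append(p)
        lab = idx[hit]
        lab_out.append(lab)
        refl_out.append(np.array([primitives[i].reflectance for i in lab]))
    points = np.concatenate(pts_out) if pts_out else np.zeros((0, 3))
    refl = np.concatenate(refl_out) if refl_out else np.zeros(0)
    labels = np.concatenate(lab_out) if lab_out else np.zeros(0, dtype=int)
    return PointCloud(points, refl, frame_label="lidar-scan"), labels


# ---------------------------------------------------------------------------
# thermal rendering helpers
# ---------------------------------------------------------------------------


def _fill_quad(image: np.ndarray, corners_px: np.ndarray, value: float) -> None:
    rr, cc = draw_polygon(corners_px[:, 1], corners_px[:, 0], shape=image.shape)
    image[rr, cc] = value


# ---------------------------------------------------------------------------
# calibration-board scene
# ---------------------------------------------------------------------------


def simulate_calibration_scene(
    pattern: PatternSpec = PatternSpec(),
    camera: Optional[CameraIntrinsics] = None,
    extrinsics: Optional[RigidTransform] = None,
    board_pose: Optional[RigidTransform] = None,
    noise: SensorNoise = SensorNoise(),
    seed: Optional[int] = None,
    lidar: LidarSpec = LidarSpec(),
    travel: float = 0.8,
    board_temp: float = 21.4,
    bulb_temp: float = 46.3,
    ambient: float = 15.0,
    blob_sigma_px: float = 6.0,
    include_floor: bool = True,
    floor_z: float = -0.7,
) -> Tuple[PointCloud, ThermalImage, SceneTruth]:
    """Heated-board calibration scene: ray-cast cloud + rendered thermal frame.

    The board rectangle (and optionally a floor plane, which the crop-box
    step removes) is ray-cast by the moving scanner.  The thermal image
    renders the board at ``board_temp`` over an ``ambient`` background with
    Gaussian hot spots of peak ``bulb_temp`` at the true bulb projections;
    the defaults reproduce the fused-cloud statistics of the reference rig
    (bulb centres ≈ 46.3 °C, board ≈ 21.4 °C).
    """
    rng = np.random.default_rng(seed)
    camera = camera or default_camera()
    extrinsics = extrinsics or default_extrinsics(travel)
    board_pose = board_pose or default_board_pose(travel)

    board = Rectangle(
        center=board_pose.t,
        u=board_pose.R[:, 0],
        v=board_pose.R[:, 1],
        half_u=pattern.board_width / 2.0,
        half_v=pattern.board_height / 2.0,
        reflectance=0.6,
        temperature=board_temp,
        label=1,
    )
    prims: List = [board]
    if include_floor:
        prims.append(
            Rectangle(
                center=np.array([lidar.max_range / 2.0, travel / 2.0, floor_z]),
                u=np.array([1.0, 0.0, 0.0]),
                v=np.array([0.0, 1.0, 0.0]),
                half_u=lidar.max_range / 2.0,
                half_v=max(travel, 2.0),
                reflectance=0.3,
                temperature=ambient,
                label=0,
            )
        )
    cloud, prim_idx = lidar_scan(prims, lidar, travel, noise.range_sigma, rng)
    labels = np.array([prims[i].label for i in prim_idx])
    if not np.any(labels == 1):
        raise ValueError("board outside the LiDAR field of view")

    # thermal frame: board quad + bulb hot spots
    h, w = 480, 640
    img = np.full((h, w), ambient)
    corners_board = np.array(
        [
            [-pattern.board_width / 2, -pattern.board_height / 2, 0.0],
            [pattern.board_width / 2, -pattern.board_height / 2, 0.0],
            [pattern.board_width / 2, pattern.board_height / 2, 0.0],
            [-pattern.board_width / 2, pattern.board_height / 2, 0.0],
        ]
    )
    cam_corners = extrinsics.apply(board_pose.apply(corners_board))
    if np.any(cam_corners[:, 2] <= 0):
        raise ValueError("board behind the camera")
    corner_px = camera.project(cam_corners)
    _fill_quad(img, corner_px, board_temp)

    bulbs_lidar = board_pose.apply(pattern_grid(pattern))
    bulb_px = camera.project(extrinsics.apply(bulbs_lidar))
    if not np.any(
        (bulb_px[:, 0] >= 0) & (bulb_px[:, 0] < w) & (bulb_px[:, 1] >= 0) & (bulb_px[:, 1] < h)
    ):
        raise ValueError("board outside the camera field of view")
    jitter = (
        rng.normal(0.0, noise.blob_sigma_px, size=bulb_px.shape)
        if noise.blob_sigma_px > 0
        else np.zeros_like(bulb_px)
    )
    for center in bulb_px + jitter:
        _add_spot_max(img, center, blob_sigma_px, board_temp, bulb_temp)
    if noise.temp_sigma > 0:
        img = img + rng.normal(0.0, noise.temp_sigma, size=img.shape)

    truth = SceneTruth(
        labels=labels,
        label_names={0: "floor", 1: "board"},
        camera=camera,
        extrinsics=extrinsics,
        seed=seed,
        info={
            "board_pose": board_pose,
            "bulbs_lidar": bulbs_lidar,
            "bulb_pixels": bulb_px,
            "board_temp": board_temp,
            "bulb_temp": bulb_temp,
            "ambient": ambient,
            "pattern": pattern,
            "travel": travel,
        },
    )
    return cloud, ThermalImage(img), truth


def _add_spot_max(image: np.ndarray, center, sigma: float, base: float, peak: float) -> None:
    """Blend a Gaussian spot rising from ``base`` to ``peak`` into the image."""
    h, w = image.shape
    x0, y0 = float(center[0]), float(center[1])
    half = int(np.ceil(4 * sigma))
    xs = np.arange(max(0, int(x0) - half), min(w, int(x0) + half + 1))
    ys = np.arange(max(0, int(y0) - half), min(h, int(y0) + half + 1))
    if len(xs) == 0 or len(ys) == 0:
        return
    X, Y = np.meshgrid(xs, ys)
    g = base + (peak - base) * np.exp(-((X - x0) ** 2 + (Y - y0) ** 2) / (2.0 * sigma**2))
    region = image[ys[0] : ys[-1] + 1, xs[0] : xs[-1] + 1]
    np.maximum(region, g, out=region)


# ---------------------------------------------------------------------------
# metal evaluation tree
# ---------------------------------------------------------------------------

S_WHITE = "S_W"  # barium-sulphate coating: high reflectance
S_BLACK = "S_B"  # urethane black: low reflectance


def _default_sphere_layout(distance: float, y_center: float):
    """15 spheres on 5 bars: 12 x 80 mm plus 3 x 60 mm (on the middle bar)."""
    bar_z = np.array([-0.45, -0.15, 0.15, 0.45, 0.75])
    spheres = []
    for bi, z in enumerate(bar_z):
        radii = (0.03, 0.03, 0.03) if bi == 2 else (0.04, 0.04, 0.04)
        offsets = (-0.40, 0.0, 0.40)
        for si, (dy, r) in enumerate(zip(offsets, radii)):
            x = distance - (0.10 if dy == 0.0 else 0.0)  # clear the trunk
            material = S_WHITE if (bi + si) % 2 == 0 else S_BLACK
            spheres.append((np.array([x, y_center + dy, z]), r, material))
    return spheres


def simulate_metal_frame(
    spheres: Optional[Sequence[Tuple[np.ndarray, float, str]]] = None,
    temps: Optional[dict] = None,
    noise: SensorNoise = SensorNoise(),
    seed: Optional[int] = None,
    lidar: LidarSpec = LidarSpec(),
    travel: float = 1.2,
    distance: float = 1.5,
    ambient: float = 19.0,
    camera: Optional[CameraIntrinsics] = None,
    extrinsics: Optional[RigidTransform] = None,
) -> Tuple[PointCloud, ThermalImage, SceneTruth]:
    """Metal tree with coated sphere targets (2 m trunk, 5 bars at 0.30 m).

    White (barium sulphate, ``S_W``) and black (urethane, ``S_B``) spheres
    bound the reflectance extremes; per-material temperatures default to
    the ambient.  Overlapping spheres are a configuration error.
    """
    rng = np.random.default_rng(seed)
    camera = camera or default_camera()
    extrinsics = extrinsics or default_extrinsics(travel)
    temps = {"S_W": ambient, "S_B": ambient, "frame": ambient, **(temps or {})}
    y_c = travel / 2.0
    if spheres is None:
        spheres = _default_sphere_layout(distance, y_c)
    for i in range(len(spheres)):
        for j in range(i + 1, len(spheres)):
            ci, ri, _ = spheres[i]
            cj, rj, _ = spheres[j]
            if np.linalg.norm(np.asarray(ci) - np.asarray(cj)) < ri + rj:
                raise ValueError(f"spheres {i} and {j} overlap")

    refl = {"S_W": 0.95, "S_B": 0.08, "frame": 0.4}
    prims: List = [
        Cylinder(
            [distance, y_c, -0.7], [distance, y_c, 1.3], 0.025,
            reflectance=refl["frame"], temperature=temps["frame"], label=0,
        )
    ]
    for z in (-0.45, -0.15, 0.15, 0.45, 0.75):
        prims.append(
            Cylinder(
                [distance, y_c - 0.15, z], [distance, y_c + 0.15, z], 0.015,
                reflectance=refl["frame"], temperature=temps["frame"], label=0,
            )
        )
    sphere_prims = []
    for k, (c, r, mat) in enumerate(spheres):
        p = Sphere(c, r, reflectance=refl[mat], temperature=temps[mat], label=1 + k)
        prims.append(p)
        sphere_prims.append(p)
    cloud, prim_idx = lidar_scan(prims, lidar, travel, noise.range_sigma, rng)
    labels = np.array([prims[i].label for i in prim_idx])
    if not np.any(labels > 0):
        raise ValueError("metal frame outside the scanner field of view")

    # thermal frame: z-ordered painter's rendering of bars, trunk, spheres
    h, w = 480, 640
    img = np.full((h, w), ambient - 2.0)
    drawables = []
    for prim in prims:
        if isinstance(prim, Cylinder):
            mid = (prim.p0 + prim.p1) / 2.0
            depth = extrinsics.apply(mid)[2]
            drawables.append((depth, "cyl", prim))
        else:
            depth = extrinsics.apply(prim.center)[2]
            drawables.append((depth, "sph", prim))
    for depth, kind, prim in sorted(drawables, key=lambda d: -d[0]):
        if kind == "cyl":
            view = extrinsics.apply(np.stack([prim.p0, prim.p1]))
            if np.any(view[:, 2] <= 0):
                continue
            axis3 = prim.p1 - prim.p0
            look = prim.p0 - np.asarray(extrinsics.inverse().t)
            side = np.cross(axis3, look)
            side = side / max(np.linalg.norm(side), 1e-12) * prim.radius
            corners = np.stack(
                [prim.p0 - side, prim.p0 + side, prim.p1 + side, prim.p1 - side]
            )
            px = camera.project(extrinsics.apply(corners))
            _fill_quad(img, px, float(prim.temperature))
        else:
            view = extrinsics.apply(prim.center)
            if view[2] <= 0:
                continue
            cpx = camera.project(view[None, :])[0]
            # inflate slightly so every 3D surface point projects inside the
            # rendered silhouette (perspective widening + distortion)
            # off-axis sphere silhouettes are radially stretched ellipses;
            # widen the disk so every surface point projects inside it
            stretch = 1.0 + (view[0] ** 2 + view[1] ** 2) / view[2] ** 2
            rpx = 1.10 * stretch * prim.radius * camera.fx / view[2]
            rr, cc = draw_disk((cpx[1], cpx[0]), rpx, shape=img.shape)
            img[rr, cc] = float(prim.temperature)
    if noise.temp_sigma > 0:
        img = img + rng.normal(0.0, noise.temp_sigma, size=img.shape)

    truth = SceneTruth(
        labels=labels,
        label_names={0: "frame", **{1 + k: f"sphere_{k}" for k in range(len(spheres))}},
        camera=camera,
        extrinsics=extrinsics,
        seed=seed,
        info={
            "spheres": [
                {"center": np.asarray(c), "radius": float(r), "material": m}
                for c, r, m in spheres
            ],
            "temps": temps,
            "ambient": ambient,
            "travel": travel,
        },
    )
    return cloud, ThermalImage(img), truth


# ---------------------------------------------------------------------------
# orchard row
# ---------------------------------------------------------------------------


def _sample_sphere_surface(rng, center, radius, n):
    v = rng.normal(size=(n, 3))
    v /= np.linalg.norm(v, axis=1, keepdims=True)
    return center + radius * v, v  # points, outward normals


def _sample_disk(rng, center, normal, radius, n):
    normal = normal / np.linalg.norm(normal)
    a = np.array([1.0, 0.0, 0.0])
    if abs(normal @ a) > 0.9:
        a = np.array([0.0, 1.0, 0.0])
    u = np.cross(normal, a)
    u /= np.linalg.norm(u)
    v = np.cross(normal, u)
    r = radius * np.sqrt(rng.uniform(size=n))
    th = rng.uniform(0, 2 * np.pi, size=n)
    pts = center + r[:, None] * (np.cos(th)[:, None] * u + np.sin(th)[:, None] * v)
    return pts, np.tile(normal, (n, 1))


def _sample_cylinder_surface(rng, p0, p1, radius, n):
    axis = np.asarray(p1) - np.asarray(p0)
    length = np.linalg.norm(axis)
    axis = axis / length
    a = np.array([1.0, 0.0, 0.0])
    if abs(axis @ a) > 0.9:
        a = np.array([0.0, 1.0, 0.0])
    u = np.cross(axis, a)
    u /= np.linalg.norm(u)
    v = np.cross(axis, u)
    h = rng.uniform(0, length, size=n)
    th = rng.uniform(0, 2 * np.pi, size=n)
    normals = np.cos(th)[:, None] * u + np.sin(th)[:, None] * v
    pts = np.asarray(p0) + h[:, None] * axis + radius * normals
    return pts, normals


def simulate_orchard_row(
    n_trees: int = 5,
    tree_pitch: float = 0.95,
    fruits_per_tree: int = 10,
    fruit_radius: Tuple[float, float] = (0.030, 0.040),
    leaves_per_tree: int = 150,
    leaf_radius: float = 0.040,
    points_per_fruit: int = 500,
    points_per_leaf: int = 200,
    trunk_points: int = 3000,
    temperature_model: Optional[dict] = None,
    reflectance_model: Optional[dict] = None,
    point_sigma: float = 0.0005,
    temp_sigma: float = 0.1,
    seed: Optional[int] = None,
    camera_fov_top: float = 2.4,
) -> Tuple[Tuple[PointCloud, PointCloud], Tuple[ThermalImage, ThermalImage], SceneTruth]:
    """Two-sided apple-row scene with per-point organ labels.

    Row frame: y along the row, z up (ground at z = 0), x toward the east
    side.  Trunks are vertical cylinders at ``tree_pitch`` spacing (the
    reference orchard's 0.95 m); leaves are oriented disks; fruits are
    spheres with higher 905 nm reflectance than foliage and a smooth
    surface-temperature field.  Fruits on the east half of a tree carry a
    configurable mean temperature offset (default +0.5 °C), emulating the
    east/west insolation asymmetry.

    Each point is assigned to the scan side its surface normal faces; the
    west cloud is expressed in the west scanner's frame, related to the row
    frame by a known rigid transform (180° about z plus an offset) stored
    in the truth.  Per-point temperatures are the fused values a thermal
    camera on that side would deliver (organ model + Gaussian fusion
    noise); points above the camera's vertical field of view carry the
    −10 °C out-of-view sentinel.
    """
    rng = np.random.default_rng(seed)
    tm = {
        "fruit_mean": 18.3, "east_offset": 0.5, "fruit_between_sd": 0.3,
        "fruit_within_amplitude": 0.3, "leaf_mean": 17.5, "leaf_sd": 0.6,
        "trunk_mean": 20.6, "trunk_sd": 0.65,
        **(temperature_model or {}),
    }
    rm = {
        "fruit": (0.85, 0.02), "leaf": (0.55, 0.05), "trunk": (0.45, 0.05),
        **(reflectance_model or {}),
    }

    pts_list, normal_list, temp_list, refl_list, label_list = [], [], [], [], []
    LABEL_TRUNK, LABEL_LEAF = 0, 1
    fruit_table = []
    stems = []
    sun = np.array([0.6, 0.0, 0.8])
    sun = sun / np.linalg.norm(sun)

    for ti in range(n_trees):
        y0 = ti * tree_pitch
        stems.append((0.0, y0))
        p, nrm = _sample_cylinder_surface(rng, [0.0, y0, 0.0], [0.0, y0, 2.2], 0.030, trunk_points)
        pts_list.append(p)
        normal_list.append(nrm)
        temp_list.append(np.full(len(p), tm["trunk_mean"]) + rng.normal(0, tm["trunk_sd"] / 4, len(p)))
        refl_list.append(np.clip(rng.normal(*rm["trunk"], len(p)), 0, 1))
        label_list.append(np.full(len(p), LABEL_TRUNK, dtype=int))

        for _ in range(leaves_per_tree):
            radial = rng.uniform(0.08, 0.40)
            ang = rng.uniform(0, 2 * np.pi)
            height = rng.uniform(0.9, 2.1)
            center = np.array([radial * np.cos(ang), y0 + radial * np.sin(ang) * 0.5, height])
            normal = rng.normal(size=3)
            normal /= np.linalg.norm(normal)
            p, nrm = _sample_disk(rng, center, normal, leaf_radius, points_per_leaf)
            pts_list.append(p)
            normal_list.append(nrm)
            leaf_t = rng.normal(tm["leaf_mean"], tm["leaf_sd"])
            temp_list.append(np.full(len(p), leaf_t))
            refl_list.append(np.clip(rng.normal(*rm["leaf"], len(p)), 0, 1))
            label_list.append(np.full(len(p), LABEL_LEAF, dtype=int))

        # fruits: half east (x > 0), half west, minimum centre separation
        centers: List[np.ndarray] = []
        for fi in range(fruits_per_tree):
            east = fi % 2 == 0
            for _ in range(200):
                radial = rng.uniform(0.12, 0.38)
                ang = rng.uniform(-1.2, 1.2) + (0.0 if east else np.pi)
                height = rng.uniform(1.0, 2.0)
                c = np.array([radial * np.cos(ang), y0 + radial * np.sin(ang) * 0.4, height])
                if abs(c[0]) < 0.08:
                    continue
                if all(np.linalg.norm(c - prev) > 0.14 for prev in centers):
                    centers.append(c)
                    break
            else:  # pragma: no cover - generous retry budget
                raise RuntimeError("could not place fruit without overlap")
            r = rng.uniform(*fruit_radius)
            fid = 2 + len(fruit_table)
            p, nrm = _sample_sphere_surface(rng, centers[-1], r, points_per_fruit)
            base = tm["fruit_mean"] + (tm["east_offset"] if east else 0.0)
            base += rng.normal(0.0, tm["fruit_between_sd"])
            t_clean = base + tm["fruit_within_amplitude"] * (nrm @ sun)
            pts_list.append(p)
            normal_list.append(nrm)
            temp_list.append(t_clean)
            refl_list.append(np.clip(rng.normal(*rm["fruit"], len(p)), 0, 1))
            label_list.append(np.full(len(p), fid, dtype=int))
            fruit_table.append(
                {
                    "id": fid,
                    "center": centers[-1],
                    "radius": float(r),
                    "side": "east" if east else "west",
                    "fst_mean": float(np.mean(t_clean)),
                    "fst_sd": float(np.std(t_clean)),
                    "tree": ti,
                }
            )

    # orchard floor: seen from BOTH sides, it anchors the side-to-side ICP
    LABEL_GROUND = -1
    n_ground = 1500 + 700 * n_trees
    gx = rng.uniform(-0.7, 0.7, n_ground)
    gy = rng.uniform(-0.5, (n_trees - 1) * tree_pitch + 0.5, n_ground)
    pts_list.append(np.column_stack([gx, gy, np.zeros(n_ground)]))
    normal_list.append(np.tile([0.0, 0.0, 1.0], (n_ground, 1)))
    temp_list.append(rng.normal(19.0, 0.3, n_ground))
    refl_list.append(np.clip(rng.normal(0.30, 0.04, n_ground), 0, 1))
    label_list.append(np.full(n_ground, LABEL_GROUND, dtype=int))

    points = np.concatenate(pts_list)
    normals = np.concatenate(normal_list)
    temps_clean = np.concatenate(temp_list)
    refl = np.concatenate(refl_list)
    labels = np.concatenate(label_list)
    if point_sigma > 0:
        points = points + rng.normal(0, point_sigma, points.shape)

    # each surface point is captured by the scan side its normal faces;
    # thin structures — the ground strip and the ~6 cm trunks — are seen
    # from both sides and anchor the side-to-side registration
    both = (labels == LABEL_GROUND) | (labels == LABEL_TRUNK)
    east_mask = (normals[:, 0] > 0) | both
    west_mask = (normals[:, 0] <= 0) | both

    sentinel = -10.0

    def side_cloud(mask, transform: RigidTransform):
        p = points[mask]
        t = temps_clean[mask] + rng.normal(0, temp_sigma, mask.sum())
        t = np.where(p[:, 2] > camera_fov_top, sentinel, t)
        return (
            PointCloud(transform.apply(p), refl[mask], t, frame_label="side"),
            labels[mask],
        )

    T_east = RigidTransform.identity()  # east side is the row frame
    # west scanner frame: rotate 180° about z, shift along x
    Rz = np.array([[-1.0, 0.0, 0.0], [0.0, -1.0, 0.0], [0.0, 0.0, 1.0]])
    row_from_west = RigidTransform(Rz, [0.0, (n_trees - 1) * tree_pitch, 0.0]).inverse()
    cloud_east, labels_east = side_cloud(east_mask, T_east)
    cloud_west, labels_west = side_cloud(west_mask, row_from_west.inverse())

    images = tuple(
        _splat_image(c, default_camera(), _side_camera_pose(sign, n_trees, tree_pitch), 16.0)
        for c, sign in ((cloud_east, +1), (cloud_west, -1))
    )

    truth = SceneTruth(
        labels=labels,
        label_names={-1: "ground", 0: "trunk", 1: "leaf",
                     **{f["id"]: f"fruit_{f['id'] - 2}" for f in fruit_table}},
        camera=default_camera(),
        seed=seed,
        info={
            "fruits": fruit_table,
            "stems": stems,
            "tree_pitch": tree_pitch,
            "row_from_west": row_from_west,
            "labels_east": labels_east,
            "labels_west": labels_west,
            "east_offset": tm["east_offset"],
            "sentinel": sentinel,
            "temperature_model": tm,
            "points_row_frame": points,
            "east_mask": east_mask,
            "west_mask": west_mask,
        },
    )
    return (cloud_east, cloud_west), images, truth


def _side_camera_pose(sign: int, n_trees: int, tree_pitch: float) -> RigidTransform:
    """Camera 1.8 m out on one side at mid-row, 1.4 m up, looking inward."""
    look = np.array([-sign, 0.0, 0.0])
    up = np.array([0.0, 0.0, 1.0])
    right = np.cross(look, up)
    R = np.stack([right, -up, look])  # rows: camera x, y (down), z axes
    C = np.array([sign * 1.8, (n_trees - 1) * tree_pitch / 2.0, 1.4])
    return RigidTransform(R, -R @ C)


def _splat_image(cloud: PointCloud, camera: CameraIntrinsics, cam_from_row: RigidTransform, background: float) -> ThermalImage:
    """Nearest-depth splat of cloud temperatures into a camera frame."""
    h, w = 480, 640
    img = np.full((h, w), background)
    depth = np.full((h, w), np.inf)
    view = cam_from_row.apply(cloud.points)
    px, ok = camera.project(view, allow_behind=True)
    ix = np.floor(px[:, 0] + 0.5).astype(np.int64, casting="unsafe", copy=False)
    iy = np.floor(px[:, 1] + 0.5).astype(np.int64, casting="unsafe", copy=False)
    temps = cloud.temperature if cloud.temperature is not None else np.full(len(cloud), background)
    good = ok & np.isfinite(px).all(axis=1)
    good &= (ix >= 0) & (ix < w) & (iy >= 0) & (iy < h) & (temps > -5.0)
    for x, y, z, t in zip(ix[good], iy[good], view[good, 2], temps[good]):
        if z < depth[y, x]:
            depth[y, x] = z
            img[y, x] = t
    return ThermalImage(img)


# ---------------------------------------------------------------------------
# analytic calibration views (no rendering)
# ---------------------------------------------------------------------------


def synthetic_views(
    camera: CameraIntrinsics,
    pattern: PatternSpec = PatternSpec(),
    n_views: int = 20,
    seed: Optional[int] = None,
    pixel_noise: float = 0.0,
    image_size: Tuple[int, int] = (640, 480),
) -> List[CalibrationView]:
    """Exact (or noise-perturbed) blob centres from random board poses.

    Poses tilt the board up to ~30° and spread it over the frame; every
    generated view keeps all ``m`` features inside the image.  The
    generating pose is stored on each view for recovery tests.
    """
    rng = np.random.default_rng(seed)
    grid = pattern_grid(pattern)
    w, h = image_size
    views: List[CalibrationView] = []
    base = np.array([[1.0, 0.0, 0.0], [0.0, -1.0, 0.0], [0.0, 0.0, -1.0]])
    while len(views) < n_views:
        rv = rng.uniform(-0.5, 0.5, size=3)
        from scipy.spatial.transform import Rotation

        R = Rotation.from_rotvec(rv).as_matrix() @ base
        t = np.array(
            [rng.uniform(-0.25, 0.25), rng.uniform(-0.18, 0.18), rng.uniform(1.0, 1.8)]
        )
        pose = RigidTransform(R, t)
        cam_pts = pose.apply(grid)
        if np.any(cam_pts[:, 2] <= 0.1):
            continue
        px = camera.project(cam_pts)
        if np.any((px[:, 0] < 5) | (px[:, 0] > w - 5) | (px[:, 1] < 5) | (px[:, 1] > h - 5)):
            continue
        if pixel_noise > 0:
            px = px + rng.normal(0.0, pixel_noise, size=px.shape)
        views.append(CalibrationView(image=None, features=px, pose=pose, status="ok"))
    return views
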