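"""Thermal point-cloud fusion: assign image temperatures to 3D points.

Every LiDAR point is mapped into the camera frame through the extrinsic
transform, projected with the full distortion model, and — if the
projected pixel falls inside the image and the point sits in front of the
camera — assigned the nearest pixel's temperature.  Points that project
outside the field of view are NOT dropped; they receive a sentinel value
(default −10 °C) chosen to lie outside the plausible scene temperature
range, so downstream statistics can exclude them unambiguously.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import List, Sequence

import numpy as np

from .geometry import RigidTransform
from .intrinsics import CameraIntrinsics
from .io import PointCloud

__all__ = ["FusionConfig", "ScanProfile", "assemble_profiles", "fuse_temperature"]

SENTINEL_DEFAULT = -10.0


@dataclass(frozen=True)
class FusionConfig:
    """Fusion policy: sentinel value and nearest-pixel lookup.

    ``sentinel`` must lie outside the plausible scene range declared by the
    caller (``scene_range``) so measured and unmeasured points can never be
    confused.
    """

    sentinel: float = SENTINEL_DEFAULT
    lookup: str = "nearest"
    scene_range: tuple = (-5.0, 60.0)
    z_buffer: bool = False

    def __post_init__(self) -> None:
        if self.lookup != "nearest":
            raise ValueError("only nearest-pixel lookup is supported")
        lo, hi = self.scene_range
        if lo <= self.sentinel <= hi:
            raise ValueError("sentinel must lie outside the declared scene range")


@dataclass(frozen=True)
class ScanProfile:
    """One 2D line-scanner sweep: a uniform angle grid with ranges.

    Angles span 180° at the scanner's angular resolution; non-finite or
    non-positive ranges mark no-return beams.  ``reflectance`` carries the
    per-beam backscattered intensity.
    """

    angles: np.ndarray
    ranges: np.ndarray
    reflectance: np.ndarray
    index: int = 0

    def __post_init__(self) -> None:
        a = np.asarray(self.angles, dtype=float)
        if len(a) > 1:
            steps = np.diff(a)
            if np.any(np.abs(steps - steps[0]) > 1e-9):
                raise ValueError("profile angle grid must be uniform")
        object.__setattr__(self, "angles", a)
        object.__setattr__(self, "ranges", np.asarray(self.ranges, dtype=float))
        object.__setattr__(self, "reflectance", np.asarray(self.reflectance, dtype=float))


def assemble_profiles(
    profiles: Sequence[ScanProfile],
    speed: float = 0.020,
    scan_rate: float = 25.0,
) -> PointCloud:
    """Stack line-scanner profiles from a constant-velocity traverse.

    The scan plane is x–z (``x = r cos θ``, ``z = r sin θ``); the platform
    travels along +y, so profile ``k`` is offset by ``k · speed/scan_rate``
    (0.8 mm at the instrument defaults of 20 mm s⁻¹ and 25 Hz).  Only beams
    with a finite positive range contribute points.
    """
    ref_angles = profiles[0].angles
    for p in profiles:
        if len(p.angles) != len(ref_angles) or np.any(np.abs(p.angles - ref_angles) > 1e-9):
            raise ValueError("profiles do not share a common angular grid")
    pts, refl = [], []
    step = speed / scan_rate
    for p in profiles:
        good = np.isfinite(p.ranges) & (p.ranges > 0)
        r = p.ranges[good]
        a = p.angles[good]
        y = np.full(len(r), p.index * step)
        pts.append(np.column_stack([r * np.cos(a), y, r * np.sin(a)]))
        refl.append(p.reflectance[good])
    return PointCloud(np.concatenate(pts), np.concatenate(refl), frame_label="assembled")


def fuse_temperature(
    cloud: PointCloud,
    image,
    intrinsics: CameraIntrinsics,
    extrinsics: RigidTransform,
    cfg: FusionConfig = FusionConfig(),
) -> PointCloud:
    """Produce a thermal point cloud; every input point is kept.

    ``extrinsics`` maps LiDAR-frame points into the camera frame.  Lookup
    is nearest-pixel (pixel centres at integer coordinates); out-of-view or
    behind-camera points receive ``cfg.sentinel``.  The optional z-buffer
    marks points occluded by a nearer point on the same pixel as
    out-of-view; it is off by default to match single-view fusion, which
    has no occlusion reasoning.
    """
    cam_pts = extrinsics.apply(cloud.points)
    px, in_front = intrinsics.project(cam_pts, allow_behind=True)
    h, w = image.values.shape
    # bounds test in float space first: projections of near-plane points can
    # be finite yet far beyond any integer range
    with np.errstate(invalid="ignore"):
        in_bounds = (
            in_front
            & np.all(np.isfinite(px), axis=1)
            & (px[:, 0] > -0.5) & (px[:, 0] < w - 0.5)
            & (px[:, 1] > -0.5) & (px[:, 1] < h - 0.5)
        )
    ix = np.full(len(cloud), -1, dtype=int)
    iy = np.full(len(cloud), -1, dtype=int)
    ix[in_bounds] = np.floor(px[in_bounds, 0] + 0.5).astype(int)
    iy[in_bounds] = np.floor(px[in_bounds, 1] + 0.5).astype(int)
    visible = in_bounds
    if cfg.z_buffer:
        depth = cam_pts[:, 2]
        flat = iy * w + ix
        nearest = np.full(h * w, np.inf)
        np.minimum.at(nearest, flat[visible], depth[visible])
        occluded = visible & (depth > nearest[np.clip(flat, 0, h * w - 1)] + 1e-9)
        visible &= ~occluded
    temperature = np.full(len(cloud), cfg.sentinel, dtype=float)
    temperature[visible] = image.values[iy[visible], ix[visible]]
    return cloud.with_temperature(temperature)
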