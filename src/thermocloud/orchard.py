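"""Per-fruit surface temperature (FST) from thermal apple-tree clouds.

Processing chain for a two-sided row scan whose points already carry fused
temperatures:

1. align the paired tree sides with ICP and merge (duplicate overlap points
   are kept — FST averaging is robust to them);
2. localise stems with a bivariate point-density histogram of the trunk
   height band and cut a cylinder per tree;
3. compute per-point covariance-eigenvalue curvature over k nearest
   neighbours, ``c = λ3 / (λ1 + λ2 + λ3)``, affinely rescaled to [0, 100]
   per cloud (high on locally spherical surfaces);
4. threshold curvature and backscattered reflectance (apples are the
   high-curvature, high-reflectance class: ``C_th ≤ C_A`` and
   ``R_th ≤ R_A``), cluster the candidates, and report per-fruit FST
   statistics over non-sentinel temperatures, with an east/west side label
   from the fruit centroid's offset across the row axis.

Frame convention: the row runs along y, z is up with the ground at z = 0,
and +x points to the configured "east" side.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import List, Optional, Sequence, Tuple

import numpy as np
from scipy import ndimage
from scipy.sparse import coo_matrix
from scipy.sparse.csgraph import connected_components
from scipy.spatial import cKDTree
from scipy.stats import gaussian_kde

from .extrinsics import ICPResult, refine_pose_icp
from .geometry import RigidTransform
from .io import PointCloud

__all__ = [
    "FeatureField",
    "FruitSegment",
    "TreeSegment",
    "align_tree_sides",
    "detect_stems",
    "segment_tree",
    "curvature_features",
    "estimate_thresholds",
    "segment_fruits",
    "categorize_side",
]

SENTINEL_DEFAULT = -10.0


@dataclass
class FeatureField:
    """Per-point geometric/radiometric features of one cloud.

    ``curvature`` is the scaled change-of-curvature in [0, 100];
    ``eigenvalues`` holds λ1 ≥ λ2 ≥ λ3 per point; ``degenerate`` flags
    neighbourhoods whose covariance vanished (duplicate points).
    """

    curvature: np.ndarray
    raw_curvature: np.ndarray
    eigenvalues: np.ndarray
    reflectance: Optional[np.ndarray]
    k: int
    degenerate: np.ndarray
    curvature_threshold: Optional[float] = None
    reflectance_threshold: Optional[float] = None


@dataclass
class FruitSegment:
    """One segmented apple: member points and FST statistics (°C)."""

    indices: np.ndarray
    centroid: np.ndarray
    radius: float
    fst_mean: float
    fst_min: float
    fst_max: float
    fst_sd: float
    n_temperature: int
    side: Optional[str] = None
    height: float = 0.0


@dataclass
class TreeSegment:
    """Points within one tree's cylindrical boundary."""

    stem: Tuple[float, float]
    radius: float
    indices: np.ndarray


# ---------------------------------------------------------------------------
# side alignment
# ---------------------------------------------------------------------------


def align_tree_sides(
    side_a: PointCloud,
    side_b: PointCloud,
    init: RigidTransform,
    max_iter: int = 50,
    tol: float = 1e-7,
    max_correspondence: float = 0.05,
) -> Tuple[PointCloud, ICPResult]:
    """ICP-refine ``init`` (mapping side_b into side_a's frame) and merge.

    Opposing sides overlap only on thin shared structures (trunks, ground,
    canopy seams), so the registration uses trimmed correspondences within
    ``max_correspondence``.  The merged cloud keeps per-point side
    provenance in ``extra['side']`` (0 = side_a, 1 = side_b) and every
    point of both inputs — overlap is not deduplicated.
    """
    # coarse-to-fine trimming: late stages are dominated by the structures
    # both sides truly share, rejecting cross-side leaf mismatches
    T = init
    icp = None
    for trim in (max_correspondence, max_correspondence / 2, max_correspondence / 5):
        icp = refine_pose_icp(
            side_b, side_a, T, max_iter=max_iter, tol=tol, max_correspondence=trim
        )
        T = icp.T_final
    icp.T_corr = init.inverse() @ T
    moved = icp.T_final.apply(side_b.points)
    merged = PointCloud(
        np.vstack([side_a.points, moved]),
        _concat_attr(side_a.reflectance, side_b.reflectance, len(side_a), len(side_b)),
        _concat_attr(side_a.temperature, side_b.temperature, len(side_a), len(side_b)),
        frame_label=side_a.frame_label or "merged",
        extra={"side": np.concatenate([np.zeros(len(side_a), int), np.ones(len(side_b), int)])},
    )
    return merged, icp


def _concat_attr(a, b, na, nb):
    if a is None and b is None:
        return None
    a = a if a is not None else np.full(na, np.nan)
    b = b if b is not None else np.full(nb, np.nan)
    return np.concatenate([a, b])


# ---------------------------------------------------------------------------
# stems and trees
# ---------------------------------------------------------------------------


def detect_stems(
    cloud: PointCloud,
    bin_size: float = 0.050,
    expected: Optional[int] = None,
    trunk_band: Tuple[float, float] = (0.2, 0.8),
    percentile_floor: float = 50.0,
    min_separation: float = 0.5,
) -> List[Tuple[float, float]]:
    """Stem ground positions from a bivariate point-density histogram.

    Points in the trunk height band are histogrammed over (x, y); local
    maxima above the ``percentile_floor`` of non-zero counts, non-maximum
    suppressed at ``min_separation`` (the tree-spacing scale), are the stem
    positions.  Finding fewer peaks than ``expected`` is a partial result,
    not an error.
    """
    z = cloud.points[:, 2]
    band = (z >= trunk_band[0]) & (z <= trunk_band[1])
    pts = cloud.points[band]
    if len(pts) == 0:
        return []
    x, y = pts[:, 0], pts[:, 1]
    xe = np.arange(x.min() - bin_size, x.max() + 2 * bin_size, bin_size)
    ye = np.arange(y.min() - bin_size, y.max() + 2 * bin_size, bin_size)
    H, xe, ye = np.histogram2d(x, y, bins=(xe, ye))
    floor = np.percentile(H[H > 0], percentile_floor)
    size = max(3, 2 * int(np.ceil(min_separation / bin_size / 2)) + 1)
    local_max = ndimage.maximum_filter(H, size=size, mode="constant") == H
    peaks = np.argwhere(local_max & (H >= floor))
    # order by count, suppress later peaks within min_separation
    order = np.argsort(-H[peaks[:, 0], peaks[:, 1]])
    centers = []
    for i in order:
        cx = (xe[peaks[i, 0]] + xe[peaks[i, 0] + 1]) / 2.0
        cy = (ye[peaks[i, 1]] + ye[peaks[i, 1] + 1]) / 2.0
        if all((cx - px) ** 2 + (cy - py) ** 2 >= min_separation**2 for px, py in centers):
            centers.append((float(cx), float(cy)))
    if expected is not None and len(centers) > expected:
        centers = centers[:expected]
    centers.sort(key=lambda c: (c[1], c[0]))
    return centers


def segment_tree(cloud: PointCloud, stem: Tuple[float, float], radius: float = 0.45) -> TreeSegment:
    """Points whose ground-plane distance to the stem axis is ≤ radius."""
    dx = cloud.points[:, 0] - stem[0]
    dy = cloud.points[:, 1] - stem[1]
    inside = dx * dx + dy * dy <= radius * radius
    return TreeSegment(stem=tuple(stem), radius=radius, indices=np.flatnonzero(inside))


# ---------------------------------------------------------------------------
# curvature features
# ---------------------------------------------------------------------------


def curvature_features(cloud: PointCloud, k: int = 30) -> FeatureField:
    """Eigenvalue curvature of each point's k-nearest-neighbour patch.

    Each neighbourhood (the query point plus its k nearest neighbours) is
    mean-centred; the covariance eigenvalues λ1 ≥ λ2 ≥ λ3 give the raw
    change-of-curvature ``c = λ3/(λ1+λ2+λ3)``, which is then affinely
    rescaled per cloud so min → 0 and max → 100.  Degenerate (zero
    covariance) neighbourhoods get curvature 0 and a flag.
    """
    if k < 4:
        raise ValueError("curvature needs k >= 4 neighbours")
    pts = cloud.points
    if len(pts) <= k:
        raise ValueError("cloud smaller than the neighbourhood size")
    tree = cKDTree(pts)
    _, idx = tree.query(pts, k=k + 1)  # includes the point itself
    nbrs = pts[idx]  # (N, k+1, 3)
    centred = nbrs - nbrs.mean(axis=1, keepdims=True)
    cov = np.einsum("nki,nkj->nij", centred, centred) / (k + 1)
    evals = np.linalg.eigvalsh(cov)  # ascending per point
    evals = np.clip(evals, 0.0, None)[:, ::-1]  # λ1 ≥ λ2 ≥ λ3
    total = evals.sum(axis=1)
    degenerate = total <= 1e-18
    raw = np.zeros(len(pts))
    np.divide(evals[:, 2], total, out=raw, where=~degenerate)
    lo, hi = raw.min(), raw.max()
    scaled = np.zeros_like(raw) if hi <= lo else (raw - lo) / (hi - lo) * 100.0
    return FeatureField(
        curvature=scaled,
        raw_curvature=raw,
        eigenvalues=evals,
        reflectance=cloud.reflectance,
        k=k,
        degenerate=degenerate,
    )


def estimate_thresholds(
    field: FeatureField,
    method: str = "kde_valley",
    percentile: float = 50.0,
    grid_points: int = 512,
    bandwidth=None,
    valley_depth: float = 0.7,
) -> Tuple[float, float]:
    """Curvature and reflectance thresholds from their distributions.

    ``kde_valley`` places each threshold at the minimum of the estimated
    probability density between its two dominant modes; the valley is
    accepted only when its density falls below ``valley_depth`` times the
    weaker mode (a genuinely bimodal feature, like apple vs foliage
    reflectance at 905 nm), otherwise the distribution is treated as
    unimodal and the ``percentile`` quantile is used — the default median
    keeps the high-valued half, leaving the real discrimination to the
    joint curvature ∧ reflectance criterion.  ``percentile`` uses the
    quantile directly.  No label information is used.
    """
    if field.reflectance is None:
        raise ValueError("feature field has no reflectance")
    c_th = _one_threshold(
        field.curvature, "curvature", method, percentile, grid_points, bandwidth, valley_depth
    )
    r_th = _one_threshold(
        field.reflectance, "reflectance", method, percentile, grid_points, bandwidth, valley_depth
    )
    field.curvature_threshold = c_th
    field.reflectance_threshold = r_th
    return c_th, r_th


def _one_threshold(values, name, method, percentile, grid_points, bandwidth, valley_depth) -> float:
    values = np.asarray(values, dtype=float)
    if np.ptp(values) <= 1e-12:
        raise ValueError(f"{name} is constant; no threshold can be estimated")
    if method == "percentile":
        return float(np.quantile(values, percentile / 100.0))
    if method != "kde_valley":
        raise ValueError(f"unknown threshold method {method!r}")
    # deterministic stride subsample keeps the KDE O(grid x 4e4)
    stride = max(1, len(values) // 40_000)
    kde = gaussian_kde(values[::stride], bw_method=bandwidth)
    grid = np.linspace(values.min(), values.max(), grid_points)
    dens = kde(grid)
    interior = (dens[1:-1] >= dens[:-2]) & (dens[1:-1] >= dens[2:])
    peaks = np.flatnonzero(interior) + 1
    if len(peaks) >= 2:
        top2 = peaks[np.argsort(dens[peaks])[::-1][:2]]
        lo, hi = np.sort(top2)
        valley = lo + int(np.argmin(dens[lo : hi + 1]))
        if dens[valley] < valley_depth * min(dens[lo], dens[hi]):
            return float(grid[valley])
    return float(np.quantile(values, percentile / 100.0))


# ---------------------------------------------------------------------------
# fruit segmentation
# ---------------------------------------------------------------------------


def _euclidean_clusters(points: np.ndarray, eps: float) -> np.ndarray:
    """Single-linkage clustering: connected components of the eps-graph."""
    tree = cKDTree(points)
    pairs = tree.query_pairs(eps, output_type="ndarray")
    n = len(points)
    graph = coo_matrix(
        (np.ones(len(pairs)), (pairs[:, 0], pairs[:, 1])), shape=(n, n)
    )
    _, comp = connected_components(graph, directed=False)
    return comp


def _fit_sphere_radius(points: np.ndarray) -> Tuple[np.ndarray, float]:
    """Algebraic least-squares sphere fit; returns (centre, radius)."""
    A = np.column_stack([2.0 * points, np.ones(len(points))])
    b = np.einsum("ij,ij->i", points, points)
    sol, *_ = np.linalg.lstsq(A, b, rcond=None)
    center = sol[:3]
    r2 = sol[3] + center @ center
    return center, float(np.sqrt(max(r2, 0.0)))


def segment_fruits(
    tree: TreeSegment,
    cloud: PointCloud,
    field: FeatureField,
    cluster_eps: float = 0.020,
    min_points: int = 30,
    sentinel: float = SENTINEL_DEFAULT,
) -> List[FruitSegment]:
    """Segment apples inside one tree's cylinder and report FST statistics.

    Candidate points satisfy ``C_th ≤ C`` and ``R_th ≤ R`` (thresholds must
    already be set on ``field``); candidates are grouped by single-linkage
    Euclidean clustering at ``cluster_eps`` and clusters below
    ``min_points`` discarded.  FST statistics use non-sentinel temperatures
    only; the fitted radius comes from an algebraic sphere fit.
    """
    if field.curvature_threshold is None or field.reflectance_threshold is None:
        raise ValueError("estimate_thresholds must run before segment_fruits")
    idx = tree.indices
    c = field.curvature[idx]
    r = field.reflectance[idx]
    cand = idx[(c >= field.curvature_threshold) & (r >= field.reflectance_threshold)]
    if len(cand) == 0:
        return []
    comp = _euclidean_clusters(cloud.points[cand], cluster_eps)
    fruits: List[FruitSegment] = []
    for cid in np.unique(comp):
        members = cand[comp == cid]
        if len(members) < min_points:
            continue
        pts = cloud.points[members]
        center, radius = _fit_sphere_radius(pts)
        temps = cloud.temperature[members] if cloud.temperature is not None else np.array([])
        temps = temps[temps != sentinel] if temps.size else temps
        if temps.size:
            stats = (
                float(np.mean(temps)), float(np.min(temps)),
                float(np.max(temps)), float(np.std(temps)),
            )
        else:
            stats = (np.nan, np.nan, np.nan, np.nan)
        fruits.append(
            FruitSegment(
                indices=members,
                centroid=pts.mean(axis=0),
                radius=radius,
                fst_mean=stats[0], fst_min=stats[1], fst_max=stats[2], fst_sd=stats[3],
                n_temperature=int(temps.size),
                height=float(pts.mean(axis=0)[2]),
            )
        )
    fruits.sort(key=lambda f: (f.centroid[1], f.centroid[0]))
    return fruits


def categorize_side(
    fruits: Sequence[FruitSegment],
    row_axis=(0.0, 1.0, 0.0),
    east_normal=(1.0, 0.0, 0.0),
    row_origin=(0.0, 0.0, 0.0),
) -> List[FruitSegment]:
    """Label each fruit east/west by its centroid's offset across the row.

    The sign of ``(centroid - row_origin) · east_normal`` decides the side;
    an exact zero ties deterministically to east.
    """
    east = np.asarray(east_normal, dtype=float)
    origin = np.asarray(row_origin, dtype=float)
    for f in fruits:
        offset = float((f.centroid - origin) @ east)
        f.side = "east" if offset >= 0 else "west"
    return list(fruits)
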