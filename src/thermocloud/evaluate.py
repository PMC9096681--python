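"""Agreement and detection metrics for thermal point-cloud evaluation.

Covers the quantities the method is judged by: descriptive statistics,
regression agreement between sensor-derived and manually measured
temperatures (MBE, RMSE, adjusted R²), detection precision/recall/F1 with
one-to-one position matching, and the sphere-target report produced with
the metal evaluation tree.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Dict, List, Optional, Sequence

import numpy as np
from scipy import stats

from .io import PointCloud

__all__ = [
    "MetricsReport",
    "DetectionReport",
    "regression_metrics",
    "detection_f1",
    "sphere_report",
]


@dataclass
class MetricsReport:
    """Descriptive + regression agreement statistics.

    MBE = mean(predicted − observed); RMSE on the same differences;
    R²_adj = 1 − (1 − R²)(n − 1)/(n − p − 1) for ``p`` predictors.
    """

    n: int
    min: float
    max: float
    mean: float
    sd: float
    mbe: float
    rmse: float
    r2: float
    r2_adj: float
    slope: float
    intercept: float


@dataclass
class DetectionReport:
    tp: int
    fp: int
    fn: int
    precision: float
    recall: float
    f1: float
    matches: List[tuple] = field(default_factory=list)


def regression_metrics(observed, predicted, p: int = 1) -> MetricsReport:
    """Agreement of predicted vs observed values (n ≥ 3, n > p + 1)."""
    obs = np.asarray(observed, dtype=float).ravel()
    pred = np.asarray(predicted, dtype=float).ravel()
    if len(obs) != len(pred):
        raise ValueError("observed and predicted must have equal length")
    n = len(obs)
    if n < 3 or n <= p + 1:
        raise ValueError(f"need n > p + 1 = {p + 1} samples, got {n}")
    diff = pred - obs
    mbe = float(np.mean(diff))
    rmse = float(np.sqrt(np.mean(diff**2)))
    if np.ptp(obs) < 1e-300 or np.ptp(pred) < 1e-300:
        # constant reference: the fit is degenerate; call it perfect only
        # when the predictions coincide with it to numerical precision
        slope, intercept, r2 = 0.0, float(np.mean(pred)), 1.0 if rmse <= 1e-9 else 0.0
    else:
        lr = stats.linregress(obs, pred)
        slope, intercept, r2 = float(lr.slope), float(lr.intercept), float(lr.rvalue**2)
    r2_adj = 1.0 - (1.0 - r2) * (n - 1) / (n - p - 1)
    return MetricsReport(
        n=n,
        min=float(pred.min()), max=float(pred.max()),
        mean=float(pred.mean()), sd=float(pred.std(ddof=1)),
        mbe=mbe, rmse=rmse, r2=r2, r2_adj=float(r2_adj),
        slope=slope, intercept=intercept,
    )


def detection_f1(detected, truth, match_radius: float) -> DetectionReport:
    """Precision/recall/F1 by greedy one-to-one nearest matching.

    Detected/truth are position arrays; pairs are matched closest-first
    within ``match_radius``, each item used at most once.
    """
    if match_radius <= 0:
        raise ValueError("match_radius must be positive")
    det = np.asarray(detected, dtype=float).reshape(len(detected), -1) if len(detected) else np.zeros((0, 1))
    tru = np.asarray(truth, dtype=float).reshape(len(truth), -1) if len(truth) else np.zeros((0, 1))
    matches: List[tuple] = []
    if len(det) and len(tru):
        d = np.linalg.norm(det[:, None, :] - tru[None, :, :], axis=2)
        order = np.argsort(d, axis=None)
        used_d, used_t = set(), set()
        for flat in order:
            i, j = np.unravel_index(flat, d.shape)
            if d[i, j] > match_radius:
                break
            if i in used_d or j in used_t:
                continue
            used_d.add(int(i))
            used_t.add(int(j))
            matches.append((int(i), int(j), float(d[i, j])))
    tp = len(matches)
    fp = len(det) - tp
    fn = len(tru) - tp
    precision = tp / (tp + fp) if tp + fp else 0.0
    recall = tp / (tp + fn) if tp + fn else 0.0
    f1 = 2 * precision * recall / (precision + recall) if precision + recall else 0.0
    return DetectionReport(tp=tp, fp=fp, fn=fn, precision=float(precision), recall=float(recall), f1=float(f1), matches=matches)


def sphere_report(
    cloud: PointCloud,
    spheres: Sequence[dict],
    manual: Sequence[float],
    radius_tolerance: float = 0.01,
    sentinel: float = -10.0,
) -> Dict[str, object]:
    """Per-material temperature agreement on the sphere-target metal tree.

    ``spheres`` rows carry ``center``, ``radius``, ``material``; ``manual``
    is the per-sphere infrared-thermometer reference (°C).  Each sphere's
    points are extracted within ``radius + radius_tolerance`` of its
    centre; sphere mean temperatures are regressed per material against
    the reference.  Spheres with no points are flagged and excluded.
    """
    if cloud.temperature is None:
        raise ValueError("sphere_report needs a fused (temperature) cloud")
    rows = []
    for sphere, ref in zip(spheres, manual):
        center = np.asarray(sphere["center"], dtype=float)
        limit = float(sphere["radius"]) + radius_tolerance
        mask = np.linalg.norm(cloud.points - center, axis=1) <= limit
        temps = cloud.temperature[mask]
        temps = temps[temps != sentinel]
        row = {
            "material": sphere["material"],
            "manual": float(ref),
            "n_points": int(temps.size),
            "empty": temps.size == 0,
        }
        if temps.size:
            row.update(
                mean=float(np.mean(temps)), min=float(np.min(temps)),
                max=float(np.max(temps)), sd=float(np.std(temps)),
            )
        rows.append(row)
    report: Dict[str, object] = {"spheres": rows}
    for material in sorted({r["material"] for r in rows}):
        sub = [r for r in rows if r["material"] == material and not r["empty"]]
        if len(sub) >= 3:
            report[material] = regression_metrics(
                [r["manual"] for r in sub], [r["mean"] for r in sub]
            )
        else:
            report[material] = None
    return report
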