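"""Shared fixtures: synthetic scenes are generated once per session."""

import numpy as np
import pytest
from scipy.spatial.transform import Rotation

from thermocloud.extrinsics import calibrate_from_scans
from thermocloud.geometry import RigidTransform
from thermocloud.intrinsics import PatternSpec
from thermocloud.orchard import (
    align_tree_sides,
    categorize_side,
    curvature_features,
    detect_stems,
    estimate_thresholds,
    segment_fruits,
    segment_tree,
)
from thermocloud.simulate import (
    SensorNoise,
    default_camera,
    default_extrinsics,
    sample_board_placements,
    simulate_calibration_scene,
    simulate_orchard_row,
)


@pytest.fixture(scope="session")
def pattern():
    return PatternSpec()


@pytest.fixture(scope="session")
def calibration_scene(pattern):
    """Noiseless heated-board scene (cloud, image, truth)."""
    return simulate_calibration_scene(
        pattern, noise=SensorNoise(range_sigma=0.0, temp_sigma=0.0), seed=1
    )


@pytest.fixture(scope="session")
def extrinsic_run(pattern):
    """Full extrinsic pipeline over 10 simulated board placements.

    Range noise 5 mm, thermal noise 0.05 °C, 0.2 px feature jitter; board
    placements cover the camera frame at varied tilts.  Returns the
    ground-truth extrinsics and the selected solution.
    """
    camera = default_camera()
    ext_true = default_extrinsics(0.8)
    rng = np.random.default_rng(42)
    poses = sample_board_placements(10, rng, pattern, camera, ext_true)
    scans = []
    for pose in poses:
        cloud, image, _ = simulate_calibration_scene(
            pattern, camera, ext_true, pose,
            noise=SensorNoise(range_sigma=0.005, temp_sigma=0.05, blob_sigma_px=0.2),
            seed=int(rng.integers(2**31)),
        )
        scans.append((cloud, image))
    solution, log = calibrate_from_scans(scans, camera, pattern)
    return {
        "camera": camera,
        "true": ext_true,
        "solution": solution,
        "log": log,
    }


@pytest.fixture(scope="session")
def orchard_scene():
    """Standard synthetic orchard fixture: 5 trees x 10 fruits, fixed seed."""
    return simulate_orchard_row(seed=7)


@pytest.fixture(scope="session")
def orchard_pipeline(orchard_scene):
    """Side alignment -> stems -> curvature -> thresholds -> fruit segments."""
    (east, west), _, truth = orchard_scene
    init = truth.info["row_from_west"]
    perturbed = RigidTransform(
        Rotation.from_rotvec([0.0, 0.0, 0.02]).as_matrix() @ init.R,
        init.t + [0.01, -0.01, 0.005],
    )
    merged, icp = align_tree_sides(east, west, perturbed)
    field = curvature_features(merged, k=30)
    estimate_thresholds(field)
    stems = detect_stems(merged)
    fruits = []
    for stem in stems:
        seg = segment_tree(merged, stem, 0.45)
        fruits.extend(segment_fruits(seg, merged, field))
    fruits = categorize_side(fruits)
    return {
        "merged": merged,
        "icp": icp,
        "field": field,
        "stems": stems,
        "fruits": fruits,
        "truth": truth,
    }
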