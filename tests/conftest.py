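import numpy as np
import pytest
from hypothesis import HealthCheck, settings
from scipy.spatial import cKDTree

import sevquant as sq

settings.register_profile(
    "suite",
    deadline=None,
    derandomize=True,
    max_examples=50,
    suppress_health_check=[HealthCheck.too_slow],
)
settings.load_profile("suite")


def match_detections(det: sq.DetectionSet, truth_yx: np.ndarray, radius: float = 2.0):
    """Greedy unique matching of detections to true positions.

    Returns (n_matched, precision, recall).
    """
    if len(det) == 0:
        return 0, float("nan"), 0.0 if len(truth_yx) else float("nan")
    if len(truth_yx) == 0:
        return 0, 0.0, float("nan")
    pos = det.positions()
    tree = cKDTree(truth_yx)
    pairs = sorted(
        (d, i, j)
        for i, p in enumerate(pos)
        for d, j in [tree.query(p)]
        if d <= radius
    )
    used_d, used_t = set(), set()
    for d, i, j in pairs:
        if i not in used_d and j not in used_t:
            used_d.add(i)
            used_t.add(j)
    n = len(used_d)
    return n, n / len(det), n / len(truth_yx)


@pytest.fixture(scope="session")
def cellline_run():
    """A mid-size simulated cell-line assay shared across tests."""
    cfg = sq.SimConfig(
        image_shape=(400, 400),
        n_particles=200,
        label_fraction={"fluor_pkh67": 1.0},
        seed=11,
    )
    images, gt = sq.simulate_frame_stack(cfg)
    return cfg, images, gt


@pytest.fixture(scope="session")
def detected_run(cellline_run):
    """Detections for the shared run: last pre-wash, post-wash, fluorescence."""
    cfg, images, gt = cellline_run
    dcfg = sq.DetectionConfig()
    pre = sq.find_particles(
        sq.ratio_image(images.panorama.pre_wash()[-1], images.panorama.background), dcfg
    )
    post = sq.find_particles(
        sq.ratio_image(images.panorama.post_wash()[0], images.panorama.background), dcfg
    )
    fstack = images.fluorescence["fluor_pkh67"]
    fluor = sq.find_particles(sq.difference_image(fstack.frames[0], fstack.background), dcfg)
    return pre, post, fluor
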