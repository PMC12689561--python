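import numpy as np
import pytest

from camuquant import CalibrationConfig, SceneSpec, default_palette, generate_scene
from camuquant.scenes import NoiseSpec


@pytest.fixture
def cfg() -> CalibrationConfig:
    return CalibrationConfig()


@pytest.fixture
def palette():
    return default_palette()


@pytest.fixture
def noiseless_scene():
    """One reproducible noiseless scene plus the calibration matching its scale."""
    spec = SceneSpec(seed=42, noise=NoiseSpec())
    image, gt = generate_scene(spec)
    scene_cfg = CalibrationConfig(px_per_cm=gt.px_per_cm)
    return image, gt, scene_cfg


def match_by_center(gt, detections):
    """Pair ground-truth fruits with detections via nearest box centers."""
    pairs = []
    used = set()
    for fruit in gt.fruits:
        cx, cy = fruit.center_px
        best, best_d = None, np.inf
        for i, det in enumerate(detections):
            if i in used:
                continue
            x, y, w, h = det.bbox
            d = (x + w / 2 - cx) ** 2 + (y + h / 2 - cy) ** 2
            if d < best_d:
                best, best_d = i, d
        assert best is not None, "unmatched ground-truth fruit"
        used.add(best)
        pairs.append((fruit, detections[best]))
    return pairs
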