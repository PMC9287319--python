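import numpy as np
import pytest

from irrimap import SynthConfig, generate_scene


@pytest.fixture(scope="session")
def small_cfg():
    return SynthConfig(shape=(60, 60), n_regions=4, seed=11, clump_sigma=2.0)


@pytest.fixture(scope="session")
def small_scene(small_cfg):
    return generate_scene(small_cfg, n_samples=400)


def brute_force_allocation(ranks, pixel_area, target):
    """Independent oracle: enumerate every nonempty superlevel set and
    return (threshold, achieved_area) minimizing |area - target|, ties
    toward the smaller area (higher threshold)."""
    best = None
    for t in sorted(set(ranks), reverse=True):
        area = sum(1 for r in ranks if r >= t) * pixel_area
        gap = abs(area - target)
        if best is None or gap < best[1] - 1e-9:
            best = (t, gap, area)
    return best[0], best[2]


def savgol_center_weights(window, polyorder):
    """Independent Savitzky-Golay oracle: the center-evaluation row of
    the least-squares design-matrix pseudoinverse."""
    half = window // 2
    design = np.vander(np.arange(-half, half + 1), polyorder + 1, increasing=True)
    return np.linalg.pinv(design)[0]
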