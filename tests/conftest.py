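import numpy as np
import pytest

import teaprof as tp


@pytest.fixture(scope="session")
def low_frame():
    """Default low-light synthetic frame with ground truth (seed 7)."""
    params = tp.SceneParams(illumination="low", seed=7)
    frame, truth = tp.generate_frame(params)
    return params, frame, truth


@pytest.fixture(scope="session")
def high_frame():
    """High-light synthetic frame with specular patches (seed 11)."""
    params = tp.SceneParams(illumination="high", specular_fraction=0.05, seed=11)
    frame, truth = tp.generate_frame(params)
    return params, frame, truth


@pytest.fixture(scope="session")
def flat_frame():
    """Noiseless, hole-free, flat canopy at exactly 45 cm."""
    params = tp.SceneParams(
        canopy_arc_sag=0.0, tilt=0.0, depth_noise_sd=0.0,
        hole_fraction=0.0, canopy_arc_peak_depth=45.0, seed=3,
    )
    frame, truth = tp.generate_frame(params)
    return params, frame, truth


@pytest.fixture(scope="session")
def rig():
    return tp.RigConfig()


@pytest.fixture(scope="session")
def table():
    return tp.default_decision_table()


def brute_force_otsu(gray: np.ndarray, exclude_zero: bool = False) -> int:
    """Exhaustive 256-candidate between-class-variance maximizer (oracle)."""
    vals = gray.ravel().astype(np.float64)
    if exclude_zero:
        vals = vals[vals != 0]
    best_t, best_v = None, -1.0
    for t in range(256):
        lo = vals[vals <= t]
        hi = vals[vals > t]
        if lo.size == 0 or hi.size == 0:
            continue
        v = lo.size * hi.size * (lo.mean() - hi.mean()) ** 2
        if v > best_v + 1e-9:
            best_v, best_t = v, t
    return best_t
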