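import numpy as np
import pytest
from hypothesis import HealthCheck, settings

import granulemap as gm
from granulemap.segment import label_foci, segment_mask

settings.register_profile(
    "default",
    derandomize=True,
    deadline=None,
    suppress_health_check=[HealthCheck.too_slow],
)
settings.load_profile("default")


@pytest.fixture(scope="session")
def sted_params():
    """Small STED-like frame: quick to generate, representative."""
    return gm.GeneratorParams(
        frame_shape=(384, 384),
        n_cells=0,
        foci_channels={
            "dsRNA": gm.FociSpec(n_foci=30, mean_area=0.019),
            "BrU": gm.FociSpec(n_foci=30, mean_area=0.017),
        },
        composition=gm.OverlapComposition(0.10, 0.60, 0.30),
        seed=7,
    )


@pytest.fixture(scope="session")
def sted_frame(sted_params):
    return gm.generate_frame(sted_params)


@pytest.fixture(scope="session")
def confocal_frame():
    params = gm.GeneratorParams.confocal(n_cells=9, seed=11)
    return params, *gm.generate_frame(params)


def matched_foci(frame, params, channel, noisy):
    """Segment a foci channel with thresholds matched to the generator:
    half the planting intensity on clean frames, a quarter of it plus a
    1 px matched smoothing under noise (blur dims small foci)."""
    spec = params.foci_channels[channel]
    frac, smooth = (0.25, 1.0) if noisy else (0.5, 0.0)
    mask = segment_mask(
        frame.channel(channel),
        method="absolute",
        threshold=spec.intensity * frac,
        smooth_sigma=smooth,
        pixel_size=params.pixel_size,
    )
    return label_foci(mask, channel=channel)


def random_blob(rng, shape, n_seeds=3, n_dilate=12):
    """Random connected-ish blob raster for oracle tests."""
    raster = np.zeros(shape, dtype=bool)
    r0 = rng.integers(5, shape[0] - 5)
    c0 = rng.integers(5, shape[1] - 5)
    pts = [(r0, c0)]
    raster[r0, c0] = True
    for _ in range(n_dilate):
        r, c = pts[rng.integers(len(pts))]
        dr, dc = rng.integers(-1, 2, size=2)
        r = int(np.clip(r + dr, 0, shape[0] - 1))
        c = int(np.clip(c + dc, 0, shape[1] - 1))
        raster[r, c] = True
        pts.append((r, c))
    return raster
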