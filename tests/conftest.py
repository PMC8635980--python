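import numpy as np
import pytest
from hypothesis import HealthCheck, settings

import endokin as ek

settings.register_profile(
    "ci", derandomize=True, deadline=None,
    suppress_health_check=[HealthCheck.too_slow])
settings.load_profile("ci")


@pytest.fixture(scope="session")
def noiseless_rp():
    return ek.RenderParams(shot_noise=False, read_noise_sigma=0.0)


@pytest.fixture(scope="session")
def default_truth():
    return ek.simulate_truth(ek.MarkerKineticsParams())


@pytest.fixture(scope="session")
def noiseless_scene(default_truth, noiseless_rp):
    """Noiseless marker-only render of the default endosome."""
    return ek.render_timelapse(default_truth, None, noiseless_rp)


@pytest.fixture(scope="session")
def noiseless_sensor_scene(default_truth, noiseless_rp):
    """Noiseless render including the YFP/CFP sensor channels."""
    return ek.render_timelapse(default_truth, ek.SensorModel(), noiseless_rp)


@pytest.fixture(scope="session")
def small_conversion_scenario():
    """Five-endosome conversion scenario shared by pipeline tests."""
    from endokin.pipeline import PipelineConfig, simulate_scenario
    return simulate_scenario(
        PipelineConfig(scenario="fig4_conversion", seed=11, n_endosomes=5))


def brute_force_circle_band(cy, cx, r, shape, lo, hi):
    """Oracle: per-pixel scan selecting lo < dist-to-center - r < hi."""
    out = set()
    for y in range(shape[0]):
        for x in range(shape[1]):
            sd = np.hypot(y - cy, x - cx) - r
            if lo < sd < hi:
                out.add((y, x))
    return out


def _point_segment_distance(py, px, ay, ax, by, bx):
    vy, vx = by - ay, bx - ax
    wy, wx = py - ay, px - ax
    denom = vy * vy + vx * vx
    t = 0.0 if denom == 0 else max(0.0, min(1.0, (wy * vy + wx * vx) / denom))
    return np.hypot(py - (ay + t * vy), px - (ax + t * vx))


def _point_in_polygon(py, px, verts):
    # ray casting along +x
    inside = False
    n = len(verts)
    for i in range(n):
        ay, ax = verts[i]
        by, bx = verts[(i + 1) % n]
        if (ay > py) != (by > py):
            x_cross = ax + (py - ay) * (bx - ax) / (by - ay)
            if px < x_cross:
                inside = not inside
    return inside


def brute_force_polygon_signed_distance(verts, shape):
    """Oracle: signed distance of every pixel to a polygon outline, by
    per-segment scanning plus ray-casting containment."""
    sd = np.empty(shape)
    n = len(verts)
    for y in range(shape[0]):
        for x in range(shape[1]):
            d = min(_point_segment_distance(
                y, x, *verts[i], *verts[(i + 1) % n]) for i in range(n))
            sd[y, x] = -d if _point_in_polygon(y, x, verts) else d
    return sd
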