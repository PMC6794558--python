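import numpy as np
import pytest

from gazetess import GazeTrace, ScreenGeometry


@pytest.fixture(scope="session")
def geometry():
    """Reference screen: 1280x1024 raster, 34.7x25.9 cm, viewed at 60 cm."""
    return ScreenGeometry(1280, 1024, 34.7, 25.9, 60.0)


def make_trace(
    t,
    left,
    right=None,
    geometry=None,
    participant="p1",
    group="g1",
    stimulus="s1",
    rate=250.0,
):
    """Build a GazeTrace from coordinate lists; None marks a missing sample."""
    geometry = geometry or ScreenGeometry(1280, 1024, 34.7, 25.9, 60.0)
    if right is None:
        right = left

    def unpack(eye):
        xs, ys, valid = [], [], []
        for p in eye:
            if p is None:
                xs.append(np.nan)
                ys.append(np.nan)
                valid.append(False)
            else:
                xs.append(float(p[0]))
                ys.append(float(p[1]))
                valid.append(True)
        return np.array(xs), np.array(ys), np.array(valid)

    lx, ly, lv = unpack(left)
    rx, ry, rv = unpack(right)
    return GazeTrace(
        participant_id=participant,
        group=group,
        stimulus_id=stimulus,
        t=np.asarray(t, dtype=float),
        left_x=lx,
        left_y=ly,
        right_x=rx,
        right_y=ry,
        valid_left=lv,
        valid_right=rv,
        geometry=geometry,
        nominal_rate=rate,
    )


def random_trace(rng, geometry, n=50, missing_rate=0.1):
    """Random valid GazeTrace for round-trip properties."""
    t = np.cumsum(rng.uniform(3.0, 5.0, size=n))
    left = []
    right = []
    for _ in range(n):
        for eye in (left, right):
            if rng.random() < missing_rate:
                eye.append(None)
            else:
                eye.append(
                    (
                        rng.uniform(-50, geometry.raster_width + 50),
                        rng.uniform(-50, geometry.raster_height + 50),
                    )
                )
    return make_trace(t, left, right, geometry=geometry)
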