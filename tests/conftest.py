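import numpy as np
import pytest

import swarmspace as ss


@pytest.fixture
def rng():
    return np.random.default_rng(12345)


def rigid_translation_tracks(n_members=5, n_frames=21, dt=1.0, v=(1.0, 0.0),
                             spacing=2.0, axis="x"):
    """Members on a line translating with common velocity; polarization 1."""
    offsets = spacing * np.arange(n_members)
    t = dt * np.arange(n_frames)
    tracks = []
    for j in range(n_members):
        x0 = offsets[j] if axis == "x" else 0.0
        y0 = offsets[j] if axis == "y" else 0.0
        tracks.append(ss.RawTrack("g", f"m{j}", t, x0 + v[0] * t, y0 + v[1] * t))
    return tracks


@pytest.fixture
def rigid_series():
    return ss.process_tracks(rigid_translation_tracks(), dt=1.0)


@pytest.fixture(scope="session")
def regime_fixture():
    """[uncoordinated 30, collective 60, uncoordinated 30] s ground truth."""
    cfg = ss.RegimeConfig(
        phases=[("uncoordinated", 30.0), ("collective", 60.0),
                ("uncoordinated", 30.0)],
        base=ss.FormationConfig(n_members=8, formation="column", dt=0.5,
                                duration=60.0, seed=7))
    tracks, truth = ss.generate_regime_sequence(cfg)
    ks = ss.process_tracks(tracks, dt=0.5)
    return ks, truth


@pytest.fixture(scope="session")
def detected_events(regime_fixture):
    ks, _ = regime_fixture
    thr = ss.quantile_thresholds(ks, 0.3)
    return ss.detect_events(ks, thr, min_duration=15.0)


def random_frame(rng, n=8, scale=10.0):
    """Random positions plus headings (radians) for one frame."""
    pos = rng.uniform(-scale, scale, size=(n, 2))
    heading = rng.uniform(-np.pi, np.pi, size=n)
    return pos, heading
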