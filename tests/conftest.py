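import numpy as np
import pytest

import rnpstoich as rs


@pytest.fixture(scope="session")
def processive_trackset() -> rs.TrackSet:
    """600 purely processive tracks on identical 20-um microtubules."""
    cfg = rs.SimConfig(n_tracks=600, n_microtubules=5, mt_length_mean=20.0,
                       mt_length_sd=0.0, class_probs=(0.0, 0.0, 1.0),
                       run_length_mean=5.0, movie_duration=400.0, seed=5)
    return rs.simulate_trackset(cfg)


@pytest.fixture(scope="session")
def mixed_trackset() -> rs.TrackSet:
    """The mixed-population study condition: 500 tracks, 80% processive."""
    cfg = rs.SimConfig(n_tracks=500, class_probs=(0.1, 0.1, 0.8),
                       run_length_mean=5.0, velocity_mean=1.0,
                       localisation_sd=0.05, seed=1)
    return rs.simulate_trackset(cfg)


def make_linear_track(slopes, n_per_seg=11, dt=0.5, x0=20.0, noise=0.0,
                      seed=0, track_id="t0", mt_id="m0") -> rs.Track:
    """Piecewise-linear track: one OLS-perfect line per slope (um/s)."""
    rng = np.random.default_rng(seed)
    xs = [x0]
    for v in slopes:
        for _ in range(n_per_seg):
            xs.append(xs[-1] + v * dt)
    x = np.asarray(xs, dtype=float)
    t = np.arange(x.size) * dt
    if noise:
        x = x + rng.normal(0.0, noise, x.size)
    return rs.Track(mt_id=mt_id, track_id=track_id, channel="ch0", times=t, positions=x)
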