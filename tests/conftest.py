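"""Shared fixtures and small builders for the test suite."""

from __future__ import annotations

import numpy as np
import pytest

from chromokin.schemes import Localization, Track


def make_track(frames, xy, track_id=0, dt=1.0):
    """Track from frame indices and (x, y) pairs with t = frame * dt."""
    locs = [
        Localization(int(f), float(f) * dt, float(x), float(y))
        for f, (x, y) in zip(frames, xy)
    ]
    return Track(id=track_id, localizations=locs)


def stationary_track(frames, x=1.0, y=1.0, sigma=0.0, rng=None, dt=1.0):
    """Bound-molecule track: fixed position plus optional localization noise."""
    rng = rng or np.random.default_rng(0)
    xy = np.tile([x, y], (len(frames), 1))
    if sigma > 0:
        xy = xy + rng.normal(0.0, sigma, size=xy.shape)
    return make_track(frames, xy, dt=dt)


@pytest.fixture
def rng():
    return np.random.default_rng(12345)
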