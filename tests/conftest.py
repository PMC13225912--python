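"""Shared fixtures: hand-built tracks/sessions and a grid-rendered session."""

import numpy as np
import pytest

from synaptodyn.track_io import CHANNELS, ImagingSession, Track


def make_track(
    track_id=0,
    channel="A",
    frames=None,
    x=None,
    y=None,
    area=0.35,
    intensity_own=100.0,
    intensity_opp=20.0,
    detected=None,
    frame_interval_s=15.0,
    image_id="img0",
):
    """Build a Track from scalars or arrays with sensible defaults."""
    frames = np.arange(10) if frames is None else np.asarray(frames)
    n = len(frames)
    x = np.full(n, 5.0) if x is None else np.asarray(x, float)
    y = np.full(n, 5.0) if y is None else np.asarray(y, float)
    area = np.full(n, area) if np.isscalar(area) else np.asarray(area, float)
    own = np.full(n, intensity_own) if np.isscalar(intensity_own) else np.asarray(intensity_own, float)
    opp = np.full(n, intensity_opp) if np.isscalar(intensity_opp) else np.asarray(intensity_opp, float)
    detected = np.ones(n, bool) if detected is None else np.asarray(detected, bool)
    other = "B" if channel == "A" else "A"
    return Track(
        track_id=track_id,
        channel=channel,
        image_id=image_id,
        frame_interval_s=frame_interval_s,
        frames=frames,
        x_um=x,
        y_um=y,
        area_um2=area,
        intensity={channel: own, other: opp},
        detected=detected,
    )


def make_session(tracks_a=(), tracks_b=(), n_frames=None, treatment="control",
                 frame_interval_s=15.0, image_id="img0"):
    all_tracks = list(tracks_a) + list(tracks_b)
    if n_frames is None:
        n_frames = max(t.last_frame for t in all_tracks) + 1 if all_tracks else 1
    return ImagingSession(
        image_id=image_id,
        treatment=treatment,
        frame_interval_s=frame_interval_s,
        n_frames=n_frames,
        tracks={"A": list(tracks_a), "B": list(tracks_b)},
    )


@pytest.fixture
def grid_session():
    """Stationary puncta on a grid, well separated for unambiguous rendering."""
    rng = np.random.default_rng(0)
    tracks = []
    tid = 0
    n_frames = 120
    for i in range(3):
        for j in range(3):
            x = 4.0 + i * 6.0 + rng.uniform(-0.3, 0.3)
            y = 4.0 + j * 6.0 + rng.uniform(-0.3, 0.3)
            tracks.append(
                make_track(tid, frames=np.arange(n_frames), x=np.full(n_frames, x),
                           y=np.full(n_frames, y))
            )
            tid += 1
    return make_session(tracks_a=tracks, n_frames=n_frames)
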