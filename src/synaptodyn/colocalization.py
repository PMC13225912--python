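"""Cross-channel colocalization: distances, event detection, classification, kinematics.

Two puncta are *colocalized* when their surfaces touch or overlap — the
disk-equivalent surface gap ``max(0, |c_a - c_b| - r_a - r_b)`` (with
``r = sqrt(area / pi)``) is zero.  A *new colocalization event* is the frame
at which a focal puncta, not colocalized with a given opposite-channel
partner for the preceding 10 minutes, comes into contact and then stays in
contact for at least 95% of the frames of the following 10 minutes; events
beginning in the final 10 minutes of a session are not scored.  The partner
is identified as the opposite-channel track whose centre lies within 1 µm
of the colocalization site at the event frame and is classed *existing* if
it was already present 10 minutes before the event, else *new* — the split
between the two distinguishes capture of pre-assembled clusters from
co-assembly of nascent ones.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass
from typing import Dict, List, Optional, Sequence, Tuple

import numpy as np

from .track_io import CHANNELS, ImagingSession, PunctaObservation, Track
from .track_metrics import BleachModel, baseline_normalize, mean_velocity

logger = logging.getLogger(__name__)


def _radius(area_um2: np.ndarray) -> np.ndarray:
    return np.sqrt(np.asarray(area_um2, dtype=float) / math.pi)


def surface_gap_distance(a: PunctaObservation, b: PunctaObservation) -> float:
    """Edge-to-edge distance (µm) between two disk-equivalent surfaces; 0 = contact."""
    if a.frame != b.frame:
        raise ValueError(f"frame mismatch: {a.frame} vs {b.frame}")
    center = math.hypot(a.x_um - b.x_um, a.y_um - b.y_um)
    gap = center - math.sqrt(a.area_um2 / math.pi) - math.sqrt(b.area_um2 / math.pi)
    return max(0.0, gap)


def _track_frame_arrays(track: Track, n_frames: int) -> Tuple[np.ndarray, ...]:
    """Dense per-session-frame position/radius arrays (NaN where absent)."""
    x = np.full(n_frames, np.nan)
    y = np.full(n_frames, np.nan)
    r = np.full(n_frames, np.nan)
    x[track.frames] = track.x_um
    y[track.frames] = track.y_um
    r[track.frames] = _radius(track.area_um2)
    return x, y, r


def pairwise_gap_series(focal: Track, partner: Track, n_frames: int) -> np.ndarray:
    """Per-session-frame surface gap between two tracks (NaN where either is absent)."""
    xa, ya, ra = _track_frame_arrays(focal, n_frames)
    xb, yb, rb = _track_frame_arrays(partner, n_frames)
    gap = np.hypot(xa - xb, ya - yb) - ra - rb
    return np.maximum(gap, 0.0)


# ---------------------------------------------------------------------------
# Colocalized fluorescence
# ---------------------------------------------------------------------------

def colocalized_fluorescence(
    focal: Track,
    opposite_channel: str,
    bleach_model: Optional[BleachModel] = None,
    baseline_min: float = 3.0,
) -> np.ndarray:
    """Opposite-channel mean intensity within the focal surface, baseline-normalized.

    The tracking export measures both channels inside every surface outline,
    so the opposite-channel series of a focal track *is* the colocalized
    fluorescence.  Bleach correction (if a model is given) precedes
    normalization to the first-3-min mean.  Bridged frames stay NaN.
    """
    series = np.array(focal.intensity[opposite_channel], dtype=float)
    if bleach_model is not None:
        t_min = focal.times_s / 60.0
        f = bleach_model.predict(t_min)
        f0 = bleach_model.predict(np.array([0.0]))[0]
        if np.any(f <= 0):
            raise ValueError("bleach model non-positive over track horizon")
        series = series * (f0 / f)
    return baseline_normalize(series, focal.frame_interval_s, baseline_min)


# ---------------------------------------------------------------------------
# Event detection and classification
# ---------------------------------------------------------------------------

@dataclass
class ColocalizationEvent:
    """A persistent cross-channel pairing that began within the session."""

    image_id: str
    direction: str            # focal channel label
    focal_track_id: int
    partner_track_id: int
    event_frame: int
    event_time_min: float
    event_position: np.ndarray  # (x, y) µm, midpoint of the two centres
    persistence_fraction: float
    partner_class: Optional[str] = None  # "new" | "existing"


@dataclass
class EventKinematics:
    """Motion of the focal puncta around its colocalization event."""

    displacement_before_total: float  # µm, session start -> event site
    mean_distance_pre10: float        # µm, mean distance to event site, 10 min before
    mean_distance_post10: float       # µm, 10 min after
    mean_velocity_before: float       # µm/s, session start -> event
    pre_window_truncated: bool = False
    post_window_truncated: bool = False


def _frames_per_min(session: ImagingSession) -> float:
    return 60.0 / session.frame_interval_s


def detect_new_colocalization_events(
    session: ImagingSession,
    direction: str = "A",
    persistence_min: float = 10.0,
    persistence_frac: float = 0.95,
    history_min: float = 10.0,
    eps_um: float = 0.0,
    strict_history: bool = True,
    classify: bool = True,
    radius_um: float = 1.0,
) -> List[ColocalizationEvent]:
    """Detect new, persistent colocalization events with the given focal channel.

    For each (focal, partner) cross-channel pair, the event frame is the
    first frame ``f`` at which contact (``gap <= eps_um``) begins such that

    * the pair was non-colocalized throughout the preceding ``history_min``
      (with ``strict_history=False``, only the previous frame is required,
      the looser published phrasing);
    * the focal track existed before ``f`` (the puncta *became* colocalized);
    * the focal track persists through the following ``persistence_min`` and
      the pair is in contact in at least ``persistence_frac`` of those
      frames;
    * ``f`` leaves at least ``persistence_min`` of recording after it.

    At most one event per pair is emitted.  Partner classification (below)
    runs unless ``classify=False``; events with no candidate partner centre
    within ``radius_um`` of the site are dropped with a warning.
    """
    other = "B" if direction == "A" else "A"
    fpm = _frames_per_min(session)
    persist_frames = int(round(persistence_min * fpm))
    hist_frames = int(round(history_min * fpm))
    n = session.n_frames
    events: List[ColocalizationEvent] = []
    for focal in session.tracks.get(direction, []):
        for partner in session.tracks.get(other, []):
            gap = pairwise_gap_series(focal, partner, n)
            coloc = np.zeros(n, dtype=bool)
            both = np.isfinite(gap)
            coloc[both] = gap[both] <= eps_um
            candidates = np.flatnonzero(coloc)
            for f in candidates:
                if f <= focal.first_frame:
                    continue  # focal must have existed before contact
                if f > n - 1 - persist_frames:
                    break  # events in the final window are not analyzed
                lo = max(0, f - hist_frames) if strict_history else f - 1
                if coloc[lo:f].any():
                    continue
                if focal.last_frame < f + persist_frames:
                    continue  # focal disappears inside the window: void
                window = coloc[f + 1: f + 1 + persist_frames]
                frac = float(window.mean())
                if frac < persistence_frac:
                    continue
                pa = focal.position_at(f)
                pb = partner.position_at(f)
                events.append(
                    ColocalizationEvent(
                        image_id=session.image_id,
                        direction=direction,
                        focal_track_id=focal.track_id,
                        partner_track_id=partner.track_id,
                        event_frame=int(f),
                        event_time_min=float(f / fpm),
                        event_position=(pa + pb) / 2.0,
                        persistence_fraction=frac,
                    )
                )
                break  # one event per pair
    if classify:
        kept = []
        for ev in events:
            try:
                classify_partner(ev, session, radius_um=radius_um, history_min=history_min)
                kept.append(ev)
            except LookupError:
                logger.warning(
                    "event at frame %d (%s, focal %s): no partner centre within %.2f µm; dropped",
                    ev.event_frame, session.image_id, ev.focal_track_id, radius_um,
                )
        events = kept
    return events


def classify_partner(
    event: ColocalizationEvent,
    session: ImagingSession,
    radius_um: float = 1.0,
    history_min: float = 10.0,
) -> str:
    """Identify the partner track by the 1 µm centre-of-mass rule and class it.

    The partner is the opposite-channel track whose centre at the event
    frame lies within ``radius_um`` of the colocalization site (nearest
    centre wins; remaining ties broken by smaller track id).  The class is
    ``existing`` when the partner's first detected frame is at least
    ``history_min`` before the event frame, else ``new``.  Updates the event
    in place and returns the class.
    """
    other = "B" if event.direction == "A" else "A"
    fpm = _frames_per_min(session)
    hist_frames = int(round(history_min * fpm))
    best: Optional[Tuple[float, int, Track]] = None
    for tr in session.tracks.get(other, []):
        if not tr.has_frame(event.event_frame):
            continue
        d = float(np.hypot(*(tr.position_at(event.event_frame) - event.event_position)))
        if d <= radius_um and (best is None or (d, tr.track_id) < (best[0], best[1])):
            best = (d, tr.track_id, tr)
    if best is None:
        raise LookupError("no opposite-channel centre within radius of the event site")
    partner = best[2]
    event.partner_track_id = partner.track_id
    event.partner_class = (
        "existing" if partner.first_detected_frame <= event.event_frame - hist_frames else "new"
    )
    return event.partner_class


def event_window_kinematics(
    event: ColocalizationEvent,
    session: ImagingSession,
    window_min: float = 10.0,
) -> EventKinematics:
    """Focal-puncta motion relative to the event site, before and around the event.

    ``displacement_before_total`` is the distance from the focal position at
    its first frame (session start for full-length tracks) to the event
    site; the pre/post means average the centre-to-site distance over the
    ``window_min`` preceding/following frames the focal track covers
    (truncated windows are flagged).
    """
    focal = next(
        t for t in session.tracks[event.direction] if t.track_id == event.focal_track_id
    )
    fpm = _frames_per_min(session)
    w = int(round(window_min * fpm))
    f = event.event_frame
    site = event.event_position
    d_start = float(np.hypot(*(focal.position_at(focal.first_frame) - site)))
    dist = np.hypot(focal.x_um - site[0], focal.y_um - site[1])

    pre_mask = (focal.frames >= f - w) & (focal.frames < f)
    post_mask = (focal.frames > f) & (focal.frames <= f + w)
    pre = float(np.mean(dist[pre_mask])) if pre_mask.any() else np.nan
    post = float(np.mean(dist[post_mask])) if post_mask.any() else np.nan

    before = focal.frames <= f
    det_before = before & focal.detected
    if det_before.sum() >= 2:
        fb = focal.frames[det_before]
        xb = focal.x_um[det_before]
        yb = focal.y_um[det_before]
        steps = np.hypot(np.diff(xb), np.diff(yb))
        dts = np.diff(fb) * focal.frame_interval_s
        v = float(np.mean(steps / dts))
    else:
        v = np.nan
    return EventKinematics(
        displacement_before_total=d_start,
        mean_distance_pre10=pre,
        mean_distance_post10=post,
        mean_velocity_before=v,
        pre_window_truncated=bool(focal.first_frame > f - w),
        post_window_truncated=bool(focal.last_frame < f + w),
    )
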