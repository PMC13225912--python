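"""Reading, validation, filtering and linking of puncta track tables.

A *puncta* is one segmented fluorescent cluster (a presynaptic bouton or a
postsynaptic scaffold/receptor cluster).  Each imaging session yields, per
channel, a table of per-frame surface observations exported by the tracking
software: centroid position (µm), surface area (µm²), the mean raw
fluorescence of *both* channels measured within the surface outline, and a
flag saying whether the surface was directly segmented in that frame or
inserted by the tracker to bridge a detection gap.

This module defines the in-memory containers (:class:`PunctaObservation`,
:class:`Track`, :class:`ImagingSession`), CSV round-trip I/O, the minimum
track-duration filter, and a deterministic greedy nearest-neighbour linker.
The linker is a documented stand-in for the commercial autoregressive
tracker: it exists so the rendered-synthetic path is testable end to end,
not as a reimplementation of the original motion model.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass, field, replace
from pathlib import Path
from typing import Dict, Iterable, List, Mapping, Optional, Sequence

import numpy as np
import pandas as pd

logger = logging.getLogger(__name__)

CHANNELS = ("A", "B")
#: columns a track table must provide (fixed dialect; see ``column_aliases``)
REQUIRED_COLUMNS = (
    "track_id",
    "channel",
    "frame",
    "x_um",
    "y_um",
    "area_um2",
    "intensity_A",
    "intensity_B",
    "detected",
)


class TrackTableFormatError(ValueError):
    """Raised when a track table is missing columns or is unparseable."""


class TrackValidationError(ValueError):
    """Raised when track contents violate an invariant (e.g. frame order)."""


@dataclass
class PunctaObservation:
    """One surface at one frame.

    ``intensity`` maps channel label -> mean raw fluorescence measured within
    this surface's outline (both channels are measured within every surface).
    ``detected`` is False for tracker-bridged placeholder rows, which carry
    interpolated position/area but no intensities.
    """

    track_id: int
    channel: str
    frame: int
    time_s: float
    x_um: float
    y_um: float
    area_um2: float
    intensity: Dict[str, float]
    detected: bool = True


@dataclass
class Track:
    """Frame-ordered observations of one puncta in one channel.

    Stored columnar (NumPy arrays) for speed; :meth:`observations` gives the
    record view.  ``intensity[ch][i]`` is the mean channel-``ch`` fluorescence
    within this surface at ``frames[i]`` (NaN on bridged frames).
    """

    track_id: int
    channel: str
    image_id: str
    frame_interval_s: float
    frames: np.ndarray
    x_um: np.ndarray
    y_um: np.ndarray
    area_um2: np.ndarray
    intensity: Dict[str, np.ndarray]
    detected: np.ndarray

    def __post_init__(self) -> None:
        self.frames = np.asarray(self.frames, dtype=int)
        self.x_um = np.asarray(self.x_um, dtype=float)
        self.y_um = np.asarray(self.y_um, dtype=float)
        self.area_um2 = np.asarray(self.area_um2, dtype=float)
        self.detected = np.asarray(self.detected, dtype=bool)
        self.intensity = {k: np.asarray(v, dtype=float) for k, v in self.intensity.items()}
        if len(self.frames) == 0:
            raise TrackValidationError(f"track {self.track_id}: empty")
        if np.any(np.diff(self.frames) <= 0):
            raise TrackValidationError(
                f"track {self.track_id}: frames not strictly increasing"
            )
        if not self.detected.any():
            raise TrackValidationError(
                f"track {self.track_id}: no directly detected observation"
            )
        if np.any(self.area_um2[self.detected] <= 0):
            raise TrackValidationError(
                f"track {self.track_id}: non-positive area on a detected frame"
            )

    # -- convenience views ------------------------------------------------
    @property
    def first_frame(self) -> int:
        return int(self.frames[0])

    @property
    def last_frame(self) -> int:
        return int(self.frames[-1])

    @property
    def span_frames(self) -> int:
        """Inclusive number of frames spanned, ``f_n - f_0 + 1``."""
        return self.last_frame - self.first_frame + 1

    @property
    def duration_s(self) -> float:
        return (self.last_frame - self.first_frame) * self.frame_interval_s

    @property
    def first_detected_frame(self) -> int:
        return int(self.frames[self.detected][0])

    @property
    def times_s(self) -> np.ndarray:
        return self.frames * self.frame_interval_s

    def has_frame(self, frame: int) -> bool:
        i = np.searchsorted(self.frames, frame)
        return i < len(self.frames) and self.frames[i] == frame

    def index_of(self, frame: int) -> int:
        i = int(np.searchsorted(self.frames, frame))
        if i >= len(self.frames) or self.frames[i] != frame:
            raise KeyError(f"track {self.track_id} has no frame {frame}")
        return i

    def position_at(self, frame: int) -> np.ndarray:
        i = self.index_of(frame)
        return np.array([self.x_um[i], self.y_um[i]])

    def observations(self) -> List[PunctaObservation]:
        return [
            PunctaObservation(
                track_id=self.track_id,
                channel=self.channel,
                frame=int(f),
                time_s=float(f * self.frame_interval_s),
                x_um=float(self.x_um[i]),
                y_um=float(self.y_um[i]),
                area_um2=float(self.area_um2[i]),
                intensity={k: float(v[i]) for k, v in self.intensity.items()},
                detected=bool(self.detected[i]),
            )
            for i, f in enumerate(self.frames)
        ]


@dataclass
class ImagingSession:
    """Two-channel track set plus metadata for one imaged cell."""

    image_id: str
    treatment: str  # "control" or "sema4d"
    frame_interval_s: float
    n_frames: int
    tracks: Dict[str, List[Track]] = field(default_factory=lambda: {c: [] for c in CHANNELS})
    provenance: str = ""

    def __post_init__(self) -> None:
        for ch, tracks in self.tracks.items():
            for t in tracks:
                if t.image_id != self.image_id:
                    raise TrackValidationError(
                        f"track {t.track_id} image_id {t.image_id!r} != session {self.image_id!r}"
                    )
                if t.last_frame >= self.n_frames:
                    raise TrackValidationError(
                        f"track {t.track_id} extends past n_frames={self.n_frames}"
                    )

    def all_tracks(self) -> List[Track]:
        return [t for ch in CHANNELS for t in self.tracks.get(ch, [])]

    @property
    def duration_s(self) -> float:
        return (self.n_frames - 1) * self.frame_interval_s


# ---------------------------------------------------------------------------
# CSV I/O
# ---------------------------------------------------------------------------

def session_to_frame(session: ImagingSession) -> pd.DataFrame:
    """Flatten a session into the canonical long table."""
    rows = []
    for ch in CHANNELS:
        for t in session.tracks.get(ch, []):
            n = len(t.frames)
            rows.append(
                pd.DataFrame(
                    {
                        "track_id": np.repeat(t.track_id, n),
                        "channel": np.repeat(ch, n),
                        "frame": t.frames,
                        "x_um": t.x_um,
                        "y_um": t.y_um,
                        "area_um2": t.area_um2,
                        "intensity_A": t.intensity.get("A", np.full(n, np.nan)),
                        "intensity_B": t.intensity.get("B", np.full(n, np.nan)),
                        "detected": t.detected.astype(int),
                    }
                )
            )
    if not rows:
        return pd.DataFrame(columns=list(REQUIRED_COLUMNS))
    out = pd.concat(rows, ignore_index=True)
    return out.sort_values(["channel", "track_id", "frame"], kind="stable").reset_index(drop=True)


def write_track_table(session: ImagingSession, path) -> None:
    session_to_frame(session).to_csv(path, index=False)


def _tracks_from_frame(
    df: pd.DataFrame, image_id: str, frame_interval_s: float
) -> Dict[str, List[Track]]:
    tracks: Dict[str, List[Track]] = {c: [] for c in CHANNELS}
    for (ch, tid), g in df.groupby(["channel", "track_id"], sort=True):
        frames = g["frame"].to_numpy(dtype=int)
        if np.any(np.diff(frames) <= 0):
            raise TrackValidationError(
                f"track {tid} (channel {ch}): frames not strictly increasing"
            )
        tracks.setdefault(str(ch), []).append(
            Track(
                track_id=int(tid),
                channel=str(ch),
                image_id=image_id,
                frame_interval_s=frame_interval_s,
                frames=frames,
                x_um=g["x_um"].to_numpy(float),
                y_um=g["y_um"].to_numpy(float),
                area_um2=g["area_um2"].to_numpy(float),
                intensity={
                    "A": g["intensity_A"].to_numpy(float),
                    "B": g["intensity_B"].to_numpy(float),
                },
                detected=g["detected"].astype(bool).to_numpy(),
            )
        )
    return tracks


def read_track_table(
    path,
    metadata: Mapping,
    column_aliases: Optional[Mapping[str, str]] = None,
) -> ImagingSession:
    """Read one session's track table from CSV.

    ``metadata`` must supply ``image_id``, ``treatment`` and
    ``frame_interval_s``; ``n_frames`` is taken from metadata when present,
    else inferred as ``max(frame) + 1``.  ``column_aliases`` maps foreign
    header names onto the canonical dialect (alias -> canonical).
    """
    df = pd.read_csv(path, float_precision="round_trip")
    if column_aliases:
        df = df.rename(columns=dict(column_aliases))
    missing = [c for c in REQUIRED_COLUMNS if c not in df.columns]
    if missing:
        raise TrackTableFormatError(f"missing required column(s): {', '.join(missing)}")
    frame_interval_s = float(metadata["frame_interval_s"])
    image_id = str(metadata["image_id"])
    n_frames = int(metadata.get("n_frames") or (df["frame"].max() + 1))
    return ImagingSession(
        image_id=image_id,
        treatment=str(metadata["treatment"]),
        frame_interval_s=frame_interval_s,
        n_frames=n_frames,
        tracks=_tracks_from_frame(df, image_id, frame_interval_s),
        provenance=str(metadata.get("provenance", f"read from {Path(path).name}")),
    )


# ---------------------------------------------------------------------------
# Filtering
# ---------------------------------------------------------------------------

def filter_short_tracks(session: ImagingSession, min_duration_s: float = 60.0) -> ImagingSession:
    """Drop tracks spanning less than ``min_duration_s`` (default 60 s).

    A track spanning frames ``f_0..f_n`` lasts ``(f_n - f_0) * dt`` seconds;
    tracks at exactly the threshold are retained.  Idempotent.
    """
    if min_duration_s < 0:
        raise ValueError("min_duration_s must be >= 0")
    kept: Dict[str, List[Track]] = {}
    removed = 0
    for ch, tracks in session.tracks.items():
        kept[ch] = [t for t in tracks if t.duration_s >= min_duration_s]
        removed += len(tracks) - len(kept[ch])
    if removed:
        logger.info(
            "filter_short_tracks: removed %d track(s) shorter than %.0f s from %s",
            removed, min_duration_s, session.image_id,
        )
    return replace(session, tracks=kept)


# ---------------------------------------------------------------------------
# Greedy linker (testing surrogate for the commercial autoregressive tracker)
# ---------------------------------------------------------------------------

class _TrackBuilder:
    __slots__ = ("track_id", "obs")

    def __init__(self, track_id: int, first: PunctaObservation):
        self.track_id = track_id
        self.obs: List[PunctaObservation] = [first]

    @property
    def last(self) -> PunctaObservation:
        return self.obs[-1]


def link_detections(
    detections: Iterable[PunctaObservation],
    max_dist_um: float = 2.0,
    max_gap: int = 8,
    frame_interval_s: float = 15.0,
    image_id: str = "linked",
    channel: Optional[str] = None,
) -> List[Track]:
    """Greedy nearest-neighbour frame-to-frame linking with gap closing.

    Per frame, candidate (track-end, detection) pairs within
    ``max_dist_um * (gap + 1)`` are assigned greedily in order of increasing
    distance (ties broken by smaller track id, then detection order), which
    realises mutual-nearest-neighbour matching on each frame pair.  Track
    ends may reconnect across up to ``max_gap`` skipped frames; bridged
    frames are inserted with ``detected=False``, linearly interpolated
    position and area, and missing intensities.  Unlinked detections start
    new tracks.  This is a deterministic surrogate for the commercial
    autoregressive tracker, provided to close the synthetic rendering loop.
    """
    by_frame: Dict[int, List[PunctaObservation]] = {}
    for d in detections:
        by_frame.setdefault(int(d.frame), []).append(d)
    if not by_frame:
        return []
    if channel is None:
        channel = next(iter(by_frame.values()))[0].channel

    builders: List[_TrackBuilder] = []
    next_id = 0
    frames_sorted = sorted(by_frame)
    first_frame = frames_sorted[0]
    for d in by_frame[first_frame]:
        builders.append(_TrackBuilder(next_id, d))
        next_id += 1
    for f in frames_sorted[1:]:
        dets = by_frame[f]
        active = [b for b in builders if 0 <= f - b.last.frame - 1 <= max_gap]
        pairs = []
        for b in active:
            gap = f - b.last.frame - 1
            allowed = max_dist_um * (gap + 1)
            for j, d in enumerate(dets):
                dist = math.hypot(d.x_um - b.last.x_um, d.y_um - b.last.y_um)
                if dist <= allowed:
                    pairs.append((dist, b.track_id, j, b))
        pairs.sort(key=lambda p: (p[0], p[1], p[2]))
        used_b: set = set()
        used_d: set = set()
        for dist, tid, j, b in pairs:
            if tid in used_b or j in used_d:
                continue
            used_b.add(tid)
            used_d.add(j)
            b.obs.append(dets[j])
        for j, d in enumerate(dets):
            if j not in used_d:
                builders.append(_TrackBuilder(next_id, d))
                next_id += 1

    out: List[Track] = []
    for b in builders:
        frames, xs, ys, areas, det = [], [], [], [], []
        inten = {c: [] for c in CHANNELS}
        for prev, cur in zip(b.obs, b.obs[1:] + [None]):
            frames.append(prev.frame)
            xs.append(prev.x_um)
            ys.append(prev.y_um)
            areas.append(prev.area_um2)
            det.append(True)
            for c in CHANNELS:
                inten[c].append(prev.intensity.get(c, np.nan))
            if cur is not None and cur.frame > prev.frame + 1:
                # bridge the gap: interpolate position and area, intensities missing
                for g in range(prev.frame + 1, cur.frame):
                    w = (g - prev.frame) / (cur.frame - prev.frame)
                    frames.append(g)
                    xs.append(prev.x_um + w * (cur.x_um - prev.x_um))
                    ys.append(prev.y_um + w * (cur.y_um - prev.y_um))
                    areas.append(prev.area_um2 + w * (cur.area_um2 - prev.area_um2))
                    det.append(False)
                    for c in CHANNELS:
                        inten[c].append(np.nan)
        out.append(
            Track(
                track_id=b.track_id,
                channel=channel,
                image_id=image_id,
                frame_interval_s=frame_interval_s,
                frames=np.array(frames),
                x_um=np.array(xs),
                y_um=np.array(ys),
                area_um2=np.array(areas),
                intensity={c: np.array(v) for c, v in inten.items()},
                detected=np.array(det),
            )
        )
    return out
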