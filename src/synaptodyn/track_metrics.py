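"""Per-track stability, kinematics, fluorescence features and photobleach correction.

Stability
    The fraction of frames, within the interval a puncta was tracked, in
    which it was *directly* segmented (tracker-bridged gap frames count
    toward the interval but not the numerator).  A puncta detected in every
    spanned frame scores exactly 1 whatever its duration, so stability
    measures signal consistency, not lifetime.

Photobleaching
    Fluorophores fade under repeated illumination.  The across-puncta mean
    intensity of the *control* arm is fitted with a monoexponential decay
    ``F(t) = A exp(-k t) + C`` (t in minutes) and every measured intensity is
    rescaled by ``F(t0) / F(t)``, which restores a flat mean for pure
    bleaching and is then applied to all treatment arms alike.

Intensity time courses are finally normalized to the mean of the first
3 minutes of the session (12 frames at a 15 s interval) so that changes read
as fold of baseline.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field, replace
from typing import Dict, Iterable, List, Optional, Sequence, Tuple

import numpy as np
from scipy.optimize import curve_fit

from .track_io import CHANNELS, ImagingSession, Track

logger = logging.getLogger(__name__)


class TrackWindowError(ValueError):
    """Raised when a track does not cover a required analysis window."""


class BaselineError(ValueError):
    """Raised when a baseline mean is non-positive or unavailable."""


# ---------------------------------------------------------------------------
# Stability and kinematics
# ---------------------------------------------------------------------------

def compute_stability(track: Track) -> float:
    """Detected-frame fraction over the inclusive spanned-frame count.

    ``stability = n_detected / (f_n - f_0 + 1)`` — bridged frames are part of
    the span but excluded from the numerator, so a gapless track of any
    duration scores exactly 1.
    """
    return float(track.detected.sum()) / track.span_frames


def displacement_from_origin(track: Track, t_start_s: float = 600.0) -> np.ndarray:
    """Per-frame distance (µm) from the track's position at the analysis start.

    The reference is the first frame at or after ``t_start_s`` (default
    10 min, where mobility analysis begins); bridged frames contribute their
    interpolated positions.  Raises :class:`TrackWindowError` if the track is
    absent at the start time.
    """
    times = track.times_s
    mask = times >= t_start_s
    if not mask.any() or times[0] > t_start_s:
        raise TrackWindowError(
            f"track {track.track_id} does not span the analysis start t={t_start_s} s"
        )
    xs = track.x_um[mask]
    ys = track.y_um[mask]
    return np.hypot(xs - xs[0], ys - ys[0])


def mean_velocity(track: Track) -> float:
    """Mean speed (µm/s) over consecutive detected-frame pairs."""
    det = track.detected
    if det.sum() < 2:
        return np.nan
    f = track.frames[det]
    x = track.x_um[det]
    y = track.y_um[det]
    d = np.hypot(np.diff(x), np.diff(y))
    dt = np.diff(f) * track.frame_interval_s
    return float(np.mean(d / dt))


def euclidean_net(track: Track, frame_a: Optional[int] = None, frame_b: Optional[int] = None) -> float:
    """Net displacement (µm) between two chosen frames (default: first/last detected)."""
    det_frames = track.frames[track.detected]
    fa = det_frames[0] if frame_a is None else frame_a
    fb = det_frames[-1] if frame_b is None else frame_b
    pa = track.position_at(int(fa))
    pb = track.position_at(int(fb))
    return float(np.hypot(*(pb - pa)))


# ---------------------------------------------------------------------------
# Photobleach model
# ---------------------------------------------------------------------------

@dataclass
class BleachModel:
    """Monoexponential photobleach model ``F(t) = A exp(-k t) + C``, t in minutes."""

    A: float
    k: float  # per minute, >= 0
    C: float
    channel: str
    residual_rms: float = 0.0
    n_points: int = 0
    no_bleach: bool = False

    def predict(self, t_min: np.ndarray) -> np.ndarray:
        return self.A * np.exp(-self.k * np.asarray(t_min, dtype=float)) + self.C


def mean_intensity_series(
    sessions: Sequence[ImagingSession], channel: str, detected_only: bool = True
) -> Tuple[np.ndarray, np.ndarray]:
    """Across-puncta mean of channel intensity per frame, pooled over sessions.

    Each surface of the given channel contributes its own-channel mean
    intensity at each frame it is (directly) detected; the returned series is
    the mean over contributing surfaces per frame, with the common time axis
    in minutes.
    """
    n_frames = max(s.n_frames for s in sessions)
    total = np.zeros(n_frames)
    count = np.zeros(n_frames)
    for s in sessions:
        for t in s.tracks.get(channel, []):
            vals = t.intensity[channel]
            mask = (t.detected if detected_only else np.ones(len(vals), bool)) & np.isfinite(vals)
            np.add.at(total, t.frames[mask], vals[mask])
            np.add.at(count, t.frames[mask], 1)
    with np.errstate(invalid="ignore"):
        series = np.where(count > 0, total / np.maximum(count, 1), np.nan)
    dt_min = sessions[0].frame_interval_s / 60.0
    t_min = np.arange(n_frames) * dt_min
    return t_min, series


def fit_bleach_model(
    control_sessions: Sequence[ImagingSession], channel: str
) -> BleachModel:
    """Fit ``F(t) = A exp(-k t) + C`` to the control-arm mean intensity.

    Initialization: ``A0 = F(0) - F(end)``, ``C0 = F(end)``, ``k0`` from a
    log-linear fit of ``F - C0``; ``k`` is bounded at 0.  A series whose end
    is not below its start is flagged ``no_bleach`` and returned as the flat
    model ``(A=0, k=0, C=mean)``.
    """
    t_min, series = mean_intensity_series(control_sessions, channel)
    ok = np.isfinite(series)
    t, y = t_min[ok], series[ok]
    if len(y) < 4:
        raise ValueError("too few frames with intensity to fit a bleach model")
    head = float(np.mean(y[: max(1, len(y) // 20)]))
    tail = float(np.mean(y[-max(1, len(y) // 20):]))
    if tail >= head:
        logger.info("fit_bleach_model: non-decreasing series for channel %s; no-bleach", channel)
        return BleachModel(A=0.0, k=0.0, C=float(np.mean(y)), channel=channel,
                           residual_rms=float(np.std(y)), n_points=len(y), no_bleach=True)
    A0 = head - tail
    C0 = tail
    resid = y - C0
    pos = resid > 0
    if pos.sum() >= 2:
        slope = np.polyfit(t[pos], np.log(resid[pos]), 1)[0]
        k0 = max(1e-4, -slope)
    else:
        k0 = 0.01
    popt, _ = curve_fit(
        lambda tt, A, k, C: A * np.exp(-k * tt) + C,
        t, y, p0=[A0, k0, C0],
        bounds=([0.0, 0.0, -np.inf], [np.inf, np.inf, np.inf]),
        maxfev=20000,
    )
    pred = popt[0] * np.exp(-popt[1] * t) + popt[2]
    return BleachModel(
        A=float(popt[0]), k=float(popt[1]), C=float(popt[2]), channel=channel,
        residual_rms=float(np.sqrt(np.mean((y - pred) ** 2))), n_points=len(y),
    )


def correct_bleach(session: ImagingSession, model: BleachModel) -> ImagingSession:
    """Rescale every intensity of the model's channel by ``F(t0)/F(t)``.

    The correction applies to the model channel's intensity as measured in
    surfaces of *both* channels (the channel bleaches wherever it is read
    out).  Frame-0 intensities are unchanged.  An evaluated ``F(t) <= 0``
    anywhere inside the session horizon invalidates the model.
    """
    t_min = np.arange(session.n_frames) * session.frame_interval_s / 60.0
    f = model.predict(t_min)
    if np.any(f <= 0):
        raise ValueError(
            f"bleach model for channel {model.channel} non-positive inside session horizon"
        )
    factor = f[0] / f
    new_tracks: Dict[str, List[Track]] = {}
    for ch, tracks in session.tracks.items():
        out = []
        for tr in tracks:
            inten = dict(tr.intensity)
            inten[model.channel] = tr.intensity[model.channel] * factor[tr.frames]
            out.append(replace(tr, intensity=inten))
        new_tracks[ch] = out
    return replace(session, tracks=new_tracks)


def apply_bleach(session: ImagingSession, model: BleachModel) -> ImagingSession:
    """Inverse of :func:`correct_bleach` (multiplies by ``F(t)/F(t0)``); test harness."""
    t_min = np.arange(session.n_frames) * session.frame_interval_s / 60.0
    f = model.predict(t_min)
    factor = f / f[0]
    new_tracks: Dict[str, List[Track]] = {}
    for ch, tracks in session.tracks.items():
        out = []
        for tr in tracks:
            inten = dict(tr.intensity)
            inten[model.channel] = tr.intensity[model.channel] * factor[tr.frames]
            out.append(replace(tr, intensity=inten))
        new_tracks[ch] = out
    return replace(session, tracks=new_tracks)


# ---------------------------------------------------------------------------
# Baseline normalization and fluorescence features
# ---------------------------------------------------------------------------

def baseline_normalize(
    series: np.ndarray, frame_interval_s: float, baseline_min: float = 3.0
) -> np.ndarray:
    """Divide a per-frame series by its mean over the first ``baseline_min`` minutes.

    At a 15 s interval the 3 min baseline covers 12 frames.  NaNs inside the
    baseline are ignored; a non-positive (or all-missing) baseline mean
    raises :class:`BaselineError`.
    """
    series = np.asarray(series, dtype=float)
    n_base = int(round(baseline_min * 60.0 / frame_interval_s))
    if len(series) < n_base:
        raise BaselineError("series shorter than the baseline window")
    base = series[:n_base]
    if not np.isfinite(base).any():
        raise BaselineError("baseline window has no finite values")
    m = float(np.nanmean(base))
    if m <= 0:
        raise BaselineError(f"baseline mean {m} <= 0")
    return series / m


@dataclass
class TrackFeatures:
    """Scalar per-track features; fluorescence features use detected frames only."""

    track_id: int
    channel: str
    stability: float
    duration_s: float
    mean_velocity: float
    euclidean_net: float
    raw_change: float = np.nan       # F_end - F_0
    fold_change: float = np.nan      # F_end / F_0
    peak_fold_change: float = np.nan  # F_max / F_0
    fluorescence_defined: bool = True


def fluorescence_features(track: Track, channel: str) -> Tuple[float, float, float, bool]:
    """(raw_change, fold_change, peak_fold_change, defined) on detected frames.

    ``F_0``/``F_end`` are the first/last detected intensities, ``F_max`` the
    detected-frame maximum; a non-positive or missing ``F_0`` leaves the
    features undefined (NaN, flagged).
    """
    vals = track.intensity[channel][track.detected]
    vals = vals[np.isfinite(vals)]
    if len(vals) == 0 or vals[0] <= 0:
        return np.nan, np.nan, np.nan, False
    f0, fend, fmax = vals[0], vals[-1], vals.max()
    return float(fend - f0), float(fend / f0), float(fmax / f0), True


def compute_track_features(track: Track, channel: Optional[str] = None) -> TrackFeatures:
    """All scalar features for one track (fluorescence read in ``channel``, default own)."""
    ch = channel or track.channel
    raw, fold, peak, ok = fluorescence_features(track, ch)
    return TrackFeatures(
        track_id=track.track_id,
        channel=track.channel,
        stability=compute_stability(track),
        duration_s=track.duration_s,
        mean_velocity=mean_velocity(track),
        euclidean_net=euclidean_net(track),
        raw_change=raw,
        fold_change=fold,
        peak_fold_change=peak,
        fluorescence_defined=ok,
    )
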