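"""Ground-truth synthetic imaging sessions for end-to-end pipeline validation.

No public dataset accompanies this kind of two-channel puncta live imaging,
so validation rests on a generator that emits sessions with *known* latent
structure, shaped like the real data:

* a majority-immobile puncta population (confined random walks on a short
  tether) with a mobile minority on a long tether, giving the heavy-tailed
  displacement distribution seen in axonal boutons;
* a treatment arm whose channel-A mobile puncta step size is multiplied
  after an onset time (default 20 min), the signature the mixed-model stage
  must detect as a time x treatment interaction;
* stochastic per-frame detection dropout, exercising the stability metric;
* monoexponential photobleaching per channel, plus intensity noise;
* planted persistent colocalization events with "new" vs "existing" partner
  provenance satisfying the detector's definitions by construction, and
  transient crossings that must be rejected;
* receptor-recruitment ramps planted on a chosen fraction of channel-B
  scaffolds, optionally restricted to the bottom quintile of baseline
  opposite-channel signal (receptor-poor scaffolds).

All randomness flows from ``(seed, arm, image_index)`` through
``numpy.random.default_rng`` SeedSequence spawning, so identical scenarios
are byte-identical on disk.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, replace
from typing import Dict, List, Optional, Sequence, Tuple

import numpy as np

from .registration import PIXEL_UM, TPSTransform
from .track_io import CHANNELS, ImagingSession, Track

_ARM_CODE = {"control": 0, "sema4d": 1}


@dataclass
class BleachParams:
    A: float
    k: float  # per minute
    C: float

    def factor(self, t_min: np.ndarray) -> np.ndarray:
        """Bleach attenuation normalized to 1 at t = 0."""
        f = self.A * np.exp(-self.k * np.asarray(t_min, float)) + self.C
        return f / (self.A + self.C)


@dataclass
class SyntheticScenario:
    """Study conditions for one simulated two-arm experiment.

    Defaults mirror a desk-scale version of the live-imaging design: 60 min
    sessions at 15 s frames, ~35 channel-A puncta per image and 10 images
    per arm (~350 tracks/arm), ~90% of puncta immobile, treatment doubling
    the mobile step size from 20 min onward.
    """

    seed: int = 0
    n_images_per_arm: int = 10
    n_frames: int = 240
    frame_interval_s: float = 15.0
    n_puncta_a: int = 35
    n_puncta_b: int = 30
    canvas_um: Tuple[float, float] = (64.0, 64.0)

    # motion model: confined (tethered, reflecting) Gaussian random walk
    mobile_fraction: float = 0.10
    sigma_immobile_um: float = 0.05   # per-axis step SD per frame
    sigma_mobile_um: float = 0.12
    tether_immobile_um: float = 0.35  # reflection radius
    tether_mobile_um: float = 6.0
    treatment_multiplier: float = 2.0  # on channel-A mobile step SD after onset
    onset_min: float = 20.0

    # detection and intensity
    dropout_p: float = 0.05
    bleach: Dict[str, BleachParams] = field(
        default_factory=lambda: {
            "A": BleachParams(A=100.0, k=0.02, C=50.0),
            "B": BleachParams(A=80.0, k=0.015, C=60.0),
        }
    )
    base_intensity_mean: float = 100.0
    base_intensity_sd: float = 25.0
    opposite_background: float = 20.0
    intensity_noise_sd: float = 0.02  # fraction of the instantaneous level
    area_mean_um2: float = 0.35
    area_sd_um2: float = 0.08

    # planted colocalization events
    n_planted_events: int = 0
    event_new_fraction: float = 0.75
    event_times_min: Optional[Sequence[float]] = None
    approach_speed_um_min: float = 0.6
    approach_start_dist_um: float = 3.0
    new_partner_lead_min: float = 5.0  # "new" partners appear this long before the event
    n_transient_crossings: int = 0
    transient_duration_min: float = 2.0

    # receptor-recruitment ramps on channel-B scaffolds
    recruit_fraction_control: float = 0.0
    recruit_fraction_treated: float = 0.0
    recruit_amplitude: float = 2.0
    recruit_start_min: float = 10.0
    recruit_bottom_quintile_only: bool = True
    receptor_baseline_sd_log: float = 0.6  # log-normal spread of scaffold receptor baselines

    def __post_init__(self) -> None:
        if not (0 <= self.mobile_fraction <= 1 and 0 <= self.dropout_p <= 1):
            raise ValueError("probabilities must lie in [0, 1]")
        if self.onset_min * 60 >= self.n_frames * self.frame_interval_s:
            raise ValueError("treatment onset must fall inside the session")
        self._validate_events()

    # -- derived quantities ------------------------------------------------
    @property
    def session_min(self) -> float:
        return (self.n_frames - 1) * self.frame_interval_s / 60.0

    @property
    def frames_per_min(self) -> float:
        return 60.0 / self.frame_interval_s

    def _validate_events(self) -> None:
        if self.event_times_min is not None and len(self.event_times_min) != self.n_planted_events:
            raise ValueError("event_times_min length must equal n_planted_events")
        for t in self.planted_event_times_min():
            if t < 10.0 + 1.0 / self.frames_per_min:
                raise ValueError(f"planted event at {t} min leaves no non-colocalized history")
            if t > self.session_min - 10.0:
                raise ValueError(
                    f"planted event at {t} min falls in the final 10 min (infeasible plant)"
                )

    def planted_event_times_min(self) -> List[float]:
        if self.n_planted_events == 0:
            return []
        if self.event_times_min is not None:
            return list(self.event_times_min)
        # evenly spread inside the analyzable window
        lo, hi = 15.0, self.session_min - 12.0
        if hi <= lo:
            raise ValueError("session too short for planted events")
        return list(np.linspace(lo, hi, self.n_planted_events))


def default_scenario(**overrides) -> SyntheticScenario:
    """Paper-scale two-arm study: mobility shift plus events and recruitment."""
    base = dict(
        n_planted_events=4,
        recruit_fraction_control=0.04,
        recruit_fraction_treated=0.115,
    )
    base.update(overrides)
    return SyntheticScenario(**base)


def small_scenario(**overrides) -> SyntheticScenario:
    """Fast preset (~50 channel-A tracks/arm, 120 frames) for test suites."""
    base = dict(
        n_images_per_arm=3,
        n_frames=120,
        n_puncta_a=17,
        n_puncta_b=14,
        onset_min=10.0,
    )
    base.update(overrides)
    return SyntheticScenario(**base)


@dataclass
class GroundTruth:
    """Latent quantities a pipeline stage should recover."""

    motion_class: Dict[str, Dict[int, str]] = field(default_factory=dict)  # image -> track -> class
    events: List[dict] = field(default_factory=list)
    bleach: Dict[str, BleachParams] = field(default_factory=dict)
    recruited: Dict[str, List[int]] = field(default_factory=dict)  # image -> channel-B track ids
    receptor_baseline: Dict[str, Dict[int, float]] = field(default_factory=dict)


# ---------------------------------------------------------------------------
# Track synthesis
# ---------------------------------------------------------------------------

def _confined_walk(
    rng: np.random.Generator,
    centers: np.ndarray,      # (n, 2)
    radius: np.ndarray,       # (n,)
    sigma: np.ndarray,        # (n, n_frames - 1) per-frame step SD
    n_frames: int,
) -> np.ndarray:
    """Reflected Gaussian random walk inside per-puncta tether disks; (n, n_frames, 2)."""
    n = len(centers)
    pos = np.empty((n, n_frames, 2))
    # start at a uniform point inside 0.8 x tether (quasi-equilibrated)
    theta = rng.uniform(0, 2 * math.pi, n)
    rr = radius * 0.8 * np.sqrt(rng.uniform(0, 1, n))
    pos[:, 0, 0] = centers[:, 0] + rr * np.cos(theta)
    pos[:, 0, 1] = centers[:, 1] + rr * np.sin(theta)
    steps = rng.normal(size=(n, n_frames - 1, 2)) * sigma[:, :, None]
    for f in range(1, n_frames):
        p = pos[:, f - 1] + steps[:, f - 1]
        d = p - centers
        r = np.hypot(d[:, 0], d[:, 1])
        over = r > radius
        if over.any():
            scale = (2 * radius[over] - r[over]) / r[over]  # radial reflection
            p[over] = centers[over] + d[over] * scale[:, None]
        pos[:, f] = p
    return pos


def _intensity(
    rng: np.random.Generator,
    base: np.ndarray,        # (n,) per-track base level
    bleach: BleachParams,
    t_min: np.ndarray,
    noise_sd: float,
    ramp: Optional[np.ndarray] = None,  # (n, n_frames) multiplicative
) -> np.ndarray:
    level = base[:, None] * bleach.factor(t_min)[None, :]
    if ramp is not None:
        level = level * ramp
    if noise_sd > 0:
        level = level * (1 + rng.normal(0, noise_sd, level.shape))
    return np.maximum(level, 0.0)


def _dropout(rng: np.random.Generator, n: int, n_frames: int, p: float) -> np.ndarray:
    det = rng.random((n, n_frames)) >= p
    det[:, 0] = True   # track endpoints are always directly detected
    det[:, -1] = True
    return det


def generate_session(
    scenario: SyntheticScenario,
    image_index: int,
    treatment: str = "control",
) -> Tuple[ImagingSession, GroundTruth]:
    """Generate one two-channel session plus its ground truth.

    Reproducible given ``(scenario.seed, treatment, image_index)``.  Planted
    event pairs live on a reserved margin strip of the canvas so background
    puncta can neither mask nor contaminate them.
    """
    if treatment not in _ARM_CODE:
        raise ValueError(f"unknown treatment {treatment!r}")
    rng = np.random.default_rng([scenario.seed, _ARM_CODE[treatment], image_index])
    image_id = f"{treatment}_{image_index:02d}"
    nf = scenario.n_frames
    t_min = np.arange(nf) * scenario.frame_interval_s / 60.0
    onset_frame = int(round(scenario.onset_min * scenario.frames_per_min))
    w, h = scenario.canvas_um
    margin_strip = 10.0  # reserved for planted pairs
    gt = GroundTruth(bleach=dict(scenario.bleach))
    gt.motion_class[image_id] = {}
    gt.receptor_baseline[image_id] = {}
    gt.recruited[image_id] = []

    tracks: Dict[str, List[Track]] = {"A": [], "B": []}
    next_id = {"A": 0, "B": 0}

    def _add_track(channel: str, frames, xy, area, inten, det) -> Track:
        tr = Track(
            track_id=next_id[channel],
            channel=channel,
            image_id=image_id,
            frame_interval_s=scenario.frame_interval_s,
            frames=np.asarray(frames),
            x_um=xy[:, 0],
            y_um=xy[:, 1],
            area_um2=area,
            intensity=inten,
            detected=det,
        )
        next_id[channel] += 1
        tracks[channel].append(tr)
        return tr

    # -- background population per channel --------------------------------
    for ch, n_ch in (("A", scenario.n_puncta_a), ("B", scenario.n_puncta_b)):
        n_mobile = int(round(n_ch * scenario.mobile_fraction))
        classes = np.array(["immobile"] * (n_ch - n_mobile) + ["mobile"] * n_mobile)
        rng.shuffle(classes)
        mobile = classes == "mobile"
        radius = np.where(mobile, scenario.tether_mobile_um, scenario.tether_immobile_um)
        # keep every walk inside the canvas; reserve the strip only when pairs are planted
        strip = margin_strip if (scenario.n_planted_events or scenario.n_transient_crossings) else 0.0
        centers = np.column_stack(
            [
                rng.uniform(radius, w - radius),
                rng.uniform(strip + radius, h - radius),
            ]
        )
        sigma = np.where(mobile, scenario.sigma_mobile_um, scenario.sigma_immobile_um)
        sig = np.repeat(sigma[:, None], nf - 1, axis=1)
        if treatment == "sema4d" and ch == "A":
            # step multiplier for mobile puncta from the onset frame onward
            sig[mobile, max(onset_frame - 1, 0):] *= scenario.treatment_multiplier
        pos = _confined_walk(rng, centers, radius, sig, nf)
        areas = np.maximum(
            rng.normal(scenario.area_mean_um2, scenario.area_sd_um2, n_ch), 0.05
        )
        base = np.maximum(
            rng.normal(scenario.base_intensity_mean, scenario.base_intensity_sd, n_ch), 10.0
        )
        own = _intensity(rng, base, scenario.bleach[ch], t_min, scenario.intensity_noise_sd)
        opp_ch = "B" if ch == "A" else "A"
        if ch == "B":
            # receptor baseline within scaffold outlines (log-normal spread)
            r0 = scenario.opposite_background * np.exp(
                rng.normal(0.0, scenario.receptor_baseline_sd_log, n_ch)
            )
            frac = (
                scenario.recruit_fraction_treated
                if treatment == "sema4d"
                else scenario.recruit_fraction_control
            )
            n_recruit = int(round(frac * n_ch))
            ramp = np.ones((n_ch, nf))
            recruit_ids: List[int] = []
            if n_recruit > 0:
                if scenario.recruit_bottom_quintile_only:
                    pool = np.argsort(r0, kind="stable")[: max(n_ch // 5, n_recruit)]
                else:
                    pool = np.arange(n_ch)
                chosen = rng.choice(pool, size=n_recruit, replace=False)
                t0 = scenario.recruit_start_min
                span = max(scenario.session_min - t0, 1e-9)
                prog = np.clip((t_min - t0) / span, 0.0, 1.0)
                ramp[chosen] = 1.0 + (scenario.recruit_amplitude - 1.0) * prog[None, :]
                recruit_ids = sorted(int(i) for i in chosen)
            opp = _intensity(
                rng, r0, scenario.bleach[opp_ch], t_min, scenario.intensity_noise_sd, ramp
            )
        else:
            r0 = np.full(n_ch, scenario.opposite_background)
            opp = _intensity(rng, r0, scenario.bleach[opp_ch], t_min, scenario.intensity_noise_sd)
        det = _dropout(rng, n_ch, nf, scenario.dropout_p)
        for i in range(n_ch):
            inten = {ch: own[i], opp_ch: opp[i]}
            tr = _add_track(ch, np.arange(nf), pos[i], np.full(nf, areas[i]), inten, det[i])
            gt.motion_class[image_id][tr.track_id] = (
                f"{ch}:{classes[i]}"
            )
            if ch == "B":
                gt.receptor_baseline[image_id][tr.track_id] = float(r0[i])
                if i in set(recruit_ids):
                    gt.recruited[image_id].append(tr.track_id)

    # -- planted colocalization events (reserved strip) --------------------
    ev_times = scenario.planted_event_times_min()
    n_new = int(round(scenario.event_new_fraction * len(ev_times)))
    classes_ev = ["new"] * n_new + ["existing"] * (len(ev_times) - n_new)
    sites_x = np.linspace(6.0, w - 6.0, max(len(ev_times) + scenario.n_transient_crossings, 2))
    area_ev = scenario.area_mean_um2
    r_ev = math.sqrt(area_ev / math.pi)
    contact = 2 * r_ev
    v_frame = scenario.approach_speed_um_min / scenario.frames_per_min
    for j, (t_ev, cls) in enumerate(zip(ev_times, classes_ev)):
        f_ev = int(round(t_ev * scenario.frames_per_min))
        site = np.array([sites_x[j], margin_strip / 2.0])
        # partner (channel B): stationary at the site
        if cls == "existing":
            p_frames = np.arange(nf)
        else:
            f_first = max(0, f_ev - int(round(scenario.new_partner_lead_min * scenario.frames_per_min)))
            p_frames = np.arange(f_first, nf)
        p_xy = np.tile(site, (len(p_frames), 1))
        base_p = np.array([scenario.base_intensity_mean])
        own_p = _intensity(rng, base_p, scenario.bleach["B"], t_min[p_frames], scenario.intensity_noise_sd)[0]
        opp_p = _intensity(rng, np.array([scenario.opposite_background]), scenario.bleach["A"],
                           t_min[p_frames], scenario.intensity_noise_sd)[0]
        partner = _add_track(
            "B", p_frames, p_xy, np.full(len(p_frames), area_ev),
            {"B": own_p, "A": opp_p}, np.ones(len(p_frames), bool),
        )
        # focal (channel A): approach along +x and dock with slight overlap
        dist = np.empty(nf)
        pre = np.arange(nf) < f_ev
        dist[pre] = contact + v_frame * (f_ev - np.arange(nf)[pre])
        dist[~pre] = 0.8 * contact  # gap exactly 0 from the event frame on
        dist = np.minimum(dist, contact + scenario.approach_start_dist_um)
        f_xy = np.column_stack([site[0] + dist, np.full(nf, site[1])])
        own_f = _intensity(rng, base_p, scenario.bleach["A"], t_min, scenario.intensity_noise_sd)[0]
        opp_f = _intensity(rng, np.array([scenario.opposite_background]), scenario.bleach["B"],
                           t_min, scenario.intensity_noise_sd)[0]
        focal = _add_track(
            "A", np.arange(nf), f_xy, np.full(nf, area_ev),
            {"A": own_f, "B": opp_f}, np.ones(nf, bool),
        )
        gt.events.append(
            dict(
                image_id=image_id,
                direction="A",
                focal_track_id=focal.track_id,
                partner_track_id=partner.track_id,
                event_frame=f_ev,
                partner_class=cls,
            )
        )

    # -- transient crossings (must NOT be detected) ------------------------
    for j in range(scenario.n_transient_crossings):
        site = np.array([sites_x[len(ev_times) + j], margin_strip / 2.0])
        f_cross = nf // 2 + 3 * j
        dur = int(round(scenario.transient_duration_min * scenario.frames_per_min))
        p_xy = np.tile(site, (nf, 1))
        partner = _add_track(
            "B", np.arange(nf), p_xy, np.full(nf, area_ev),
            {"B": _intensity(rng, np.array([scenario.base_intensity_mean]), scenario.bleach["B"], t_min, 0)[0],
             "A": np.full(nf, scenario.opposite_background)},
            np.ones(nf, bool),
        )
        dist = np.full(nf, contact + scenario.approach_start_dist_um)
        inside = (np.arange(nf) >= f_cross) & (np.arange(nf) < f_cross + dur)
        dist[inside] = 0.8 * contact
        f_xy = np.column_stack([site[0] + dist, np.full(nf, site[1])])
        _add_track(
            "A", np.arange(nf), f_xy, np.full(nf, area_ev),
            {"A": _intensity(rng, np.array([scenario.base_intensity_mean]), scenario.bleach["A"], t_min, 0)[0],
             "B": np.full(nf, scenario.opposite_background)},
            np.ones(nf, bool),
        )

    session = ImagingSession(
        image_id=image_id,
        treatment=treatment,
        frame_interval_s=scenario.frame_interval_s,
        n_frames=nf,
        tracks=tracks,
        provenance=f"synthetic scenario seed={scenario.seed}",
    )
    return session, gt


def generate_study(scenario: SyntheticScenario) -> Tuple[List[ImagingSession], GroundTruth]:
    """Both arms of the study; ground truths merged across images."""
    sessions: List[ImagingSession] = []
    merged = GroundTruth(bleach=dict(scenario.bleach))
    for arm in ("control", "sema4d"):
        for i in range(scenario.n_images_per_arm):
            s, gt = generate_session(scenario, i, treatment=arm)
            sessions.append(s)
            merged.motion_class.update(gt.motion_class)
            merged.events.extend(gt.events)
            merged.recruited.update(gt.recruited)
            merged.receptor_baseline.update(gt.receptor_baseline)
    return sessions, merged


# ---------------------------------------------------------------------------
# Rendering and deformation (registration test harness)
# ---------------------------------------------------------------------------

def render_frames(
    session: ImagingSession,
    psf_sigma_px: float = 2.0,
    pixel_um: float = PIXEL_UM,
    channel: str = "A",
    poisson_noise: bool = False,
    rng: Optional[np.random.Generator] = None,
) -> np.ndarray:
    """Render detected puncta of one channel as 2-D Gaussian spots.

    Each detected observation contributes a Gaussian of integrated intensity
    ``mean_intensity x area / pixel_um^2`` at its centroid.  Returns a
    float stack ``(n_frames, h, w)``; positions outside the canvas raise.
    """
    # infer canvas from positions (session metadata carries µm positions only)
    all_x = np.concatenate([t.x_um for t in session.tracks.get(channel, [])])
    all_y = np.concatenate([t.y_um for t in session.tracks.get(channel, [])])
    w_px = int(math.ceil((all_x.max() + 5) / pixel_um))
    h_px = int(math.ceil((all_y.max() + 5) / pixel_um))
    stack = np.zeros((session.n_frames, h_px, w_px))
    half = int(math.ceil(4 * psf_sigma_px))
    for tr in session.tracks.get(channel, []):
        xs_px = tr.x_um / pixel_um
        ys_px = tr.y_um / pixel_um
        if np.any(xs_px < 0) or np.any(ys_px < 0) or np.any(xs_px >= w_px) or np.any(ys_px >= h_px):
            raise ValueError(f"track {tr.track_id} leaves the canvas")
        amp = tr.intensity[channel] * tr.area_um2 / pixel_um**2
        for i, f in enumerate(tr.frames):
            if not tr.detected[i] or not np.isfinite(amp[i]):
                continue
            cx, cy = xs_px[i], ys_px[i]
            x0, x1 = int(cx) - half, int(cx) + half + 1
            y0, y1 = int(cy) - half, int(cy) + half + 1
            x0c, y0c = max(x0, 0), max(y0, 0)
            x1c, y1c = min(x1, w_px), min(y1, h_px)
            yy, xx = np.mgrid[y0c:y1c, x0c:x1c]
            g = np.exp(-((xx - cx) ** 2 + (yy - cy) ** 2) / (2 * psf_sigma_px**2))
            g *= amp[i] / (2 * math.pi * psf_sigma_px**2)
            stack[f, y0c:y1c, x0c:x1c] += g
    if poisson_noise:
        rng = rng or np.random.default_rng(0)
        stack = rng.poisson(np.maximum(stack, 0)).astype(float)
    return stack


def apply_deformation(stack: np.ndarray, transform) -> np.ndarray:
    """Pull-back warp a stack with a TPS map (one map, or one per frame).

    ``deformed[f](x) = stack[f](T(x))`` sampled bilinearly — the standard
    image-warp convention, so a spot at ``p`` appears near ``T^-1(p)`` in
    the deformed output.  Used to plant known deformations that the unwarp
    stage must undo.
    """
    from scipy import ndimage

    stack = np.asarray(stack, dtype=float)
    n, h, w = stack.shape
    transforms = transform if isinstance(transform, (list, tuple)) else [transform] * n
    if len(transforms) != n:
        raise ValueError("need one transform, or one per frame")
    ys, xs = np.mgrid[0:h, 0:w]
    grid = np.column_stack([xs.ravel(), ys.ravel()]).astype(float)
    out = np.empty_like(stack)
    for f, tf in enumerate(transforms):
        if tf is None:
            out[f] = stack[f]
            continue
        mapped = tf(grid)
        coords = np.vstack([mapped[:, 1], mapped[:, 0]])
        out[f] = ndimage.map_coordinates(stack[f], coords, order=1, cval=0.0).reshape(h, w)
    return out


def measure_centroids(frame: np.ndarray, approx_positions_px: np.ndarray, window: int = 8) -> np.ndarray:
    """Intensity-weighted centroids in windows around approximate positions (px)."""
    h, w = frame.shape
    out = np.empty_like(np.atleast_2d(approx_positions_px), dtype=float)
    for i, (cx, cy) in enumerate(np.atleast_2d(approx_positions_px)):
        x0, x1 = max(int(cx) - window, 0), min(int(cx) + window + 1, w)
        y0, y1 = max(int(cy) - window, 0), min(int(cy) + window + 1, h)
        patch = frame[y0:y1, x0:x1]
        tot = patch.sum()
        if tot <= 0:
            out[i] = (np.nan, np.nan)
            continue
        yy, xx = np.mgrid[y0:y1, x0:x1]
        out[i] = ((xx * patch).sum() / tot, (yy * patch).sum() / tot)
    return out
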