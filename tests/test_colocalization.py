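"""Surface distances, colocalized fluorescence, event detection and kinematics."""

import math

import numpy as np
import pytest

from synaptodyn import synthetic_data as synth
from synaptodyn.colocalization import (
    classify_partner,
    colocalized_fluorescence,
    detect_new_colocalization_events,
    event_window_kinematics,
    surface_gap_distance,
)
from synaptodyn.track_io import PunctaObservation

from conftest import make_session, make_track


def _obs(x, y, area=math.pi, frame=0):
    return PunctaObservation(track_id=0, channel="A", frame=frame, time_s=0.0,
                             x_um=x, y_um=y, area_um2=area, intensity={"A": 1.0, "B": 1.0})


class TestSurfaceGapDistance:
    def test_tangent_disks_touch(self):
        # two disks of area pi (r = 1) with centres 2 µm apart: gap 0
        assert surface_gap_distance(_obs(0, 0), _obs(2, 0)) == 0.0

    def test_separated_disks(self):
        assert surface_gap_distance(_obs(0, 0), _obs(5, 0)) == pytest.approx(3.0)

    def test_overlap_clamps_to_zero(self):
        assert surface_gap_distance(_obs(0, 0), _obs(0.5, 0)) == 0.0

    def test_frame_mismatch_rejected(self):
        with pytest.raises(ValueError):
            surface_gap_distance(_obs(0, 0, frame=0), _obs(1, 0, frame=1))

    def test_random_pairs_match_formula(self):
        rng = np.random.default_rng(0)
        for _ in range(50):
            xa, ya, xb, yb = rng.uniform(0, 10, 4)
            aa, ab = rng.uniform(0.1, 2.0, 2)
            got = surface_gap_distance(_obs(xa, ya, aa), _obs(xb, yb, ab))
            expect = max(
                0.0,
                math.hypot(xa - xb, ya - yb)
                - math.sqrt(aa / math.pi) - math.sqrt(ab / math.pi),
            )
            assert got == pytest.approx(expect)


class TestColocalizedFluorescence:
    def test_constant_opposite_signal_normalizes_to_one(self):
        tr = make_track(frames=np.arange(40), intensity_opp=50.0)
        out = colocalized_fluorescence(tr, "B")
        np.testing.assert_allclose(out, 1.0)

    def test_planted_linear_ramp_ends_at_two(self):
        n = 240
        ramp = 20.0 * (1 + np.arange(n) / (n - 1))  # 1x -> 2x over the session
        tr = make_track(frames=np.arange(n), intensity_opp=ramp)
        out = colocalized_fluorescence(tr, "B")
        base = ramp[:12].mean() / 20.0
        assert out[-1] == pytest.approx(2.0 / base, rel=1e-9)
        assert out[-1] == pytest.approx(2.0, rel=0.05)  # within baseline-window error


def _docking_session(event_frame=100, n_frames=240, partner_first_frame=0,
                     approach_speed=0.15, start_dist=3.0):
    """Focal channel-A track approaches a stationary channel-B partner and docks."""
    area = 0.35
    r = math.sqrt(area / math.pi)
    contact = 2 * r
    site = np.array([10.0, 10.0])
    dist = np.empty(n_frames)
    idx = np.arange(n_frames)
    dist[idx < event_frame] = contact + approach_speed * (event_frame - idx[idx < event_frame])
    dist[idx >= event_frame] = 0.8 * contact
    dist = np.minimum(dist, contact + start_dist)
    focal = make_track(0, "A", frames=idx, x=site[0] + dist, y=np.full(n_frames, site[1]),
                       area=area)
    pframes = np.arange(partner_first_frame, n_frames)
    partner = make_track(0, "B", frames=pframes, x=np.full(len(pframes), site[0]),
                         y=np.full(len(pframes), site[1]), area=area)
    return make_session(tracks_a=[focal], tracks_b=[partner], n_frames=n_frames)


class TestEventDetection:
    def test_planted_docking_detected_at_docking_frame(self):
        s = _docking_session(event_frame=100)  # t = 25 min of a 60 min session
        evs = detect_new_colocalization_events(s)
        assert len(evs) == 1
        assert evs[0].event_frame == 100
        assert evs[0].persistence_fraction == 1.0

    def test_transient_crossing_rejected(self):
        n = 240
        area = 0.35
        contact = 2 * math.sqrt(area / math.pi)
        dist = np.full(n, contact + 3.0)
        dist[100:108] = 0.8 * contact  # 2 min crossing only
        focal = make_track(0, "A", frames=np.arange(n), x=10.0 + dist, y=np.full(n, 10.0),
                           area=area)
        partner = make_track(0, "B", frames=np.arange(n), x=np.full(n, 10.0),
                             y=np.full(n, 10.0), area=area)
        s = make_session(tracks_a=[focal], tracks_b=[partner], n_frames=n)
        assert detect_new_colocalization_events(s) == []

    def test_final_ten_minutes_excluded(self):
        s = _docking_session(event_frame=220)  # t = 55 min of 60: not analyzed
        assert detect_new_colocalization_events(s) == []

    def test_boundary_event_exactly_ten_minutes_before_end(self):
        s = _docking_session(event_frame=199)  # leaves exactly 40 frames = 10 min
        evs = detect_new_colocalization_events(s)
        assert [e.event_frame for e in evs] == [199]

    def test_intensity_rescaling_invariance(self):
        s = _docking_session()
        evs0 = detect_new_colocalization_events(s)
        for tr in s.all_tracks():  # geometry only: scaling intensities changes nothing
            tr.intensity = {k: v * 37.5 for k, v in tr.intensity.items()}
        evs1 = detect_new_colocalization_events(s)
        assert [(e.focal_track_id, e.event_frame) for e in evs0] == [
            (e.focal_track_id, e.event_frame) for e in evs1
        ]

    def test_persistence_threshold_monotonicity(self):
        n = 240
        area = 0.35
        contact = 2 * math.sqrt(area / math.pi)
        rng = np.random.default_rng(1)
        dist = np.full(n, contact + 3.0)
        dist[100:] = np.where(rng.random(n - 100) < 0.9, 0.8 * contact, contact + 0.5)
        focal = make_track(0, "A", frames=np.arange(n), x=10.0 + dist, y=np.full(n, 10.0),
                           area=area)
        partner = make_track(0, "B", frames=np.arange(n), x=np.full(n, 10.0),
                             y=np.full(n, 10.0), area=area)
        s = make_session(tracks_a=[focal], tracks_b=[partner], n_frames=n)
        counts = [
            len(detect_new_colocalization_events(s, persistence_frac=q))
            for q in (1.0, 0.95, 0.85, 0.7, 0.5)
        ]
        assert counts == sorted(counts)  # lowering the bar never loses events

    def test_detected_events_self_consistent(self):
        """Re-evaluating the persistence predicate on each reported event passes."""
        from synaptodyn.colocalization import pairwise_gap_series

        sc = synth.small_scenario(seed=9, n_planted_events=2, n_transient_crossings=1,
                                  dropout_p=0.0, intensity_noise_sd=0.0)
        s, _ = synth.generate_session(sc, 0, "control")
        evs = detect_new_colocalization_events(s)
        assert evs
        persist = int(round(10.0 * 60 / s.frame_interval_s))
        for ev in evs:
            focal = next(t for t in s.tracks["A"] if t.track_id == ev.focal_track_id)
            partner = next(t for t in s.tracks["B"] if t.track_id == ev.partner_track_id)
            gap = pairwise_gap_series(focal, partner, s.n_frames)
            window = gap[ev.event_frame + 1: ev.event_frame + 1 + persist]
            assert np.mean(window <= 0.0) >= 0.95
            assert ev.event_frame <= s.n_frames - 1 - persist


class TestClassifyPartner:
    def test_existing_partner(self):
        s = _docking_session(event_frame=100, partner_first_frame=0)
        ev = detect_new_colocalization_events(s)[0]
        assert ev.partner_class == "existing"  # present from t = 0, > 10 min before

    def test_new_partner(self):
        s = _docking_session(event_frame=100, partner_first_frame=84)  # 4 min before
        ev = detect_new_colocalization_events(s)[0]
        assert ev.partner_class == "new"

    def test_boundary_exactly_ten_minutes_is_existing(self):
        s = _docking_session(event_frame=100, partner_first_frame=60)  # exactly 10 min
        ev = detect_new_colocalization_events(s)[0]
        assert ev.partner_class == "existing"

    def test_planted_mixture_recovered_exactly(self):
        sc = synth.SyntheticScenario(
            seed=21, n_images_per_arm=1, n_frames=240, n_puncta_a=0, n_puncta_b=0,
            n_planted_events=4, event_new_fraction=0.75,
            dropout_p=0.0, intensity_noise_sd=0.0,
        )
        s, gt = synth.generate_session(sc, 0, "control")
        evs = detect_new_colocalization_events(s)
        got = {(e.focal_track_id, e.partner_class) for e in evs}
        want = {(e["focal_track_id"], e["partner_class"]) for e in gt.events}
        assert got == want
        classes = [e.partner_class for e in evs]
        assert classes.count("new") == 3 and classes.count("existing") == 1


class TestEventKinematics:
    def test_stationary_focal_all_zero(self):
        n = 240
        area = 0.35
        focal = make_track(0, "A", frames=np.arange(n), x=np.full(n, 10.0),
                           y=np.full(n, 10.0), area=area)
        partner = make_track(0, "B", frames=np.arange(120, n), x=np.full(120, 10.0),
                             y=np.full(120, 10.0), area=area)
        s = make_session(tracks_a=[focal], tracks_b=[partner], n_frames=n)
        evs = detect_new_colocalization_events(s)
        assert len(evs) == 1  # partner appears on top of the focal puncta
        kin = event_window_kinematics(evs[0], s)
        assert kin.displacement_before_total == 0.0
        assert kin.mean_distance_pre10 == 0.0
        assert kin.mean_distance_post10 == 0.0

    def test_constant_approach_closed_form(self):
        s = _docking_session(event_frame=160, approach_speed=0.05, start_dist=100.0)
        ev = detect_new_colocalization_events(s)[0]
        kin = event_window_kinematics(ev, s)
        # distances to the site decrease linearly through the pre-window:
        # mean over frames f-40..f-1 of (offset + v * lag), lag = 1..40
        focal = s.tracks["A"][0]
        site = ev.event_position
        d = np.hypot(focal.x_um - site[0], focal.y_um - site[1])
        assert kin.mean_distance_pre10 == pytest.approx(np.mean(d[ev.event_frame - 40: ev.event_frame]))
        # closed form: site sits 0.4 x contact ahead of the docked centre, so the
        # pre-window distance is 0.6 x contact + v x lag, lag = 1..40
        contact = 2 * math.sqrt(0.35 / math.pi)
        lags = np.arange(1, 41)
        assert kin.mean_distance_pre10 == pytest.approx(
            float(np.mean(0.6 * contact + 0.05 * lags)), rel=1e-9
        )

    def test_random_events_match_brute_force(self):
        sc = synth.small_scenario(seed=13, n_planted_events=2, dropout_p=0.0)
        s, _ = synth.generate_session(sc, 0, "control")
        evs = detect_new_colocalization_events(s)
        assert evs
        w = int(round(10 * 60 / s.frame_interval_s))
        for ev in evs:
            kin = event_window_kinematics(ev, s)
            focal = next(t for t in s.tracks["A"] if t.track_id == ev.focal_track_id)
            d = np.hypot(focal.x_um - ev.event_position[0], focal.y_um - ev.event_position[1])
            pre = d[(focal.frames >= ev.event_frame - w) & (focal.frames < ev.event_frame)]
            post = d[(focal.frames > ev.event_frame) & (focal.frames <= ev.event_frame + w)]
            assert kin.mean_distance_pre10 == pytest.approx(float(pre.mean()))
            assert kin.mean_distance_post10 == pytest.approx(float(post.mean()))
            assert kin.displacement_before_total == pytest.approx(
                float(np.hypot(*(np.array([focal.x_um[0], focal.y_um[0]]) - ev.event_position)))
            )
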