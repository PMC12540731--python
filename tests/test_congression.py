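"""Classification, alignment events, kinematics and counting."""

import numpy as np
import pandas as pd
import pytest

from spindlekin.congression import (AnalysisConfig, PairTrack,
                                    classify_pair, congression_velocity,
                                    detect_alignment_event, fill_gaps,
                                    cell_frames, initiation_vs_distance,
                                    mitosis_duration, polar_count_at_time,
                                    residence_time, analyze_cell)
from spindlekin.geometry import build_frame, pair_geometry
from spindlekin.synthetic import get_preset, simulate_cell

from conftest import make_moving_pair, make_static_cell


def _frames_static(pole_a, pole_b, n):
    return {i: build_frame(pole_a, pole_b, i) for i in range(n)}


class TestClassifyPair:
    @pytest.mark.parametrize("sisters,expected", [
        (((1.1, 0), (1.9, 0)), "polar"),    # near pole, > 3 µm from plane
        (((3.6, 0), (4.4, 0)), "aligned"),  # sister within 3 µm of plane
        (((5.0, 1), (5.0, -1)), "aligned"),  # midpoint on the plane
    ])
    def test_examples(self, cfg, sisters, expected):
        fr = build_frame((0, 0), (10, 0), 0)
        g = pair_geometry(fr, *sisters)
        assert classify_pair(g, cfg) == expected

    def test_center_rule_unions_with_plane_rule(self, cfg):
        # far from the plane laterally but closer to center than any pole
        fr = build_frame((0, 0), (10, 0), 0)
        g = pair_geometry(fr, (5, 8), (5, 8.5))
        assert g.sister_dist_plane_min < 1
        assert classify_pair(g, cfg) == "aligned"

    def test_threshold_monotonicity(self):
        """Raising the aligned threshold can only add aligned pairs."""
        rng = np.random.default_rng(11)
        fr = build_frame((0, 0), (12, 0), 0)
        geoms = [pair_geometry(fr, rng.normal(size=2) * 5 + (6, 0),
                               rng.normal(size=2) * 5 + (6, 0))
                 for _ in range(300)]
        counts = []
        for thr in (1.0, 2.0, 3.0, 4.0, 6.0):
            c = AnalysisConfig(aligned_dist_threshold=thr,
                               alignment_cross_threshold=min(thr, 2.0))
            counts.append(sum(classify_pair(g, c) == "aligned" for g in geoms))
        assert counts == sorted(counts)

    def test_partition(self, cfg):
        rng = np.random.default_rng(5)
        fr = build_frame((0, 0), (12, 0), 0)
        for _ in range(200):
            g = pair_geometry(fr, rng.normal(size=2) * 6,
                              rng.normal(size=2) * 6)
            assert classify_pair(g, cfg) in ("polar", "aligned")


class TestDetectAlignment:
    def test_moving_midpoint_crosses_at_expected_frame(self, cfg):
        track = make_moving_pair(lambda t: 0.5 + 0.5 * t, 15)
        frames = _frames_static((0, 0), (10, 0), 15)
        ev = detect_alignment_event(track, frames, cfg)
        assert ev.t_alignment == pytest.approx(5.0)  # x(5) = 3.0, dist 2.0

    def test_stationary_midpoint_is_censored(self, cfg):
        track = make_moving_pair(lambda t: 0.8, 15)
        frames = _frames_static((0, 0), (10, 0), 15)
        ev = detect_alignment_event(track, frames, cfg)
        assert ev.censored and ev.censored_reason == "end_of_track"

    def test_already_within_threshold_returns_first_frame(self, cfg):
        track = make_moving_pair(lambda t: 3.5, 15)  # dist_plane 1.5
        frames = _frames_static((0, 0), (10, 0), 15)
        ev = detect_alignment_event(track, frames, cfg)
        assert ev.t_alignment == pytest.approx(0.0)

    def test_censored_reason_anaphase(self, cfg):
        track = make_moving_pair(lambda t: 0.5 + 0.5 * t, 15)
        frames = _frames_static((0, 0), (10, 0), 15)
        ev = detect_alignment_event(track, frames, cfg, t_anaphase_onset=4.0)
        assert ev.censored and ev.censored_reason == "anaphase"

    def test_empty_overlap_raises(self, cfg):
        track = make_moving_pair(lambda t: 1.0, 5)
        with pytest.raises(ValueError, match="overlap"):
            detect_alignment_event(track, {100: build_frame((0, 0), (10, 0), 100)},
                                   cfg)

    def test_agrees_with_brute_force_scan(self, cfg):
        """Event detection equals an independent full-scan oracle on
        random-walk tracks over a static spindle."""
        rng = np.random.default_rng(2024)
        frames = _frames_static((0, 0), (10, 0), 30)
        for _ in range(1000):
            xs = np.cumsum(rng.normal(0.3, 0.8, size=30)) + rng.uniform(0, 2)
            ys = rng.normal(0, 1, size=30)
            mid = np.column_stack([xs, ys])
            track = PairTrack("c", "p", np.arange(30), np.arange(30.0),
                              mid + (0, 0.1), mid - (0, 0.1))
            ev = detect_alignment_event(track, frames, cfg)
            dist = np.abs(xs - 5.0)
            hit = np.flatnonzero(dist <= 2.0)
            if hit.size:
                assert ev.t_alignment == pytest.approx(float(hit[0]))
            else:
                assert ev.censored


class TestCongressionVelocity:
    def test_constant_speed_recovered_exactly(self, cfg):
        track = make_moving_pair(lambda t: 0.5 + 1.0 * t, 16)
        frames = _frames_static((0, 0), (30, 0), 16)
        ev = detect_alignment_event(track, frames, cfg)
        assert ev.t_alignment == pytest.approx(13.0)  # x = 13.5, dist 1.5... first <=2 at x>=13
        v = congression_velocity(track, frames, ev.t_alignment, cfg)
        assert v.velocity == pytest.approx(1.0, abs=1e-9)
        assert not v.partial_window

    def test_net_displacement_hand_example(self, cfg):
        # dist_plane 8.3 at t_alignment-6 and 2.0 at t_alignment
        track = make_moving_pair(lambda t: 1.7 + 1.05 * t, 7)
        frames = _frames_static((0, 0), (20, 0), 7)
        ev = detect_alignment_event(track, frames, cfg)
        assert ev.t_alignment == pytest.approx(6.0)
        v = congression_velocity(track, frames, ev.t_alignment, cfg)
        assert v.velocity == pytest.approx((8.3 - 2.0) / 6, abs=1e-9)

    def test_insufficient_window_undefined(self, cfg):
        # only 2 min of track before the crossing
        track = make_moving_pair(lambda t: 1.0 + 1.0 * t, 8)
        frames = {i: build_frame((0, 0), (10, 0), i) for i in range(8)}
        ev = detect_alignment_event(track, frames, cfg)
        assert ev.t_alignment == pytest.approx(2.0)
        assert congression_velocity(track, frames, ev.t_alignment, cfg) is None

    def test_partial_window_flagged(self, cfg):
        track = make_moving_pair(lambda t: 1.0 + 1.0 * t, 8)
        frames = _frames_static((0, 0), (16, 0), 8)
        ev = detect_alignment_event(track, frames, cfg)  # crosses at x>=6, t=5
        v = congression_velocity(track, frames, ev.t_alignment, cfg)
        assert v is not None and v.partial_window
        assert v.window_used == pytest.approx(5.0)
        assert v.velocity == pytest.approx(1.0, abs=1e-9)

    def test_velocity_recovery_with_noise(self, cfg):
        """MAE < 0.05 µm/min at 0.05 µm isotropic positional noise."""
        rng = np.random.default_rng(99)
        frames = _frames_static((0, 0), (30, 0), 20)
        errs = []
        for _ in range(200):
            v_true = rng.uniform(0.5, 1.5)
            fi = np.arange(20)
            xs = 0.5 + v_true * fi
            mid = np.column_stack([xs, np.zeros(20)])
            noise = rng.normal(0, 0.05, size=(2, 20, 2))
            track = PairTrack("c", "p", fi, fi.astype(float),
                              mid + (0, 0.1) + noise[0],
                              mid - (0, 0.1) + noise[1])
            ev = detect_alignment_event(track, frames, cfg)
            if ev.censored or ev.t_alignment < 6:
                continue
            v = congression_velocity(track, frames, ev.t_alignment, cfg)
            errs.append(abs(v.velocity - v_true))
        assert len(errs) > 150
        assert np.mean(errs) < 0.05


class TestResidenceAndDuration:
    def test_residence_cases(self):
        assert residence_time(10, 40) == (30.0, False)
        assert residence_time(10, None, t_anaphase_onset=120) == (110.0, True)
        assert residence_time(10, 10) == (0.0, False)

    def test_residence_clamped_with_warning(self):
        with pytest.warns(UserWarning, match="clamped"):
            val, cens = residence_time(10, 8)
        assert val == 0.0 and not cens

    def test_mitosis_duration_frame_conventions(self, cfg):
        cell = make_static_cell([(6, 0)], n_frames=61, t_anaphase_onset=60.0)
        assert mitosis_duration(cell) == (59.0, False)
        cell = make_static_cell([(6, 0)], n_frames=61, frame_interval=0.5,
                                t_bipolarization=5.0, t_anaphase_onset=30.0)
        assert mitosis_duration(cell) == (29.5, False)

    def test_mitosis_duration_censored_at_last_frame(self):
        cell = make_static_cell([(6, 0)], n_frames=31)
        dur, censored = mitosis_duration(cell)
        assert censored and dur == pytest.approx(30.0)

    def test_residence_bounded_by_mitosis_duration(self, cfg):
        """residence_time <= mitosis_duration + frame interval, per pair."""
        for seed in (1, 2):
            cell, _ = simulate_cell(get_preset("control_2v2"), seed)
            dur, _ = mitosis_duration(cell)
            for r in analyze_cell(cell, cfg):
                assert r.residence_time <= dur + cell.frame_interval + 1e-9


class TestPolarCount:
    def test_all_aligned_gives_zero(self, cfg):
        cell = make_static_cell([(5.5, 1), (6.5, -1), (6, 0)])
        assert polar_count_at_time(cell, 10, cfg).total == 0

    def test_fixture_with_three_polar_pairs(self, cfg):
        """3 pairs 1 µm from a pole of a 12-µm spindle are polar; verified
        pairwise against classify_pair."""
        mids = [(1.0, 0), (1.0, 0.3), (11.0, 0), (6, 0), (5.5, 1)]
        cell = make_static_cell(mids)
        count = polar_count_at_time(cell, 10, cfg)
        assert count.total == 3
        frames = cell_frames(cell)
        expected = 0
        for tr in cell.pair_tracks:
            g = pair_geometry(frames[10], tr.sister1[10], tr.sister2[10])
            expected += classify_pair(g, cfg) == "polar"
        assert count.total == expected

    def test_per_pole_split(self, cfg):
        mids = [(1.0, 0), (1.5, 0.5), (11.0, 0), (6, 0)]
        cell = make_static_cell(mids)
        count = polar_count_at_time(cell, 10, cfg)
        assert count.per_pole == {"A": 2, "B": 1}

    def test_time_outside_span_raises(self, cfg):
        cell = make_static_cell([(6, 0)])
        with pytest.raises(ValueError, match="outside imaging span"):
            polar_count_at_time(cell, 500, cfg)


class TestGapHandling:
    def test_short_gap_interpolated(self):
        fi = np.arange(7)
        xs = np.array([0, 1, np.nan, np.nan, 4, 5, 6.0])
        mid = np.column_stack([xs, np.zeros(7)])
        tr = PairTrack("c", "p", fi, fi.astype(float),
                       mid + (0, 0.1), mid - (0, 0.1))
        filled = fill_gaps(tr, max_gap=2)
        assert np.allclose(filled.sister1[:, 0], np.arange(7))
        # a gap longer than the limit stays missing
        filled1 = fill_gaps(tr, max_gap=1)
        assert np.isnan(filled1.sister1[2, 0])


class TestInitiationVsDistance:
    def test_exact_line(self, cfg):
        # three pairs at distances 1, 2, 3 aligning 9, 8, 7 min after start
        mids = {1.0: 9, 2.0: 8, 3.0: 7}
        cells = []
        pairs = []
        fi = np.arange(16)
        for k, (d, dur) in enumerate(mids.items()):
            xs = np.where(fi < dur, d, 4.0)  # jump within 2 µm at t=dur
            mid = np.column_stack([xs, np.zeros(16)])
            pairs.append(PairTrack("c", f"p{k}", fi, fi.astype(float),
                                   mid + (0, 0.1), mid - (0, 0.1)))
        cell = make_static_cell([(6, 0)], n_frames=16)
        cell.pair_tracks = pairs
        table, fit = initiation_vs_distance([cell], cfg)
        assert fit is not None
        assert fit.slope == pytest.approx(-1.0)
        assert fit.r_squared == pytest.approx(1.0)
        assert not table["censored"].any()

    def test_all_censored_returns_table_without_fit(self, cfg):
        cell = make_static_cell([(1.0, 0), (1.2, 0), (11.0, 0)])
        table, fit = initiation_vs_distance([cell], cfg)
        assert fit is None
        assert table["censored"].all()
        assert len(table) == 3

    def test_generator_distance_hazard_gives_negative_slope(self, cfg):
        """With the distance-releasing hazard of acentriolar spindles, the
        congression-duration vs initial-distance fit is negative in >=95%
        of seeded runs."""
        preset = get_preset("cenpe_inhibited_0v0")
        neg = 0
        runs = 100
        for seed in range(runs):
            cells = [simulate_cell(preset, 10_000 + 17 * seed + j)[0]
                     for j in range(2)]
            _, fit = initiation_vs_distance(cells, cfg)
            if fit is not None and fit.slope < 0:
                neg += 1
        assert neg >= 95
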