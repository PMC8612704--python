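"""Motility classification, bout summaries, arrest-time estimation, and
kymograph track extraction round trips."""

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from axocascade import (
    arrest_time,
    classify_motility,
    extract_tracks,
    render_kymograph,
    sample_event_schedule,
    simulate_kymograph_bouts,
    summarize_bout,
)
from axocascade.kymo import BoutSummary
from axocascade.simulate import KymographBout, MitoTrack, default_bout_times


def track(positions, tid=0):
    return MitoTrack(track_id=tid, positions_um=np.asarray(positions, dtype=float))


class TestClassifier:
    def test_six_micron_net_displacement_is_mobile(self):
        call = classify_motility(track(np.linspace(0, 6, 60)))
        assert call.label == "mobile"
        assert call.net_displacement == pytest.approx(6.0)

    def test_exactly_five_micron_is_stationary(self):
        # "more than 5 um" is a strict inequality
        call = classify_motility(track(np.linspace(0, 5.0, 60)))
        assert call.label == "stationary"

    def test_constant_position_is_stationary(self):
        call = classify_motility(track(np.full(60, 3.0)))
        assert call.label == "stationary"
        assert call.net_displacement == 0.0

    def test_back_and_forth_excursion_uses_net_not_path(self):
        pos = np.concatenate([np.linspace(0, 8, 30), np.linspace(8, 0.5, 30)])
        assert classify_motility(track(pos)).label == "stationary"

    def test_short_track_rejected(self):
        with pytest.raises(ValueError):
            classify_motility(track([1.0]))

    @given(thr=st.floats(min_value=0.5, max_value=12.0))
    @settings(max_examples=50, derandomize=True)
    def test_raising_threshold_never_makes_mobile(self, thr):
        t = track(np.linspace(0, 7.3, 60))
        lo = classify_motility(t, threshold_um=thr)
        hi = classify_motility(t, threshold_um=thr + 1.0)
        assert not (lo.label == "stationary" and hi.label == "mobile")

    def test_direction_reversal_invariance(self):
        pos = np.linspace(2, 11, 60)
        a = classify_motility(track(pos))
        b = classify_motility(track(pos[::-1].copy()))
        assert a.label == b.label
        assert a.net_displacement == pytest.approx(b.net_displacement)


class TestBoutSummary:
    def test_counting(self):
        tracks = [track(np.linspace(0, 6, 60), i) for i in range(6)]
        tracks += [track(np.full(60, float(i)), 6 + i) for i in range(14)]
        bout = KymographBout(bout_start=0.0, frame_interval=5, n_frames=60, tracks=tracks)
        s = summarize_bout(bout)
        assert (s.n_tracks, s.n_mobile) == (20, 6)
        assert s.mobile_fraction == pytest.approx(0.30)

    def test_all_stationary(self):
        tracks = [track(np.full(60, 1.0), i) for i in range(5)]
        bout = KymographBout(bout_start=0.0, frame_interval=5, n_frames=60, tracks=tracks)
        assert summarize_bout(bout).mobile_fraction == 0.0

    def test_empty_bout_flagged(self):
        bout = KymographBout(bout_start=1.0, frame_interval=5, n_frames=60, tracks=[])
        s = summarize_bout(bout)
        assert s.n_tracks == 0 and s.degenerate

    def test_simulated_bout_fraction_within_binomial_ci(self, params, rng):
        sched = sample_event_schedule(params, "a", rng)
        p = params.baseline_mobile_fraction
        n = params.tracks_per_bout
        fracs = [
            summarize_bout(
                simulate_kymograph_bouts(sched, params, [-0.25], rng)[0]
            ).mobile_fraction
            for _ in range(40)
        ]
        half = 3 * np.sqrt(p * (1 - p) / (40 * n))
        assert np.mean(fracs) == pytest.approx(p, abs=half)


class TestArrestTime:
    def test_first_sustained_zero(self):
        fracs = [0.3, 0.2, 0.1, 0.0, 0.0]
        summaries = [
            BoutSummary(bout_start=float(h), n_tracks=10, n_mobile=int(10 * f),
                        mobile_fraction=f)
            for h, f in enumerate(fracs)
        ]
        assert arrest_time(summaries) == 3.0

    def test_transient_zero_is_not_arrest(self):
        fracs = [0.3, 0.0, 0.2, 0.0, 0.0]
        summaries = [
            BoutSummary(bout_start=float(h), n_tracks=10, n_mobile=int(10 * f),
                        mobile_fraction=f)
            for h, f in enumerate(fracs)
        ]
        assert arrest_time(summaries) == 3.0

    def test_never_arrested(self):
        summaries = [
            BoutSummary(bout_start=float(h), n_tracks=10, n_mobile=2, mobile_fraction=0.2)
            for h in range(5)
        ]
        assert arrest_time(summaries) is None

    def test_empty_list_rejected(self):
        with pytest.raises(ValueError):
            arrest_time([])

    def test_round_trip_within_one_bout_interval(self, quiet_params, rng):
        sched = sample_event_schedule(quiet_params, "a", rng)
        bouts = simulate_kymograph_bouts(
            sched, quiet_params, default_bout_times(sched), rng
        )
        est = arrest_time([summarize_bout(b) for b in bouts])
        assert est is not None
        assert sched.t_mito_stop - 1e-9 <= est <= sched.t_mito_stop + 5 / 60 + 1e-9

    def test_arrest_estimate_unbiased_over_cohort(self, params, rng):
        """Mean signed error of the arrest estimate stays within one bout
        interval over 100 simulated axons."""
        errors = []
        for i in range(100):
            sched = sample_event_schedule(params, f"a{i}", rng)
            bouts = simulate_kymograph_bouts(
                sched, params, default_bout_times(sched), rng
            )
            est = arrest_time([summarize_bout(b) for b in bouts])
            assert est is not None
            errors.append(est - sched.t_mito_stop)
        assert abs(np.mean(errors)) <= 5 / 60


class TestKymographExtraction:
    def test_blank_image_gives_no_tracks(self):
        assert extract_tracks(np.zeros((60, 200)), 0.3, 5.0) == []

    def test_single_track_round_trip(self, rng):
        truth = np.linspace(20.0, 35.0, 60)
        bout = KymographBout(
            bout_start=0.0, frame_interval=5, n_frames=60,
            tracks=[MitoTrack(track_id=0, positions_um=truth)],
        )
        img = render_kymograph(bout, pixel_size=0.3, length_um=60.0, rng=rng)
        tracks = extract_tracks(img, pixel_size=0.3, frame_interval=5.0)
        assert len(tracks) == 1
        got = tracks[0].positions_um
        assert np.isfinite(got).all()
        assert np.max(np.abs(got - truth)) <= 0.3  # within one pixel

    def test_two_separated_tracks_no_identity_swap(self, rng):
        a = np.linspace(10.0, 24.0, 60)
        b = np.linspace(45.0, 41.0, 60)
        bout = KymographBout(
            bout_start=0.0, frame_interval=5, n_frames=60,
            tracks=[MitoTrack(0, a), MitoTrack(1, b)],
        )
        img = render_kymograph(bout, pixel_size=0.3, length_um=60.0, rng=rng)
        tracks = extract_tracks(img, pixel_size=0.3, frame_interval=5.0)
        assert len(tracks) == 2
        recovered = sorted(tracks, key=lambda t: t.positions_um[0])
        assert np.max(np.abs(recovered[0].positions_um - a)) <= 0.45
        assert np.max(np.abs(recovered[1].positions_um - b)) <= 0.45

    def test_label_recovery_on_rendered_bouts(self, rng):
        """Render-and-extract agrees with ground-truth motility labels on
        >= 99% of resolvable (non-crossing) tracks at default rendering
        noise."""
        agree = total = 0
        for _ in range(25):
            tracks = []
            for j in range(8):
                start = 12.0 + 15.0 * j + rng.uniform(-2, 2)
                mobile = rng.random() < 0.4
                if mobile:
                    net = rng.uniform(7.0, 10.0)  # same direction: no crossings
                    pos = start + np.linspace(0.0, net, 60)
                else:
                    pos = start + np.cumsum(rng.normal(0, 0.05, 60))
                tracks.append(MitoTrack(j, pos, ground_truth_mobile=mobile))
            bout = KymographBout(
                bout_start=0.0, frame_interval=5, n_frames=60, tracks=tracks
            )
            img = render_kymograph(bout, pixel_size=0.3, length_um=150.0, rng=rng)
            got = extract_tracks(img, pixel_size=0.3, frame_interval=5.0)
            assert len(got) == len(tracks)
            for g in got:
                finite = g.positions_um[np.isfinite(g.positions_um)]
                nearest = min(
                    tracks, key=lambda t: abs(t.positions_um[0] - finite[0])
                )
                total += 1
                want = "mobile" if nearest.ground_truth_mobile else "stationary"
                agree += classify_motility(g).label == want
        assert total == 200
        assert agree / total >= 0.99
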