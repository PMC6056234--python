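"""Track classification, segmentation, run-length statistics and colocalisation."""

import numpy as np
import pytest

import rnpstoich as rs
from rnpstoich.motility import VelocitySegmenter, _ols_slope

from conftest import make_linear_track

MT = rs.MicrotubuleRef("m0", length=30.0)


def classify(track, mt=MT, movie_end=None, **param_overrides):
    params = rs.ClassifyParams(**param_overrides) if param_overrides else None
    return rs.classify_track(track, mt, params=params, movie_end=movie_end)


class TestClassifyTrack:
    def test_constant_position_is_static(self):
        t = np.arange(10) * 0.5
        ev = classify(rs.Track("m0", "t", "c", t, np.full(10, 12.0)))
        assert ev.category == "static"
        assert ev.net_displacement == 0.0

    def test_straight_minusward_run_is_processive_with_run_length(self):
        t = np.arange(10) * 0.5  # 10 frames at -1 um/s: net -4.5 um
        ev = classify(rs.Track("m0", "t", "c", t, 20.0 - 1.0 * t))
        assert ev.category == "processive"
        assert ev.run_length == pytest.approx(4.5)
        assert ev.net_displacement == pytest.approx(-4.5)

    def test_two_frame_track_rejected_as_binding_event(self):
        ev = classify(rs.Track("m0", "t", "c", np.array([0.0, 0.5]), np.array([5.0, 4.0])))
        assert ev is None

    def test_three_frame_track_is_a_binding_event(self):
        t = np.arange(3) * 0.5
        assert classify(rs.Track("m0", "t", "c", t, np.full(3, 5.0))) is not None

    def test_unbiased_random_walk_is_diffusive(self):
        # resampled seed such that |net| < 0.5 um by construction
        for seed in range(100):
            rng = np.random.default_rng(seed)
            steps = rng.normal(0, np.sqrt(2 * 0.05 * 0.5), 50)
            steps[0] = 0.0
            x = 15.0 + np.cumsum(steps)
            if abs(x[-1] - x[0]) < 0.5 and np.max(np.abs(x - x.mean())) > 0.15:
                ev = classify(rs.Track("m0", "t", "c", np.arange(50) * 0.5, x))
                assert ev.category == "diffusive"
                return
        pytest.fail("no qualifying random walk found")

    def test_unordered_times_rejected(self):
        with pytest.raises(ValueError, match="increasing"):
            rs.Track("m0", "t", "c", np.array([0.0, 0.5, 0.4]), np.zeros(3))

    def test_plus_end_directed_track_is_not_processive(self):
        t = np.arange(10) * 0.5
        ev = classify(rs.Track("m0", "t", "c", t, 5.0 + 1.0 * t))
        assert ev.category == "diffusive"  # directed, but toward the plus end

    def test_axis_reflection_symmetry(self):
        """Reflecting coordinates (and the minus-end convention) preserves classes."""
        t = np.arange(12) * 0.5
        x = 20.0 - 1.0 * t
        ev = classify(rs.Track("m0", "t", "c", t, x))
        mirrored = rs.MicrotubuleRef("m0", length=30.0, minus_end_position=30.0)
        # reflected track moves toward coordinate 30 = reflected minus end
        ev2 = rs.classify_track(rs.Track("m0", "t", "c", t, 30.0 - x), mirrored,
                                params=rs.ClassifyParams(processive_min_net=0.5))
        assert ev.category == "processive"
        # reflected geometry: net displacement sign flips but magnitude matches
        assert abs(ev2.net_displacement) == pytest.approx(abs(ev.net_displacement))

    def test_time_shift_invariance(self):
        t = np.arange(20) * 0.5
        x = 20.0 - 0.8 * t
        a = classify(rs.Track("m0", "t", "c", t, x))
        b = classify(rs.Track("m0", "t", "c", t + 137.0, x))
        assert a.category == b.category == "processive"
        assert a.run_length == pytest.approx(b.run_length)

    def test_ground_truth_recovered_on_clean_tracks(self):
        """Noiseless tracks whose ground truth exceeds the scoring thresholds
        are classified exactly as generated."""
        cfg = rs.SimConfig(n_tracks=300, class_probs=(0.3, 0.2, 0.5),
                           localisation_sd=0.0, seed=12)
        ts = rs.simulate_trackset(cfg)
        events = {e.track_id: e for e in rs.classify_trackset(ts)}
        checked = 0
        for tr in ts.tracks:
            truth = ts.ground_truth[tr.track_id]
            ev = events.get(tr.track_id)
            if ev is None:
                continue
            if truth["class"] == "processive":
                # identifiable only if the observable displacement clears 0.5 um
                if abs(tr.positions.min() - tr.positions[0]) > 0.7:
                    assert ev.category == "processive"
                    checked += 1
            elif truth["class"] == "static":
                assert ev.category == "static"
                checked += 1
        assert checked > 50


class TestSegmentation:
    def test_noiseless_two_segment_track_exact(self):
        tr = make_linear_track([-1.0, -2.0], n_per_seg=10)
        segs = rs.segment_velocities(tr)
        assert len(segs) == 2
        assert segs[0].velocity == pytest.approx(-1.0, abs=1e-9)
        assert segs[1].velocity == pytest.approx(-2.0, abs=1e-9)

    def test_noiseless_constant_velocity_single_segment(self):
        tr = make_linear_track([-1.5], n_per_seg=20)
        segs = rs.segment_velocities(tr)
        assert len(segs) == 1
        assert segs[0].velocity == pytest.approx(-1.5, abs=1e-9)

    def test_segments_tile_without_overlap(self):
        tr = make_linear_track([-1.0, -0.3, -2.0], n_per_seg=8, noise=0.03, seed=5)
        segs = rs.segment_velocities(tr)
        for a, b in zip(segs[:-1], segs[1:]):
            assert a.t_end == pytest.approx(b.t_start)
        assert segs[0].t_start == tr.times[0]

    def test_short_track_single_segment_fallback(self):
        tr = make_linear_track([-1.0], n_per_seg=3)
        segs = rs.segment_velocities(tr, rs.ClassifyParams(min_segment_frames=3))
        assert len(segs) == 1

    def test_matches_exhaustive_single_changepoint_oracle(self):
        """DP segmentation = brute-force least-squares search, single-changepoint tracks."""
        rng = np.random.default_rng(42)
        agree = 0
        for i in range(50):
            cp = int(rng.integers(8, 25))
            v2 = -2.0 + rng.normal(0, 0.4)
            t = np.arange(32) * 0.5
            x = np.empty(32)
            x[:cp] = 25.0 - 1.0 * t[:cp]
            x[cp:] = x[cp - 1] + v2 * (t[cp:] - t[cp - 1])
            x_noisy = x + rng.normal(0, 0.05, 32)
            # oracle: exhaustive single-changepoint RSS minimisation
            best_cp, best_rss = None, np.inf
            for c in range(3, 30):
                rss = 0.0
                for sl in (slice(0, c), slice(c, 32)):
                    tt, xx = t[sl], x_noisy[sl]
                    resid = xx - (np.polyval(np.polyfit(tt, xx, 1), tt))
                    rss += float(resid @ resid)
                if rss < best_rss:
                    best_cp, best_rss = c, rss
            seg = VelocitySegmenter().fit(rs.Track("m", f"t{i}", "c", t, x_noisy))
            if len(seg.changepoints_) == 1 and abs(seg.changepoints_[0] - best_cp) <= 1:
                agree += 1
        assert agree >= 45

    def test_changepoint_recovery_rate_under_noise(self):
        """>= 90% of changepoints recovered within +/-2 frames at 50-nm noise."""
        rng = np.random.default_rng(0)
        hits = 0
        n = 200
        for i in range(n):
            cp = int(rng.integers(10, 30))
            v2 = -2.0 + rng.normal(0, 0.3)
            t = np.arange(40) * 0.5
            x = np.empty(40)
            x[:cp] = 30.0 - 1.0 * t[:cp]
            x[cp:] = x[cp - 1] + v2 * (t[cp:] - t[cp - 1])
            x += rng.normal(0, 0.05, 40)
            seg = VelocitySegmenter().fit(rs.Track("m", f"t{i}", "c", t, x))
            if seg.changepoints_ and min(abs(c - cp) for c in seg.changepoints_) <= 2:
                hits += 1
        assert hits / n >= 0.90

    def test_velocity_times_duration_bounds_net_displacement(self, processive_trackset):
        events = rs.classify_trackset(processive_trackset)
        for ev in events[:100]:
            if ev.category != "processive":
                continue
            travel = sum(abs(s.velocity) * s.duration for s in ev.segments)
            assert travel >= abs(ev.net_displacement) - 0.35  # rasterisation slack


class TestRunLengths:
    def test_censoring_rule_examples(self):
        t = np.arange(12) * 0.5
        near = classify(rs.Track("m0", "t", "c", t, 3.0 - 0.5 * t), movie_end=5.5)
        assert near.category == "processive"
        assert not near.eligible_for_run_stats  # starts 3 um in, truncated by movie end
        far = classify(rs.Track("m0", "t", "c", t + 20.0, 20.0 - 0.5 * t))
        assert far.eligible_for_run_stats  # fully observed, ends off the minus end

    def test_censoring_reduces_bias_on_simulated_runs(self, processive_trackset):
        events = rs.classify_trackset(processive_trackset)
        eligible = rs.extract_run_lengths(events)
        all_runs = [e.run_length for e in events if e.run_length is not None]
        truth = 5.0
        assert abs(np.mean(eligible) - truth) < abs(np.mean(all_runs) - truth)
        assert abs(np.mean(eligible) - truth) < 0.1 * truth

    def test_decay_fit_recovers_exponential_scale(self):
        rng = np.random.default_rng(3)
        runs = rng.exponential(5.0, 1000)
        fit = rs.fit_decay(runs)
        mle = float(np.mean(runs))  # maximum-likelihood oracle
        assert abs(fit.scale - 5.0) / 5.0 < 0.05
        assert abs(fit.scale - mle) / mle < 0.05
        assert fit.n_runs == 1000

    def test_decay_fit_scale_converges_with_n(self):
        rng = np.random.default_rng(8)
        err = {}
        for n in (100, 1000):
            scales = [rs.fit_decay(rng.exponential(5.0, n)).scale for _ in range(20)]
            err[n] = float(np.std(scales))
        assert err[1000] < err[100]

    def test_degenerate_identical_runs_flagged(self):
        fit = rs.fit_decay([2.0] * 15)
        assert fit.scale > 0 and fit.poorly_conditioned

    def test_too_few_runs_error(self):
        with pytest.raises(ValueError, match="10"):
            rs.fit_decay([1.0] * 5)


class TestCountsAndFractions:
    def test_background_subtraction_arithmetic(self):
        t = np.arange(5) * 0.5
        events = [classify(rs.Track("m0", f"t{i}", "c", t, np.full(5, 5.0))) for i in range(10)]
        df = rs.count_events(events, {"m0": 10.0}, background_counts=[2, 2],
                             background_region_length=10.0)
        assert df.loc[0, "n_binding"] == 10
        assert df.loc[0, "n_binding_corrected"] == pytest.approx(8.0)

    def test_background_floor_at_zero(self):
        t = np.arange(5) * 0.5
        events = [classify(rs.Track("m0", "t0", "c", t, np.full(5, 5.0)))]
        df = rs.count_events(events, {"m0": 10.0}, background_counts=[5.0],
                             background_region_length=10.0)
        assert df.loc[0, "n_binding_corrected"] == 0.0

    def test_missing_background_warns_and_skips(self):
        with pytest.warns(UserWarning, match="background"):
            df = rs.count_events([], {"m0": 10.0})
        assert df.loc[0, "n_binding_corrected"] == 0

    def test_background_correction_unbiased_over_replicates(self):
        """Uniform glass landing + true MT events: corrected counts unbiased."""
        rng = np.random.default_rng(1)
        true_rate, bg_rate, length = 12, 0.4, 10.0  # bg events per um of region
        errs = []
        for _ in range(100):
            raw = true_rate + rng.poisson(bg_rate * length)
            bg_regions = rng.poisson(bg_rate * length, size=5)
            corrected = max(raw - np.mean(bg_regions), 0.0)
            errs.append(corrected - true_rate)
        se = np.std(errs, ddof=1) / 10.0
        assert abs(np.mean(errs)) < 3 * se

    def test_motility_fractions_sum_to_one_and_match_counts(self, mixed_trackset):
        events = rs.classify_trackset(mixed_trackset)
        df = rs.motility_fractions(events)
        frac_cols = ["fraction_processive", "fraction_static", "fraction_diffusive"]
        assert np.allclose(df[frac_cols].sum(axis=1), 1.0)
        pooled = df[df.mt_id == "pooled"].iloc[0]
        assert pooled.n_events == len(events)
        # static + diffusive + processive = total accepted events per MT
        per_mt = df[df.mt_id != "pooled"]
        assert per_mt.n_events.sum() == len(events)

    def test_all_processive_gives_unit_fraction(self):
        t = np.arange(10) * 0.5
        evs = [classify(rs.Track("m0", f"t{i}", "c", t, 20.0 - t)) for i in range(4)]
        df = rs.motility_fractions(evs)
        assert np.all(df.fraction_processive == 1.0)

    def test_no_events_reported_absent(self):
        assert rs.motility_fractions([]).empty


class TestColocalize:
    def test_identical_trajectories_colocalise(self):
        t = np.arange(10) * 0.5
        a = rs.Track("m0", "a0", "chA", t, 20.0 - t)
        b = rs.Track("m0", "b0", "chB", t, 20.0 - t)
        pairs, df = rs.colocalize([a], [b])
        assert pairs == [("a0", "b0")]
        assert df.fraction_A_coloc.iloc[0] == 1.0

    def test_different_microtubules_never_colocalise(self):
        t = np.arange(10) * 0.5
        a = rs.Track("m0", "a0", "chA", t, 20.0 - t)
        b = rs.Track("m1", "b0", "chB", t, 20.0 - t)
        pairs, _ = rs.colocalize([a], [b])
        assert pairs == []

    def test_identical_channel_labels_rejected(self):
        t = np.arange(5) * 0.5
        a = rs.Track("m0", "a0", "chA", t, np.full(5, 3.0))
        with pytest.raises(ValueError, match="channel"):
            rs.colocalize([a], [a])

    def test_duplicated_fraction_recovered(self):
        """75% of channel-B tracks copied (with 50-nm jitter) from channel A."""
        rng = np.random.default_rng(11)
        cfg = rs.SimConfig(n_tracks=200, n_microtubules=4, class_probs=(0, 0, 1),
                           channel="chA", seed=7)
        ts = rs.simulate_trackset(cfg)
        tracks_b = []
        n_dup = 0
        for i, tr in enumerate(ts.tracks):
            if rng.random() < 0.75:
                n_dup += 1
                tracks_b.append(rs.Track(tr.mt_id, f"b{i}", "chB", tr.times,
                                         tr.positions + rng.normal(0, 0.05, tr.n_frames)))
            else:
                t0 = 0.5 * round(rng.uniform(0, 150) / 0.5)
                t = t0 + np.arange(12) * 0.5
                x0 = rng.uniform(2, 10)
                tracks_b.append(rs.Track(tr.mt_id, f"b{i}", "chB", t,
                                         np.full(12, x0) + rng.normal(0, 0.05, 12)))
        pairs, _ = rs.colocalize(ts.tracks, tracks_b)
        true_frac = n_dup / len(tracks_b)
        se = np.sqrt(true_frac * (1 - true_frac) / len(tracks_b))
        assert abs(len(pairs) / len(tracks_b) - true_frac) < 3 * se + 0.02


def test_ols_slope_matches_polyfit():
    rng = np.random.default_rng(2)
    t = np.arange(20) * 0.5
    x = 3.0 - 0.7 * t + rng.normal(0, 0.1, 20)
    assert _ols_slope(t, x) == pytest.approx(np.polyfit(t, x, 1)[0])
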