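import numpy as np
import pytest

from gazetess import (
    DetectionConfig,
    ScanpathSpec,
    classify_events,
    compute_velocity,
    detect_fixations,
    estimate_threshold,
    fuse_eyes,
    generate_trace,
    merge_fixations,
    pixels_per_degree,
)
from gazetess.events import Fixation, FixationSet, VelocityThreshold
from gazetess.simulate import random_fixation_plan

from .conftest import make_trace


class TestFuseEyes:
    def test_both_eyes_average(self, geometry):
        tr = make_trace([0.0], [(100.0, 100.0)], [(104.0, 104.0)], geometry=geometry)
        ct = fuse_eyes(tr)
        assert (ct.x[0], ct.y[0]) == (102.0, 102.0)
        assert ct.source[0] == "both_eyes"

    def test_one_eye_substitutes(self, geometry):
        tr = make_trace([0.0, 4.0], [None, (1.0, 2.0)], [(250.0, 300.0), None], geometry=geometry)
        ct = fuse_eyes(tr)
        assert (ct.x[0], ct.y[0]) == (250.0, 300.0)
        assert ct.source[0] == "right_only"
        assert (ct.x[1], ct.y[1]) == (1.0, 2.0)
        assert ct.source[1] == "left_only"

    def test_both_missing_stays_missing(self, geometry):
        tr = make_trace([0.0, 4.0, 8.0], [(0.0, 0.0), None, (8.0, 8.0)],
                        [(0.0, 0.0), None, (8.0, 8.0)], geometry=geometry)
        ct = fuse_eyes(tr)
        assert np.isnan(ct.x[1]) and ct.source[1] == "missing"
        # downstream velocity must skip pairs spanning the hole
        vs = compute_velocity(ct)
        assert len(vs) == 0


class TestComputeVelocity:
    def test_three_four_five_triangle(self, geometry):
        tr = make_trace([0.0, 4.0], [(100.0, 100.0), (103.0, 104.0)], geometry=geometry)
        vs = compute_velocity(fuse_eyes(tr))
        assert vs.v[0] == pytest.approx(5.0 / 0.004)
        assert vs.t[0] == pytest.approx(2.0)

    def test_constant_position_zero_velocity(self, geometry):
        tr = make_trace(np.arange(10) * 4.0, [(50.0, 50.0)] * 10, geometry=geometry)
        vs = compute_velocity(fuse_eyes(tr))
        assert len(vs) == 9
        assert np.all(vs.v == 0.0)

    def test_gap_drops_one_pair(self, geometry):
        pts = [(50.0, 50.0)] * 5
        pts[2] = None
        tr = make_trace(np.arange(5) * 4.0, pts, geometry=geometry)
        vs = compute_velocity(fuse_eyes(tr))
        assert len(vs) == 2  # pairs (0,1) and (3,4)

    def test_insufficient_data_errors(self, geometry):
        tr = make_trace([0.0, 4.0], [(1.0, 1.0), None], [(1.0, 1.0), None], geometry=geometry)
        with pytest.raises(ValueError, match="insufficient data"):
            compute_velocity(fuse_eyes(tr))


class TestEstimateThreshold:
    def test_separates_planted_two_mode_mixture(self):
        rng = np.random.default_rng(0)
        slow = 10 ** rng.normal(1.7, 0.15, 500)
        fast = 10 ** rng.normal(3.7, 0.15, 500)
        v = np.concatenate([slow, fast])
        truth = np.concatenate([np.zeros(500, bool), np.ones(500, bool)])
        thr = estimate_threshold(v)
        assert thr.method == "adaptive_bimodal"
        agreement = np.mean((v >= thr.value) == truth)
        assert agreement >= 0.99

    def test_degenerate_series_uses_fallback_above_data(self):
        thr = estimate_threshold(np.full(100, 10.0))
        assert thr.method == "fallback_robust"
        assert thr.value > 10.0  # zero saccades on this trace

    def test_thresholds_adapt_per_trace(self, geometry):
        # noisier slow mode -> more conservative (higher) cut, trace by trace
        rng = np.random.default_rng(1)
        fast = 10 ** rng.normal(4.2, 0.1, 100)
        t1 = estimate_threshold(np.concatenate([10 ** rng.normal(1.5, 0.1, 400), fast]))
        t2 = estimate_threshold(np.concatenate([10 ** rng.normal(2.7, 0.1, 400), fast]))
        assert t1.method == t2.method == "adaptive_bimodal"
        assert t2.value > 2 * t1.value

    def test_fixed_override(self):
        thr = estimate_threshold(np.arange(1.0, 100.0), DetectionConfig(fixed_threshold=42.0))
        assert (thr.value, thr.method) == (42.0, "fixed")

    def test_deterministic(self):
        rng = np.random.default_rng(2)
        v = 10 ** np.concatenate([rng.normal(1.7, 0.2, 300), rng.normal(3.8, 0.2, 100)])
        assert estimate_threshold(v).value == estimate_threshold(v).value


class TestClassifyEvents:
    def test_one_second_constant_trace_single_fixation(self, geometry):
        n = 250
        tr = make_trace(np.arange(n) * 4.0, [(400.0, 300.0)] * n, geometry=geometry)
        fs = detect_fixations(tr)
        assert len(fs) == 1
        f = fs.fixations[0]
        assert f.duration == pytest.approx(996.0)
        assert (f.x, f.y) == (400.0, 300.0)

    def test_two_dwells_one_sweep(self, geometry):
        spec = ScanpathSpec(
            fixation_plan=((300.0, 300.0, 300.0), (900.0, 700.0, 300.0)),
            saccade_dur_range_ms=(40.0, 40.0),
            noise_sd_deg=0.0,
            missing_rate=0.0,
            interocular_offset_px=0.0,
            seed=0,
        )
        tr, truth = generate_trace(spec, geometry)
        fs = detect_fixations(tr)
        assert len(fs) == 2
        for f, tf in zip(fs.fixations, truth.fixations):
            assert abs(f.onset - tf.onset) <= 4.0
            assert abs(f.offset - tf.offset) <= 4.0

    def test_short_blip_removed_by_noise_filter(self, geometry):
        # 20 ms sub-threshold dwell between two sweeps
        t = np.arange(30) * 4.0
        pos = []
        for i in range(30):
            if i < 10:
                pos.append((100.0 + 60.0 * i, 100.0))  # fast sweep
            elif i < 15:
                pos.append((700.0, 100.0))  # 20 ms dwell
            else:
                pos.append((700.0 + 60.0 * (i - 14), 100.0))
        tr = make_trace(t, pos, geometry=geometry)
        ct = fuse_eyes(tr)
        thr = VelocityThreshold(1000.0, "fixed", ct.trace_id)
        fs = classify_events(ct, thr, DetectionConfig(min_fixation_ms=60.0, smooth_window=1))
        assert len(fs) == 0

    def test_sample_partition_is_exhaustive(self, geometry):
        spec = ScanpathSpec(
            fixation_plan=random_fixation_plan(np.random.default_rng(3), geometry),
            noise_sd_deg=0.3,
            missing_rate=0.05,
            seed=3,
        )
        tr, _ = generate_trace(spec, geometry)
        ct = fuse_eyes(tr)
        vs = compute_velocity(ct)
        fs = classify_events(ct, estimate_threshold(vs), DetectionConfig(smooth_window=1))
        labels = fs.sample_labels
        assert labels.shape == (len(tr),)
        assert set(labels) <= {"fixation", "saccade", "discarded", "missing"}
        assert np.sum(labels == "missing") == np.sum(~ct.valid)
        # fixation-labeled samples match the events' sample counts
        assert np.sum(labels == "fixation") == sum(f.n_samples for f in fs.fixations)

    def test_translation_invariance(self, geometry):
        rng = np.random.default_rng(4)
        plan = random_fixation_plan(rng, geometry, n_fixations=5, margin_px=200.0)
        spec = ScanpathSpec(fixation_plan=plan, noise_sd_deg=0.2, missing_rate=0.0, seed=4)
        tr, _ = generate_trace(spec, geometry)
        shifted_plan = tuple((x + 50.0, y - 30.0, d) for x, y, d in plan)
        tr2, _ = generate_trace(
            ScanpathSpec(fixation_plan=shifted_plan, noise_sd_deg=0.2, missing_rate=0.0, seed=4),
            geometry,
        )
        fs1 = detect_fixations(tr)
        fs2 = detect_fixations(tr2)
        assert len(fs1) == len(fs2)
        for a, b in zip(fs1.fixations, fs2.fixations):
            assert b.x - a.x == pytest.approx(50.0, abs=1e-6)
            assert b.y - a.y == pytest.approx(-30.0, abs=1e-6)
            assert a.onset == b.onset and a.offset == b.offset


def _fix(x, y, onset, offset, **kw):
    return Fixation(x=x, y=y, onset=onset, offset=offset,
                    duration=offset - onset, n_samples=max(int((offset - onset) / 4), 1), **kw)


def _fixset(fixations, geometry):
    return FixationSet(
        trace_id="p:s",
        participant_id="p",
        group="g",
        stimulus_id="s",
        fixations=fixations,
        threshold=VelocityThreshold(100.0, "fixed", "p:s"),
        total_on_screen_duration=sum(f.duration for f in fixations),
        geometry=geometry,
    )


class TestMergeFixations:
    def test_close_pair_merges_with_weighted_centroid(self, geometry):
        fs = _fixset(
            [_fix(400.0, 300.0, 0.0, 200.0), _fix(403.0, 301.0, 220.0, 370.0)], geometry
        )
        merged = merge_fixations(fs)
        assert len(merged) == 1
        f = merged.fixations[0]
        assert (f.onset, f.offset) == (0.0, 370.0)
        assert f.merged_from == 2
        # duration-weighted centroid: (200*400 + 150*403) / 350
        assert f.x == pytest.approx((200 * 400.0 + 150 * 403.0) / 350.0)

    def test_far_pair_never_merges(self, geometry):
        fs = _fixset(
            [_fix(100.0, 100.0, 0.0, 200.0), _fix(400.0, 100.0, 210.0, 400.0)], geometry
        )
        assert len(merge_fixations(fs)) == 2

    def test_long_gap_never_merges(self, geometry):
        fs = _fixset(
            [_fix(400.0, 300.0, 0.0, 200.0), _fix(401.0, 300.0, 400.0, 600.0)], geometry
        )
        assert len(merge_fixations(fs)) == 2

    @pytest.mark.parametrize("seed", range(5))
    def test_idempotent_on_random_sets(self, geometry, seed):
        rng = np.random.default_rng(seed)
        t = 0.0
        fixations = []
        for _ in range(12):
            dur = rng.uniform(50, 300)
            fixations.append(
                _fix(rng.uniform(0, 1280), rng.uniform(0, 1024), t, t + dur)
            )
            t += dur + rng.uniform(5, 120)
        once = merge_fixations(_fixset(fixations, geometry))
        twice = merge_fixations(once)
        assert [(f.x, f.y, f.onset, f.offset) for f in once.fixations] == [
            (f.x, f.y, f.onset, f.offset) for f in twice.fixations
        ]


class TestNoiseRobustness:
    def test_lower_noise_never_recovers_fewer_fixations(self, geometry):
        """Recovery count is monotone along a noise ladder at fixed seed."""
        plan = random_fixation_plan(np.random.default_rng(10), geometry)
        counts = []
        for sigma in (0.0, 0.1, 0.2, 0.3, 0.45):
            spec = ScanpathSpec(fixation_plan=plan, noise_sd_deg=sigma,
                                missing_rate=0.02, seed=77)
            tr, truth = generate_trace(spec, geometry)
            fs = detect_fixations(tr)
            ok = 0
            for tf in truth.fixations:
                err = min(
                    (max(abs(f.onset - tf.onset), abs(f.offset - tf.offset))
                     for f in fs.fixations),
                    default=np.inf,
                )
                ok += err <= 8.0
            counts.append(ok)
        assert all(a >= b for a, b in zip(counts, counts[1:]))
        assert counts[0] == len(plan)
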