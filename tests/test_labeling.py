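import numpy as np
import pytest

import fixclust as fc
from fixclust.labeling import FixationCandidate

from conftest import make_recording


def ws(weight, coverage=None):
    weight = np.asarray(weight, dtype=float)
    if coverage is None:
        coverage = np.ones(len(weight), dtype=int)
    return fc.WeightSignal(weight, np.asarray(coverage))


class TestWeightCutoff:
    def test_hand_computed_example(self):
        # weights [0,0,0,1,0,0]: mean 1/6, sample SD 0.40825, cutoff 0.98316
        cut = fc.weight_cutoff(ws([0, 0, 0, 1, 0, 0]), fc.Config())
        assert cut == pytest.approx(1 / 6 + 2 * np.sqrt(np.sum((np.array([0, 0, 0, 1, 0, 0]) - 1 / 6) ** 2) / 5), abs=1e-12)
        assert cut == pytest.approx(0.98316, abs=1e-5)

    def test_constant_weights_give_cutoff_at_that_value(self):
        assert fc.weight_cutoff(ws([0.3] * 10), fc.Config()) == pytest.approx(0.3)

    def test_zero_sd_multiplier_gives_mean(self):
        cut = fc.weight_cutoff(ws([0.0, 1.0]), fc.Config(cutoff_sd=0.0))
        assert cut == pytest.approx(0.5)

    def test_too_few_covered_samples_rejected(self):
        with pytest.raises(fc.InputError):
            fc.weight_cutoff(ws([0.5], [1]), fc.Config())


class TestExtractCandidates:
    def test_all_below_cutoff_is_one_candidate(self):
        cands = fc.extract_candidates(ws(np.zeros(50)), cutoff=0.5)
        assert [(c.start, c.end) for c in cands] == [(0, 50)]

    def test_one_supra_cutoff_sample_splits_in_two(self):
        w = np.zeros(50)
        w[20] = 1.0
        cands = fc.extract_candidates(ws(w), cutoff=0.5)
        assert [(c.start, c.end) for c in cands] == [(0, 20), (21, 50)]

    def test_coverage_gap_breaks_candidates(self):
        w = np.zeros(50)
        cov = np.ones(50, dtype=int)
        cov[30:35] = 0
        w[30:35] = np.nan
        cands = fc.extract_candidates(ws(w, cov), cutoff=0.5)
        assert [(c.start, c.end) for c in cands] == [(0, 30), (35, 50)]

    def test_inclusion_is_at_or_below_cutoff(self):
        cands = fc.extract_candidates(ws(np.full(20, 0.5)), cutoff=0.5)
        assert [(c.start, c.end) for c in cands] == [(0, 20)]


def merge_oracle(spans, rec, cfg):
    """Fixed point of exhaustive pairwise merging, recomputed per pass."""
    from fixclust.labeling import _centroid

    spans = list(spans)
    while True:
        for i in range(len(spans) - 1):
            a, b = spans[i], spans[i + 1]
            ca = _centroid(rec, *a)
            cb = _centroid(rec, *b)
            gap_ms = (b[0] - a[1]) * 1000.0 / rec.fs
            if gap_ms < cfg.merge_gap_ms and np.hypot(
                ca[0] - cb[0], ca[1] - cb[1]
            ) < cfg.merge_dist_deg:
                spans[i : i + 2] = [(a[0], b[1])]
                break
        else:
            return spans


class TestMergeCandidates:
    def rec_with_positions(self, positions, seg=30, gap=6):
        """Candidates of `seg` samples at given x positions, `gap` apart."""
        n = len(positions) * (seg + gap)
        x = np.zeros(n)
        spans = []
        for k, p in enumerate(positions):
            s = k * (seg + gap)
            x[s : s + seg] = p
            x[s + seg : s + seg + gap] = p  # gap samples share the position
            spans.append((s, s + seg))
        return make_recording(x), spans

    def test_close_candidates_merge(self):
        rec, spans = self.rec_with_positions([0.0, 0.5])
        cands = [FixationCandidate(*s) for s in spans]
        out = fc.merge_candidates(cands, rec, fc.Config())
        assert [(c.start, c.end) for c in out] == [(spans[0][0], spans[1][1])]

    def test_distant_candidates_stay_separate(self):
        rec, spans = self.rec_with_positions([0.0, 1.0])
        cands = [FixationCandidate(*s) for s in spans]
        out = fc.merge_candidates(cands, rec, fc.Config())
        assert len(out) == 2

    def test_long_gap_prevents_merge(self):
        rec, spans = self.rec_with_positions([0.0, 0.2], gap=15)  # 50-ms gap
        cands = [FixationCandidate(*s) for s in spans]
        out = fc.merge_candidates(cands, rec, fc.Config())
        assert len(out) == 2

    def test_chain_merges_to_fixed_point(self):
        rec, spans = self.rec_with_positions([0.0, 0.5, 1.0, 1.5])
        cands = [FixationCandidate(*s) for s in spans]
        out = fc.merge_candidates(cands, rec, fc.Config())
        expected = merge_oracle(spans, rec, fc.Config())
        assert [(c.start, c.end) for c in out] == expected

    def test_overlapping_candidates_rejected(self):
        rec, _ = self.rec_with_positions([0.0])
        with pytest.raises(fc.InputError):
            fc.merge_candidates(
                [FixationCandidate(0, 20), FixationCandidate(10, 30)],
                rec,
                fc.Config(),
            )


class TestFilterShort:
    def test_short_candidate_removed(self):
        rec = make_recording(np.zeros(100))
        out = fc.filter_short([FixationCandidate(0, 9)], rec, fc.Config())  # 30 ms
        assert out == []

    def test_exactly_minimum_duration_kept(self):
        rec = make_recording(np.zeros(100))
        out = fc.filter_short([FixationCandidate(0, 12)], rec, fc.Config())  # 40 ms
        assert len(out) == 1
        assert out[0].duration_ms == pytest.approx(40.0)

    def test_empty_input_gives_empty_output(self):
        rec = make_recording(np.zeros(100))
        assert fc.filter_short([], rec, fc.Config()) == []

    def test_quality_descriptors_filled(self):
        rec = make_recording(np.full(100, 3.0), y=np.full(100, -2.0))
        (fix,) = fc.filter_short([FixationCandidate(0, 60)], rec, fc.Config())
        assert fix.x == pytest.approx(3.0)
        assert fix.y == pytest.approx(-2.0)
        assert fix.rms_s2s == pytest.approx(0.0)
        assert fix.frac_missing == 0.0
        assert fix.frac_interpolated == 0.0


class TestDetectFixations:
    def test_two_fixation_step_recovered_exactly(self, step_recording):
        res = fc.detect_fixations(step_recording)
        assert len(res.fixations) == 2
        f1, f2 = res.fixations
        # truth: [0, 150) at 0 deg and [150, 300) at 8 deg
        assert abs(f1.start - 0) <= 1 and abs(f1.end - 150) <= 1
        assert abs(f2.start - 150) <= 1 and abs(f2.end - 300) <= 1
        assert f1.x == pytest.approx(0.0, abs=1e-9)
        assert f2.x == pytest.approx(8.0, abs=1e-9)

    def test_robust_to_one_degree_noise(self, step_recording):
        noisy = fc.add_noise(step_recording, fc.NoiseSpec(1.0), seed=3)
        res = fc.detect_fixations(noisy)
        assert len(res.fixations) == 2

    def test_fully_missing_recording_rejected(self):
        rec = make_recording(np.zeros(300), missing=np.arange(300))
        with pytest.raises(fc.InputError):
            fc.detect_fixations(rec)

    def test_deterministic_bit_identical(self, step_recording):
        noisy = fc.add_noise(step_recording, fc.NoiseSpec(2.0), seed=9)
        r1 = fc.detect_fixations(noisy)
        r2 = fc.detect_fixations(noisy)
        assert [(f.start, f.end, f.x, f.y) for f in r1.fixations] == [
            (f.start, f.end, f.x, f.y) for f in r2.fixations
        ]
        np.testing.assert_array_equal(r1.weight.weight, r2.weight.weight)
        assert r1.cutoff == r2.cutoff

    def test_fixations_disjoint_ordered_and_long_enough(self):
        rec, _ = fc.generate_scanpath(n_fix=8, seed=4)
        noisy = fc.add_noise(rec, fc.NoiseSpec(1.5), seed=5)
        res = fc.detect_fixations(noisy)
        cfg = fc.Config()
        for f in res.fixations:
            assert f.duration_ms >= cfg.min_fix_ms
        for a, b in zip(res.fixations, res.fixations[1:]):
            assert a.end <= b.start

    def test_merge_distance_monotonicity(self):
        rec, _ = fc.generate_scanpath(n_fix=8, seed=4)
        noisy = fc.add_noise(rec, fc.NoiseSpec(2.0), seed=6)
        counts = []
        for dist in (0.1, 0.7, 2.0, 5.0):
            cfg = fc.Config(merge_dist_deg=dist)
            counts.append(len(fc.detect_fixations(noisy, cfg).fixations))
        assert all(a >= b for a, b in zip(counts, counts[1:]))

    def test_cutoff_monotonicity_in_candidate_samples(self):
        rec, _ = fc.generate_scanpath(n_fix=8, seed=4)
        noisy = fc.add_noise(rec, fc.NoiseSpec(2.0), seed=6)
        totals = []
        for sd in (0.5, 1.0, 2.0, 4.0):
            cfg = fc.Config(cutoff_sd=sd)
            res = fc.detect_fixations(noisy, cfg)
            cands = fc.extract_candidates(res.weight, res.cutoff)
            totals.append(sum(c.end - c.start for c in cands))
        assert all(a <= b for a, b in zip(totals, totals[1:]))

    def test_stride_choice_leaves_outcome_measures_stable(self, step_recording):
        # A 20-ms stride and a one-sample stride give the same fixation
        # count; boundaries may shift by at most one nominal stride.
        res20 = fc.detect_fixations(step_recording, fc.Config(step_ms=20.0))
        res1 = fc.detect_fixations(step_recording, fc.Config(step_ms=10.0 / 3))
        assert len(res20.fixations) == len(res1.fixations)
        for a, b in zip(res20.fixations, res1.fixations):
            assert abs(a.start_ms - b.start_ms) <= 20.0
            assert abs(a.end_ms - b.end_ms) <= 20.0
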