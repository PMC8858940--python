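"""Window segmentation, vector magnitude and per-window statistics."""

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

import tabata_ee as t
from tabata_ee.features import EXERCISE, INTERVAL


def make_counts(vm_values):
    """Tri-axial counts whose per-sample VM equals the given values."""
    v = np.asarray(vm_values, dtype=float)
    return np.column_stack([v, np.zeros_like(v), np.zeros_like(v)])


def make_subject():
    return t.SubjectProfile("s", "female", 21.0, 1.67, 59.61,
                            bmi=59.61 / 1.67**2, body_fat=18.0)


class TestWindowPlan:
    @pytest.mark.parametrize("protocol,expected", [
        ((8, 20, 10, 10), "EEI" * 8),
        ((1, 20, 10, 10), "EEI"),
        ((2, 30, 30, 10), "EEEIII" * 2),
    ])
    def test_patterns(self, protocol, expected):
        plan = t.build_window_plan(t.TabataProtocol(*protocol))
        assert len(plan) == len(expected)
        got = "".join("E" if w.period == EXERCISE else "I" for w in plan)
        assert got == expected

    def test_windows_contiguous_and_conserve_time(self):
        proto = t.TabataProtocol(5, 40, 20, 10)
        plan = t.build_window_plan(proto)
        starts = [w.start_s for w in plan]
        ends = [w.end_s for w in plan]
        assert starts[0] == 0
        assert all(e == s for e, s in zip(ends[:-1], starts[1:]))
        assert sum(e - s for s, e in zip(starts, ends)) == proto.duration_s


class TestVectorMagnitude:
    def test_hand_examples(self):
        assert t.vector_magnitude(make_counts([0, 0]), 0, 2) == 0.0
        assert t.vector_magnitude(np.array([[3.0, 4.0, 12.0]]), 0, 1) == 13.0
        two = np.array([[1.0, 2.0, 2.0], [2.0, 3.0, 6.0]])
        assert t.vector_magnitude(two, 0, 2) == 10.0

    def test_empty_window_rejected(self):
        with pytest.raises(ValueError):
            t.vector_magnitude(make_counts([1.0]), 1, 1)

    def test_linearity(self, rng):
        counts = rng.uniform(0, 50, (30, 3))
        assert t.vector_magnitude(2 * counts, 0, 30) == pytest.approx(
            2 * t.vector_magnitude(counts, 0, 30), rel=1e-12)


class TestWindowFeatures:
    def plan1(self):
        return t.build_window_plan(t.TabataProtocol(1, 2, 1, 1))

    def test_constant_signal(self):
        plan = self.plan1()
        counts = make_counts(np.full(9, 5.0))  # 3 windows x 3 samples
        hr = np.full(3, 120.0)
        rows = t.window_features(counts, hr, plan, make_subject(), "site",
                                 sampling_rate=3)
        r = rows[0]
        for attr in ("vm_mean", "vm_min", "vm_max", "vm_p10", "vm_p25",
                     "vm_p50", "vm_p75", "vm_p90"):
            assert getattr(r, attr) == pytest.approx(5.0)
        assert r.vm_sd == 0.0
        assert r.vm_sum == pytest.approx(15.0)
        assert r.hr_mean == 120.0

    def test_median_uses_linear_interpolation(self):
        plan = t.build_window_plan(t.TabataProtocol(1, 2, 2, 2))
        counts = make_counts([1, 2, 3, 4, 1, 1, 1, 1])  # 4 samples/window
        hr = np.full(4, 100.0)
        rows = t.window_features(counts, hr, plan, make_subject(), "site",
                                 sampling_rate=2)
        assert rows[0].vm_p50 == pytest.approx(2.5)

    def test_adjacent_covariance(self, rng):
        plan = self.plan1()
        v = rng.uniform(1, 10, 3)
        counts = make_counts(np.concatenate([v, v, v]))
        hr = np.full(3, 100.0)
        rows = t.window_features(counts, hr, plan, make_subject(), "site",
                                 sampling_rate=3)
        assert rows[0].vm_cov_adjacent == 0.0  # no predecessor
        # window identical to its predecessor: cov equals the variance
        assert rows[1].vm_cov_adjacent == pytest.approx(np.var(v, ddof=1))

    def test_feature_vector_has_14_entries(self, small_features):
        assert len(t.FEATURE_COLUMNS) == 14
        row = small_features.iloc[0]
        assert all(c in small_features.columns for c in t.FEATURE_COLUMNS)
        assert np.isfinite(row[t.FEATURE_COLUMNS].to_numpy(float)).all()

    @settings(max_examples=30, deadline=None, derandomize=True)
    @given(st.integers(0, 2**31 - 1))
    def test_percentile_ordering_invariant(self, seed):
        rng = np.random.default_rng(seed)
        plan = self.plan1()
        counts = rng.uniform(0, 100, (9, 3))
        hr = rng.uniform(60, 180, 3)
        for r in t.window_features(counts, hr, plan, make_subject(), "s",
                                   sampling_rate=3):
            q = [r.vm_min, r.vm_p10, r.vm_p25, r.vm_p50, r.vm_p75,
                 r.vm_p90, r.vm_max]
            assert all(a <= b + 1e-12 for a, b in zip(q, q[1:]))
            assert r.vm_sd >= 0 and r.vm_sum >= 0

    def test_short_hr_gap_interpolated_long_gap_rejected(self):
        plan = t.build_window_plan(t.TabataProtocol(1, 20, 10, 10))
        counts = make_counts(np.ones(30))
        hr = np.full(30, 150.0)
        hr[5] = np.nan
        rows = t.window_features(counts, hr, plan, make_subject(), "s",
                                 sampling_rate=1)
        assert rows[0].hr_mean == pytest.approx(150.0)
        hr[3:14] = np.nan  # 11-s gap exceeds the 10-s window
        with pytest.raises(ValueError, match="gap"):
            t.window_features(counts, hr, plan, make_subject(), "s",
                              sampling_rate=1)

    def test_length_mismatch_rejected(self):
        plan = self.plan1()
        with pytest.raises(ValueError):
            t.window_features(make_counts(np.ones(8)), np.full(3, 100.0),
                              plan, make_subject(), "s", sampling_rate=3)


class TestStageVM:
    def make_rows(self, vm_sums, stage=0):
        rows = []
        for i, v in enumerate(vm_sums):
            rows.append(t.WindowFeatureRow(
                window_index=i, stage_index=stage, period=EXERCISE,
                site="s", vm_sum=v, vm_mean=0, vm_sd=0, vm_cov_adjacent=0,
                vm_min=0, vm_max=0, vm_p10=0, vm_p25=0, vm_p50=0, vm_p75=0,
                vm_p90=0, hr_mean=100, height=1.6, weight=60, sex_code=0))
        return rows

    def test_sums_and_linearity(self):
        assert t.stage_vm(self.make_rows([100, 200, 0]), 0) == 300
        assert t.stage_vm(self.make_rows([0, 0, 0]), 0) == 0
        assert t.stage_vm(self.make_rows([2 * v for v in (100, 200, 0)]), 0) \
            == 600

    def test_missing_stage_rejected(self):
        with pytest.raises(ValueError):
            t.stage_vm(self.make_rows([1.0]), stage=3)


class TestIntensitySummary:
    def test_mets_and_pct_hrmax(self, classic_plan):
        sub = t.SubjectProfile("s", "male", 20.0, 1.7, 60.0,
                               bmi=60 / 1.7**2, body_fat=12.0)
        hr = np.full(240, 150.0)
        hr[0] = 165.0
        ee = np.full(24, 1.5)
        s = t.intensity_summary(hr, ee, sub, classic_plan)
        assert s.mean_mets == pytest.approx(9.0)  # 1.5 * 360 / 60
        assert s.pct_hrmax == pytest.approx(82.5)  # 165 / 200
        assert s.max_hr >= s.mean_exercise_hr

    def test_zero_ee(self, classic_plan):
        sub = make_subject()
        s = t.intensity_summary(np.full(240, 120.0), np.zeros(24), sub,
                                classic_plan)
        assert s.mean_mets == 0.0

    def test_zero_weight_rejected(self, classic_plan):
        sub = make_subject()
        object.__setattr__(sub, "weight", 0.0)
        with pytest.raises(ValueError):
            t.intensity_summary(np.full(240, 120.0), np.zeros(24), sub,
                                classic_plan)
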