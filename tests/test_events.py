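"""Event detection, epoching, normalization and metric tests with brute-force oracles."""

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

import hemoloco as hl
from conftest import make_epochs

RATE = 32.0


def brute_force_metrics(row, rate=RATE, pre_s=5.0, window=(0.0, 5.0), halfwidth_s=0.25):
    """Independent full-scan recomputation of every metric for one epoch row."""
    a = int(round((window[0] + pre_s) * rate))
    b = int(round((window[1] + pre_s) * rate))
    seg = [row[i] for i in range(a, b + 1)]
    dt = 1.0 / rate
    # trapezoid by explicit sum
    auc = sum((seg[i] + seg[i + 1]) / 2.0 * dt for i in range(len(seg) - 1))
    imax = max(range(len(seg)), key=lambda i: seg[i])
    imin = min(range(len(seg)), key=lambda i: seg[i])
    hw = int(round(halfwidth_s * rate))

    def win_mean(idx):
        lo, hi = max(idx - hw, 0), min(idx + hw, len(seg) - 1)
        vals = seg[lo : hi + 1]
        return sum(vals) / len(vals)

    t_max, t_min = imax * dt, imin * dt
    max_peak, min_peak = win_mean(imax), win_mean(imin)
    return dict(
        auc=auc,
        max_peak=max_peak,
        time_to_max=t_max,
        min_peak=min_peak,
        time_to_min=t_min,
        norm_speed_max=abs(max_peak) / max(t_max, dt),
        norm_speed_min=abs(min_peak) / max(t_min, dt),
    )


class TestDetect:
    def test_all_zero_trace_has_no_onsets(self):
        trace = hl.LocomotionTrace(np.zeros(int(750 * RATE)), RATE)
        assert hl.detect_events(trace).size == 0

    def test_single_bout_onset_at_first_movement_sample(self):
        x = np.zeros(int(750 * RATE))
        start = int(100 * RATE)
        x[start : start + int(3 * RATE)] = 2.0
        onsets = hl.detect_events(hl.LocomotionTrace(x, RATE))
        assert np.array_equal(onsets, [start])

    def test_generator_round_trip_recovers_ground_truth(self):
        cfg = hl.SimConfig(seed=13, n_events=12)
        loco, truth = hl.simulate_locomotion(cfg)
        detected = hl.detect_events(hl.LocomotionTrace(loco, RATE))
        assert np.array_equal(detected, truth)

    def test_short_runs_and_unquiet_onsets_skipped(self):
        x = np.zeros(int(100 * RATE))
        x[int(30 * RATE) : int(30 * RATE) + 4] = 1.0  # too short (0.125 s)
        onsets = hl.detect_events(hl.LocomotionTrace(x, RATE), min_duration_s=0.5)
        assert onsets.size == 0


class TestEpoch:
    def test_exact_window_row_equals_whole_trace(self):
        trace = np.arange(800.0)
        ep = hl.epoch(trace, [160], RATE)
        assert ep.n_events == 1
        np.testing.assert_array_equal(ep.data[0], trace)
        assert ep.onset_index == 160

    def test_underrunning_onset_dropped(self, caplog):
        trace = np.arange(800.0)
        with caplog.at_level("WARNING"):
            ep = hl.epoch(trace, [100, 160], RATE)
        assert ep.n_events == 1
        assert "dropped" in caplog.text

    def test_ramp_segment_reproduced_exactly(self):
        trace = np.arange(4000.0)
        ep = hl.epoch(trace, [1000], RATE)
        np.testing.assert_array_equal(ep.data[0], trace[840:1640])

    def test_nonpositive_rate_rejected(self):
        with pytest.raises(ValueError, match="rate"):
            hl.epoch(np.zeros(800), [160], 0.0)

    def test_keys_broadcast_across_events(self):
        trace = np.zeros(4000)
        ep = hl.epoch(trace, [500, 1500], RATE, keys=dict(animal_id="M1", vessel="artery"))
        assert list(ep.keys.animal_id) == ["M1", "M1"]
        assert list(ep.keys.event_id) == [0, 1]


class TestNormalize:
    def test_constant_row_normalizes_to_zero(self):
        ep = make_epochs(np.full((1, 800), 100.0), normalized=False, units="um")
        out = hl.normalize(ep)
        assert np.allclose(out.data, 0.0)
        assert out.units == "%" and out.normalized

    def test_printed_equation_on_hemodynamic_scale(self):
        row = np.full(800, 100.0)
        row[300:] = 107.33
        out = hl.normalize(make_epochs(row, normalized=False, units="um"))
        assert out.data[0, 400] == pytest.approx(7.33)

    def test_negative_baseline_preserves_sign_through_abs_denominator(self):
        row = np.full(800, -2.0)
        row[200:] = -1.0
        out = hl.normalize(make_epochs(row, normalized=False, units="a.u."))
        assert out.data[0, 300] == pytest.approx(0.5)

    def test_zero_baseline_falls_back_to_subtraction_and_flags(self):
        row = np.zeros(800)
        row[400:] = 3.0
        out = hl.normalize(make_epochs(row, normalized=False, units="a.u."))
        assert out.flags[0]
        assert out.data[0, 500] == pytest.approx(3.0)

    def test_double_normalization_rejected(self):
        out = hl.normalize(make_epochs(np.full((1, 800), 5.0), normalized=False))
        with pytest.raises(ValueError, match="already"):
            hl.normalize(out)

    @settings(deadline=None, max_examples=25, derandomize=True)
    @given(k=st.floats(min_value=0.01, max_value=100.0),
           seed=st.integers(min_value=0, max_value=10_000))
    def test_scale_invariance_for_positive_baselines(self, k, seed):
        rng = np.random.default_rng(seed)
        row = 100.0 + rng.normal(0, 5, 800)
        a = hl.normalize(make_epochs(row, normalized=False, units="um"))
        b = hl.normalize(make_epochs(k * row, normalized=False, units="um"))
        np.testing.assert_allclose(a.data, b.data, atol=1e-9)


class TestMetrics:
    def test_constant_one_gives_auc_five(self):
        table = hl.metrics(make_epochs(np.ones((1, 800))))
        assert table.auc[0] == pytest.approx(5.0)

    def test_triangle_fixture_matches_brute_force(self):
        t = np.arange(800) / RATE - 5.0
        row = np.where((t >= 0) & (t <= 5), 10.0 * (1.0 - np.abs(t - 2.5) / 2.5), 0.0)
        table = hl.metrics(make_epochs(row))
        expect = brute_force_metrics(row)
        assert table.auc[0] == pytest.approx(25.0)  # exact: vertices on the grid
        assert table.time_to_max[0] == pytest.approx(2.5)
        assert table.max_peak[0] < 10.0  # ±0.25 s averaging across the vertex
        for k, v in expect.items():
            assert table[k][0] == pytest.approx(v, abs=1e-12)

    def test_normalized_speed_is_peak_over_time(self):
        row = np.zeros(800)
        row[252:269] = 7.33  # plateau spanning ±0.25 s around t = 3.125 s
        row[260] = 7.34  # pin the argmax at the plateau center
        table = hl.metrics(make_epochs(row))
        assert table.time_to_max[0] == pytest.approx(3.125)
        assert table.max_peak[0] == pytest.approx(7.33, abs=0.01)
        assert table.norm_speed_max[0] == pytest.approx(
            table.max_peak[0] / table.time_to_max[0]
        )
        assert table.norm_speed_max[0] == pytest.approx(2.346, abs=0.01)

    def test_every_metric_matches_brute_force_on_random_epochs(self):
        rng = np.random.default_rng(99)
        data = rng.normal(0, 3, (200, 800))
        table = hl.metrics(make_epochs(data))
        for i in range(200):
            expect = brute_force_metrics(data[i])
            for k, v in expect.items():
                assert table[k][i] == pytest.approx(v, abs=1e-10), (i, k)

    def test_unnormalized_epochs_rejected(self):
        with pytest.raises(ValueError, match="normalized"):
            hl.metrics(make_epochs(np.ones((1, 800)), normalized=False))

    def test_window_outside_epoch_rejected(self):
        with pytest.raises(ValueError, match="window"):
            hl.metrics(make_epochs(np.ones((1, 800))), window_s=(0.0, 30.0))


class TestRankAndSplit:
    def test_study_scale_split_sizes(self):
        table = pd.DataFrame({"locomotion_auc": np.arange(2343.0)})
        bottom, top = hl.rank_and_split(table, q=0.10)
        assert len(bottom) == 234 and len(top) == 234

    def test_small_distinct_split(self):
        table = pd.DataFrame({"locomotion_auc": [5, 1, 9, 3, 7, 2, 8, 4, 6, 0]})
        bottom, top = hl.rank_and_split(table, q=0.2)
        assert sorted(bottom.locomotion_auc) == [0, 1]
        assert sorted(top.locomotion_auc) == [8, 9]

    def test_boundary_ties_resolved_by_original_order(self):
        table = pd.DataFrame({"locomotion_auc": [1.0, 1.0, 1.0, 2.0, 3.0]})
        bottom, _ = hl.rank_and_split(table, q=0.2)
        assert list(bottom.index) == [0]  # stable sort keeps first occurrence

    def test_too_few_events_rejected(self):
        with pytest.raises(ValueError, match="<"):
            hl.rank_and_split(pd.DataFrame({"locomotion_auc": [1.0, 2.0]}), q=0.1)


class TestGrandAverage:
    def test_single_row_sem_zero_by_convention(self):
        mean, sem, n = hl.grand_average(np.array([[1.0, 2.0, 3.0]]))
        np.testing.assert_array_equal(mean, [1, 2, 3])
        assert not sem.any() and n == 1

    def test_plus_minus_one_rows(self):
        data = np.array([[1.0, 1.0], [-1.0, -1.0]])
        mean, sem, n = hl.grand_average(data)
        # brute force: SD = sqrt(((1-0)^2 + (-1-0)^2)/1) = sqrt(2); SEM = sqrt(2)/sqrt(2)
        np.testing.assert_allclose(mean, 0.0)
        np.testing.assert_allclose(sem, 1.0)

    def test_row_permutation_invariance(self):
        rng = np.random.default_rng(7)
        data = rng.normal(size=(20, 50))
        m1, s1, _ = hl.grand_average(data)
        perm = rng.permutation(20)
        m2, s2, _ = hl.grand_average(data[perm])
        np.testing.assert_allclose(m1, m2)
        np.testing.assert_allclose(s1, s2)
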