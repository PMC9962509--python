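"""Peak finding, event matching, zoned MAE scoring."""

import math

import numpy as np
import pytest

from gaitesn.events import EventSet
from gaitesn.evaluation import (
    EventMatchReport,
    PeakFinderConfig,
    compute_event_mae,
    compute_grf_mae,
    detect_predicted_events,
    match_events,
    zone_mask,
)


def _brute_force_peaks(y, floor, distance):
    """Independent peak finder: strict maxima above floor, higher-first pruning."""
    cand = [
        i for i in range(1, y.size - 1)
        if y[i] > y[i - 1] and y[i] > y[i + 1] and y[i] >= floor
    ]
    kept = []
    for i in sorted(cand, key=lambda i: (-y[i], i)):
        if all(abs(i - j) >= distance for j in kept):
            kept.append(i)
    return sorted(kept)


class TestDetectPredictedEvents:
    def test_single_impulse(self):
        y = np.zeros(400)
        y[137] = 1.0
        cfg = PeakFinderConfig(min_peak_distance=1.06)
        assert detect_predicted_events(y, 200.0, cfg).tolist() == [137]

    def test_close_peaks_keep_the_higher(self):
        y = np.zeros(600)
        y[100] = 0.8
        y[200] = 1.0  # 0.5 s later at 200 Hz
        cfg = PeakFinderConfig(min_peak_distance=1.06)
        assert detect_predicted_events(y, 200.0, cfg).tolist() == [200]

    def test_all_zero_row_yields_no_peaks(self):
        cfg = PeakFinderConfig(min_peak_distance=0.5)
        assert detect_predicted_events(np.zeros(100), 200.0, cfg).size == 0

    def test_tiny_distance_degenerates_to_plain_extrema(self):
        rng = np.random.default_rng(0)
        y = rng.normal(size=150)
        cfg = PeakFinderConfig(min_peak_distance=1e-9, relative_height_floor=0.0)
        got = detect_predicted_events(y, 200.0, cfg)
        strict = [i for i in range(1, 149) if y[i] > y[i - 1] and y[i] > y[i + 1]
                  and y[i] > 0]
        assert got.tolist() == strict

    @pytest.mark.parametrize("seed", range(5))
    def test_against_brute_force_oracle(self, seed):
        rng = np.random.default_rng(seed)
        y = np.zeros(200)
        spikes = rng.choice(200, size=12, replace=False)
        y[spikes] = rng.uniform(0.2, 1.0, 12)
        cfg = PeakFinderConfig(min_peak_distance=0.05, relative_height_floor=0.3)
        got = detect_predicted_events(y, 200.0, cfg)
        want = _brute_force_peaks(y, 0.3 * y.max(), round(0.05 * 200))
        assert got.tolist() == want


class TestMatchEvents:
    def test_identical_lists_zero_error(self):
        rep = match_events([10, 200, 390], [10, 200, 390], 200.0)
        assert np.all(rep.errors_ms == 0.0)
        assert rep.unmatched_targets == 0

    def test_constant_shift_in_ms(self):
        rep = match_events([10, 200, 390], [12, 202, 392], 200.0)
        assert np.allclose(rep.errors_ms, 10.0)  # 2 samples at 200 Hz

    def test_empty_predictions_all_unmatched(self):
        rep = match_events([10, 20], [], 200.0)
        assert rep.unmatched_targets == 2
        assert math.isnan(rep.mae_ms)

    def test_one_to_one(self):
        rep = match_events([10, 11], [10], 200.0)
        assert len(rep.pairs) == 1
        assert rep.unmatched_targets == 1

    @pytest.mark.parametrize("seed", range(6))
    def test_greedy_bounded_by_optimal_assignment_oracle(self, seed):
        """Greedy-by-distance matching can only exceed the optimal total.

        On adversarial spacings greedy and the exhaustive minimum-total
        assignment genuinely diverge; the contract is the documented greedy
        rule, so only the one-sided bound is asserted here (the realistic
        near-diagonal case is checked separately).
        """
        from itertools import permutations

        rng = np.random.default_rng(seed)
        targets = np.sort(rng.choice(500, size=4, replace=False))
        preds = np.sort(rng.choice(500, size=5, replace=False))
        rep = match_events(targets, preds, 200.0)
        assert len(rep.pairs) == 4
        best = min(
            sum(abs(int(t) - int(p)) for t, p in zip(targets, perm)) / 200.0 * 1000
            for perm in permutations(preds, len(targets))
        )
        assert rep.errors_ms.sum() >= best - 1e-9

    @pytest.mark.parametrize("seed", range(6))
    def test_greedy_optimal_on_gait_like_instances(self, seed):
        """One prediction near each target (plus a spurious one): greedy = optimal."""
        from itertools import permutations

        rng = np.random.default_rng(seed)
        targets = np.arange(4) * 200 + rng.integers(0, 20)
        preds = np.sort(np.concatenate([
            targets + rng.integers(-10, 10, size=4), [900]
        ]))
        rep = match_events(targets, preds, 200.0)
        best = min(
            sum(abs(int(t) - int(p)) for t, p in zip(targets, perm)) / 200.0 * 1000
            for perm in permutations(preds, len(targets))
        )
        assert rep.errors_ms.sum() == pytest.approx(best)


class TestEventMae:
    def _report(self, errors):
        return EventMatchReport(errors_ms=np.asarray(errors, dtype=float))

    def test_single_record_mean(self):
        res = compute_event_mae([self._report([10.0, 20.0])], "HS")
        assert res.value == pytest.approx(15.0)

    def test_record_weighted_not_pair_weighted(self):
        res = compute_event_mae([self._report([10.0]), self._report([30.0])], "HS")
        assert res.value == pytest.approx(20.0)

    def test_unbalanced_records_diverge_from_pair_weighting(self):
        # record A: one 0 ms match; record B: nine 10 ms matches
        a = self._report([0.0])
        b = self._report([10.0] * 9)
        res = compute_event_mae([a, b], "TO")
        pair_weighted = 90.0 / 10.0
        assert res.value == pytest.approx(5.0)  # (0 + 10) / 2, record-weighted
        assert res.value != pytest.approx(pair_weighted)

    def test_no_matches_is_nan_with_count(self):
        rep = EventMatchReport(unmatched_targets=4)
        res = compute_event_mae([rep], "FF")
        assert math.isnan(res.value)
        assert res.unmatched == 4


def _cycles(starts, cycle_len):
    out = []
    for s in starts:
        out.append({"HS": s, "HP": s + cycle_len // 5, "FF": s + cycle_len // 3,
                    "TP": s + cycle_len // 2, "TO": s + int(0.6 * cycle_len)})
    return out


class TestZoneMask:
    def test_full_cycle_zone_covers_complete_cycles_only(self):
        events = EventSet(_cycles([100, 300, 500], 200), 200.0)
        mask = zone_mask(events, (0.0, 100.0), 700)
        assert mask[:100].sum() == 0
        assert mask[100:500].all()
        assert mask[500:].sum() == 0  # no next HS: incomplete cycle

    def test_window_arithmetic_on_200_sample_cycle(self):
        events = EventSet(_cycles([0, 200], 200), 200.0)
        mask = zone_mask(events, (10.0, 18.0), 400)
        assert np.array_equal(np.nonzero(mask)[0], np.arange(20, 36))

    def test_zones_disjoint(self):
        events = EventSet(_cycles([0, 200, 400], 200), 200.0)
        a = zone_mask(events, (10.0, 18.0), 600)
        b = zone_mask(events, (44.0, 52.0), 600)
        assert not np.any(a & b)

    def test_partition_reassembles_full_cycle(self):
        events = EventSet(_cycles([0, 200], 200), 200.0)
        full = zone_mask(events, (0.0, 100.0), 400)
        parts = [zone_mask(events, z, 400)
                 for z in ((0.0, 30.0), (30.0, 64.0), (64.0, 100.0))]
        assert np.array_equal(np.logical_or.reduce(parts), full)

    def test_invalid_zone(self):
        events = EventSet(_cycles([0, 200], 200), 200.0)
        with pytest.raises(ValueError, match="zone"):
            zone_mask(events, (18.0, 10.0), 400)


class TestGrfMae:
    def test_identical_arrays_zero(self):
        y = np.random.default_rng(0).normal(size=(3, 50))
        mask = np.ones(50, dtype=bool)
        res = compute_grf_mae([y], [y], [mask])
        assert all(res[ax].value == 0.0 for ax in ("AP", "ML", "V"))

    def test_constant_offset(self):
        y = np.zeros((3, 40))
        p = y.copy()
        p[2] += 0.05
        res = compute_grf_mae([p], [y], [np.ones(40, dtype=bool)])
        assert res["V"].value == pytest.approx(0.05)
        assert res["AP"].value == 0.0

    def test_two_record_hand_oracle(self):
        t1 = np.zeros((3, 4))
        p1 = t1 + np.array([[0.1], [0.0], [0.2]])
        t2 = np.zeros((3, 2))
        p2 = t2 + np.array([[0.3], [0.0], [0.4]])
        masks = [np.ones(4, dtype=bool), np.ones(2, dtype=bool)]
        res = compute_grf_mae([p1, p2], [t1, t2], masks)
        assert res["AP"].value == pytest.approx((0.1 + 0.3) / 2)
        assert res["V"].value == pytest.approx((0.2 + 0.4) / 2)

    def test_empty_mask_records_skipped(self):
        y = np.zeros((3, 10))
        res = compute_grf_mae([y, y + 1], [y, y],
                              [np.zeros(10, dtype=bool), np.ones(10, dtype=bool)])
        assert res["V"].value == pytest.approx(1.0)
        assert res["V"].n_records == 1
        res_none = compute_grf_mae([y], [y], [np.zeros(10, dtype=bool)])
        assert math.isnan(res_none["V"].value)

    def test_mae_symmetry_and_triangle(self):
        rng = np.random.default_rng(1)
        a, b, c = (rng.normal(size=(3, 30)) for _ in range(3))
        mask = [np.ones(30, dtype=bool)]

        def mae(x, y):
            return compute_grf_mae([x], [y], mask)["V"].value

        assert mae(a, b) == pytest.approx(mae(b, a))
        assert mae(a, c) <= mae(a, b) + mae(b, c) + 1e-12
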