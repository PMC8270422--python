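"""Discrimination and calibration metrics against independent oracles."""

import numpy as np
import pandas as pd
import pytest

from chime.core import MetricError
from chime.validation import (
    brier_score,
    calibration,
    compare_models,
    harrell_c,
    r_squared,
    rmspe,
)


def brute_force_c(times, events, scores):
    """O(n^2) pair-enumeration oracle for Harrell's C."""
    credit, usable = 0.0, 0
    n = len(times)
    for i in range(n):
        for j in range(n):
            if i == j or times[i] >= times[j] or not events[i]:
                continue
            usable += 1
            if scores[i] > scores[j]:
                credit += 1.0
            elif scores[i] == scores[j]:
                credit += 0.5
    return credit / usable


class TestHarrellC:
    def test_perfectly_ordered_scores(self):
        times = np.array([1.0, 2.0, 3.0, 4.0])
        events = np.ones(4)
        scores = np.array([0.9, 0.7, 0.5, 0.3])
        c, _ = harrell_c(times, events, scores, B=0)
        assert c == 1.0

    def test_worked_example(self):
        times = [5, 3, 8, 2]
        events = [1, 1, 1, 0]
        scores = [0.8, 0.9, 0.85, 0.7]
        c, _ = harrell_c(times, events, scores, B=0)
        assert c == pytest.approx(2 / 3)

    def test_all_scores_tied_gives_half(self):
        c, _ = harrell_c([1, 2, 3], [1, 1, 1], [0.5, 0.5, 0.5], B=0)
        assert c == 0.5

    def test_no_usable_pairs_rejected(self):
        with pytest.raises(MetricError):
            harrell_c([5, 5], [1, 1], [0.2, 0.8], B=0)

    def test_matches_brute_force_on_random_instances(self):
        rng = np.random.default_rng(0)
        for _ in range(40):
            n = rng.integers(5, 60)
            times = rng.integers(1, 15, n).astype(float)
            events = rng.integers(0, 2, n).astype(float)
            scores = np.round(rng.random(n), 2)
            if not ((events > 0) & (times < times.max())).any():
                continue
            c, _ = harrell_c(times, events, scores, B=0)
            assert c == pytest.approx(
                brute_force_c(times, events, scores), abs=1e-12)

    def test_agrees_with_lifelines_without_ties(self):
        from lifelines.utils import concordance_index
        rng = np.random.default_rng(1)
        times = rng.exponential(5, 300) + rng.random(300) * 1e-6
        events = rng.integers(0, 2, 300)
        scores = rng.random(300)
        c, _ = harrell_c(times, events, scores, B=0)
        # lifelines orders by predicted survival time (higher = later)
        assert c == pytest.approx(
            concordance_index(times, -scores, events), abs=1e-12)

    def test_bootstrap_ci_brackets_estimate(self):
        rng = np.random.default_rng(2)
        times = rng.exponential(5, 200)
        events = rng.integers(0, 2, 200)
        scores = -times + rng.normal(0, 2, 200)
        c, (lo, hi) = harrell_c(times, events, scores, B=50, seed=3)
        assert lo <= c <= hi
        assert hi - lo < 0.3


class TestCalibration:
    def test_self_consistent_predictions_near_identity(self):
        rng = np.random.default_rng(4)
        pred = rng.uniform(0.02, 0.5, 100_000)
        obs = (rng.random(100_000) < pred).astype(float)
        table = calibration(pred, obs)
        assert 0.9 <= table.slope <= 1.1
        assert abs(table.intercept) <= 0.01
        assert table.n_groups == 10

    def test_doubled_predictions_halve_the_slope(self):
        rng = np.random.default_rng(5)
        pred = rng.uniform(0.02, 0.4, 50_000)
        obs = (rng.random(50_000) < pred).astype(float)
        table = calibration(np.clip(2 * pred, 0, 1), obs)
        assert table.slope == pytest.approx(0.5, abs=0.05)

    def test_sparse_decile_triggers_regrouping(self):
        rng = np.random.default_rng(6)
        n = 2_000
        pred = np.sort(rng.uniform(0, 1, n))
        obs = np.zeros(n)
        # events only in the top half: bottom deciles hold < 5 events
        obs[-300:] = (rng.random(300) < 0.5).astype(float)
        table = calibration(pred, obs)
        assert table.n_groups < 10
        assert table.n_groups == 3 or \
            (table.groups["events"] >= 5).all()

    def test_floor_of_three_groups(self):
        rng = np.random.default_rng(7)
        pred = rng.uniform(0, 1, 200)
        obs = np.zeros(200)
        obs[:6] = 1.0
        table = calibration(pred, obs)
        assert table.n_groups >= 3

    def test_too_few_events_rejected(self):
        rng = np.random.default_rng(8)
        with pytest.raises(MetricError):
            calibration(rng.random(100), np.r_[np.ones(2), np.zeros(98)])


class TestEndpointMetrics:
    def test_rmspe_values(self):
        assert rmspe([10.0, 20.0], [10.0, 20.0]) == 0.0
        assert rmspe([10, 20], [12, 16]) == pytest.approx(np.sqrt(10))
        assert rmspe([5.0], [9.0]) == 4.0
        with pytest.raises(MetricError):
            rmspe([1, 2], [1])

    def test_rmspe_relative_mode(self):
        assert rmspe([11.0], [10.0], mode="relative") == pytest.approx(0.1)
        with pytest.raises(MetricError):
            rmspe([1.0], [0.0], mode="relative")

    def test_rmspe_order_invariant(self):
        p, o = np.array([1.0, 5.0, 9.0]), np.array([2.0, 4.0, 10.0])
        perm = [2, 0, 1]
        assert rmspe(p, o) == rmspe(p[perm], o[perm])

    def test_r_squared_values(self):
        assert r_squared([1, 2, 3], [1, 2, 3]) == 1.0
        obs = np.array([1.0, 2.0, 4.0])
        assert r_squared(np.full(3, obs.mean()), obs) == pytest.approx(0.0)
        assert r_squared([1, 2, 3], [1, 2, 4]) == \
            pytest.approx(1 - 1 / (14 / 3), abs=1e-9)
        with pytest.raises(MetricError):
            r_squared([1, 2], [3, 3])

    def test_brier_excludes_early_censoring(self):
        times = np.array([2.0, 12.0, 11.0, 3.0])
        events = np.array([1.0, 0.0, 0.0, 0.0])   # last censored before 10y
        pred = np.array([1.0, 0.0, 0.0, 0.9])
        assert brier_score(times, events, pred, horizon=10.0) == 0.0


class TestCompareModels:
    def _observed(self, n=1_500, seed=9):
        rng = np.random.default_rng(seed)
        risk = rng.uniform(0.05, 0.6, n)
        event = rng.random(n) < risk
        times = np.where(event, rng.uniform(1, 10, n), 12.0)
        obs = pd.DataFrame({"id": [f"p{i}" for i in range(n)],
                            "time_mortality": times,
                            "event_mortality": event.astype(float)})
        return obs, risk

    def test_report_shape_and_quality(self):
        obs, risk = self._observed()
        pred = pd.DataFrame({"id": obs["id"], "mortality": risk})
        report = compare_models({"mine": pred}, obs, horizon=10.0,
                                c_bootstrap=0)
        row = report[report["outcome"] == "mortality"].iloc[0]
        assert row["c"] > 0.6
        assert row["slope"] == pytest.approx(1.0, abs=0.25)
        summary = report[report["status"] == "summary"].iloc[0]
        assert summary["rmspe"] < 2.0

    def test_missing_outcome_is_cell_not_failure(self):
        obs, risk = self._observed()
        obs["time_ihd"] = obs["time_mortality"]
        obs["event_ihd"] = obs["event_mortality"]
        pred = pd.DataFrame({"id": obs["id"], "mortality": risk})
        report = compare_models({"m": pred}, obs, c_bootstrap=0)
        assert (report[report["outcome"] == "ihd"]["status"] == "missing").all()

    def test_missing_individual_is_join_error(self):
        obs, risk = self._observed(n=100)
        pred = pd.DataFrame({"id": obs["id"][:-1], "mortality": risk[:-1]})
        with pytest.raises(MetricError, match="missing"):
            compare_models({"m": pred}, obs, c_bootstrap=0)
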