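"""Person-period construction, AFT fitting, AIC selection, bootstrap."""

import numpy as np
import pandas as pd
import pytest

from chime.core import FitError, MetricError, Term
from chime.estimation import (
    backwards_select,
    bootstrap_coefficients,
    build_person_periods,
    compute_knots,
    fit_aft,
    optimism_corrected_c,
    person_outcome_survival,
    select_family,
)
from chime.synthetic import aft_episode_panel


def _design_panel(rows):
    """Minimal design-layout panel: id, year, covariates, events."""
    df = pd.DataFrame(rows)
    defaults = {"age": 60.0, "duration": 0.0, "female": 0.0, "diabetes": 0.0,
                "smoking_current": 0.0, "smoking_past": 0.0, "hba1c": 6.0,
                "censored": 0.0}
    for c, v in defaults.items():
        if c not in df.columns:
            df[c] = v
    for c in df.columns:
        if c.startswith("event_") or c.startswith("hist_"):
            df[c] = df[c].fillna(0.0)
    return df


class TestBuildPersonPeriods:
    def test_within_year_measurements_averaged(self):
        panel = _design_panel([
            {"id": "a", "year": 0, "hba1c": 6.0, "event_mortality": 0},
            {"id": "a", "year": 1, "hba1c": 7.0, "event_mortality": 0},
            {"id": "a", "year": 1, "hba1c": 8.0, "event_mortality": 0},
        ])
        table = build_person_periods(panel)
        y1 = table.frame[(table.frame["id"] == "a")
                         & (table.frame["year"] == 1)]
        assert y1["hba1c"].iloc[0] == pytest.approx(7.5)
        assert len(table.frame) == 2

    def test_event_becomes_history_next_cycle(self):
        rows = [{"id": "a", "year": y, "event_mi": 1 if y == 2 else 0}
                for y in range(5)]
        table = build_person_periods(_design_panel(rows))
        hist = table.frame.sort_values("year")["hist_mi"].tolist()
        assert hist == [0, 0, 0, 1, 1]
        # at risk for mi only before it becomes history
        assert table.frame.sort_values("year")["at_risk_mi"].tolist() == \
            [1, 1, 1, 0, 0]

    def test_no_rows_after_death(self):
        rows = [{"id": "a", "year": y,
                 "event_mortality": 1 if y == 4 else 0} for y in range(8)]
        table = build_person_periods(_design_panel(rows))
        assert table.frame["year"].max() == 4

    def test_gap_years_carried_forward_with_flag(self):
        panel = _design_panel([
            {"id": "a", "year": 0, "hba1c": 6.0},
            {"id": "a", "year": 3, "hba1c": 9.0},
        ])
        table = build_person_periods(panel)
        f = table.frame.sort_values("year")
        assert list(f["year"]) == [0, 1, 2, 3]
        assert f["hba1c"].tolist() == [6.0, 6.0, 6.0, 9.0]
        assert f["carried_forward"].tolist() == [0.0, 1.0, 1.0, 0.0]

    def test_history_propagation_is_monotone(self, small_cohort):
        _, panel, _ = small_cohort
        table = build_person_periods(panel)
        for col in ("hist_mi", "hist_cataract", "hist_renal_failure"):
            mono = (table.frame.sort_values(["id", "year"])
                    .groupby("id")[col]
                    .apply(lambda s: s.is_monotonic_increasing))
            assert mono.all()


class TestComputeKnots:
    def test_linear_interpolation_percentiles(self):
        k = compute_knots(np.arange(1, 101, dtype=float))
        assert k == pytest.approx((10.9, 50.5, 90.1))

    def test_constant_vector_demotes(self):
        with pytest.warns(UserWarning, match="demoting"):
            assert compute_knots(np.ones(50)) is None

    def test_small_sample_strictly_ascending(self):
        k = compute_knots(np.arange(1, 11, dtype=float))
        assert k[0] < k[1] < k[2]


class TestFitAft:
    def test_exponential_mle_uncensored(self):
        df = pd.DataFrame({"id": [f"p{i}" for i in range(10)],
                           "start": 0.0, "stop": 2.0, "event": 1.0})
        res = fit_aft(df, "mortality", "exponential", [])
        assert res.equation.intercept == pytest.approx(np.log(2), abs=1e-6)
        assert res.n_events == 10

    def test_exponential_mle_with_censoring(self):
        ev = pd.DataFrame({"id": [f"p{i}" for i in range(10)],
                           "start": 0.0, "stop": 2.0, "event": 1.0})
        cz = ev.assign(id=[f"c{i}" for i in range(10)], event=0.0)
        res = fit_aft(pd.concat([ev, cz], ignore_index=True),
                      "mortality", "exponential", [])
        assert res.equation.intercept == pytest.approx(np.log(4), abs=1e-6)

    def test_weibull_recovery_within_3_se(self):
        truth = {"x1": 0.5, "female": -0.3}
        df = aft_episode_panel("weibull", 0.6, 2.0, truth, 20_000, seed=7)
        terms = [Term(v, "linear", 0.0) for v in truth]
        res = fit_aft(df, "mortality", "weibull", terms)
        assert res.converged
        for t in res.equation.terms:
            se = res.se[t.variable]
            assert abs(t.coefficient - truth[t.variable]) < 3 * se
            # survival-time-ratio accuracy
            assert np.exp(t.coefficient) == pytest.approx(
                np.exp(truth[t.variable]), rel=0.05)
        assert res.equation.scale == pytest.approx(0.6, rel=0.05)

    def test_no_events_refused(self):
        df = pd.DataFrame({"id": ["a"], "start": 0.0, "stop": 1.0,
                           "event": 0.0})
        with pytest.raises(FitError, match="no events"):
            fit_aft(df, "mortality", "exponential", [])

    def test_rank_deficiency_detected(self):
        df = aft_episode_panel("exponential", 1.0, 2.0, {"x1": 0.3},
                               500, seed=1)
        df["x1_copy"] = df["x1"]
        with pytest.raises(FitError, match="rank deficient"):
            fit_aft(df, "mortality", "exponential",
                    [Term("x1", "linear", 0.0),
                     Term("x1_copy", "linear", 0.0)])


class TestSelectFamily:
    def test_selects_generating_weibull(self):
        df = aft_episode_panel("weibull", 0.5, 2.0, {"x1": 0.4}, 5_000,
                               seed=3)
        terms = [Term("x1", "linear", 0.0)]
        best = select_family(df, "mortality", terms)
        assert best.equation.family == "weibull"
        exp_fit = fit_aft(df, "mortality", "exponential", terms)
        assert exp_fit.aic - best.aic > 10

    def test_exponential_data_prefers_simplicity(self):
        """Weibull nests exponential; sigma-hat near 1 and AIC within ~2, so
        the simpler family wins unless noise favours weibull."""
        df = aft_episode_panel("exponential", 1.0, 2.0, {"x1": 0.4}, 5_000,
                               seed=4)
        terms = [Term("x1", "linear", 0.0)]
        wei = fit_aft(df, "mortality", "weibull", terms)
        exp_fit = fit_aft(df, "mortality", "exponential", terms)
        assert wei.equation.scale == pytest.approx(1.0, abs=0.05)
        assert abs(wei.aic - exp_fit.aic) < 3
        best = select_family(df, "mortality", terms)
        assert best.equation.family in ("exponential", "weibull")


class TestBackwardsSelect:
    def test_pure_noise_covariate_removed(self):
        df = aft_episode_panel("weibull", 0.6, 2.0,
                               {"x1": 0.5, "noise": 0.0}, 5_000, seed=2)
        full = fit_aft(df, "mortality", "weibull",
                       [Term("x1", "linear", 0.0),
                        Term("noise", "linear", 0.0)])
        selected = backwards_select(full, df)
        assert [t.variable for t in selected.equation.terms] == ["x1"]
        # a duplicated pure-noise covariate costs ~2 AIC
        red = fit_aft(df, "mortality", "weibull", [Term("x1", "linear", 0.0)])
        assert full.aic - red.aic == pytest.approx(2.0, abs=1.5)

    def test_strong_covariates_kept(self):
        df = aft_episode_panel("weibull", 0.6, 2.0,
                               {"x1": 0.5, "female": -0.4}, 5_000, seed=5)
        full = fit_aft(df, "mortality", "weibull",
                       [Term("x1", "linear", 0.0),
                        Term("female", "linear", 0.0)])
        selected = backwards_select(full, df)
        assert len(selected.equation.terms) == 2

    def test_intercept_only_is_fixpoint(self):
        df = aft_episode_panel("exponential", 1.0, 2.0, {}, 500, seed=6)
        fit = fit_aft(df, "mortality", "exponential", [])
        assert backwards_select(fit, df) is fit


class TestBootstrap:
    def test_identity_resample_reproduces_fit(self):
        df = aft_episode_panel("exponential", 1.0, 2.0, {"x1": 0.4}, 1_000,
                               seed=8)
        terms = [Term("x1", "linear", 0.0)]
        original = fit_aft(df, "mortality", "exponential", terms)
        boot = bootstrap_coefficients(
            df, "mortality", "exponential", terms, B=1, seed=0,
            sampler=lambda rng, ids: ids)
        assert boot.n_failed == 0
        assert boot.equations[0].intercept == pytest.approx(
            original.equation.intercept, abs=1e-6)
        assert boot.equations[0].terms[0].coefficient == pytest.approx(
            original.equation.terms[0].coefficient, abs=1e-6)

    def test_fixed_seed_reproducible(self):
        df = aft_episode_panel("exponential", 1.0, 2.0, {"x1": 0.4}, 400,
                               seed=9)
        terms = [Term("x1", "linear", 0.0)]
        b1 = bootstrap_coefficients(df, "mortality", "exponential", terms,
                                    B=5, seed=42)
        b2 = bootstrap_coefficients(df, "mortality", "exponential", terms,
                                    B=5, seed=42)
        for e1, e2 in zip(b1.equations, b2.equations):
            assert e1.intercept == e2.intercept
            assert e1.terms[0].coefficient == e2.terms[0].coefficient

    def test_coefficient_spread_tracks_analytic_se(self):
        truth = {"x1": 0.4}
        df = aft_episode_panel("exponential", 1.0, 2.0, truth, 2_000, seed=10)
        terms = [Term("x1", "linear", 0.0)]
        original = fit_aft(df, "mortality", "exponential", terms)
        boot = bootstrap_coefficients(df, "mortality", "exponential", terms,
                                      B=60, seed=11)
        spread = np.std([e.terms[0].coefficient for e in boot.equations])
        assert spread == pytest.approx(original.se["x1"], rel=0.5)


class TestOptimismCorrection:
    def test_zero_replicates_returns_apparent(self):
        df = aft_episode_panel("weibull", 0.6, 2.0, {"x1": 0.5}, 800, seed=12)
        out = optimism_corrected_c(df, "mortality", "weibull",
                                   [Term("x1", "linear", 0.0)], B=0)
        assert out["corrected_c"] == out["apparent_c"]
        assert out["corrected_brier"] == out["apparent_brier"]

    def test_overfitted_model_is_penalised(self):
        rng = np.random.default_rng(13)
        df = aft_episode_panel("exponential", 1.0, 1.5, {"x1": 0.3}, 300,
                               seed=13)
        terms = [Term("x1", "linear", 0.0)]
        for j in range(15):
            df[f"n{j}"] = rng.normal(size=len(df))
            terms.append(Term(f"n{j}", "linear", 0.0))
        out = optimism_corrected_c(df, "mortality", "exponential", terms,
                                   B=10, seed=14)
        assert out["corrected_c"] < out["apparent_c"]

    def test_too_few_events_refused(self):
        df = pd.DataFrame({"id": [f"p{i}" for i in range(20)],
                           "start": 0.0, "stop": 2.0,
                           "event": [1.0] + [0.0] * 19})
        with pytest.raises(MetricError, match="fewer than 5"):
            optimism_corrected_c(df, "mortality", "exponential", [], B=2)


def test_person_outcome_survival_times(small_cohort):
    _, panel, _ = small_cohort
    table = build_person_periods(panel)
    surv = person_outcome_survival(table, "mortality")
    assert (surv["time"] >= 1).all()
    dead = surv[surv["event"] == 1]
    frame = table.frame
    for pid in dead["id"].head(5):
        death_year = frame[(frame["id"] == pid)
                           & (frame["event_mortality"] > 0)]["stop"].iloc[0]
        assert dead.set_index("id").loc[pid, "time"] == death_year
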