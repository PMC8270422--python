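"""Discrete-time engine: cycle bookkeeping, determinism, closed forms."""

import numpy as np
import pandas as pd
import pytest

from chime.core import (
    BIOMARKERS,
    OUTCOMES,
    PROGRESSED_BIOMARKERS,
    BiomarkerEquation,
    IndividualState,
    ModelBundle,
    RiskEquation,
    Term,
)
from chime.simulator import run_cycle, simulate_cohort
from chime.synthetic import (
    constant_covariate_bundle,
    default_profile,
    _sample_baseline,
)
import chime.survival as sv


def _bundle_with(overrides: dict[str, RiskEquation]) -> ModelBundle:
    """All outcomes switched off except the provided equations."""
    eqs = []
    for o in OUTCOMES:
        pop = "prediabetes_only" if o == "diabetes_onset" else "both"
        eqs.append(overrides.get(
            o, RiskEquation(o, "exponential", 20.0, 1.0, [], population=pop)))
    bio = [BiomarkerEquation(b, 0.0, {"lag1_mean": 1.0}, 0.0)
           for b in PROGRESSED_BIOMARKERS]
    return ModelBundle(eqs, bio)


def _null_bundle():
    return _bundle_with({})


def _prediabetic_state():
    return IndividualState(
        id="s", age=60, sex="female", glycemic_status="prediabetes",
        duration=0, smoking="never",
        biomarkers={b: 6.0 if b == "hba1c" else 50.0 for b in BIOMARKERS})


def _cohort_frame(n, seed=5):
    profile = default_profile(n=n)
    return _sample_baseline(profile, np.random.default_rng(seed))


class TestRunCycle:
    def test_null_model_only_ages(self, rng):
        state = _prediabetic_state()
        model = _null_bundle()
        for _ in range(10):
            state, incidents = run_cycle(state, model, rng)
            assert incidents == []
        assert state.age == 70
        assert state.time_since_enrollment == 10
        assert state.alive

    def test_certain_mortality_dies_in_cycle_one(self, rng):
        model = _bundle_with({"mortality": RiskEquation(
            "mortality", "exponential", -20.0, 1.0, [])})
        state, incidents = run_cycle(_prediabetic_state(), model, rng)
        assert "mortality" in incidents
        assert not state.alive
        assert state.time_since_enrollment == 1

    def test_other_events_recorded_in_death_cycle(self, rng):
        model = _bundle_with({
            "mortality": RiskEquation("mortality", "exponential", -20.0,
                                      1.0, []),
            "ihd": RiskEquation("ihd", "exponential", -20.0, 1.0, []),
        })
        _, incidents = run_cycle(_prediabetic_state(), model, rng)
        assert set(incidents) >= {"mortality", "ihd"}

    def test_diabetes_onset_bookkeeping(self, rng):
        model = _bundle_with({"diabetes_onset": RiskEquation(
            "diabetes_onset", "exponential", -20.0, 1.0, [],
            population="prediabetes_only")})
        state, incidents = run_cycle(_prediabetic_state(), model, rng)
        assert incidents == ["diabetes_onset"]
        assert state.glycemic_status == "diabetes"
        assert state.duration == 0
        state, incidents = run_cycle(state, model, rng)
        assert incidents == []          # onset is not re-drawn
        assert state.duration == 1

    def test_absorbing_history_not_redrawn(self, rng):
        model = _bundle_with({"mi": RiskEquation("mi", "exponential",
                                                 -20.0, 1.0, [])})
        state, incidents = run_cycle(_prediabetic_state(), model, rng)
        assert incidents == ["mi"]
        assert state.history["mi"] == 1
        _, incidents = run_cycle(state, model, rng)
        assert incidents == []


class TestSimulateCohort:
    def test_constant_hazard_closed_form(self):
        lam = -np.log(0.9)      # annual p = 0.1
        model = _bundle_with({"mortality": RiskEquation(
            "mortality", "exponential", float(-np.log(lam)), 1.0, [])})
        cohort = _cohort_frame(20_000)
        res = simulate_cohort(cohort, model, horizon=10, seed=3)
        expected = 1 - 0.9 ** 10
        assert res.cumulative_incidence("mortality") == \
            pytest.approx(expected, abs=0.01)
        # per-cycle incidence among survivors stays near 0.1
        assert res.annual_incidence["mortality"].iloc[0] == \
            pytest.approx(0.1, abs=0.01)

    def test_same_seed_bit_identical(self):
        model = constant_covariate_bundle({"mortality": 0.02, "ihd": 0.015})
        cohort = _cohort_frame(2_000)
        r1 = simulate_cohort(cohort, model, horizon=8, seed=17)
        r2 = simulate_cohort(cohort, model, horizon=8, seed=17)
        pd.testing.assert_frame_equal(r1.event_times, r2.event_times)
        pd.testing.assert_frame_equal(r1.annual_incidence, r2.annual_incidence)

    def test_horizon_one_matches_mean_annual_probability(self):
        model = constant_covariate_bundle({"mortality": 0.03})
        cohort = _cohort_frame(30_000)
        eq = model.risk_equation("mortality")
        p = sv.annual_probability_from_eta(
            eq.family, sv.linear_predictor(cohort, eq), eq.scale, 0)
        res = simulate_cohort(cohort, model, horizon=1, seed=9)
        assert res.cumulative_incidence("mortality") == \
            pytest.approx(float(np.mean(p)), abs=0.005)

    def test_event_times_are_integer_cycles(self):
        model = constant_covariate_bundle({"mortality": 0.05, "mi": 0.03})
        res = simulate_cohort(_cohort_frame(2_000), model, horizon=6, seed=2)
        for o in ("mortality", "mi"):
            t = res.event_times[o].dropna()
            assert ((t >= 1) & (t <= 6)).all()
            assert (t == t.round()).all()

    def test_closed_form_distribution_constant_covariates(self):
        """With constant covariates, simulated first-event times follow the
        parametric S(t) at integer t."""
        model = constant_covariate_bundle({"mortality": 0.04})
        cohort = _cohort_frame(50_000)
        cohort[[f"hist_{h}" for h in
                [c[5:] for c in cohort.columns if c.startswith("hist_")]]] = 0.0
        eq = model.risk_equation("mortality")
        eta = sv.linear_predictor(cohort, eq)
        res = simulate_cohort(cohort, model, horizon=12, seed=4)
        t = res.event_times["mortality"].to_numpy()
        for T in (3, 6, 9, 12):
            model_s = float(np.mean(sv.survival(eq.family, eta, eq.scale,
                                                float(T))))
            empirical_s = float(np.mean(~(t <= T)))
            assert empirical_s == pytest.approx(model_s, abs=0.01)

    def test_monotone_harm_in_hba1c(self):
        """Raising everyone's HbA1c cannot reduce 10-year incidence of an
        outcome with a negative HbA1c coefficient (common random numbers)."""
        model = constant_covariate_bundle({"ihd": 0.012})
        cohort = _cohort_frame(10_000)
        res_lo = simulate_cohort(cohort, model, horizon=10, seed=21)
        worse = cohort.copy()
        worse["hba1c"] = worse["hba1c"] + 1.0
        res_hi = simulate_cohort(worse, model, horizon=10, seed=21)
        assert res_hi.cumulative_incidence("ihd") >= \
            res_lo.cumulative_incidence("ihd")

    def test_replicates_differ_but_reproduce(self):
        model = constant_covariate_bundle({"mortality": 0.05})
        cohort = _cohort_frame(1_000)
        reps = simulate_cohort(cohort, model, horizon=5, seed=6, replicates=3)
        assert len(reps) == 3
        assert reps[0].cumulative_incidence("mortality") != \
            reps[1].cumulative_incidence("mortality")
        again = simulate_cohort(cohort, model, horizon=5, seed=6,
                                replicates=3)
        for a, b in zip(reps, again):
            pd.testing.assert_frame_equal(a.event_times, b.event_times)

    def test_invalid_individuals_skipped_and_counted(self):
        model = _null_bundle()
        states = [_prediabetic_state() for _ in range(3)]
        states[1].age = 15          # violates the adults-only invariant
        states[1].id = "bad"
        res = simulate_cohort(states, model, horizon=2, seed=1)
        assert res.n_skipped == 1
        assert res.skipped_ids == ["bad"]
        assert len(res.ids) == 2

    def test_second_order_coefficient_sets(self):
        cohort = _cohort_frame(500)
        bundles = [constant_covariate_bundle({"mortality": r})
                   for r in (0.02, 0.05)]
        results = simulate_cohort(cohort, bundles[0], horizon=5, seed=8,
                                  coefficient_sets=bundles)
        assert len(results) == 2
        assert results[1].cumulative_incidence("mortality") > \
            results[0].cumulative_incidence("mortality")
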