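"""Annual discrete-time individual-level simulation engine.

Each cycle, for every living individual, the 13 risk equations are turned
into annual event probabilities conditional on survival to the cycle start;
independent uniform draws decide which events occur. Draws happen in a
fixed outcome order (mortality first, then the remaining outcomes
alphabetically) and all outcomes are drawn even in a death cycle, so times
to other events occurring in the same cycle as death are still recorded.
Survivors are then aged one year, histories are updated (first events
become absorbing history), a prediabetes individual who converts starts
diabetes duration at zero, and the seven progressed biomarkers advance via
their trajectory equations.

Randomness is counter-based: each (replicate, cycle) pair gets its own
Philox stream, and within a cycle the uniform matrix is indexed by
(individual row, outcome), so results do not depend on iteration order and
are bit-reproducible for a given seed.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .core import (
    ABSORBING_OUTCOMES,
    EVENT_ORDER,
    OUTCOMES,
    PROGRESSED_BIOMARKERS,
    IndividualState,
    InvariantError,
    ModelBundle,
    design_frame_from_csv_frame,
    states_to_design_frame,
)
from . import survival as sv
from .biomarkers import predict_next_array

__all__ = ["SimulationResult", "run_cycle", "simulate_cohort"]


@dataclass
class SimulationResult:
    """Trajectories and cohort summaries from one simulation run."""

    ids: np.ndarray
    horizon: int
    seed: int
    replicate: int
    #: per-individual time to first event per outcome (NaN if none by horizon)
    event_times: pd.DataFrame
    #: per-cycle incident events / alive at cycle start, one row per cycle
    annual_incidence: pd.DataFrame
    #: alive-at-cycle-start mean of each progressed biomarker, per cycle
    biomarker_means: pd.DataFrame
    #: individuals skipped for invariant violations
    n_skipped: int = 0
    skipped_ids: list = field(default_factory=list)

    @property
    def time_to_death(self) -> pd.Series:
        return self.event_times["mortality"]

    @property
    def time_to_diabetes(self) -> pd.Series:
        return self.event_times["diabetes_onset"]

    def cumulative_incidence(self, outcome: str,
                             horizon: float | None = None) -> float:
        """Fraction of the cohort with a first event by ``horizon``."""
        t = self.event_times[outcome]
        h = self.horizon if horizon is None else horizon
        return float((t <= h).mean())

    def endpoint_percentages(self, horizon: float | None = None) -> dict:
        return {o: 100.0 * self.cumulative_incidence(o, horizon)
                for o in OUTCOMES}


def _cycle_rng(seed: int, replicate: int, cycle: int) -> np.random.Generator:
    return np.random.Generator(
        np.random.Philox(key=[seed & 0xFFFFFFFFFFFFFFFF,
                              (replicate << 32) | cycle]))


def _annual_probs(frame: pd.DataFrame, model: ModelBundle,
                  u: np.ndarray) -> dict[str, np.ndarray]:
    """Applicable annual event probabilities for every outcome (0 where the
    outcome does not apply to the individual)."""
    probs = {}
    for outcome in EVENT_ORDER:
        eq = model.risk_equation(outcome)
        eta = sv.linear_predictor(frame, eq)
        p = sv.annual_probability_from_eta(eq.family, eta, eq.scale, u)
        p = np.asarray(p, dtype=float)
        if np.any((p < 0) | (p > 1) | ~np.isfinite(p)):
            raise InvariantError(
                f"{outcome}: annual probability outside [0, 1]")
        if outcome == "diabetes_onset":
            p = np.where(frame["diabetes"].to_numpy() > 0, 0.0, p)
        elif outcome in ABSORBING_OUTCOMES:
            p = np.where(frame[f"hist_{outcome}"].to_numpy() > 0, 0.0, p)
        probs[outcome] = p
    return probs


def simulate_cohort(cohort, model: ModelBundle, horizon: int, seed: int,
                    replicates: int = 1,
                    stochastic_biomarkers: bool = False,
                    treatment_effects: dict[str, float] | None = None,
                    coefficient_sets: list[ModelBundle] | None = None,
                    record_paths: bool = False):
    """Simulate a cohort for ``horizon`` annual cycles.

    Parameters
    ----------
    cohort : list of IndividualState or DataFrame
        Baseline states (a baseline CSV frame or design frame also works).
    model : ModelBundle
        Risk and biomarker equations.
    horizon : int
        Number of annual cycles (>= 1).
    seed : int
        Master seed; every replicate and cycle derives a counter-based
        substream from it.
    replicates : int
        First-order Monte Carlo replicates; > 1 returns a list of results.
    stochastic_biomarkers : bool
        Add Normal(0, rmse) innovations to biomarker progression.
    treatment_effects : dict, optional
        Per-biomarker relative effect fraction; from year 2 onward the
        biomarker is held at its year-1 value times (1 - fraction).
    coefficient_sets : list of ModelBundle, optional
        Second-order uncertainty: one simulation per bundle (each with
        ``replicates`` first-order replicates collapsed to 1); returns a
        list of results.
    record_paths : bool
        Also record per-individual biomarker paths (memory-heavy).

    Returns
    -------
    SimulationResult or list of SimulationResult
    """
    if horizon < 1:
        raise ValueError("horizon must be >= 1")
    if coefficient_sets is not None:
        return [simulate_cohort(cohort, m, horizon, seed + 1 + i,
                                replicates=1,
                                stochastic_biomarkers=stochastic_biomarkers,
                                treatment_effects=treatment_effects,
                                record_paths=record_paths)
                for i, m in enumerate(coefficient_sets)]
    model.validate()
    frame, start_u, skipped = _prepare_frame(cohort)
    if replicates > 1:
        return [_run(frame.copy(), start_u, model, horizon, seed, r,
                     stochastic_biomarkers, treatment_effects, record_paths,
                     skipped)
                for r in range(replicates)]
    return _run(frame, start_u, model, horizon, seed, 0,
                stochastic_biomarkers, treatment_effects, record_paths,
                skipped)


def _prepare_frame(cohort):
    skipped = []
    if isinstance(cohort, pd.DataFrame):
        frame = cohort if "female" in cohort.columns else \
            design_frame_from_csv_frame(cohort)
        frame = frame.reset_index(drop=True).copy()
        bad = (frame["age"] < 20)
        for b in PROGRESSED_BIOMARKERS:
            bad |= ~(frame[b] > 0)
        if bad.any():
            skipped = frame.loc[bad, "id"].tolist()
            frame = frame[~bad].reset_index(drop=True)
        start_u = frame["year"].to_numpy(dtype=int) if "year" in frame.columns \
            else np.zeros(len(frame), dtype=int)
        return frame, start_u, skipped
    states = []
    for s in cohort:
        try:
            s.validate()
        except InvariantError:
            skipped.append(s.id)
            continue
        states.append(s)
    frame = states_to_design_frame(states)
    start_u = np.array([s.time_since_enrollment for s in states], dtype=int)
    return frame, start_u, skipped


def _run(frame, start_u, model, horizon, seed, replicate,
         stochastic_biomarkers, treatment_effects, record_paths, skipped):
    n = len(frame)
    alive = np.ones(n, dtype=bool)
    event_time = {o: np.full(n, np.nan) for o in OUTCOMES}
    lag2 = {b: frame[b].to_numpy(dtype=float).copy()
            for b in PROGRESSED_BIOMARKERS}
    year1_value = {b: frame[b].to_numpy(dtype=float).copy()
                   for b in (treatment_effects or {})}
    incidence_rows, biomarker_rows = [], []
    paths = {b: [frame[b].to_numpy(dtype=float).copy()]
             for b in PROGRESSED_BIOMARKERS} if record_paths else None

    for c in range(horizon):
        if not alive.any():
            break
        u = start_u + c
        rng = _cycle_rng(seed, replicate, c)
        U = rng.random((n, len(EVENT_ORDER)))
        noise = rng.standard_normal((n, len(PROGRESSED_BIOMARKERS))) \
            if stochastic_biomarkers else None

        probs = _annual_probs(frame, model, u)
        biomarker_rows.append(
            {b: float(frame.loc[alive, b].mean()) for b in PROGRESSED_BIOMARKERS})

        fired = {}
        inc = {"cycle": c + 1, "n_at_risk": int(alive.sum())}
        for k, outcome in enumerate(EVENT_ORDER):
            f = alive & (U[:, k] < probs[outcome])
            new = f & np.isnan(event_time[outcome])
            event_time[outcome][new] = u[new] + 1
            fired[outcome] = f
            inc[outcome] = float(f.sum() / max(alive.sum(), 1))
        incidence_rows.append(inc)

        died = fired["mortality"]
        survivors = alive & ~died

        # state updates for survivors entering the next cycle
        was_diabetic = frame["diabetes"].to_numpy() > 0
        frame.loc[survivors, "age"] += 1.0
        frame.loc[survivors & was_diabetic, "duration"] += 1.0
        onset = survivors & fired["diabetes_onset"]
        frame.loc[onset, "diabetes"] = 1.0
        frame.loc[onset, "duration"] = 0.0
        for o in ABSORBING_OUTCOMES:
            frame.loc[survivors & fired[o], f"hist_{o}"] = 1.0

        # biomarker progression (lag1 = this cycle's value, lag2 = previous)
        for j, b in enumerate(PROGRESSED_BIOMARKERS):
            # copy: to_numpy may alias the column, and lag2 must keep the
            # pre-update values
            cur = frame[b].to_numpy(dtype=float).copy()
            beq = model.biomarker_equation(b)
            nxt = predict_next_array(
                beq, frame, cur, lag2[b],
                noise=noise[:, j] if noise is not None else None)
            if treatment_effects and b in treatment_effects and c >= 1:
                # full effect from year 2: hold at year-1 value * (1 - f)
                if c == 1:
                    year1_value[b] = cur.copy()
                nxt = year1_value[b] * (1.0 - treatment_effects[b])
            lag2[b] = cur
            frame.loc[survivors, b] = nxt[survivors.nonzero()[0]]
            if paths is not None:
                paths[b].append(frame[b].to_numpy(dtype=float).copy())

        alive = survivors

    result = SimulationResult(
        ids=frame["id"].to_numpy(),
        horizon=horizon,
        seed=seed,
        replicate=replicate,
        event_times=pd.DataFrame(event_time, index=frame["id"].to_numpy()),
        annual_incidence=pd.DataFrame(incidence_rows).set_index("cycle")
        if incidence_rows else pd.DataFrame(),
        biomarker_means=pd.DataFrame(biomarker_rows),
        n_skipped=len(skipped),
        skipped_ids=list(skipped),
    )
    if record_paths:
        result.biomarker_paths = {b: np.column_stack(v)
                                  for b, v in paths.items()}
    return result


def run_cycle(state: IndividualState, model: ModelBundle,
              rng: np.random.Generator,
              lags: dict[str, tuple[float, float]] | None = None,
              stochastic_biomarkers: bool = False):
    """Advance one individual through one annual cycle.

    Draws one uniform per applicable outcome in the fixed order (all draws
    occur even when death fires). Returns ``(new_state, incident_events)``;
    ``new_state.alive`` is False if mortality fired. ``lags`` optionally
    supplies (lag1, lag2) annual averages per biomarker; both default to
    the current value (cold start).
    """
    if not state.alive:
        raise ValueError("individual is not alive at cycle start")
    from copy import deepcopy
    from .survival import annual_event_probability
    from .biomarkers import predict_next

    u = state.time_since_enrollment
    incidents = []
    for outcome in EVENT_ORDER:
        eq = model.risk_equation(outcome)
        if outcome == "diabetes_onset" and state.glycemic_status == "diabetes":
            rng.random()
            continue
        if outcome in ABSORBING_OUTCOMES and state.history.get(outcome, 0):
            rng.random()
            continue
        p = annual_event_probability(eq, state, u)
        if not 0.0 <= p <= 1.0:
            raise InvariantError(f"{outcome}: probability {p} outside [0,1]")
        if rng.random() < p:
            incidents.append(outcome)

    new = deepcopy(state)
    new.time_since_enrollment = u + 1
    if "mortality" in incidents:
        new.alive = False
        return new, incidents
    was_diabetic = state.glycemic_status == "diabetes"
    new.age += 1.0
    if was_diabetic:
        new.duration += 1.0
    if "diabetes_onset" in incidents:
        new.glycemic_status = "diabetes"
        new.duration = 0.0
    for o in incidents:
        if o in ABSORBING_OUTCOMES:
            new.history[o] = 1
    for b in PROGRESSED_BIOMARKERS:
        cur = state.biomarkers[b]
        lag1, lag2 = (lags or {}).get(b, (cur, cur))
        new.biomarkers[b] = predict_next(
            model.biomarker_equation(b), state, lag1, lag2,
            stochastic=stochastic_biomarkers, rng=rng)
    return new, incidents
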