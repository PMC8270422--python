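"""Domain types and file formats shared by every stage of the model.

The package models progression of prediabetes and type 2 diabetes with 13
outcome risk equations (parametric accelerated-failure-time survival models)
and 7 biomarker trajectory equations (lagged linear models), applied in an
annual discrete-time individual-level simulation.

This module defines:

* the outcome / biomarker / covariate vocabulary used everywhere,
* :class:`IndividualState`, :class:`Term`, :class:`RiskEquation`,
  :class:`BiomarkerEquation` and :class:`ModelBundle`,
* CSV readers for baseline and panel (person-period) cohort files,
* JSON (de)serialisation of a fitted :class:`ModelBundle` with bit-exact
  coefficient round-trip.
"""

from __future__ import annotations

import json
import warnings
from dataclasses import dataclass, field, asdict
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd

# ---------------------------------------------------------------------------
# Vocabulary
# ---------------------------------------------------------------------------

#: The 13 modelled outcomes.
OUTCOMES: tuple[str, ...] = (
    "mortality",
    "mi",
    "ihd",
    "heart_failure",
    "cerebrovascular",
    "pvd",
    "neuropathy",
    "amputation",
    "skin_ulcer",
    "renal_failure",
    "cataract",
    "retinopathy",
    "diabetes_onset",
)

#: Fixed within-cycle draw order: mortality first, the rest alphabetical.
EVENT_ORDER: tuple[str, ...] = ("mortality",) + tuple(
    sorted(o for o in OUTCOMES if o != "mortality")
)

#: Biomarkers advanced each cycle by their trajectory equations.
PROGRESSED_BIOMARKERS: tuple[str, ...] = (
    "hba1c", "sbp", "dbp", "hdl", "ldl", "triglycerides", "bmi",
)

#: Biomarkers used as covariates but held at baseline during simulation.
STATIC_BIOMARKERS: tuple[str, ...] = ("egfr", "hemoglobin", "wbc")

BIOMARKERS: tuple[str, ...] = PROGRESSED_BIOMARKERS + STATIC_BIOMARKERS

MEDICATIONS: tuple[str, ...] = ("insulin", "oha", "antihypertensive", "statin")

#: Pre-existing-condition flags carried in the state (13 flags; includes
#: atrial fibrillation and hemodialysis which are covariates only, never
#: simulated outcomes).
HISTORY_FLAGS: tuple[str, ...] = (
    "atrial_fibrillation",
    "mi",
    "ihd",
    "heart_failure",
    "cerebrovascular",
    "pvd",
    "neuropathy",
    "amputation",
    "renal_failure",
    "hemodialysis",
    "retinopathy",
    "cataract",
    "skin_ulcer",
)

#: Outcomes that become state history after first occurrence (absorbing).
ABSORBING_OUTCOMES: tuple[str, ...] = tuple(
    o for o in OUTCOMES if o in HISTORY_FLAGS
)

FAMILIES: tuple[str, ...] = ("exponential", "weibull", "loglogistic", "lognormal")

SMOKING_LEVELS: tuple[str, ...] = ("never", "past", "current")

#: Coefficient slots of a biomarker trajectory equation, in canonical order.
BIOMARKER_COEF_NAMES: tuple[str, ...] = (
    "lag1_mean", "lag2_mean", "age", "female", "duration",
    "statin", "oha_or_insulin", "antihypertensive",
)

#: Predictor names resolvable against an IndividualState / cohort frame.
DESIGN_VARIABLES: tuple[str, ...] = (
    ("age", "duration", "female", "diabetes", "smoking_current", "smoking_past")
    + BIOMARKERS
    + MEDICATIONS
    + ("oha_or_insulin",)
    + tuple(f"hist_{h}" for h in HISTORY_FLAGS)
)

#: Columns of a baseline cohort CSV.
BASELINE_COLUMNS: tuple[str, ...] = (
    ("id", "age", "sex", "glycemic_status", "duration", "smoking")
    + BIOMARKERS
    + MEDICATIONS
    + HISTORY_FLAGS
)

#: Columns of a person-period (panel) cohort CSV.
PANEL_COLUMNS: tuple[str, ...] = (
    BASELINE_COLUMNS
    + ("year",)
    + tuple(f"event_{o}" for o in OUTCOMES)
    + ("censored",)
)

#: Lower floor applied to biomarker values to keep them positive.
BIOMARKER_FLOOR: dict[str, float] = {b: 1e-3 for b in BIOMARKERS}


# ---------------------------------------------------------------------------
# Errors
# ---------------------------------------------------------------------------

class ChimeError(Exception):
    """Base class for all package errors."""


class SchemaError(ChimeError):
    """A required column is missing or a file does not match its schema."""


class CohortParseError(ChimeError):
    """A row-level parse failure in a cohort file (carries the row index)."""

    def __init__(self, message: str, row: int | None = None):
        super().__init__(message)
        self.row = row


class InvariantError(ChimeError):
    """A domain-type invariant is violated."""


class ModelFormatError(ChimeError):
    """A model JSON file is malformed or inconsistent."""


class FitError(ChimeError):
    """Estimation failed (non-convergence, separation, rank deficiency)."""


class MetricError(ChimeError):
    """A validation metric cannot be computed on the given inputs."""


# ---------------------------------------------------------------------------
# Domain types
# ---------------------------------------------------------------------------

@dataclass
class IndividualState:
    """One simulated person at the start of an annual cycle.

    ``duration`` is years since diabetes onset and stays 0 for prediabetes.
    ``time_since_enrollment`` is the integer cycle counter used as the time
    axis of the survival equations.
    """

    id: str
    age: float
    sex: str                      # "female" | "male"
    glycemic_status: str          # "prediabetes" | "diabetes"
    duration: float
    smoking: str                  # "never" | "past" | "current"
    biomarkers: dict[str, float]
    medications: dict[str, int] = field(default_factory=dict)
    history: dict[str, int] = field(default_factory=dict)
    alive: bool = True
    time_since_enrollment: int = 0

    def __post_init__(self) -> None:
        self.medications = {m: int(self.medications.get(m, 0)) for m in MEDICATIONS}
        self.history = {h: int(self.history.get(h, 0)) for h in HISTORY_FLAGS}

    def validate(self) -> None:
        if self.age < 20:
            raise InvariantError(
                f"individual {self.id!r}: age {self.age} < 20 (adults only)")
        if self.duration < 0:
            raise InvariantError(f"individual {self.id!r}: negative duration")
        if self.duration > 0 and self.glycemic_status != "diabetes":
            raise InvariantError(
                f"individual {self.id!r}: duration > 0 requires diabetes status")
        if self.sex not in ("female", "male"):
            raise InvariantError(f"individual {self.id!r}: bad sex {self.sex!r}")
        if self.glycemic_status not in ("prediabetes", "diabetes"):
            raise InvariantError(
                f"individual {self.id!r}: bad glycemic_status "
                f"{self.glycemic_status!r}")
        if self.smoking not in SMOKING_LEVELS:
            raise InvariantError(
                f"individual {self.id!r}: bad smoking {self.smoking!r}")
        if self.time_since_enrollment < 0:
            raise InvariantError(
                f"individual {self.id!r}: negative time_since_enrollment")
        for b in BIOMARKERS:
            v = self.biomarkers.get(b)
            if v is None or not np.isfinite(v):
                raise InvariantError(
                    f"individual {self.id!r}: biomarker {b} missing")
            if v <= 0:
                raise InvariantError(
                    f"individual {self.id!r}: biomarker {b} = {v} not positive")

    def value(self, variable: str) -> float:
        """Resolve a design-matrix predictor name against this state."""
        return _state_value(self, variable)


def _state_value(state: IndividualState, variable: str) -> float:
    if variable == "age":
        return float(state.age)
    if variable == "duration":
        return float(state.duration)
    if variable == "female":
        return 1.0 if state.sex == "female" else 0.0
    if variable == "diabetes":
        return 1.0 if state.glycemic_status == "diabetes" else 0.0
    if variable == "smoking_current":
        return 1.0 if state.smoking == "current" else 0.0
    if variable == "smoking_past":
        return 1.0 if state.smoking == "past" else 0.0
    if variable in BIOMARKERS:
        try:
            return float(state.biomarkers[variable])
        except KeyError:
            raise InvariantError(
                f"individual {state.id!r}: biomarker {variable} missing")
    if variable in MEDICATIONS:
        return float(state.medications.get(variable, 0))
    if variable == "oha_or_insulin":
        return float(bool(state.medications.get("oha", 0))
                     or bool(state.medications.get("insulin", 0)))
    if variable.startswith("hist_"):
        flag = variable[5:]
        if flag in HISTORY_FLAGS:
            return float(state.history.get(flag, 0))
    raise InvariantError(f"unknown predictor variable {variable!r}")


@dataclass
class Term:
    """One predictor term of a risk equation.

    ``coefficient`` is on the AFT log-time scale, so exp(coefficient) is the
    survival time ratio for a one-unit change of the (transformed) predictor.
    """

    variable: str
    transform: str                # "linear" | "spline_nonlinear" | "indicator"
    coefficient: float
    knots: tuple[float, float, float] | None = None

    def __post_init__(self) -> None:
        if self.knots is not None:
            self.knots = tuple(float(k) for k in self.knots)  # type: ignore

    def validate(self) -> None:
        if self.transform not in ("linear", "spline_nonlinear", "indicator"):
            raise InvariantError(f"unknown transform {self.transform!r}")
        if self.transform == "spline_nonlinear":
            if self.knots is None or len(self.knots) != 3:
                raise InvariantError(
                    f"spline term on {self.variable!r} requires 3 knots")
            k1, k2, k3 = self.knots
            if not (k1 < k2 < k3):
                raise InvariantError(
                    f"spline knots for {self.variable!r} must ascend: "
                    f"{self.knots}")


@dataclass
class RiskEquation:
    """A fitted parametric AFT survival equation for one outcome."""

    outcome: str
    family: str
    intercept: float
    scale: float
    terms: list[Term] = field(default_factory=list)
    population: str = "both"      # "both" | "prediabetes_only"

    def validate(self) -> None:
        if self.outcome not in OUTCOMES:
            raise InvariantError(f"unknown outcome {self.outcome!r}")
        if self.family not in FAMILIES:
            raise ModelFormatError(f"unknown family {self.family!r}")
        if self.family == "exponential":
            if self.scale != 1.0:
                raise InvariantError(
                    f"{self.outcome}: exponential requires scale = 1, "
                    f"got {self.scale}")
        elif not self.scale > 0:
            raise InvariantError(
                f"{self.outcome}: scale must be > 0, got {self.scale}")
        if self.population not in ("both", "prediabetes_only"):
            raise InvariantError(f"bad population {self.population!r}")
        if self.outcome == "diabetes_onset" and self.population != "prediabetes_only":
            raise InvariantError(
                "diabetes_onset applies to the prediabetes population only")
        for t in self.terms:
            t.validate()

    def variables(self) -> set[str]:
        return {t.variable for t in self.terms}


@dataclass
class BiomarkerEquation:
    """Lagged linear trajectory model for one progressed biomarker.

    The conditional mean of the current annual average is
    ``intercept + sum(coefficients[k] * x_k)`` over
    :data:`BIOMARKER_COEF_NAMES`; ``rmse`` is the residual root-mean-square
    error used for stochastic draws.
    """

    biomarker: str
    intercept: float
    coefficients: dict[str, float]
    rmse: float

    def __post_init__(self) -> None:
        self.coefficients = {
            k: float(self.coefficients.get(k, 0.0)) for k in BIOMARKER_COEF_NAMES
        }

    def validate(self) -> None:
        if self.biomarker not in PROGRESSED_BIOMARKERS:
            raise InvariantError(
                f"{self.biomarker!r} is not a progressed biomarker")
        if self.rmse < 0:
            raise InvariantError(f"{self.biomarker}: rmse must be >= 0")


@dataclass
class ModelBundle:
    """The full fitted model: 13 risk equations + 7 biomarker equations."""

    risk_equations: list[RiskEquation]
    biomarker_equations: list[BiomarkerEquation]
    metadata: dict = field(default_factory=dict)

    def validate(self) -> None:
        outcomes = [eq.outcome for eq in self.risk_equations]
        missing = [o for o in OUTCOMES if o not in outcomes]
        extra = [o for o in outcomes if outcomes.count(o) > 1]
        if missing:
            raise ModelFormatError(
                f"missing risk equations for outcomes: {missing}")
        if extra:
            raise ModelFormatError(f"duplicate risk equations for: {sorted(set(extra))}")
        markers = [eq.biomarker for eq in self.biomarker_equations]
        bmissing = [b for b in PROGRESSED_BIOMARKERS if b not in markers]
        if bmissing:
            raise ModelFormatError(
                f"missing biomarker equations for: {bmissing}")
        if len(set(markers)) != len(markers):
            raise ModelFormatError("duplicate biomarker equations")
        for eq in self.risk_equations:
            eq.validate()
        for beq in self.biomarker_equations:
            beq.validate()

    def risk_equation(self, outcome: str) -> RiskEquation:
        for eq in self.risk_equations:
            if eq.outcome == outcome:
                return eq
        raise KeyError(outcome)

    def biomarker_equation(self, biomarker: str) -> BiomarkerEquation:
        for eq in self.biomarker_equations:
            if eq.biomarker == biomarker:
                return eq
        raise KeyError(biomarker)


# ---------------------------------------------------------------------------
# Cohort CSV I/O
# ---------------------------------------------------------------------------

_MANDATORY_NUMERIC = ("age", "duration") + BIOMARKERS


def _check_columns(df: pd.DataFrame, required: Sequence[str], path) -> None:
    missing = [c for c in required if c not in df.columns]
    if missing:
        raise SchemaError(f"{path}: missing mandatory column(s): {missing}")
    unknown = [c for c in df.columns if c not in required]
    if unknown:
        warnings.warn(f"{path}: ignoring unknown column(s): {unknown}",
                      stacklevel=3)


def _coerce_numeric(df: pd.DataFrame, columns: Iterable[str], path) -> pd.DataFrame:
    for c in columns:
        coerced = pd.to_numeric(df[c], errors="coerce")
        bad = coerced.isna() & df[c].notna()
        if bad.any():
            row = int(np.flatnonzero(bad.to_numpy())[0])
            raise CohortParseError(
                f"{path}: non-numeric value {df[c].iloc[row]!r} in column "
                f"{c!r} at row {row}", row=row)
        df[c] = coerced
    return df


def _row_to_state(row: pd.Series) -> IndividualState:
    return IndividualState(
        id=str(row["id"]),
        age=float(row["age"]),
        sex=str(row["sex"]),
        glycemic_status=str(row["glycemic_status"]),
        duration=float(row["duration"]),
        smoking=str(row["smoking"]),
        biomarkers={b: float(row[b]) for b in BIOMARKERS},
        medications={m: int(row[m]) for m in MEDICATIONS},
        history={h: int(row[h]) for h in HISTORY_FLAGS},
        time_since_enrollment=int(row.get("year", 0)),
    )


def read_cohort(path, schema: str = "baseline", complete_case: bool | None = None):
    """Read a cohort CSV.

    Parameters
    ----------
    path : path-like
        CSV file with the documented column set.
    schema : {"baseline", "panel"}
        Baseline files yield a list of :class:`IndividualState`; panel files
        yield a person-period DataFrame sorted by (id, year).
    complete_case : bool, optional
        Drop rows with any missing biomarker. Defaults to True for panel
        files (estimation uses complete cases) and False for baseline files
        is not allowed — baseline simulation requires complete states, so
        missing baseline biomarkers always raise.
    """
    if schema not in ("baseline", "panel"):
        raise ValueError(f"unknown schema {schema!r}")
    df = pd.read_csv(path)
    required = BASELINE_COLUMNS if schema == "baseline" else PANEL_COLUMNS
    _check_columns(df, required, path)
    df = df[[c for c in required if c in df.columns]].copy()
    numeric = list(_MANDATORY_NUMERIC) + list(MEDICATIONS) + list(HISTORY_FLAGS)
    if schema == "panel":
        numeric += ["year", "censored"] + [f"event_{o}" for o in OUTCOMES]
    df = _coerce_numeric(df, numeric, path)

    if schema == "baseline":
        states = []
        for _, row in df.iterrows():
            state = _row_to_state(row)
            state.validate()
            states.append(state)
        return states

    # panel
    if complete_case is None:
        complete_case = True
    n_missing = int(df[list(BIOMARKERS)].isna().any(axis=1).sum())
    if complete_case and n_missing:
        warnings.warn(
            f"{path}: dropping {n_missing} person-period rows with missing "
            "biomarkers (complete-case)", stacklevel=2)
        df = df[~df[list(BIOMARKERS)].isna().any(axis=1)]
    bad_age = df["age"] < 20
    if bad_age.any():
        raise InvariantError(
            f"{path}: {int(bad_age.sum())} rows with age < 20 (adults only); "
            f"first offending row index {int(np.flatnonzero(bad_age)[0])}")
    return df.sort_values(["id", "year"], kind="mergesort").reset_index(drop=True)


def write_cohort(frame_or_states, path) -> None:
    """Write a baseline or panel cohort CSV."""
    if isinstance(frame_or_states, pd.DataFrame):
        frame_or_states.to_csv(path, index=False)
    else:
        states_to_csv_frame(frame_or_states).to_csv(path, index=False)


def states_to_csv_frame(states: Sequence[IndividualState]) -> pd.DataFrame:
    """Serialise states into the baseline CSV column layout."""
    rows = []
    for s in states:
        row = {
            "id": s.id, "age": s.age, "sex": s.sex,
            "glycemic_status": s.glycemic_status, "duration": s.duration,
            "smoking": s.smoking,
        }
        row.update({b: s.biomarkers[b] for b in BIOMARKERS})
        row.update({m: s.medications[m] for m in MEDICATIONS})
        row.update({h: s.history[h] for h in HISTORY_FLAGS})
        rows.append(row)
    return pd.DataFrame(rows, columns=list(BASELINE_COLUMNS))


def states_to_design_frame(states: Sequence[IndividualState]) -> pd.DataFrame:
    """Numeric design frame with one column per :data:`DESIGN_VARIABLES`."""
    data = {"id": [s.id for s in states]}
    for v in DESIGN_VARIABLES:
        data[v] = [_state_value(s, v) for s in states]
    return pd.DataFrame(data)


def design_frame_from_csv_frame(df: pd.DataFrame) -> pd.DataFrame:
    """Convert CSV-layout columns to the numeric design-frame encoding.

    Sex is encoded female=1/male=0; smoking enters as two indicators
    (current, past) against a never-smoker baseline; history flags gain a
    ``hist_`` prefix.
    """
    out = pd.DataFrame(index=df.index)
    out["id"] = df["id"].astype(str)
    out["age"] = df["age"].astype(float)
    out["duration"] = df["duration"].astype(float)
    out["female"] = (df["sex"] == "female").astype(float)
    out["diabetes"] = (df["glycemic_status"] == "diabetes").astype(float)
    out["smoking_current"] = (df["smoking"] == "current").astype(float)
    out["smoking_past"] = (df["smoking"] == "past").astype(float)
    for b in BIOMARKERS:
        out[b] = df[b].astype(float)
    for m in MEDICATIONS:
        out[m] = df[m].astype(float)
    out["oha_or_insulin"] = ((df["oha"] > 0) | (df["insulin"] > 0)).astype(float)
    for h in HISTORY_FLAGS:
        out[f"hist_{h}"] = df[h].astype(float)
    for extra in ("year", "censored"):
        if extra in df.columns:
            out[extra] = df[extra].astype(float)
    for o in OUTCOMES:
        col = f"event_{o}"
        if col in df.columns:
            out[col] = df[col].astype(float)
    return out


# ---------------------------------------------------------------------------
# Model JSON I/O
# ---------------------------------------------------------------------------

def _term_to_json(t: Term) -> dict:
    return {
        "variable": t.variable,
        "transform": t.transform,
        "knots": list(t.knots) if t.knots is not None else None,
        "coefficient": t.coefficient,
    }


def write_model(bundle: ModelBundle, path) -> None:
    """Serialise a validated bundle to JSON (coefficients round-trip exactly)."""
    bundle.validate()
    doc = {
        "risk_equations": [
            {
                "outcome": eq.outcome,
                "family": eq.family,
                "intercept": eq.intercept,
                "scale": eq.scale,
                "population": eq.population,
                "terms": [_term_to_json(t) for t in eq.terms],
            }
            for eq in bundle.risk_equations
        ],
        "biomarker_equations": [
            {
                "biomarker": eq.biomarker,
                "intercept": eq.intercept,
                "coefficients": dict(eq.coefficients),
                "rmse": eq.rmse,
            }
            for eq in bundle.biomarker_equations
        ],
        "metadata": bundle.metadata,
    }
    with open(path, "w") as fh:
        json.dump(doc, fh, indent=1)


def read_model(path) -> ModelBundle:
    """Read and validate a model JSON file."""
    with open(path) as fh:
        doc = json.load(fh)
    try:
        risk = [
            RiskEquation(
                outcome=e["outcome"],
                family=e["family"],
                intercept=float(e["intercept"]),
                scale=float(e["scale"]),
                population=e.get("population", "both"),
                terms=[
                    Term(
                        variable=t["variable"],
                        transform=t["transform"],
                        coefficient=float(t["coefficient"]),
                        knots=tuple(t["knots"]) if t.get("knots") else None,
                    )
                    for t in e["terms"]
                ],
            )
            for e in doc["risk_equations"]
        ]
        bio = [
            BiomarkerEquation(
                biomarker=e["biomarker"],
                intercept=float(e["intercept"]),
                coefficients={k: float(v) for k, v in e["coefficients"].items()},
                rmse=float(e["rmse"]),
            )
            for e in doc["biomarker_equations"]
        ]
    except (KeyError, TypeError) as exc:
        raise ModelFormatError(f"{path}: malformed model JSON ({exc})") from exc
    bundle = ModelBundle(risk_equations=risk, biomarker_equations=bio,
                         metadata=doc.get("metadata", {}))
    bundle.validate()
    return bundle
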