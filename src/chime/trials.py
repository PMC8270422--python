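"""Simulated trial-arm cohorts from published aggregate baselines.

External validation against published trials works by reconstituting each
trial arm as a synthetic cohort: every continuous baseline variable is
drawn from a normal distribution with the reported mean and SD, truncated
to the protocol's inclusion bounds; every binary characteristic (sex,
smoking, medications, prior events) is drawn as a Bernoulli with the
reported prevalence. Variables are sampled independently (marginals only).
Treatment effects on biomarkers are expressed as a fraction of the baseline
mean and reach full effect in year 2 of the simulation, holding the
biomarker at its year-1 value times (1 - fraction) thereafter.

Arm specifications live in YAML files; see :class:`TrialArmSpec.from_yaml`.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
import yaml
from scipy import stats

from .core import (
    BIOMARKERS,
    HISTORY_FLAGS,
    MEDICATIONS,
    PROGRESSED_BIOMARKERS,
    ChimeError,
    ModelBundle,
)
from .simulator import simulate_cohort

__all__ = [
    "TrialArmSpec",
    "sample_truncated_normal",
    "sample_binary",
    "relative_effect",
    "apply_treatment_schedule",
    "generate_arm",
]


@dataclass
class ContinuousSpec:
    mean: float
    sd: float
    lower: float | None = None
    upper: float | None = None

    def validate(self, name: str) -> None:
        if self.sd < 0:
            raise ChimeError(f"{name}: sd must be >= 0")
        lo = -np.inf if self.lower is None else self.lower
        hi = np.inf if self.upper is None else self.upper
        if not lo < hi:
            raise ChimeError(f"{name}: bounds must satisfy lower < upper")


@dataclass
class TreatmentEffect:
    absolute_change: float
    baseline_mean: float

    @property
    def fraction(self) -> float:
        return relative_effect(self.absolute_change, self.baseline_mean)


@dataclass
class TrialArmSpec:
    """Aggregate baseline summaries and treatment schedule for one arm."""

    name: str
    population: str                       # "prediabetes" | "diabetes"
    follow_up: int
    n_simulated: int = 100_000
    continuous: dict[str, ContinuousSpec] = field(default_factory=dict)
    binary: dict[str, float] = field(default_factory=dict)
    #: explicit constant fills for covariates the trial did not report
    fill: dict[str, float] = field(default_factory=dict)
    treatment_effects: dict[str, TreatmentEffect] = field(default_factory=dict)

    def validate(self) -> None:
        for name, c in self.continuous.items():
            c.validate(name)
        for name, p in self.binary.items():
            if not 0.0 <= p <= 1.0:
                raise ChimeError(f"{name}: probability {p} outside [0, 1]")
        if self.population not in ("prediabetes", "diabetes"):
            raise ChimeError(f"bad population {self.population!r}")
        if self.follow_up < 1:
            raise ChimeError("follow_up must be >= 1")

    @classmethod
    def from_yaml(cls, path) -> "TrialArmSpec":
        with open(path) as fh:
            doc = yaml.safe_load(fh)
        spec = cls(
            name=doc["name"],
            population=doc["population"],
            follow_up=int(doc["follow_up"]),
            n_simulated=int(doc.get("n_simulated", 100_000)),
            continuous={
                k: ContinuousSpec(mean=float(v["mean"]), sd=float(v["sd"]),
                                  lower=v.get("lower"), upper=v.get("upper"))
                for k, v in (doc.get("continuous") or {}).items()
            },
            binary={k: float(v) for k, v in (doc.get("binary") or {}).items()},
            fill={k: float(v) for k, v in (doc.get("fill") or {}).items()},
            treatment_effects={
                k: TreatmentEffect(absolute_change=float(v["absolute_change"]),
                                   baseline_mean=float(v["baseline_mean"]))
                for k, v in (doc.get("treatment_effects") or {}).items()
            },
        )
        spec.validate()
        return spec


def sample_truncated_normal(mean: float, sd: float, lower: float | None,
                            upper: float | None, n: int,
                            rng: np.random.Generator) -> np.ndarray:
    """I.i.d. draws from Normal(mean, sd) truncated to [lower, upper]."""
    if n < 1:
        raise ValueError("n must be >= 1")
    lo = -np.inf if lower is None else float(lower)
    hi = np.inf if upper is None else float(upper)
    if sd == 0:
        if not (lo <= mean <= hi):
            raise ChimeError(
                f"sd = 0 with mean {mean} outside bounds [{lo}, {hi}]")
        return np.full(n, float(mean))
    a, b = (lo - mean) / sd, (hi - mean) / sd
    mass = stats.norm.cdf(b) - stats.norm.cdf(a)
    if mass < 1e-3:
        raise ChimeError(
            f"bounds [{lo}, {hi}] exclude {100 * (1 - mass):.2f}% of the "
            f"Normal({mean}, {sd}) mass — check the arm specification")
    return stats.truncnorm.rvs(a, b, loc=mean, scale=sd, size=n,
                               random_state=rng)


def sample_binary(p: float, n: int, rng: np.random.Generator) -> np.ndarray:
    """Bernoulli(p) draws as a 0/1 float array."""
    if not 0.0 <= p <= 1.0:
        raise ValueError(f"probability {p} outside [0, 1]")
    return (rng.random(n) < p).astype(float)


def relative_effect(absolute_change: float, baseline_mean: float) -> float:
    """Treatment effect as a fraction of the baseline mean."""
    if baseline_mean == 0:
        raise ChimeError("baseline_mean must be nonzero")
    return absolute_change / baseline_mean


def apply_treatment_schedule(value_year1: float, effect_fraction: float,
                             year: int) -> float:
    """Biomarker value under the treatment step schedule.

    Years 0-1 are unadjusted; from year 2 the full effect applies as a
    relative decrease from the year-1 value (a step, not a ramp).
    """
    if year < 2:
        return value_year1
    return value_year1 * (1.0 - effect_fraction)


#: Inputs of the biomarker trajectory equations (always needed to simulate).
_TRAJECTORY_INPUTS = ("age", "female", "duration", "statin",
                      "oha_or_insulin", "antihypertensive")


def _required_variables(model: ModelBundle) -> set[str]:
    required = set(_TRAJECTORY_INPUTS) | set(PROGRESSED_BIOMARKERS)
    for eq in model.risk_equations:
        required |= eq.variables()
    return required


def _sample_baseline(spec: TrialArmSpec, model: ModelBundle,
                     rng: np.random.Generator) -> pd.DataFrame:
    n = spec.n_simulated

    provided = (set(spec.continuous) | set(spec.binary) | set(spec.fill)
                | {"diabetes"})
    if {"oha", "insulin"} & provided:
        provided.add("oha_or_insulin")
    if spec.population == "prediabetes":
        provided.add("duration")        # prediabetes has duration 0
    gaps = sorted(_required_variables(model) - provided)
    if gaps:
        raise ChimeError(
            f"arm {spec.name!r}: specification missing covariates required "
            f"by the model (add them under continuous/binary or as explicit "
            f"fill values): {gaps}")

    frame = pd.DataFrame({"id": [f"{spec.name}-{i}" for i in range(n)]})
    for name, c in spec.continuous.items():
        frame[name] = sample_truncated_normal(c.mean, c.sd, c.lower, c.upper,
                                              n, rng)
    for name, p in spec.binary.items():
        frame[name] = sample_binary(p, n, rng)
    for name, value in spec.fill.items():
        if name not in frame.columns:
            frame[name] = float(value)

    frame["diabetes"] = 1.0 if spec.population == "diabetes" else 0.0
    if spec.population == "prediabetes":
        frame["duration"] = 0.0
    # unreferenced covariates default to zero so the frame is complete
    for name in ("smoking_current", "smoking_past") + MEDICATIONS:
        if name not in frame.columns:
            frame[name] = 0.0
    for b in BIOMARKERS:
        if b not in frame.columns:
            frame[b] = 1.0
    if "oha_or_insulin" not in frame.columns:
        frame["oha_or_insulin"] = ((frame["oha"] > 0) | (frame["insulin"] > 0)
                                   ).astype(float)
    for h in HISTORY_FLAGS:
        col = f"hist_{h}"
        if col not in frame.columns:
            frame[col] = 0.0
    return frame


def generate_arm(spec: TrialArmSpec, model: ModelBundle, seed: int,
                 convergence_step: int = 10_000):
    """Sample one trial arm and simulate it to follow-up.

    Returns ``(result, endpoints, convergence)`` where ``endpoints`` maps
    each outcome to its cumulative-incidence percentage at follow-up and
    ``convergence`` is a DataFrame of running endpoint means versus number
    of participants (the S3-Fig-style convergence diagnostic).
    """
    spec.validate()
    if spec.n_simulated < 1_000:
        raise ChimeError("n_simulated must be >= 1,000")
    if spec.n_simulated < 100_000:
        warnings.warn(
            f"arm {spec.name!r}: n_simulated = {spec.n_simulated} < 100,000; "
            "endpoint estimates may not be converged", stacklevel=2)
    rng = np.random.default_rng(seed)
    baseline = _sample_baseline(spec, model, rng)
    effects = {b: e.fraction for b, e in spec.treatment_effects.items()}
    result = simulate_cohort(baseline, model, horizon=spec.follow_up,
                             seed=seed, treatment_effects=effects or None)
    endpoints = result.endpoint_percentages()

    rows = []
    counts = np.arange(convergence_step, spec.n_simulated + 1,
                       convergence_step)
    if len(counts) == 0 or counts[-1] != spec.n_simulated:
        counts = np.append(counts, spec.n_simulated)
    occurred = {o: (result.event_times[o].to_numpy() <= spec.follow_up)
                for o in result.event_times.columns}
    for m in counts:
        row = {"n": int(m)}
        for o, flags in occurred.items():
            row[o] = 100.0 * float(np.mean(flags[:m]))
        rows.append(row)
    convergence = pd.DataFrame(rows).set_index("n")
    return result, endpoints, convergence
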