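"""Biomarker trajectory equations: fitting and per-cycle prediction.

Each of the seven progressed biomarkers (HbA1c, systolic/diastolic blood
pressure, HDL, LDL, triglycerides, BMI) follows an ordinary-least-squares
model of the current annual average on its lagged annual averages in the
previous two years plus age, sex, diabetes duration and medication use:

    value_t = b0 + b1*lag1 + b2*lag2 + b3*age + b4*female + b5*duration
              + b6*statin + b7*(oha or insulin) + b8*antihypertensive + e

Model fit is summarised by the residual RMSE, which also scales the
optional stochastic innovation added during simulation. During simulation
the first cycles lack lagged averages, so both lags are cold-started at the
baseline value.
"""

from __future__ import annotations

import numpy as np
import pandas as pd
import statsmodels.api as sm

from .core import (
    BIOMARKER_COEF_NAMES,
    BIOMARKER_FLOOR,
    PROGRESSED_BIOMARKERS,
    BiomarkerEquation,
    FitError,
    IndividualState,
    design_frame_from_csv_frame,
)

__all__ = ["build_biomarker_panel", "fit_biomarker", "predict_next",
           "predict_next_array"]


def build_biomarker_panel(panel: pd.DataFrame, biomarker: str) -> pd.DataFrame:
    """Attach lag1/lag2 annual averages of one biomarker to a panel.

    Rows without both lags (the first two years of each person) are
    dropped, matching the estimation sample of the trajectory models.
    """
    if biomarker not in PROGRESSED_BIOMARKERS:
        raise ValueError(f"{biomarker!r} is not a progressed biomarker")
    if "sex" in panel.columns:
        df = design_frame_from_csv_frame(panel)
    else:
        df = panel.copy()
    df = df.sort_values(["id", "year"], kind="mergesort")
    # annual smoothing of duplicate measurements
    flags = [c for c in df.columns if c.startswith("event_") or c == "censored"]
    agg = {c: "mean" for c in df.columns if c not in ("id", "year") and c not in flags}
    agg.update({c: "max" for c in flags})
    df = df.groupby(["id", "year"], as_index=False, sort=True).agg(agg)
    g = df.groupby("id", sort=False)[biomarker]
    df["lag1_mean"] = g.shift(1)
    df["lag2_mean"] = g.shift(2)
    # shifts can cross gap years; only consecutive years count as lags
    year_gap1 = df["year"] - df.groupby("id", sort=False)["year"].shift(1)
    year_gap2 = df["year"] - df.groupby("id", sort=False)["year"].shift(2)
    df.loc[year_gap1 != 1, "lag1_mean"] = np.nan
    df.loc[year_gap2 != 2, "lag2_mean"] = np.nan
    return df.dropna(subset=["lag1_mean", "lag2_mean"]).reset_index(drop=True)


def fit_biomarker(panel: pd.DataFrame, biomarker: str,
                  min_rows: int = 50) -> BiomarkerEquation:
    """OLS fit of one biomarker's trajectory equation.

    ``panel`` is a person-period table (raw CSV layout or design layout);
    lags are constructed internally. Raises :class:`FitError` on rank
    deficiency, naming the collinear columns.
    """
    df = build_biomarker_panel(panel, biomarker)
    if len(df) < min_rows:
        raise FitError(
            f"{biomarker}: only {len(df)} usable rows (< {min_rows})")
    X = df[list(BIOMARKER_COEF_NAMES)].to_numpy(dtype=float)
    y = df[biomarker].to_numpy(dtype=float)
    Xc = sm.add_constant(X, has_constant="add")
    rank = np.linalg.matrix_rank(Xc)
    if rank < Xc.shape[1]:
        # name columns that add no rank
        bad = []
        base = np.ones((len(df), 1))
        for j, name in enumerate(BIOMARKER_COEF_NAMES):
            cand = np.column_stack([base, X[:, j]])
            if np.linalg.matrix_rank(cand) == base.shape[1]:
                bad.append(name)
            else:
                base = cand
        raise FitError(
            f"{biomarker}: design matrix rank deficient; collinear or "
            f"constant columns: {bad or 'unknown'}")
    fit = sm.OLS(y, Xc).fit()
    resid = y - fit.predict(Xc)
    rmse = float(np.sqrt(np.mean(resid ** 2)))
    return BiomarkerEquation(
        biomarker=biomarker,
        intercept=float(fit.params[0]),
        coefficients={name: float(b)
                      for name, b in zip(BIOMARKER_COEF_NAMES, fit.params[1:])},
        rmse=rmse,
    )


def _conditional_mean(eq: BiomarkerEquation, lag1, lag2, age, female,
                      duration, statin, oha_or_insulin, antihypertensive):
    c = eq.coefficients
    return (eq.intercept
            + c["lag1_mean"] * lag1 + c["lag2_mean"] * lag2
            + c["age"] * age + c["female"] * female
            + c["duration"] * duration + c["statin"] * statin
            + c["oha_or_insulin"] * oha_or_insulin
            + c["antihypertensive"] * antihypertensive)


def predict_next(eq: BiomarkerEquation, state: IndividualState,
                 lag1: float, lag2: float, stochastic: bool = False,
                 rng: np.random.Generator | None = None) -> float:
    """Next-cycle biomarker value for one individual.

    Deterministic conditional mean by default; with ``stochastic`` a
    Normal(0, rmse) innovation is added. The result is floored at a small
    positivity epsilon.
    """
    mean = _conditional_mean(
        eq, lag1, lag2,
        state.value("age"), state.value("female"), state.value("duration"),
        state.value("statin"), state.value("oha_or_insulin"),
        state.value("antihypertensive"))
    if stochastic:
        if rng is None:
            raise ValueError("stochastic prediction requires an rng")
        mean += rng.normal(0.0, eq.rmse)
    return float(max(mean, BIOMARKER_FLOOR[eq.biomarker]))


def predict_next_array(eq: BiomarkerEquation, frame: pd.DataFrame,
                       lag1: np.ndarray, lag2: np.ndarray,
                       noise: np.ndarray | None = None) -> np.ndarray:
    """Vectorised next-cycle values over a cohort design frame.

    ``noise``, if given, is a standard-normal array scaled by the equation
    RMSE (pre-drawn by the caller so the random stream stays reproducible).
    """
    mean = _conditional_mean(
        eq, np.asarray(lag1, float), np.asarray(lag2, float),
        frame["age"].to_numpy(float), frame["female"].to_numpy(float),
        frame["duration"].to_numpy(float), frame["statin"].to_numpy(float),
        frame["oha_or_insulin"].to_numpy(float),
        frame["antihypertensive"].to_numpy(float))
    if noise is not None:
        mean = mean + eq.rmse * np.asarray(noise, float)
    return np.maximum(mean, BIOMARKER_FLOOR[eq.biomarker])
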