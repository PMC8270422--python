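"""Discrimination and calibration metrics for risk-model validation.

* :func:`harrell_c` — Harrell's concordance for right-censored data: among
  usable pairs (the shorter follow-up time is an event and the times
  differ), the probability that the higher predicted risk belongs to the
  earlier event; tied risk scores count one half. Confidence intervals by
  percentile bootstrap over individuals.
* :func:`calibration` — slope and intercept of observed event proportion
  against mean predicted risk across risk-quantile groups, starting from
  deciles and coarsening (down to a floor of 3 groups) until every group
  holds at least 5 observed events.
* :func:`brier_score` — mean squared difference between predicted risk and
  observed event status at a fixed horizon (individuals censored before the
  horizon without an event are excluded).
* :func:`rmspe` / :func:`r_squared` — endpoint-level goodness of fit on the
  percentage scale; R^2 is computed about the identity line of the
  predicted-versus-observed scatter, not a refitted line.
* :func:`compare_models` — multi-model report over per-individual predicted
  risks supplied as CSV-like frames.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats

from .core import MetricError

__all__ = [
    "CalibrationTable",
    "harrell_c",
    "calibration",
    "brier_score",
    "rmspe",
    "r_squared",
    "compare_models",
]


@dataclass
class CalibrationTable:
    """Group-level calibration summary plus the fitted line."""

    groups: pd.DataFrame      # columns: mean_predicted, observed, n, events
    slope: float
    intercept: float

    @property
    def n_groups(self) -> int:
        return len(self.groups)


# ---------------------------------------------------------------------------
# Concordance
# ---------------------------------------------------------------------------

def _c_counts(times: np.ndarray, events: np.ndarray, scores: np.ndarray,
              block: int = 2048) -> tuple[float, int]:
    """(concordance credit, usable pair count) in O(n^2) blocks."""
    n = len(times)
    credit = 0.0
    usable = 0
    for i0 in range(0, n, block):
        t_i = times[i0:i0 + block, None]
        e_i = events[i0:i0 + block, None]
        s_i = scores[i0:i0 + block, None]
        # pair (i, j) usable iff t_i < t_j and e_i = 1
        use = (t_i < times[None, :]) & (e_i > 0)
        usable += int(use.sum())
        conc = use & (s_i > scores[None, :])
        tied = use & (s_i == scores[None, :])
        credit += float(conc.sum()) + 0.5 * float(tied.sum())
    return credit, usable


def harrell_c(times, events, scores, B: int = 100,
              seed: int = 0) -> tuple[float, tuple[float, float] | None]:
    """Harrell's C-statistic with an optional percentile-bootstrap CI.

    Returns ``(C, (lo, hi))``; the CI is ``None`` when ``B = 0``.
    """
    times = np.asarray(times, dtype=float)
    events = np.asarray(events, dtype=float)
    scores = np.asarray(scores, dtype=float)
    credit, usable = _c_counts(times, events, scores)
    if usable == 0:
        raise MetricError("no usable pairs (need an event with a strictly "
                          "shorter time than some other follow-up)")
    c = credit / usable
    if B <= 0:
        return float(c), None
    rng = np.random.default_rng(seed)
    n = len(times)
    reps = []
    for _ in range(B):
        idx = rng.integers(0, n, size=n)
        cr, us = _c_counts(times[idx], events[idx], scores[idx])
        if us > 0:
            reps.append(cr / us)
    lo, hi = np.percentile(reps, [2.5, 97.5])
    return float(c), (float(lo), float(hi))


# ---------------------------------------------------------------------------
# Calibration
# ---------------------------------------------------------------------------

def calibration(predicted, observed, max_groups: int = 10,
                min_events_per_group: int = 5,
                floor_groups: int = 3) -> CalibrationTable:
    """Grouped calibration slope/intercept with the small-count rule.

    Groups are quantiles of predicted risk. Starting from ``max_groups``
    (deciles), the number of groups is decremented while any group has
    fewer than ``min_events_per_group`` observed events, down to a floor of
    ``floor_groups``. The slope/intercept come from an OLS fit of observed
    event proportion on mean predicted risk across groups.
    """
    predicted = np.asarray(predicted, dtype=float)
    observed = np.asarray(observed, dtype=float)
    if len(predicted) != len(observed):
        raise MetricError("predicted and observed must have equal length")
    if len(predicted) < 30:
        raise MetricError("need at least 30 individuals for calibration")
    if observed.sum() < min_events_per_group:
        raise MetricError(
            f"fewer than {min_events_per_group} total events")

    for g in range(max_groups, floor_groups - 1, -1):
        try:
            bins = pd.qcut(predicted, g, labels=False, duplicates="drop")
        except ValueError:
            continue
        if bins.max() + 1 < g:       # too few distinct quantiles
            continue
        tab = pd.DataFrame({"bin": bins, "pred": predicted, "obs": observed})
        grouped = tab.groupby("bin").agg(
            mean_predicted=("pred", "mean"),
            observed=("obs", "mean"),
            n=("obs", "size"),
            events=("obs", "sum"),
        )
        if g == floor_groups or (grouped["events"] >= min_events_per_group).all():
            res = stats.linregress(grouped["mean_predicted"],
                                   grouped["observed"])
            return CalibrationTable(groups=grouped.reset_index(drop=True),
                                    slope=float(res.slope),
                                    intercept=float(res.intercept))
    raise MetricError("could not form calibration groups")


def brier_score(times, events, predicted, horizon: float) -> float:
    """Brier score at a fixed horizon.

    Observed status is event-by-horizon; individuals censored before the
    horizon without an event are excluded (they contribute no observable
    status under this convention).
    """
    times = np.asarray(times, dtype=float)
    events = np.asarray(events, dtype=float)
    predicted = np.asarray(predicted, dtype=float)
    had_event = (events > 0) & (times <= horizon)
    evaluable = had_event | (times >= horizon)
    if not evaluable.any():
        raise MetricError("no individuals evaluable at the horizon")
    obs = had_event[evaluable].astype(float)
    return float(np.mean((predicted[evaluable] - obs) ** 2))


# ---------------------------------------------------------------------------
# Endpoint-level goodness of fit
# ---------------------------------------------------------------------------

def rmspe(predicted, observed, mode: str = "absolute") -> float:
    """Root mean square (percentage-point) error between paired endpoint
    percentages.

    ``mode="absolute"`` (default): sqrt(mean((pred - obs)^2)) with both in
    percent units. ``mode="relative"`` divides each difference by the
    observed value first.
    """
    predicted = np.asarray(predicted, dtype=float)
    observed = np.asarray(observed, dtype=float)
    if predicted.shape != observed.shape or predicted.size < 1:
        raise MetricError("predicted and observed must be equal-length, "
                          "non-empty vectors")
    diff = predicted - observed
    if mode == "relative":
        if np.any(observed == 0):
            raise MetricError("relative RMSPE undefined with observed = 0")
        diff = diff / observed
    elif mode != "absolute":
        raise ValueError(f"unknown mode {mode!r}")
    return float(np.sqrt(np.mean(diff ** 2)))


def r_squared(predicted, observed) -> float:
    """Coefficient of determination about the identity line."""
    predicted = np.asarray(predicted, dtype=float)
    observed = np.asarray(observed, dtype=float)
    if predicted.shape != observed.shape:
        raise MetricError("predicted and observed must have equal length")
    ss_tot = float(np.sum((observed - observed.mean()) ** 2))
    if ss_tot == 0:
        raise MetricError("observed values have zero variance")
    ss_res = float(np.sum((observed - predicted) ** 2))
    return 1.0 - ss_res / ss_tot


# ---------------------------------------------------------------------------
# Multi-model comparison report
# ---------------------------------------------------------------------------

def compare_models(predictions: dict[str, pd.DataFrame],
                   observed: pd.DataFrame, horizon: float = 10.0,
                   c_bootstrap: int = 100, seed: int = 0,
                   rmspe_mode: str = "absolute") -> pd.DataFrame:
    """Validation report across models and outcomes.

    ``observed`` has columns ``id`` plus ``time_<outcome>`` and
    ``event_<outcome>`` per outcome; each entry of ``predictions`` has
    ``id`` plus one column per outcome with the predicted risk at
    ``horizon``. Returns a long-format frame with one row per
    (model, outcome) carrying C (with CI), calibration slope/intercept,
    and per-model RMSPE/R^2 rows over the endpoint percentages.
    """
    outcomes = sorted(c[5:] for c in observed.columns if c.startswith("time_"))
    rows = []
    for name, pred in predictions.items():
        missing_ids = set(observed["id"]) - set(pred["id"])
        if missing_ids:
            raise MetricError(
                f"model {name!r}: predictions missing for ids "
                f"{sorted(missing_ids)[:10]}")
        merged = observed.merge(pred, on="id", how="left",
                                suffixes=("", "_pred"))
        pct_pred, pct_obs = [], []
        for outcome in outcomes:
            if outcome not in pred.columns:
                rows.append({"model": name, "outcome": outcome,
                             "status": "missing"})
                continue
            t = merged[f"time_{outcome}"].to_numpy(float)
            e = merged[f"event_{outcome}"].to_numpy(float)
            r = merged[outcome].to_numpy(float)
            c, ci = harrell_c(t, e, r, B=c_bootstrap, seed=seed)
            had = (e > 0) & (t <= horizon)
            evaluable = had | (t >= horizon)
            cal = calibration(r[evaluable], had[evaluable].astype(float))
            pct_pred.append(100.0 * float(np.mean(r)))
            pct_obs.append(100.0 * float(np.mean(had[evaluable])))
            rows.append({
                "model": name, "outcome": outcome, "status": "ok",
                "c": c, "c_lo": ci[0] if ci else np.nan,
                "c_hi": ci[1] if ci else np.nan,
                "slope": cal.slope, "intercept": cal.intercept,
                "n_groups": cal.n_groups,
            })
        if pct_pred:
            r2 = np.nan
            if len(pct_obs) > 1 and np.var(pct_obs) > 0:
                r2 = r_squared(np.array(pct_pred), np.array(pct_obs))
            rows.append({
                "model": name, "outcome": "(all)", "status": "summary",
                "rmspe": rmspe(pct_pred, pct_obs, mode=rmspe_mode),
                "r2": r2,
            })
    return pd.DataFrame(rows)
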