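"""Estimation of the risk equations from longitudinal person-period data.

The fitting pipeline mirrors how the model is meant to be developed from a
clinic-visit panel:

1. :func:`build_person_periods` — smooth within-year biomarker measurements
   by annual averaging, propagate history-of-event flags forward (an event
   in cycle u becomes history from cycle u+1 onward), and construct per-
   outcome risk sets.
2. :func:`fit_aft` — maximum-likelihood AFT fit with right censoring and
   time-varying covariates entered through person-period episodes
   (start u, stop u+1). Each episode contributes the conditional
   log-likelihood of its interval given survival to its start, which is the
   standard counting-process decomposition.
3. :func:`select_family` — refit under all four families and keep the
   minimum-AIC model (ties broken towards the simpler family).
4. :func:`backwards_select` — optional AIC-based backwards elimination
   (spline linear+nonlinear pairs are dropped as a unit; the nonlinear part
   may be dropped alone).
5. :func:`bootstrap_coefficients` — second-order (parameter) uncertainty by
   resampling individuals with replacement and refitting.
6. :func:`optimism_corrected_c` — overfitting-corrected Harrell's C and
   Brier score at a fixed horizon via the Harrell bootstrap-optimism
   procedure.

Events are timed at episode stops. By default an event episode contributes
the event-time density at its stop (``event_likelihood="exact"``, the
classic continuous-time likelihood, appropriate when stops are observed
event times). ``event_likelihood="interval"`` instead uses the probability
mass over the episode, the exactly matched likelihood for panels whose
events were generated by annual Bernoulli draws.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import optimize

from .core import (
    ABSORBING_OUTCOMES,
    BIOMARKERS,
    FAMILIES,
    OUTCOMES,
    FitError,
    MetricError,
    RiskEquation,
    Term,
    design_frame_from_csv_frame,
)
from . import survival as sv

__all__ = [
    "PersonPeriodTable",
    "FitResult",
    "BootstrapResult",
    "build_person_periods",
    "compute_knots",
    "fit_aft",
    "select_family",
    "backwards_select",
    "bootstrap_coefficients",
    "optimism_corrected_c",
    "person_outcome_survival",
]

#: Convergence control for the likelihood optimiser.
MAX_ITER = 200
FTOL = 1e-8


@dataclass
class PersonPeriodTable:
    """Smoothed, history-propagated person-period episodes.

    ``frame`` has one row per person-year with design-encoded covariates,
    ``start``/``stop`` episode bounds, ``event_<outcome>`` indicators and
    ``at_risk_<outcome>`` flags.
    """

    frame: pd.DataFrame

    @property
    def ids(self) -> np.ndarray:
        return self.frame["id"].unique()


@dataclass
class FitResult:
    """A fitted risk equation with its likelihood bookkeeping."""

    equation: RiskEquation
    loglik: float
    aic: float
    n_events: int
    n_at_risk: int
    converged: bool
    se: dict[str, float] = field(default_factory=dict)


@dataclass
class BootstrapResult:
    """Bootstrap-refitted equations; non-converged replicates are dropped."""

    equations: list[RiskEquation]
    n_failed: int


# ---------------------------------------------------------------------------
# Person-period construction
# ---------------------------------------------------------------------------

def build_person_periods(panel: pd.DataFrame) -> PersonPeriodTable:
    """Turn raw person-period records into an analysable episode table.

    Within-year duplicate measurements are averaged (this is the annual
    smoothing), gap years carry the last smoothed covariates forward with a
    ``carried_forward`` flag, history flags are recomputed from baseline
    flags plus prior events, and per-outcome at-risk indicators are built.
    Rows after a death event are discarded.
    """
    if "sex" in panel.columns:
        df = design_frame_from_csv_frame(panel)
    else:
        df = panel.copy()
    if "year" not in df.columns:
        raise FitError("panel must contain a 'year' column")
    df = df.sort_values(["id", "year"], kind="mergesort")

    event_cols = [f"event_{o}" for o in OUTCOMES if f"event_{o}" in df.columns]
    flag_cols = event_cols + (["censored"] if "censored" in df.columns else [])
    value_cols = [c for c in df.columns
                  if c not in ("id", "year") and c not in flag_cols]

    # annual smoothing: average duplicate (id, year) measurements
    agg = {c: "mean" for c in value_cols}
    agg.update({c: "max" for c in flag_cols})
    df = df.groupby(["id", "year"], as_index=False, sort=True).agg(agg)

    # fill gap years, carrying last smoothed values forward
    pieces = []
    for pid, g in df.groupby("id", sort=True):
        years = g["year"].to_numpy()
        full = np.arange(years.min(), years.max() + 1)
        if len(full) != len(g):
            g = g.set_index("year").reindex(full)
            g["id"] = pid
            g["carried_forward"] = g[value_cols[0]].isna().astype(float)
            g[value_cols] = g[value_cols].ffill()
            g[flag_cols] = g[flag_cols].fillna(0.0)
            g = g.reset_index(names="year")
        else:
            g = g.copy()
            g["carried_forward"] = 0.0
        pieces.append(g)
    df = pd.concat(pieces, ignore_index=True)

    # history propagation: event in cycle < u (or baseline flag) => history at u
    for o in ABSORBING_OUTCOMES:
        ecol, hcol = f"event_{o}", f"hist_{o}"
        if ecol not in df.columns:
            continue
        base = df.groupby("id")[hcol].transform("first") if hcol in df.columns \
            else 0.0
        prior = (df.groupby("id")[ecol]
                   .transform(lambda s: s.shift(fill_value=0.0).cumsum()))
        df[hcol] = ((base > 0) | (prior > 0)).astype(float)

    # diabetes status propagation
    if "event_diabetes_onset" in df.columns:
        base_dm = df.groupby("id")["diabetes"].transform("first")
        prior_on = (df.groupby("id")["event_diabetes_onset"]
                      .transform(lambda s: s.shift(fill_value=0.0).cumsum()))
        df["diabetes"] = ((base_dm > 0) | (prior_on > 0)).astype(float)

    # drop rows after death
    if "event_mortality" in df.columns:
        dead_before = (df.groupby("id")["event_mortality"]
                         .transform(lambda s: s.shift(fill_value=0.0).cumsum()))
        df = df[dead_before == 0].copy()

    df["start"] = df["year"].astype(float)
    df["stop"] = df["year"].astype(float) + 1.0

    df["at_risk_mortality"] = 1.0
    for o in ABSORBING_OUTCOMES:
        df[f"at_risk_{o}"] = 1.0 - df.get(f"hist_{o}", 0.0)
    df["at_risk_diabetes_onset"] = 1.0 - df["diabetes"]

    return PersonPeriodTable(frame=df.reset_index(drop=True))


def compute_knots(values) -> tuple[float, float, float] | None:
    """Spline knots at the empirical 10th/50th/90th percentiles.

    Uses the linear-interpolation (type-7) percentile definition. Returns
    ``None`` (with a warning) when the data cannot support three distinct
    knots, in which case the variable should enter linearly.
    """
    values = np.asarray(values, dtype=float)
    values = values[np.isfinite(values)]
    if len(values) < 10:
        raise ValueError("need at least 10 values to place spline knots")
    k1, k2, k3 = np.percentile(values, [10, 50, 90])
    if not (k1 < k2 < k3):
        warnings.warn(
            "fewer than 3 distinct knot percentiles; demoting to linear",
            stacklevel=2)
        return None
    return float(k1), float(k2), float(k3)


# ---------------------------------------------------------------------------
# AFT likelihood
# ---------------------------------------------------------------------------

def _episode_arrays(table, outcome):
    frame = table.frame if isinstance(table, PersonPeriodTable) else table
    ecol = f"event_{outcome}" if f"event_{outcome}" in frame.columns else "event"
    if ecol not in frame.columns:
        raise FitError(f"no event column for outcome {outcome!r}")
    rcol = f"at_risk_{outcome}"
    if rcol in frame.columns:
        frame = frame[frame[rcol] > 0]
    if "start" not in frame.columns or "stop" not in frame.columns:
        frame = frame.copy()
        frame["start"] = frame["year"].astype(float)
        frame["stop"] = frame["year"].astype(float) + 1.0
    return frame, ecol


def _design_matrix(frame: pd.DataFrame, terms: list[Term]) -> np.ndarray:
    cols = []
    for t in terms:
        if t.variable not in frame.columns:
            raise FitError(f"missing covariate {t.variable!r} in panel")
        x = frame[t.variable].to_numpy(dtype=float)
        if t.transform == "spline_nonlinear":
            x = sv.rcs_nonlinear(x, t.knots)
        cols.append(x)
    if not cols:
        return np.empty((len(frame), 0))
    return np.column_stack(cols)


def _neg_loglik(params, family, X, start, stop, event, likelihood):
    if family == "exponential":
        beta, log_sigma = params, 0.0
    else:
        beta, log_sigma = params[:-1], params[-1]
    sigma = np.exp(log_sigma)
    eta = np.full(len(start), beta[0])
    if X.shape[1]:
        eta = eta + X @ beta[1:]
    ls_stop = sv.log_survival(family, eta, sigma, stop)
    ls_start = sv.log_survival(family, eta, sigma, start)
    ev = event > 0
    ll = np.where(ev, 0.0, ls_stop - ls_start)
    if np.any(ev):
        if likelihood == "exact":
            ll_ev = sv.log_density(family, eta[ev], sigma, stop[ev]) \
                - ls_start[ev]
        else:  # interval: log(S(start) - S(stop)) - log S(start)
            diff = np.minimum(ls_stop[ev] - ls_start[ev], -1e-12)
            ll_ev = np.log(-np.expm1(diff))
        total = ll.sum() + ll_ev.sum()
    else:
        total = ll.sum()
    if not np.isfinite(total):
        return 1e10
    return -total


def fit_aft(table, outcome: str, family: str, terms: list[Term],
            event_likelihood: str = "exact") -> FitResult:
    """Censored maximum-likelihood AFT fit for one outcome.

    ``table`` is a :class:`PersonPeriodTable` (or any DataFrame carrying
    ``start``/``stop``/``event_<outcome>`` columns plus the covariates named
    by ``terms``). ``terms`` fixes the model structure; fitted coefficients
    are returned on the log-time scale inside a :class:`RiskEquation`.
    """
    if family not in FAMILIES:
        raise ValueError(f"unknown family {family!r}")
    frame, ecol = _episode_arrays(table, outcome)
    start = frame["start"].to_numpy(dtype=float)
    stop = frame["stop"].to_numpy(dtype=float)
    event = frame[ecol].to_numpy(dtype=float)
    n_events = int(event.sum())
    if n_events < 1:
        raise FitError(f"{outcome}: no events in risk set")
    X = _design_matrix(frame, terms)

    # full-rank check on [1 | X]
    aug = np.column_stack([np.ones(len(frame)), X]) if X.shape[1] else \
        np.ones((len(frame), 1))
    if np.linalg.matrix_rank(aug) < aug.shape[1]:
        raise FitError(
            f"{outcome}: design matrix is rank deficient "
            f"(covariates: {[t.variable for t in terms]})")

    # standardise columns for optimiser conditioning
    mu = X.mean(axis=0) if X.shape[1] else np.empty(0)
    sd = X.std(axis=0) if X.shape[1] else np.empty(0)
    sd = np.where(sd > 0, sd, 1.0)
    Xs = (X - mu) / sd if X.shape[1] else X

    total_time = float(np.sum(stop - start))
    x0 = np.zeros(1 + X.shape[1] + (0 if family == "exponential" else 1))
    x0[0] = np.log(max(total_time, 1e-9) / n_events)

    res = optimize.minimize(
        _neg_loglik, x0,
        args=(family, Xs, start, stop, event, event_likelihood),
        method="L-BFGS-B",
        options={"maxiter": MAX_ITER, "ftol": FTOL, "maxfun": 20000},
    )
    params = res.x
    if family == "exponential":
        beta_s, sigma = params, 1.0
    else:
        beta_s, sigma = params[:-1], float(np.exp(params[-1]))

    # un-standardise
    beta = np.empty_like(beta_s)
    beta[1:] = beta_s[1:] / sd if X.shape[1] else beta_s[1:]
    beta[0] = beta_s[0] - float(beta[1:] @ mu) if X.shape[1] else beta_s[0]

    if X.shape[1] and np.any(np.abs(beta_s[1:]) > 50):
        j = int(np.argmax(np.abs(beta_s[1:])))
        raise FitError(
            f"{outcome}: apparent separation on covariate "
            f"{terms[j].variable!r} (|standardised beta| > 50)")

    loglik = -float(res.fun)
    k = len(params)
    aic = 2.0 * k - 2.0 * loglik
    eq = RiskEquation(
        outcome=outcome,
        family=family,
        intercept=float(beta[0]),
        scale=float(sigma),
        terms=[Term(variable=t.variable, transform=t.transform,
                    knots=t.knots, coefficient=float(b))
               for t, b in zip(terms, beta[1:])],
        population=("prediabetes_only" if outcome == "diabetes_onset" else "both"),
    )

    se = _coefficient_se(params, family, Xs, start, stop, event,
                         event_likelihood, sd, terms)
    # L-BFGS-B can report failure when started at the optimum; a tiny
    # gradient still counts as converged
    grad_ok = res.jac is not None and \
        float(np.max(np.abs(res.jac))) < 1e-3 * max(1.0, abs(float(res.fun)))
    converged = (bool(res.success) or grad_ok) and np.isfinite(loglik)
    if not converged:
        warnings.warn(f"{outcome}/{family}: optimiser did not converge "
                      f"({res.message})", stacklevel=2)
    return FitResult(equation=eq, loglik=loglik, aic=aic,
                     n_events=n_events,
                     n_at_risk=int(frame["id"].nunique()),
                     converged=converged, se=se)


def _coefficient_se(params, family, Xs, start, stop, event, likelihood,
                    sd, terms) -> dict[str, float]:
    """Delta-method SEs from a numerical Hessian of the log-likelihood."""
    try:
        eps = 1e-5
        n = len(params)
        H = np.zeros((n, n))
        f0 = _neg_loglik(params, family, Xs, start, stop, event, likelihood)
        for i in range(n):
            for j in range(i, n):
                pi = params.copy(); pi[i] += eps
                pj = params.copy(); pj[j] += eps
                pij = params.copy(); pij[i] += eps; pij[j] += eps
                H[i, j] = H[j, i] = (
                    _neg_loglik(pij, family, Xs, start, stop, event, likelihood)
                    - _neg_loglik(pi, family, Xs, start, stop, event, likelihood)
                    - _neg_loglik(pj, family, Xs, start, stop, event, likelihood)
                    + f0) / eps**2
        cov = np.linalg.inv(H)
        se_s = np.sqrt(np.clip(np.diag(cov), 0.0, None))
    except np.linalg.LinAlgError:
        return {}
    out = {"intercept": float(se_s[0])}
    for idx, t in enumerate(terms):
        key = t.variable + (":nonlinear" if t.transform == "spline_nonlinear" else "")
        out[key] = float(se_s[1 + idx] / sd[idx])
    return out


def select_family(table, outcome: str, terms: list[Term],
                  event_likelihood: str = "exact") -> FitResult:
    """Fit all four families and return the minimum-AIC fit.

    Ties (to machine precision) go to the simpler family in the order
    exponential < Weibull < log-logistic < log-normal.
    """
    fits: list[tuple[float, int, FitResult]] = []
    errors = []
    for rank, family in enumerate(FAMILIES):
        try:
            fits.append((0.0, rank, fit_aft(table, outcome, family, terms,
                                            event_likelihood)))
        except (FitError, ValueError) as exc:
            errors.append(f"{family}: {exc}")
    if not fits:
        raise FitError(
            f"{outcome}: all families failed to fit: " + "; ".join(errors))
    fits.sort(key=lambda t: (t[2].aic, t[1]))
    return fits[0][2]


def _removal_candidates(terms: list[Term]):
    """Droppable units: whole variables (spline pairs together) and
    nonlinear spline parts alone."""
    byvar: dict[str, list[int]] = {}
    for i, t in enumerate(terms):
        byvar.setdefault(t.variable, []).append(i)
    for var, idxs in byvar.items():
        nonlin = [i for i in idxs if terms[i].transform == "spline_nonlinear"]
        if nonlin and len(idxs) > len(nonlin):
            yield f"{var}:nonlinear", nonlin
        yield var, idxs


def backwards_select(fit: FitResult, table,
                     event_likelihood: str = "exact") -> FitResult:
    """AIC backwards elimination starting from a fitted model.

    Repeatedly removes the droppable unit whose removal most decreases AIC,
    stopping when no removal improves it.
    """
    best = fit
    outcome = fit.equation.outcome
    family = fit.equation.family
    while best.equation.terms:
        candidates = []
        terms = best.equation.terms
        for label, idxs in _removal_candidates(terms):
            reduced = [t for i, t in enumerate(terms) if i not in idxs]
            try:
                cand = fit_aft(table, outcome, family, reduced, event_likelihood)
            except FitError:
                continue
            candidates.append((cand.aic, label, cand))
        if not candidates:
            break
        candidates.sort(key=lambda c: c[0])
        if candidates[0][0] < best.aic:
            best = candidates[0][2]
        else:
            break
    return best


# ---------------------------------------------------------------------------
# Bootstrap
# ---------------------------------------------------------------------------

def _resample_table(frame: pd.DataFrame, ids: np.ndarray) -> pd.DataFrame:
    """Concatenate the person-periods of (possibly repeated) ids, giving
    each draw a fresh id so repeated individuals stay distinct."""
    groups = dict(tuple(frame.groupby("id", sort=False)))
    pieces = []
    for j, pid in enumerate(ids):
        g = groups[pid].copy()
        g["id"] = f"b{j}"
        pieces.append(g)
    return pd.concat(pieces, ignore_index=True)


def bootstrap_coefficients(table, outcome: str, family: str,
                           terms: list[Term], B: int, seed: int,
                           event_likelihood: str = "exact",
                           sampler=None) -> BootstrapResult:
    """Refit the equation on B bootstrap resamples of individuals.

    The resampling unit is the individual (all their person-periods move
    together). ``sampler(rng, ids) -> ids`` may be injected to override the
    default with-replacement draw (e.g. an identity resample).
    """
    if B < 1:
        raise ValueError("B must be >= 1")
    frame = table.frame if isinstance(table, PersonPeriodTable) else table
    ids = frame["id"].unique()
    rng = np.random.default_rng(seed)
    equations, n_failed = [], 0
    for _ in range(B):
        drawn = sampler(rng, ids) if sampler is not None else \
            rng.choice(ids, size=len(ids), replace=True)
        bframe = _resample_table(frame, np.asarray(drawn))
        try:
            res = fit_aft(bframe, outcome, family, terms, event_likelihood)
        except FitError:
            n_failed += 1
            continue
        if not res.converged:
            n_failed += 1
            continue
        equations.append(res.equation)
    return BootstrapResult(equations=equations, n_failed=n_failed)


# ---------------------------------------------------------------------------
# Optimism-corrected discrimination
# ---------------------------------------------------------------------------

def person_outcome_survival(table, outcome: str) -> pd.DataFrame:
    """Per-person (time, event) for one outcome plus baseline covariates.

    Time to first event (episode stop) or censoring (last at-risk stop).
    """
    frame, ecol = _episode_arrays(table, outcome)
    first = frame.groupby("id", sort=False).first().reset_index()
    ev = frame[frame[ecol] > 0].groupby("id", sort=False)["stop"].min()
    last = frame.groupby("id", sort=False)["stop"].max()
    out = first.copy()
    out["time"] = out["id"].map(ev).fillna(out["id"].map(last))
    out["event"] = out["id"].map(ev).notna().astype(int)
    return out


def _risk_at_horizon(eq: RiskEquation, baseline: pd.DataFrame,
                     horizon: float) -> np.ndarray:
    eta = sv.linear_predictor(baseline, eq)
    return 1.0 - sv.survival(eq.family, eta, eq.scale, horizon)


def optimism_corrected_c(table, outcome: str, family: str, terms: list[Term],
                         B: int = 100, seed: int = 0, horizon: float = 10.0,
                         event_likelihood: str = "exact") -> dict:
    """Harrell bootstrap-optimism corrected C-statistic and Brier score.

    Apparent performance is measured on the development data with predicted
    risk at ``horizon``; optimism is the mean over replicates of
    (performance on the bootstrap sample minus performance of the
    bootstrap-fitted model on the original data); corrected = apparent -
    optimism. ``B=0`` returns the apparent values unchanged.
    """
    from .validation import harrell_c, brier_score

    frame = table.frame if isinstance(table, PersonPeriodTable) else table
    surv = person_outcome_survival(frame, outcome)
    if surv["event"].sum() < 5:
        raise MetricError(
            f"{outcome}: fewer than 5 events; optimism correction would be "
            "unstable — refusing")

    full = fit_aft(frame, outcome, family, terms, event_likelihood)
    risk = _risk_at_horizon(full.equation, surv, horizon)
    apparent_c, _ = harrell_c(surv["time"], surv["event"], risk, B=0)
    apparent_b = brier_score(surv["time"], surv["event"], risk, horizon)

    rng = np.random.default_rng(seed)
    opt_c, opt_b = [], []
    ids = frame["id"].unique()
    for _ in range(B):
        drawn = rng.choice(ids, size=len(ids), replace=True)
        bframe = _resample_table(frame, drawn)
        try:
            bfit = fit_aft(bframe, outcome, family, terms, event_likelihood)
        except FitError:
            continue
        bsurv = person_outcome_survival(bframe, outcome)
        brisk = _risk_at_horizon(bfit.equation, bsurv, horizon)
        c_boot, _ = harrell_c(bsurv["time"], bsurv["event"], brisk, B=0)
        b_boot = brier_score(bsurv["time"], bsurv["event"], brisk, horizon)
        orisk = _risk_at_horizon(bfit.equation, surv, horizon)
        c_orig, _ = harrell_c(surv["time"], surv["event"], orisk, B=0)
        b_orig = brier_score(surv["time"], surv["event"], orisk, horizon)
        opt_c.append(c_boot - c_orig)
        opt_b.append(b_boot - b_orig)
    return {
        "apparent_c": apparent_c,
        "corrected_c": apparent_c - (float(np.mean(opt_c)) if opt_c else 0.0),
        "apparent_brier": apparent_b,
        "corrected_brier": apparent_b - (float(np.mean(opt_b)) if opt_b else 0.0),
        "n_replicates": len(opt_c),
    }
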