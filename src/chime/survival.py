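"""Spline basis, AFT linear predictors and annual event probabilities.

The risk equations are accelerated-failure-time (AFT) survival models: the
linear predictor eta acts on the log of event time, so exp(beta) is a
survival time ratio (> 1 is protective). Four parametric families are
supported — exponential, Weibull, log-logistic and log-normal — with the
standard AFT survival functions

* Weibull:       S(t) = exp(-(t / e^eta)^(1/sigma))
* exponential:   Weibull with sigma = 1
* log-logistic:  S(t) = 1 / (1 + (t / e^eta)^(1/sigma))
* log-normal:    S(t) = 1 - Phi((ln t - eta) / sigma)

Continuous predictors may enter through a restricted cubic spline with three
knots placed at the 10th/50th/90th percentiles of the development data; the
nonlinear basis uses the (k3 - k1)^2 normalisation so its tail slope is
bounded and the function is linear beyond the last knot.

The discrete-time simulation converts the continuous survival curve into an
annual event probability conditional on having survived to the cycle start,
with covariates frozen within the cycle:

    p_u = 1 - S(u + 1 | eta) / S(u | eta).
"""

from __future__ import annotations

import warnings

import numpy as np
from scipy import special

from .core import FAMILIES, IndividualState, RiskEquation, InvariantError

__all__ = [
    "rcs_nonlinear",
    "linear_predictor",
    "survival",
    "log_survival",
    "log_density",
    "annual_event_probability",
    "annual_probability_from_eta",
]


def rcs_nonlinear(x, knots):
    """Nonlinear restricted-cubic-spline basis term with 3 knots.

    Evaluates ``[(x-k1)+^3 - (x-k2)+^3 (k3-k1)/(k3-k2)
    + (x-k3)+^3 (k2-k1)/(k3-k2)] / (k3-k1)^2``.

    The result is 0 for x <= k1 and linear in x beyond k3. Accepts scalars
    or arrays.
    """
    k1, k2, k3 = (float(k) for k in knots)
    if not (k1 < k2 < k3):
        raise ValueError(f"knots must be strictly ascending, got {knots}")
    x = np.asarray(x, dtype=float)
    p1 = np.clip(x - k1, 0.0, None) ** 3
    p2 = np.clip(x - k2, 0.0, None) ** 3
    p3 = np.clip(x - k3, 0.0, None) ** 3
    out = (p1 - p2 * (k3 - k1) / (k3 - k2) + p3 * (k2 - k1) / (k3 - k2))
    out /= (k3 - k1) ** 2
    return out if out.ndim else float(out)


def linear_predictor(state, eq: RiskEquation):
    """AFT linear predictor eta for one state (or a cohort design frame).

    ``state`` may be an :class:`~chime.core.IndividualState` or a design
    frame (DataFrame with one column per predictor); the latter returns an
    array of per-row etas.
    """
    if isinstance(state, IndividualState):
        eta = eq.intercept
        for term in eq.terms:
            try:
                x = state.value(term.variable)
            except InvariantError as exc:
                raise InvariantError(
                    f"outcome {eq.outcome!r}: {exc}") from exc
            if term.transform == "spline_nonlinear":
                x = rcs_nonlinear(x, term.knots)
            eta += term.coefficient * x
        return float(eta)
    # vectorised path over a design frame
    frame = state
    eta = np.full(len(frame), float(eq.intercept))
    for term in eq.terms:
        if term.variable not in frame.columns:
            raise InvariantError(
                f"outcome {eq.outcome!r}: missing covariate {term.variable!r}")
        x = frame[term.variable].to_numpy(dtype=float)
        if term.transform == "spline_nonlinear":
            x = rcs_nonlinear(x, term.knots)
        eta += term.coefficient * x
    return eta


def _check_args(t, sigma):
    if np.any(np.asarray(t) < 0):
        raise ValueError("t must be >= 0")
    if np.any(np.asarray(sigma) <= 0):
        raise ValueError("sigma must be > 0")


def survival(family: str, eta, sigma, t):
    """Parametric survival probability S(t | eta, sigma) in [0, 1]."""
    _check_args(t, sigma)
    if family not in FAMILIES:
        raise ValueError(f"unknown family {family!r}")
    return np.exp(log_survival(family, eta, sigma, t))


def log_survival(family: str, eta, sigma, t):
    """log S(t); numerically stable, with log S(0) = 0 for every family."""
    eta = np.asarray(eta, dtype=float)
    sigma = np.asarray(sigma, dtype=float)
    t = np.asarray(t, dtype=float)
    with np.errstate(divide="ignore"):
        logt = np.log(t)                     # -inf at t = 0
    w = (logt - eta) / sigma
    if family in ("weibull", "exponential"):
        if family == "exponential":
            w = logt - eta
        return -np.exp(w)
    if family == "loglogistic":
        return -np.logaddexp(0.0, w)
    if family == "lognormal":
        return special.log_ndtr(-w)
    raise ValueError(f"unknown family {family!r}")


def log_density(family: str, eta, sigma, t):
    """log f(t) of the AFT event-time density (t > 0)."""
    eta = np.asarray(eta, dtype=float)
    sigma = np.asarray(sigma, dtype=float)
    t = np.asarray(t, dtype=float)
    logt = np.log(t)
    w = (logt - eta) / sigma
    if family == "exponential":
        # f = lambda exp(-lambda t), lambda = e^-eta
        return -eta - np.exp(logt - eta)
    if family == "weibull":
        # f = (1/(sigma t)) z exp(-z), z = e^w
        return -np.log(sigma) - logt + w - np.exp(w)
    if family == "loglogistic":
        # f = (1/(sigma t)) e^w / (1 + e^w)^2
        return -np.log(sigma) - logt + w - 2.0 * np.logaddexp(0.0, w)
    if family == "lognormal":
        return -np.log(sigma) - logt - 0.5 * w * w - 0.5 * np.log(2.0 * np.pi)
    raise ValueError(f"unknown family {family!r}")


def annual_probability_from_eta(family: str, eta, sigma, u):
    """p = 1 - S(u+1)/S(u) vectorised over eta / u arrays."""
    _check_args(u, sigma)
    ls1 = log_survival(family, eta, sigma, np.asarray(u, dtype=float) + 1.0)
    ls0 = log_survival(family, eta, sigma, np.asarray(u, dtype=float))
    with np.errstate(invalid="ignore"):
        log_ratio = ls1 - ls0
    dead_floor = ~np.isfinite(ls0) | (np.asarray(ls0) < np.log(1e-300))
    if np.any(dead_floor):
        warnings.warn(
            "S(u) underflowed to 0 for some individuals; returning p = 1",
            stacklevel=2)
        log_ratio = np.where(dead_floor, -np.inf, log_ratio)
    p = -np.expm1(log_ratio)
    p = np.clip(p, 0.0, 1.0)
    return p if np.ndim(p) else float(p)


def annual_event_probability(eq: RiskEquation, state: IndividualState,
                             u: int | None = None) -> float:
    """Annual event probability for one individual at cycle start ``u``.

    Covariates are held fixed within the cycle; ``u`` defaults to the
    state's ``time_since_enrollment``.
    """
    if u is None:
        u = state.time_since_enrollment
    if u < 0:
        raise ValueError("u must be >= 0")
    eta = linear_predictor(state, eq)
    return annual_probability_from_eta(eq.family, eta, eq.scale, u)
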