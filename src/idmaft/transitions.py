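"""Weibull accelerated-failure-time building blocks for a single transition.

The illness-death model has three transitions: incidence ``i`` (healthy ->
diseased), mortality without disease ``m0`` (healthy -> dead) and mortality
after diagnosis ``m1`` (diseased -> dead).  Each transition is modelled by a
Weibull AFT regression on the age scale,

    log T = x' beta + u + (1/kappa) * eps,

so that conditional on the covariates ``x`` and the subject-level random
effect ``u`` the event age is Weibull with scale ``eta = exp(x' beta + u)``
(years) and shape ``kappa``:

    S(t) = exp(-(t / eta) ** kappa).

Covariates act multiplicatively on the event age: ``exp(beta_k)`` is the
acceleration factor of covariate ``k``.  Because the Weibull family is closed
under both AFT and proportional-hazards parameterisations, an AFT coefficient
converts to a hazard ratio as ``HR = exp(-kappa * beta_k)``.

Everything in this module is a pure function of its arguments; survival is
evaluated in log space, ``log S(t) = -exp(kappa * (log t - log eta))``, so
large ages and shapes do not overflow.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy.special import gamma as _gamma_fn

__all__ = [
    "TransitionParams",
    "weibull_scale",
    "log_survival",
    "survival",
    "hazard",
    "log_density",
    "density",
    "conditional_survival_m1",
    "weibull_mean",
    "weibull_median",
    "acceleration_factor",
    "hazard_ratio",
]

TRANSITIONS = ("i", "m0", "m1")


@dataclass
class TransitionParams:
    """Regression coefficients and Weibull shape for one transition.

    Parameters
    ----------
    beta
        Coefficient vector on the log-age scale; the first entry is the
        intercept.
    kappa
        Weibull shape parameter, > 0.
    label
        Transition identifier, one of ``"i"``, ``"m0"``, ``"m1"``.
    """

    beta: np.ndarray
    kappa: float
    label: str = "i"

    def __post_init__(self) -> None:
        self.beta = np.atleast_1d(np.asarray(self.beta, dtype=float))
        if self.beta.ndim != 1 or self.beta.size < 1:
            raise ValueError("beta must be a non-empty 1-d vector")
        if not np.all(np.isfinite(self.beta)):
            raise ValueError("beta must be finite")
        if not (np.isfinite(self.kappa) and self.kappa > 0):
            raise ValueError(f"kappa must be positive and finite, got {self.kappa}")
        if self.label not in TRANSITIONS:
            raise ValueError(f"label must be one of {TRANSITIONS}, got {self.label!r}")

    @property
    def n_params(self) -> int:
        return self.beta.size + 1


def weibull_scale(x, params: TransitionParams, u: float = 0.0) -> float:
    """Weibull scale ``eta = exp(x' beta + u)`` in years.

    ``x`` is a covariate vector whose first element is the constant 1.
    Raises if the result over/underflows to a non-finite or zero value.
    """
    x = np.asarray(x, dtype=float)
    if x.shape[-1] != params.beta.size:
        raise ValueError(
            f"covariate vector length {x.shape[-1]} does not match "
            f"beta length {params.beta.size}"
        )
    lin = x @ params.beta + u
    eta = np.exp(lin)
    if not np.all(np.isfinite(eta)) or np.any(eta <= 0):
        raise FloatingPointError(f"Weibull scale overflow: linear predictor {lin}")
    return eta


def log_survival(t, scale, kappa):
    """``log S(t) = -(t/scale)**kappa`` evaluated in log space; S(0) = 1."""
    t = np.asarray(t, dtype=float)
    if np.any(t < 0):
        raise ValueError("ages must be non-negative")
    with np.errstate(divide="ignore"):  # log(0) -> -inf gives log S(0) = 0
        z = kappa * (np.log(t) - np.log(scale))
    return -np.exp(z)


def survival(t, scale, kappa):
    """Weibull survival function ``S(t) = exp(-(t/scale)**kappa)``."""
    return np.exp(log_survival(t, scale, kappa))


def hazard(t, scale, kappa):
    """Weibull hazard ``(kappa/scale) * (t/scale)**(kappa-1)`` per year.

    Requires ``t > 0`` (the hazard is singular at 0 when ``kappa < 1``).
    """
    t = np.asarray(t, dtype=float)
    if np.any(t <= 0):
        raise ValueError("hazard requires t > 0")
    return (kappa / scale) * np.exp((kappa - 1.0) * (np.log(t) - np.log(scale)))


def log_density(t, scale, kappa):
    """Log of the Weibull density, ``log hazard(t) + log S(t)``."""
    t = np.asarray(t, dtype=float)
    if np.any(t <= 0):
        raise ValueError("density requires t > 0")
    logt_scaled = np.log(t) - np.log(scale)
    return (
        np.log(kappa)
        - np.log(scale)
        + (kappa - 1.0) * logt_scaled
        - np.exp(kappa * logt_scaled)
    )


def density(t, scale, kappa):
    return np.exp(log_density(t, scale, kappa))


def conditional_survival_m1(t2, t1, scale, kappa):
    """Markov conditional survival ``S(t2)/S(t1)`` for the m1 transition.

    Under the Markov assumption the post-diagnosis death hazard depends only
    on current age, so the survival of ``T2 | T1 = t1`` is the ratio of the
    unconditional m1 survival functions.  Requires ``0 < t1 <= t2``.
    """
    t1 = np.asarray(t1, dtype=float)
    t2 = np.asarray(t2, dtype=float)
    if np.any(t1 <= 0):
        raise ValueError("t1 must be positive")
    if np.any(t2 < t1):
        raise ValueError("t2 must be >= t1")
    return np.exp(log_survival(t2, scale, kappa) - log_survival(t1, scale, kappa))


def weibull_mean(linpred, kappa):
    """Mean event age ``exp(linpred) * Gamma(1 + 1/kappa)`` in years."""
    if kappa <= 0:
        raise ValueError("kappa must be positive")
    return np.exp(linpred) * _gamma_fn(1.0 + 1.0 / kappa)


def weibull_median(linpred, kappa):
    """Median event age ``exp(linpred) * (log 2)**(1/kappa)`` in years."""
    if kappa <= 0:
        raise ValueError("kappa must be positive")
    return np.exp(linpred) * np.log(2.0) ** (1.0 / kappa)


def acceleration_factor(beta_coef):
    """AFT acceleration factor ``exp(beta)`` of a covariate effect."""
    return np.exp(beta_coef)


def hazard_ratio(beta_coef, kappa):
    """Weibull AFT -> proportional-hazards conversion ``exp(-kappa * beta)``.

    A negative AFT coefficient (earlier event) maps to a hazard ratio > 1.
    Identity: ``hazard_ratio(b, k) == acceleration_factor(b) ** (-k)``.
    """
    if kappa <= 0:
        raise ValueError("kappa must be positive")
    return np.exp(-kappa * np.asarray(beta_coef, dtype=float))
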