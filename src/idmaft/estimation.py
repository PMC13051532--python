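"""Maximum-likelihood estimation for the trivariate Weibull AFT
illness-death model.

Fitting strategy
----------------
1. Three univariate transition models without random effects are fitted
   first; their estimates seed the trivariate optimization (warm starts).
2. Random-effect variances are initialized by a coarse grid search over
   {1e-6, 1e-4, 1e-2}, keeping the value with the best marginal likelihood.
3. The marginal log-likelihood (Gauss-Hermite quadrature over the random
   effects) is maximized by a bounded quasi-Newton method (L-BFGS-B with
   numerically differenced gradients, iteration cap 500).

Working parameterization: regression coefficients on the natural scale,
shapes and variances as logs, and the two free correlations of the hetvar
structure through a sequential bounded transform
``r_im1 = tanh(z1)``, ``r_m0m1 = tanh(z2) * sqrt(1 - r_im1**2)``
which keeps the covariance matrix positive semi-definite for every real
(z1, z2).  Estimates and standard errors are reported on the natural scale
(delta method from the inverse observed information, computed by central
finite differences; a pseudo-inverse is used and affected entries flagged
NaN when the Hessian is near-singular).
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import optimize
from scipy.stats import norm

from .likelihood import (
    ModelParams,
    RandomEffectSpec,
    SubjectArrays,
    marginal_loglik,
)
from .transitions import (
    TransitionParams,
    hazard_ratio,
    weibull_mean,
    weibull_median,
)

__all__ = [
    "FitResult",
    "ProfileSummary",
    "fit_univariate",
    "fit",
    "wald_ci",
    "effect_table",
    "profile_summaries",
    "median_survival_difference",
]

_RE_NAMES = {
    "none": [],
    "homvar": ["s2"],
    "hetvar": ["si2", "sm02", "sm12", "ci_m1", "cm0_m1"],
}
_LOGK_BOUNDS = (np.log(0.05), np.log(60.0))
_LOGV_BOUNDS = (-25.0, 3.0)


# ---------------------------------------------------------------------------
# Working-scale parameter vector
# ---------------------------------------------------------------------------


class _Parameterization:
    """Maps between the optimizer's working vector and model parameters."""

    def __init__(self, d: int, structure: str):
        self.d = d
        self.structure = structure
        self.n_re = len(_RE_NAMES[structure])
        self.n_params = 3 * (d + 1) + self.n_re
        self.names = []
        for lab in ("i", "m0", "m1"):
            self.names += [f"b{j}_{lab}" for j in range(d)] + [f"kappa_{lab}"]
        self.names += _RE_NAMES[structure]

    def pack(self, params: ModelParams) -> np.ndarray:
        x = []
        for tp in params.transition_params:
            x.extend(tp.beta)
            x.append(np.log(tp.kappa))
        re = params.re
        if self.structure == "homvar":
            x.append(np.log(max(re.s2, 1e-12)))
        elif self.structure == "hetvar":
            v = [max(re.si2, 1e-12), max(re.sm02, 1e-12), max(re.sm12, 1e-12)]
            x.extend(np.log(v))
            r1 = re.ci_m1 / np.sqrt(v[0] * v[2])
            r1 = np.clip(r1, -0.999, 0.999)
            denom = np.sqrt(max(1.0 - r1**2, 1e-12))
            r2 = np.clip(re.cm0_m1 / np.sqrt(v[1] * v[2]) / denom, -0.999, 0.999)
            x.extend([np.arctanh(r1), np.arctanh(r2)])
        return np.array(x, dtype=float)

    def unpack(self, x: np.ndarray) -> ModelParams:
        d = self.d
        tps = []
        for k, lab in enumerate(("i", "m0", "m1")):
            off = k * (d + 1)
            tps.append(TransitionParams(x[off : off + d], np.exp(x[off + d]), lab))
        off = 3 * (d + 1)
        if self.structure == "none":
            re = RandomEffectSpec("none")
        elif self.structure == "homvar":
            re = RandomEffectSpec("homvar", s2=np.exp(x[off]))
        else:
            si2, sm02, sm12 = np.exp(x[off : off + 3])
            r1 = np.tanh(x[off + 3])
            r2 = np.tanh(x[off + 4]) * np.sqrt(1.0 - r1**2)
            re = RandomEffectSpec(
                "hetvar",
                si2=si2,
                sm02=sm02,
                sm12=sm12,
                ci_m1=r1 * np.sqrt(si2 * sm12),
                cm0_m1=r2 * np.sqrt(sm02 * sm12),
            )
        return ModelParams(*tps, re=re)

    def natural(self, x: np.ndarray) -> np.ndarray:
        """Natural-scale parameter vector in the order of ``self.names``."""
        p = self.unpack(x)
        out = []
        for tp in p.transition_params:
            out.extend(tp.beta)
            out.append(tp.kappa)
        re = p.re
        if self.structure == "homvar":
            out.append(re.s2)
        elif self.structure == "hetvar":
            out.extend([re.si2, re.sm02, re.sm12, re.ci_m1, re.cm0_m1])
        return np.array(out)

    def natural_jacobian(self, x: np.ndarray, h: float = 1e-6) -> np.ndarray:
        """d(natural)/d(working), by central differences (transform only)."""
        J = np.empty((self.n_params, self.n_params))
        for j in range(self.n_params):
            step = h * max(1.0, abs(x[j]))
            xp, xm = x.copy(), x.copy()
            xp[j] += step
            xm[j] -= step
            J[:, j] = (self.natural(xp) - self.natural(xm)) / (2 * step)
        return J

    def bounds(self):
        b = []
        for _ in range(3):
            b += [(-20.0, 20.0)] * self.d + [_LOGK_BOUNDS]
        if self.structure == "homvar":
            b += [_LOGV_BOUNDS]
        elif self.structure == "hetvar":
            b += [_LOGV_BOUNDS] * 3 + [(-6.0, 6.0)] * 2
        return b


# ---------------------------------------------------------------------------
# Univariate warm starts
# ---------------------------------------------------------------------------


def _weibull_moment_init(ages: np.ndarray) -> tuple[float, float]:
    """Moment-based (log-scale, shape) from a sample of event ages."""
    ages = ages[np.isfinite(ages) & (ages > 0)]
    if ages.size == 0:
        return np.log(80.0), 5.0
    m, s = float(np.mean(ages)), float(np.std(ages))
    cv = s / m if m > 0 else 0.5
    kappa = float(np.clip(cv ** (-1.086) if cv > 0 else 10.0, 0.5, 30.0))
    return float(np.log(m)), kappa


def _univariate_nll(label: str, data: SubjectArrays):
    """Negative log-likelihood factor of one transition (no random effect)."""
    d1, d2 = data.d1, data.d2

    def logS(t, lin, kappa):
        with np.errstate(divide="ignore", invalid="ignore", over="ignore"):
            return -np.exp(kappa * (np.log(t) - lin))

    def logf(t, lin, kappa):
        with np.errstate(divide="ignore", invalid="ignore", over="ignore"):
            z = np.log(t) - lin
            return np.log(kappa) - lin + (kappa - 1.0) * z - np.exp(kappa * z)

    def nll(x):
        beta, kappa = x[:-1], np.exp(x[-1])
        lin = data.X @ beta
        if label == "i":
            with np.errstate(divide="ignore", invalid="ignore"):
                a = logS(np.where(d1, data.t_left, data.last), lin, kappa)
                b = np.where(d1, logS(np.where(d1, data.t_right, 2.0), lin, kappa), -np.inf)
                diff = np.minimum(b - a, 0.0)
                onset = np.where(d1, a + np.log1p(-np.exp(diff)), a)
            ll = onset - logS(data.entry, lin, kappa)
        elif label == "m0":
            term = np.where(
                d1,
                logS(np.where(d1, data.t_right, 1.0), lin, kappa),
                np.where(d2, logf(data.last, lin, kappa), logS(data.last, lin, kappa)),
            )
            ll = term - logS(data.entry, lin, kappa)
        else:  # m1: diagnosed subjects only, truncated at the interval
            # midpoint (capped at the last observed age, as in the full model)
            tstar = np.where(d1, np.minimum(data.t_mid, data.last), 1.0)
            term = np.where(
                d2, logf(data.last, lin, kappa), logS(data.last, lin, kappa)
            ) - logS(tstar, lin, kappa)
            ll = np.where(d1, term, 0.0)
        ll = np.where(np.isfinite(ll), ll, -1e10)
        return -float(ll.sum())

    return nll


def fit_univariate(label: str, data, maxiter: int = 500) -> TransitionParams:
    """Fit one transition's Weibull AFT submodel without random effects.

    Used for warm starts: the likelihood is restricted to the factor of the
    full model involving transition ``label`` only.  If the data contain no
    informative event for the transition, a moment-based initialization is
    returned with a warning.
    """
    if not isinstance(data, SubjectArrays):
        data = SubjectArrays(data)
    d = data.X.shape[1]
    d1, d2 = data.d1, data.d2
    if label == "i":
        events, ages = d1, data.t_mid[d1]
    elif label == "m0":
        events, ages = (~d1) & d2, data.last[(~d1) & d2]
    elif label == "m1":
        events, ages = d1 & d2, data.last[d1 & d2]
    else:
        raise ValueError(f"unknown transition {label!r}")
    log_scale, kappa0 = _weibull_moment_init(
        ages if events.any() else data.last
    )
    x0 = np.zeros(d + 1)
    x0[0], x0[-1] = log_scale, np.log(kappa0)
    if not events.any():
        warnings.warn(
            f"no informative events for transition {label!r}; falling back to "
            "moment-based initialization",
            stacklevel=2,
        )
        return TransitionParams(x0[:-1], np.exp(x0[-1]), label)
    nll = _univariate_nll(label, data)
    bounds = [(None, None)] * d + [_LOGK_BOUNDS]
    res = optimize.minimize(
        nll, x0, method="L-BFGS-B", bounds=bounds, options={"maxiter": maxiter}
    )
    return TransitionParams(res.x[:-1], float(np.exp(res.x[-1])), label)


# ---------------------------------------------------------------------------
# Trivariate fit
# ---------------------------------------------------------------------------


@dataclass
class FitResult:
    """Fitted model: natural-scale estimates, uncertainty and fit criteria."""

    structure: str
    params_hat: ModelParams
    param_names: list
    estimates: np.ndarray
    se: np.ndarray
    cov: np.ndarray  # natural-scale covariance of the estimates
    loglik: float
    aic: float
    bic: float
    n_subjects: int
    n_free_params: int
    converged: bool
    n_points: int
    covariate_names: list = field(default_factory=list)
    m1_truncation: str = "midpoint"
    optimizer_trace: dict = field(default_factory=dict)

    def summary(self, level: float = 0.95) -> pd.DataFrame:
        lo, hi = wald_ci(self.estimates, self.se, level)
        return pd.DataFrame(
            {"estimate": self.estimates, "se": self.se, "ci_low": lo, "ci_high": hi},
            index=pd.Index(self.param_names, name="parameter"),
        )

    def __getitem__(self, name: str) -> float:
        return float(self.estimates[self.param_names.index(name)])

    def to_text(self) -> str:
        head = (
            f"structure: {self.structure}\n"
            f"n_subjects: {self.n_subjects}\n"
            f"n_free_params: {self.n_free_params}\n"
            f"n_quadrature_points: {self.n_points}\n"
            f"converged: {self.converged}\n"
            f"loglik: {self.loglik:.6f}\n"
            f"aic: {self.aic:.6f}\nbic: {self.bic:.6f}\n"
        )
        return head + self.summary().to_string() + "\n"


def _hessian(fun, x: np.ndarray, rel_step: float = 1e-3) -> np.ndarray:
    """Central finite-difference Hessian (symmetrized)."""
    p = x.size
    h = rel_step * np.maximum(1.0, np.abs(x))
    H = np.empty((p, p))
    f0 = fun(x)
    for i in range(p):
        ei = np.zeros(p)
        ei[i] = h[i]
        fpp = fun(x + ei)
        fmm = fun(x - ei)
        H[i, i] = (fpp - 2 * f0 + fmm) / h[i] ** 2
        for j in range(i + 1, p):
            ej = np.zeros(p)
            ej[j] = h[j]
            H[i, j] = H[j, i] = (
                fun(x + ei + ej) - fun(x + ei - ej) - fun(x - ei + ej) + fun(x - ei - ej)
            ) / (4 * h[i] * h[j])
    return 0.5 * (H + H.T)


def fit(
    data,
    structure: str = "homvar",
    n_points: int = 2,
    m1_truncation: str = "midpoint",
    start: ModelParams | None = None,
    re_variance_grid=(1e-6, 1e-4, 1e-2),
    compute_se: bool = True,
    maxiter: int = 500,
    seed: int = 0,
) -> FitResult:
    """Maximum-likelihood fit of the trivariate illness-death AFT model.

    Parameters
    ----------
    data
        Dataset (DataFrame, list of SubjectRecord, or SubjectArrays).
    structure
        Random-effect structure: ``"none"``, ``"homvar"`` or ``"hetvar"``.
    n_points
        Gauss-Hermite quadrature points per random-effect dimension.
    start
        Optional warm start; when absent, univariate fits plus a variance
        grid search provide it.
    compute_se
        Whether to compute the observed-information standard errors (the
        finite-difference Hessian dominates the cost of small fits).
    """
    if not isinstance(data, SubjectArrays):
        data = SubjectArrays(data)
    d = data.X.shape[1]
    par = _Parameterization(d, structure)

    def nll(x):
        if not np.all(np.isfinite(x)):
            return 1e12
        try:
            return -marginal_loglik(
                data, par.unpack(x), n_points, m1_truncation, impossible="floor"
            )
        except (ValueError, FloatingPointError):
            return 1e12

    if start is not None:
        x0 = par.pack(start)
    else:
        tps = [fit_univariate(lab, data) for lab in ("i", "m0", "m1")]
        base = ModelParams(*tps, re=RandomEffectSpec("none"))
        if structure == "none":
            x0 = par.pack(base)
        else:
            best_x0, best_val = None, np.inf
            for v in re_variance_grid:
                if structure == "homvar":
                    re = RandomEffectSpec("homvar", s2=v)
                else:
                    re = RandomEffectSpec("hetvar", si2=v, sm02=v, sm12=v)
                cand = par.pack(ModelParams(*tps, re=re))
                val = nll(cand)
                if val < best_val:
                    best_x0, best_val = cand, val
            x0 = best_x0

    rng = np.random.default_rng(seed)
    for attempt in range(4):
        if np.isfinite(nll(x0)) and nll(x0) < 1e11:
            break
        x0 = x0 + rng.normal(scale=0.05, size=x0.size)  # jittered restart

    opts = {"maxiter": maxiter, "ftol": 1e-9, "gtol": 1e-5}

    def _minimize(x_start):
        return optimize.minimize(
            nll, x_start, method="L-BFGS-B", bounds=par.bounds(), options=opts
        )

    res = _minimize(x0)
    declared_converged = bool(res.success)
    # polish restarts: a line-search abort near the optimum is declared
    # converged when another run improves the objective by less than the
    # relative function-change tolerance
    for _ in range(2):
        if declared_converged:
            break
        res2 = _minimize(res.x)
        improvement = float(res.fun) - float(res2.fun)
        if res2.fun <= res.fun:
            res = res2
        if res2.success or improvement <= 1e-8 * max(1.0, abs(float(res.fun))):
            declared_converged = True
    xhat, best = res.x, float(res.fun)
    if structure != "none":
        # the likelihood is nearly flat in log-variance near the zero-variance
        # boundary and the optimizer can stall slightly above it; check the
        # boundary candidate and re-polish if it improves
        n_var = 1 if structure == "homvar" else 3
        cand = xhat.copy()
        cand[3 * (d + 1) : 3 * (d + 1) + n_var] = _LOGV_BOUNDS[0]
        if nll(cand) < best:
            res2 = _minimize(cand)
            if res2.fun <= best:
                res, xhat, best = res2, res2.x, float(res2.fun)
    loglik = -float(res.fun)
    k = par.n_params
    n = data.n
    converged = declared_converged and np.isfinite(loglik) and loglik > -1e11

    names = list(par.names)
    est = par.natural(xhat)
    se = np.full(k, np.nan)
    cov_nat = np.full((k, k), np.nan)
    if compute_se:
        H = _hessian(nll, xhat)
        # pseudo-inverse guards near-singular information (e.g. variance
        # components pinned near zero); unidentified entries stay NaN
        eigvals = np.linalg.eigvalsh(H)
        if eigvals[0] <= 1e-10 * max(1.0, abs(eigvals[-1])):
            warnings.warn(
                "observed information is near-singular; using a pseudo-inverse "
                "and flagging affected standard errors",
                stacklevel=2,
            )
            cov_w = np.linalg.pinv(H, rcond=1e-10)
        else:
            cov_w = np.linalg.inv(H)
        J = par.natural_jacobian(xhat)
        cov_nat = J @ cov_w @ J.T
        diag = np.diag(cov_nat).copy()
        se = np.sqrt(np.where(diag >= 0, diag, np.nan))

    return FitResult(
        structure=structure,
        params_hat=par.unpack(xhat),
        param_names=names,
        estimates=est,
        se=se,
        cov=cov_nat,
        loglik=loglik,
        aic=-2 * loglik + 2 * k,
        bic=-2 * loglik + np.log(n) * k,
        n_subjects=n,
        n_free_params=k,
        converged=converged,
        n_points=n_points,
        covariate_names=[f"x{j}" for j in range(1, d)],
        m1_truncation=m1_truncation,
        optimizer_trace={
            "optimizer": "L-BFGS-B",
            "message": str(res.message),
            "n_iterations": int(res.nit),
            "n_evaluations": int(res.nfev),
        },
    )


# ---------------------------------------------------------------------------
# Inference helpers
# ---------------------------------------------------------------------------


def wald_ci(estimate, se, level: float = 0.95):
    """Wald confidence interval ``estimate +/- z_{1-alpha/2} * se``."""
    z = norm.ppf(0.5 + level / 2.0)
    estimate = np.asarray(estimate, dtype=float)
    se = np.asarray(se, dtype=float)
    return estimate - z * se, estimate + z * se


def effect_table(
    fit_result: FitResult, covariate_names=None, level: float = 0.95
) -> pd.DataFrame:
    """Per-transition covariate effects: beta, acceleration factor exp(beta)
    and hazard ratio exp(-kappa*beta), each with a Wald-type CI.

    The AF interval exponentiates the beta interval; the HR interval applies
    the delta method to kappa*beta using the joint covariance of the
    estimates.
    """
    names = fit_result.param_names
    z = norm.ppf(0.5 + level / 2.0)
    d = len(fit_result.covariate_names) + 1
    cov_names = covariate_names or fit_result.covariate_names
    rows = []
    for lab in ("i", "m0", "m1"):
        ik = names.index(f"kappa_{lab}")
        kappa = fit_result.estimates[ik]
        for j in range(1, d):
            ib = names.index(f"b{j}_{lab}")
            beta = fit_result.estimates[ib]
            se_b = fit_result.se[ib]
            b_lo, b_hi = beta - z * se_b, beta + z * se_b
            g = kappa * beta  # log HR is -g
            var_g = (
                kappa**2 * fit_result.cov[ib, ib]
                + beta**2 * fit_result.cov[ik, ik]
                + 2 * kappa * beta * fit_result.cov[ib, ik]
            )
            se_g = np.sqrt(var_g) if var_g >= 0 else np.nan
            hr_bounds = sorted([np.exp(-(g - z * se_g)), np.exp(-(g + z * se_g))])
            rows.append(
                {
                    "transition": lab,
                    "covariate": cov_names[j - 1],
                    "beta": beta,
                    "beta_low": b_lo,
                    "beta_high": b_hi,
                    "af": np.exp(beta),
                    "af_low": np.exp(b_lo),
                    "af_high": np.exp(b_hi),
                    "hr": float(hazard_ratio(beta, kappa)),
                    "hr_low": hr_bounds[0],
                    "hr_high": hr_bounds[1],
                }
            )
    return pd.DataFrame(rows)


@dataclass
class ProfileSummary:
    """Mean and median event ages (years) with CIs for one covariate
    pattern and one transition."""

    profile: str
    transition: str
    mean: float
    mean_low: float
    mean_high: float
    median: float
    median_low: float
    median_high: float


def _delta_ci(fun, fit_result: FitResult, idx, level: float, h: float = 1e-5):
    """Delta-method CI of a scalar function of the natural estimates."""
    theta = fit_result.estimates[idx]
    val = fun(theta)
    grad = np.empty(len(idx))
    for j in range(len(idx)):
        step = h * max(1.0, abs(theta[j]))
        tp, tm = theta.copy(), theta.copy()
        tp[j] += step
        tm[j] -= step
        grad[j] = (fun(tp) - fun(tm)) / (2 * step)
    var = float(grad @ fit_result.cov[np.ix_(idx, idx)] @ grad)
    se = np.sqrt(var) if var >= 0 else np.nan
    z = norm.ppf(0.5 + level / 2.0)
    return val, val - z * se, val + z * se


def profile_summaries(
    fit_result: FitResult, profiles, level: float = 0.95
) -> list[ProfileSummary]:
    """Mean/median event ages per transition for covariate patterns.

    ``profiles`` maps labels to covariate vectors *without* the leading 1,
    e.g. ``{"female": [0], "male": [1]}``.  CIs propagate the joint
    uncertainty of (beta, kappa) by the delta method.
    """
    names = fit_result.param_names
    d = len(fit_result.covariate_names) + 1
    out = []
    for label, xcov in profiles.items():
        x = np.concatenate(([1.0], np.asarray(xcov, dtype=float)))
        for lab in ("i", "m0", "m1"):
            idx = [names.index(f"b{j}_{lab}") for j in range(d)] + [
                names.index(f"kappa_{lab}")
            ]

            def mean_fn(th):
                return weibull_mean(float(x @ th[:-1]), th[-1])

            def med_fn(th):
                return weibull_median(float(x @ th[:-1]), th[-1])

            m, m_lo, m_hi = _delta_ci(mean_fn, fit_result, idx, level)
            md, md_lo, md_hi = _delta_ci(med_fn, fit_result, idx, level)
            out.append(
                ProfileSummary(label, lab, m, m_lo, m_hi, md, md_lo, md_hi)
            )
    return out


def profile_table(summaries) -> pd.DataFrame:
    return pd.DataFrame([vars(s) for s in summaries])


def median_survival_difference(
    fit_result: FitResult, profile, level: float = 0.95
):
    """Difference of median death ages, disease-free minus post-diagnosis,
    for one covariate pattern; CI by the delta method.

    Quantifies how much the disease shortens the median lifetime for
    subjects with covariates ``profile`` (vector without the leading 1).
    """
    names = fit_result.param_names
    d = len(fit_result.covariate_names) + 1
    x = np.concatenate(([1.0], np.asarray(profile, dtype=float)))
    idx = (
        [names.index(f"b{j}_m0") for j in range(d)]
        + [names.index("kappa_m0")]
        + [names.index(f"b{j}_m1") for j in range(d)]
        + [names.index("kappa_m1")]
    )

    def diff_fn(th):
        m0 = weibull_median(float(x @ th[:d]), th[d])
        m1 = weibull_median(float(x @ th[d + 1 : 2 * d + 1]), th[2 * d + 1])
        return m0 - m1

    return _delta_ci(diff_fn, fit_result, idx, level)
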