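"""Observed-data likelihood for the Weibull AFT illness-death model.

Each subject contributes one of four terms, determined by the diagnosis
indicator ``delta1`` and death indicator ``delta2``:

======  ======  ======  ==========================================================
case    delta1  delta2  contribution (conditional on covariates x and effects u)
======  ======  ======  ==========================================================
I       1       1       [S_i(Tl)-S_i(Tr)] S_m0(Tr) f_m1(Y2) / [S_i(L) S_m0(L) S_m1(Tm)]
II      1       0       [S_i(Tl)-S_i(Tr)] S_m0(Tr) S_m1(Y2) / [S_i(L) S_m0(L) S_m1(Tm)]
III     0       1       S_i(Y2) f_m0(Y2) / [S_i(L) S_m0(L)]
IV      0       0       S_i(Y2) S_m0(Y2) / [S_i(L) S_m0(L)]
======  ======  ======  ==========================================================

Division by ``S_i(L) S_m0(L)`` conditions on being event-free at study entry
age ``L`` (left truncation / delayed entry); the interval ``[Tl, Tr]`` carries
the interval censoring of the disease onset; the post-diagnosis death
distribution is left-truncated at the interval midpoint ``Tm`` (the interval
right bound ``Tr`` is available as an alternative).

The marginal likelihood integrates the trivariate normal random effect out of
the conditional contribution by non-adaptive Gauss-Hermite quadrature; the
mixture over nodes is accumulated with log-sum-exp because individual
contributions underflow at realistic ages.
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy.special import logsumexp

from .transitions import TransitionParams, log_density, log_survival

__all__ = [
    "SubjectRecord",
    "RandomEffectSpec",
    "ModelParams",
    "case_of",
    "log_contribution",
    "quadrature_grid",
    "marginal_loglik",
    "SubjectArrays",
]

RE_STRUCTURES = ("none", "homvar", "hetvar")


@dataclass
class SubjectRecord:
    """One individual's observed tuple.

    Ages are in years.  For undiagnosed subjects (``delta1 == 0``) the onset
    interval degenerates to ``[last_age, inf)``.
    """

    entry_age: float
    t_left: float
    t_right: float
    last_age: float
    delta1: int
    delta2: int
    x: np.ndarray
    t_mid: float = float("nan")

    def __post_init__(self) -> None:
        self.x = np.atleast_1d(np.asarray(self.x, dtype=float))
        if self.x[0] != 1.0:
            raise ValueError("covariate vector must start with the constant 1")
        if self.delta1 not in (0, 1) or self.delta2 not in (0, 1):
            raise ValueError("delta1 and delta2 must be 0 or 1")
        if not (self.entry_age >= 0 and self.last_age > self.entry_age):
            raise ValueError(
                f"need 0 <= entry_age < last_age, got L={self.entry_age}, "
                f"Y2={self.last_age}"
            )
        if self.delta1 == 1:
            if math.isnan(self.t_mid):
                self.t_mid = 0.5 * (self.t_left + self.t_right)
            # Tr may exceed Y2: a visit interval built around a true onset
            # can end after death or censoring; the likelihood handles it
            if not (self.t_left < self.t_right < float("inf")):
                raise ValueError(
                    f"diagnosed subject needs a finite interval Tl < Tr, got "
                    f"[{self.t_left}, {self.t_right}]"
                )
        else:
            self.t_left = self.last_age
            self.t_right = float("inf")
            self.t_mid = float("nan")


@dataclass
class RandomEffectSpec:
    """Variance structure of the trivariate random effect ``u``.

    ``structure`` is one of

    * ``"none"``   -- no random effect (u fixed at 0);
    * ``"homvar"`` -- one shared scalar effect, ``u ~ N(0, s2)``, added to all
      three linear predictors;
    * ``"hetvar"`` -- transition-specific effects with covariance matrix

        [[si2,   0,      ci_m1 ],
         [0,     sm02,   cm0_m1],
         [ci_m1, cm0_m1, sm12  ]]

      (independence of disease onset and disease-free mortality is imposed by
      fixing the (i, m0) covariance at zero).
    """

    structure: str = "none"
    s2: float = 0.0
    si2: float = 0.0
    sm02: float = 0.0
    sm12: float = 0.0
    ci_m1: float = 0.0
    cm0_m1: float = 0.0

    def __post_init__(self) -> None:
        if self.structure not in RE_STRUCTURES:
            raise ValueError(f"structure must be one of {RE_STRUCTURES}")
        for name in ("s2", "si2", "sm02", "sm12"):
            if getattr(self, name) < 0:
                raise ValueError(f"{name} must be non-negative")
        if self.structure == "hetvar":
            cov = self.covariance()
            eigmin = np.linalg.eigvalsh(cov)[0]
            if eigmin < -1e-10 * max(1.0, np.abs(cov).max()):
                raise ValueError("hetvar covariance matrix is not positive semi-definite")

    def covariance(self) -> np.ndarray:
        """3x3 covariance matrix of (u_i, u_m0, u_m1)."""
        if self.structure == "none":
            return np.zeros((3, 3))
        if self.structure == "homvar":
            return np.full((3, 3), self.s2)
        return np.array(
            [
                [self.si2, 0.0, self.ci_m1],
                [0.0, self.sm02, self.cm0_m1],
                [self.ci_m1, self.cm0_m1, self.sm12],
            ]
        )


@dataclass
class ModelParams:
    """Full parameter vector theta: three transition submodels plus the
    random-effect structure."""

    inc: TransitionParams
    mort0: TransitionParams
    mort1: TransitionParams
    re: RandomEffectSpec = field(default_factory=RandomEffectSpec)

    def __post_init__(self) -> None:
        d = self.inc.beta.size
        if not (self.mort0.beta.size == d and self.mort1.beta.size == d):
            raise ValueError("the three beta vectors must have equal length")

    @property
    def transition_params(self) -> tuple[TransitionParams, ...]:
        return (self.inc, self.mort0, self.mort1)


def case_of(subject: SubjectRecord) -> str:
    """Likelihood case of a subject: I (1,1), II (1,0), III (0,1), IV (0,0)."""
    return {(1, 1): "I", (1, 0): "II", (0, 1): "III", (0, 0): "IV"}[
        (subject.delta1, subject.delta2)
    ]


# ---------------------------------------------------------------------------
# Vectorized internals
# ---------------------------------------------------------------------------


class SubjectArrays:
    """Column-oriented view of a dataset for fast likelihood evaluation.

    Built once per dataset; all likelihood evaluations then operate on plain
    numpy arrays of shape (n,) or (n, d).
    """

    def __init__(self, subjects) -> None:
        if isinstance(subjects, pd.DataFrame):
            subjects = dataframe_to_records(subjects)
        if len(subjects) == 0:
            raise ValueError("dataset is empty")
        self.n = len(subjects)
        self.entry = np.array([s.entry_age for s in subjects])
        self.t_left = np.array([s.t_left for s in subjects])
        self.t_right = np.array([s.t_right for s in subjects])
        self.t_mid = np.array([s.t_mid for s in subjects])
        self.last = np.array([s.last_age for s in subjects])
        self.d1 = np.array([s.delta1 for s in subjects], dtype=bool)
        self.d2 = np.array([s.delta2 for s in subjects], dtype=bool)
        self.X = np.array([s.x for s in subjects])
        # clamp diagnosis intervals that straddle study entry (possible in
        # real data); the likelihood requires Tl >= L
        bad = self.d1 & (self.t_left < self.entry)
        if np.any(bad):
            warnings.warn(
                f"{int(bad.sum())} diagnosis interval(s) start before study "
                "entry; left bounds clamped to the entry age",
                stacklevel=2,
            )
            self.t_left = np.where(bad, self.entry, self.t_left)
            self.t_mid = np.where(bad, 0.5 * (self.t_left + self.t_right), self.t_mid)
        # precomputed logs and case index sets for the vectorized likelihood
        with np.errstate(divide="ignore", invalid="ignore"):
            self.log_entry = np.log(self.entry)
            self.log_last = np.log(self.last)
            self.log_tl = np.log(self.t_left)
            self.log_tr = np.log(self.t_right)
            # m1 truncation points, capped at the last observed age
            self.log_tmid_capped = np.log(np.minimum(self.t_mid, self.last))
            self.log_tr_capped = np.log(np.minimum(self.t_right, self.last))
        self.idx_case = {
            "I": np.nonzero(self.d1 & self.d2)[0],
            "II": np.nonzero(self.d1 & ~self.d2)[0],
            "III": np.nonzero(~self.d1 & self.d2)[0],
            "IV": np.nonzero(~self.d1 & ~self.d2)[0],
        }


def dataframe_to_records(df: pd.DataFrame) -> list[SubjectRecord]:
    """Convert a dataset DataFrame to SubjectRecord objects (validating)."""
    cov_cols = [
        c
        for c in df.columns
        if c
        not in ("entry_age", "t_left", "t_right", "t_mid", "last_age", "delta1", "delta2")
    ]
    records = []
    for idx, row in enumerate(df.itertuples(index=False)):
        r = row._asdict()
        try:
            records.append(
                SubjectRecord(
                    entry_age=float(r["entry_age"]),
                    t_left=float(r["t_left"]),
                    t_right=float(r["t_right"]),
                    t_mid=float(r.get("t_mid", float("nan"))),
                    last_age=float(r["last_age"]),
                    delta1=int(r["delta1"]),
                    delta2=int(r["delta2"]),
                    x=np.concatenate(([1.0], [float(r[c]) for c in cov_cols])),
                )
            )
        except ValueError as err:
            raise ValueError(f"row {idx}: {err}") from err
    return records


def log_contribution_matrix(
    data: SubjectArrays,
    params: ModelParams,
    nodes: np.ndarray,
    m1_truncation: str = "midpoint",
) -> np.ndarray:
    """Log conditional contributions for every subject at every node.

    Parameters
    ----------
    nodes
        Array of shape (q, 3): random-effect values (u_i, u_m0, u_m1).

    Returns
    -------
    (n, q) array of log contributions.
    """
    if m1_truncation not in ("midpoint", "right"):
        raise ValueError("m1_truncation must be 'midpoint' or 'right'")
    nodes = np.atleast_2d(nodes)
    n, q = data.n, nodes.shape[0]

    # per-subject linear predictors (log Weibull scales at u = 0)
    lin = [data.X @ tp.beta for tp in params.transition_params]
    kap = [tp.kappa for tp in params.transition_params]
    u = [nodes[None, :, k] for k in range(3)]

    def neg_logS(logt, idx, k):
        """(t/eta_k)^kappa_k = -log S_k(t) for subjects idx at all nodes."""
        with np.errstate(divide="ignore", invalid="ignore", over="ignore"):
            z = logt[idx, None] - lin[k][idx, None] - u[k]
            return np.exp(kap[k] * z)

    def log_f(logt, idx, k):
        with np.errstate(divide="ignore", invalid="ignore", over="ignore"):
            z = logt[idx, None] - lin[k][idx, None] - u[k]
            return np.log(kap[k]) + (kap[k] - 1.0) * z - (
                lin[k][idx, None] + u[k]
            ) - np.exp(kap[k] * z)

    def log_onset_interval(idx):
        """log[S_i(Tl) - S_i(Tr)]; -inf for numerically empty intervals."""
        a = -neg_logS(data.log_tl, idx, 0)
        b = -neg_logS(data.log_tr, idx, 0)
        diff = b - a
        with np.errstate(divide="ignore", invalid="ignore"):
            val = a + np.log1p(-np.exp(np.minimum(diff, 0.0)))
        return np.where(diff >= 0.0, -np.inf, val)

    # the m1 truncation point (interval midpoint or right bound) is capped at
    # the last observed age: a visit interval can reach past the death age,
    # and conditioning on survival beyond an observed death would make the
    # likelihood improper (unbounded in kappa_m1)
    log_tstar = (
        data.log_tmid_capped if m1_truncation == "midpoint" else data.log_tr_capped
    )

    # left-truncation correction, all cases: - log S_i(L) - log S_m0(L)
    out = neg_logS(data.log_entry, slice(None), 0)
    out += neg_logS(data.log_entry, slice(None), 1)

    with np.errstate(invalid="ignore"):  # -inf - -inf at extreme parameters
        for case, idx in data.idx_case.items():
            if idx.size == 0:
                continue
            if case in ("III", "IV"):
                c = -neg_logS(data.log_last, idx, 0)
                if case == "III":
                    c += log_f(data.log_last, idx, 1)
                else:
                    c -= neg_logS(data.log_last, idx, 1)
            else:
                c = log_onset_interval(idx)
                c -= neg_logS(data.log_tr, idx, 1)
                if case == "I":
                    c += log_f(data.log_last, idx, 2)
                else:
                    c -= neg_logS(data.log_last, idx, 2)
                c += neg_logS(log_tstar, idx, 2)
            out[idx] += np.where(np.isnan(c), -np.inf, c)
    return out


def log_contribution(
    subject: SubjectRecord,
    params: ModelParams,
    u,
    m1_truncation: str = "midpoint",
) -> float:
    """Log of one subject's conditional likelihood contribution at effect u.

    ``u`` is a 3-vector (u_i, u_m0, u_m1); for the shared-effect model pass
    the same scalar in all three positions.  Returns ``-inf`` (with a
    warning) when the onset interval carries no probability mass at the given
    parameters.
    """
    u = np.broadcast_to(np.asarray(u, dtype=float), (3,))
    data = SubjectArrays([subject])
    val = float(
        log_contribution_matrix(data, params, u[None, :], m1_truncation)[0, 0]
    )
    if val == -np.inf:
        warnings.warn("likelihood contribution underflowed to 0", stacklevel=2)
    return val


# ---------------------------------------------------------------------------
# Gauss-Hermite quadrature over the random effects
# ---------------------------------------------------------------------------


def _gh_standard(n_points: int) -> tuple[np.ndarray, np.ndarray]:
    """Nodes/weights for a standard normal N(0,1), weights summing to 1."""
    x, w = np.polynomial.hermite.hermgauss(n_points)
    return x * math.sqrt(2.0), w / math.sqrt(math.pi)


def quadrature_grid(
    re: RandomEffectSpec, n_points: int = 2
) -> tuple[np.ndarray, np.ndarray]:
    """Gauss-Hermite nodes and weights for the random-effect distribution.

    Returns ``(nodes, weights)`` with ``nodes`` of shape (q, 3) holding the
    random-effect values (u_i, u_m0, u_m1) and ``weights`` summing to 1.

    * ``none`` or a degenerate (zero-variance) normal: one node at 0;
    * ``homvar``: a 1-d grid of ``n_points`` nodes replicated across the
      three transitions;
    * ``hetvar``: a full tensor grid of ``n_points**3`` standard-normal nodes
      mapped through a symmetric square root of the covariance matrix (the
      eigen square root degrades gracefully as variances approach 0).
    """
    if n_points < 1:
        raise ValueError("n_points must be >= 1")
    if re.structure == "none":
        return np.zeros((1, 3)), np.ones(1)
    if re.structure == "homvar":
        if re.s2 == 0.0:
            return np.zeros((1, 3)), np.ones(1)
        z, w = _gh_standard(n_points)
        u = math.sqrt(re.s2) * z
        return np.repeat(u[:, None], 3, axis=1), w
    cov = re.covariance()
    if np.allclose(cov, 0.0):
        return np.zeros((1, 3)), np.ones(1)
    vals, vecs = np.linalg.eigh(cov)
    if vals[0] < -1e-10 * max(1.0, vals[-1]):
        raise ValueError("covariance matrix is not positive semi-definite")
    root = vecs @ np.diag(np.sqrt(np.clip(vals, 0.0, None))) @ vecs.T
    z, w = _gh_standard(n_points)
    Z = np.stack(np.meshgrid(z, z, z, indexing="ij"), axis=-1).reshape(-1, 3)
    W = (w[:, None, None] * w[None, :, None] * w[None, None, :]).reshape(-1)
    return Z @ root.T, W


def marginal_loglik(
    data,
    params: ModelParams,
    n_points: int = 2,
    m1_truncation: str = "midpoint",
    impossible: str = "raise",
) -> float:
    """Marginal log-likelihood: random effects integrated out by quadrature.

    ``data`` may be a list of :class:`SubjectRecord`, a dataset DataFrame, or
    a pre-built :class:`SubjectArrays`.  With ``structure="none"`` (or zero
    variance) this is exactly the no-random-effect log-likelihood.

    ``impossible`` controls the handling of subjects whose contribution is
    zero at every quadrature node: ``"raise"`` reports their indices in a
    ValueError; ``"floor"`` replaces the contribution by a large finite
    penalty (used inside the optimizer, where a hard cliff would break the
    line search).
    """
    if not isinstance(data, SubjectArrays):
        data = SubjectArrays(data)
    nodes, weights = quadrature_grid(params.re, n_points)
    logc = log_contribution_matrix(data, params, nodes, m1_truncation)
    with np.errstate(divide="ignore"):
        per_subject = logsumexp(logc + np.log(weights)[None, :], axis=1)
    bad = ~np.isfinite(per_subject)
    if np.any(bad):
        if impossible == "floor":
            per_subject = np.where(bad, -1e4, per_subject)
        else:
            raise ValueError(
                "zero likelihood contribution for subject indices "
                f"{np.nonzero(bad)[0].tolist()}"
            )
    return float(per_subject.sum())
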