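"""Synthetic semi-competing-risks data generator.

The generator emulates a prospective ageing cohort observed on the age scale:
latent disease-onset and death ages are drawn from transition-specific
Weibull AFT models linked by a trivariate normal random effect, subjects
enter the study late (uniform entry age), are right censored
(administratively, uniform censoring age), and disease onset is only
observed inside a visit interval around the true onset age.

Generation steps per cohort:

1. draw random effects (u_i, u_m0, u_m1) from N(0, Sigma_gen), where the
   generator covariance has cov(u_i, u_m0) = cov(u_m0, u_m1) = 0 and a free
   cov(u_i, u_m1);
2. draw a binary sex covariate ~ Bernoulli(p);
3. draw onset age t1 ~ Weibull(exp(x'b_i + u_i), kappa_i) and disease-free
   death age ~ Weibull(exp(x'b_m0 + u_m0), kappa_m0);
4. if t1 precedes disease-free death, replace the death age by a draw from
   the post-diagnosis distribution left-truncated at t1 (inverse cumulative
   hazard);
5. draw entry age l and censoring age c from the scenario's uniforms;
6. drop subjects whose entry age exceeds an event age (left truncation);
7. assign delta1/delta2 and, for diagnosed subjects, build the visit
   interval [t1 - U1, t1 + U2] with independent U1, U2 ~ U(0, h).

Scale calibration: the intercept of each transition is solved from a target
mean event age E via E = exp(b0) * Gamma(1 + 1/kappa) for the reference
(female) profile; the lognormal random-effect factor then lifts the marginal
mean by exp(sigma^2 / 2), about 0.4% at the default variances.
"""

from __future__ import annotations

import importlib.resources
import logging
import math
from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd
import yaml
from scipy.special import gamma as _gamma_fn

from .likelihood import ModelParams, RandomEffectSpec, SubjectRecord
from .transitions import TransitionParams

__all__ = [
    "Scenario",
    "calibrate_intercept",
    "scenario",
    "scenario_names",
    "draw_latent",
    "draw_death_after_diagnosis",
    "apply_observation",
    "generate",
]

logger = logging.getLogger(__name__)

DATASET_COLUMNS = [
    "entry_age",
    "t_left",
    "t_right",
    "t_mid",
    "last_age",
    "delta1",
    "delta2",
    "sex",
]


def calibrate_intercept(target_mean: float, kappa: float, offset: float = 0.0) -> float:
    """Intercept b0 such that exp(b0 + offset) * Gamma(1 + 1/kappa) equals the
    target mean event age for the reference covariate profile."""
    if target_mean <= 0 or kappa <= 0:
        raise ValueError("target_mean and kappa must be positive")
    return math.log(target_mean / _gamma_fn(1.0 + 1.0 / kappa)) - offset


@dataclass
class Scenario:
    """Configuration of one simulation setting.

    The shipped catalogue varies censoring (early U(85,95) vs late
    U(95,105)), the mean age at death after diagnosis (65 vs 80) and the
    initial cohort size (2400 / 1200 / 500); entry age is U(55,60), sex
    prevalence 0.4 and visit half-widths U(0,3) throughout.
    """

    name: str
    n_initial: int
    entry_bounds: tuple[float, float] = (55.0, 60.0)
    censor_bounds: tuple[float, float] = (85.0, 95.0)
    sex_prob: float = 0.4
    visit_halfwidth_bounds: tuple[float, float] = (0.0, 3.0)
    # transition truth: mean event ages for the reference (female) profile,
    # sex coefficients and Weibull shapes
    mean_onset: float = 95.0
    mean_death_healthy: float = 85.0
    mean_death_diseased: float = 65.0
    beta_sex: tuple[float, float, float] = (0.03, -0.04, -0.08)
    kappa: tuple[float, float, float] = (7.0, 10.8, 8.1)
    # generator random-effect covariance (cov(i,m0) = cov(m0,m1) = 0)
    var_i: float = 0.008237
    var_m0: float = 0.000714
    var_m1: float = 0.000063
    cov_i_m1: float = 0.000115
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_initial <= 0:
            raise ValueError("n_initial must be positive")
        if not (0.0 <= self.sex_prob <= 1.0):
            raise ValueError("sex_prob must lie in [0, 1]")
        if not all(e < c for e, c in zip(self.entry_bounds, self.censor_bounds)):
            raise ValueError("entry bounds must lie below censoring bounds")
        lo, hi = self.visit_halfwidth_bounds
        if not (0.0 <= lo <= hi):
            raise ValueError("visit half-width bounds must satisfy 0 <= lo <= hi")
        if np.linalg.eigvalsh(self.generator_covariance())[0] < -1e-12:
            raise ValueError("generator random-effect covariance is not PSD")

    def generator_covariance(self) -> np.ndarray:
        return np.array(
            [
                [self.var_i, 0.0, self.cov_i_m1],
                [0.0, self.var_m0, 0.0],
                [self.cov_i_m1, 0.0, self.var_m1],
            ]
        )

    @property
    def intercepts(self) -> tuple[float, float, float]:
        targets = (self.mean_onset, self.mean_death_healthy, self.mean_death_diseased)
        return tuple(
            calibrate_intercept(e, k) for e, k in zip(targets, self.kappa)
        )

    def true_params(self, structure: str = "none") -> ModelParams:
        """Truth as a ModelParams bundle for the requested model structure.

        The generator covariance is transition-specific, so for the hetvar
        model the true variance components carry over directly (with
        cov(m0, m1) = 0); for homvar/none models only the regression and
        shape parameters have a well-defined truth.
        """
        b0 = self.intercepts
        tps = [
            TransitionParams(np.array([b0[k], self.beta_sex[k]]), self.kappa[k], lab)
            for k, lab in enumerate(("i", "m0", "m1"))
        ]
        if structure == "hetvar":
            re = RandomEffectSpec(
                "hetvar",
                si2=self.var_i,
                sm02=self.var_m0,
                sm12=self.var_m1,
                ci_m1=self.cov_i_m1,
                cm0_m1=0.0,
            )
        elif structure == "homvar":
            re = RandomEffectSpec("homvar", s2=0.0)
        else:
            re = RandomEffectSpec("none")
        return ModelParams(*tps, re=re)


def _catalogue() -> dict[str, dict]:
    text = (
        importlib.resources.files("idmaft").joinpath("scenarios.yaml").read_text()
    )
    return yaml.safe_load(text)


def scenario_names() -> list[str]:
    return sorted(_catalogue().keys())


def scenario(name: str, **overrides) -> Scenario:
    """Look up a scenario from the shipped catalogue (e.g. ``"E65_L"``).

    Spaces and underscores in the name are interchangeable.  Keyword
    overrides replace catalogue fields (e.g. ``n_initial=500, seed=7``).
    """
    key = name.replace(" ", "_")
    cat = _catalogue()
    if key not in cat:
        raise KeyError(
            f"unknown scenario {name!r}; available: {', '.join(sorted(cat))}"
        )
    cfg = dict(cat[key])
    for bound_key in ("entry_bounds", "censor_bounds", "visit_halfwidth_bounds"):
        if bound_key in cfg:
            cfg[bound_key] = tuple(cfg[bound_key])
    cfg.update(overrides)
    return Scenario(name=key, **{k: v for k, v in cfg.items() if k != "name"})


# ---------------------------------------------------------------------------
# Generation steps
# ---------------------------------------------------------------------------


def draw_latent(n: int, scen: Scenario, rng: np.random.Generator):
    """Latent quantities before observation: random effects, sex, onset age
    and disease-free death age.

    Returns a dict of arrays ``u`` (n, 3), ``sex``, ``t1``, ``t2_healthy``.
    """
    cov = scen.generator_covariance()
    u = rng.multivariate_normal(np.zeros(3), cov, size=n, method="eigh")
    sex = rng.binomial(1, scen.sex_prob, size=n).astype(float)
    b0 = scen.intercepts
    eta_i = np.exp(b0[0] + scen.beta_sex[0] * sex + u[:, 0])
    eta_m0 = np.exp(b0[1] + scen.beta_sex[1] * sex + u[:, 1])
    t1 = eta_i * rng.weibull(scen.kappa[0], size=n)
    t2_healthy = eta_m0 * rng.weibull(scen.kappa[1], size=n)
    return {"u": u, "sex": sex, "t1": t1, "t2_healthy": t2_healthy}


def draw_death_after_diagnosis(t1, scale, kappa, rng: np.random.Generator):
    """Death age after diagnosis, left-truncated at the onset age t1.

    Inverts the truncated cumulative hazard Lambda(t) - Lambda(t1) =
    -log(1 - U):  t2 = (t1^kappa - scale^kappa * log(1 - U))^(1/kappa),
    which exceeds t1 almost surely.
    """
    t1 = np.asarray(t1, dtype=float)
    if np.any(t1 <= 0):
        raise ValueError("t1 must be positive")
    u = rng.uniform(size=t1.shape)
    return (t1**kappa - scale**kappa * np.log1p(-u)) ** (1.0 / kappa)


def apply_observation(latents: dict, scen: Scenario, rng: np.random.Generator):
    """Overlay study entry, censoring and the visit process on the latents.

    Returns ``(dataset, truth)`` DataFrames restricted to subjects retained
    after left truncation (entry age below both latent event ages).
    """
    sex, t1, t2_healthy = latents["sex"], latents["t1"], latents["t2_healthy"]
    u = latents["u"]
    n = t1.size
    b0 = scen.intercepts

    diseased = t1 < t2_healthy
    t2 = t2_healthy.copy()
    if np.any(diseased):
        eta_m1 = np.exp(b0[2] + scen.beta_sex[2] * sex[diseased] + u[diseased, 2])
        t2[diseased] = draw_death_after_diagnosis(
            t1[diseased], eta_m1, scen.kappa[2], rng
        )

    entry = rng.uniform(*scen.entry_bounds, size=n)
    censor = rng.uniform(*scen.censor_bounds, size=n)
    halfwidths = rng.uniform(*scen.visit_halfwidth_bounds, size=(n, 2))

    keep = entry < np.minimum(t1, t2)
    if not np.any(keep):
        raise ValueError(
            f"scenario {scen.name!r}: no subjects survive left truncation "
            f"(entry {scen.entry_bounds}, mean event ages "
            f"{scen.mean_onset}/{scen.mean_death_healthy})"
        )

    last = np.minimum(t2, censor)
    delta2 = (t2 < censor).astype(int)
    # diagnosed iff onset precedes both death and censoring; the visit
    # interval is then built around the true onset age (its right bound may
    # fall beyond the last observed age)
    delta1 = (diseased & (t1 < censor)).astype(int)
    t_left_vis = np.maximum(t1 - halfwidths[:, 0], entry)
    t_right_vis = t1 + halfwidths[:, 1]

    d1 = delta1 == 1
    t_left = np.where(d1, t_left_vis, last)
    t_right = np.where(d1, t_right_vis, np.inf)
    t_mid = np.where(d1, 0.5 * (t_left + t_right), np.nan)

    dataset = pd.DataFrame(
        {
            "entry_age": entry,
            "t_left": t_left,
            "t_right": t_right,
            "t_mid": t_mid,
            "last_age": last,
            "delta1": delta1,
            "delta2": delta2,
            "sex": sex.astype(int),
        }
    )[keep].reset_index(drop=True)
    truth = pd.DataFrame(
        {
            "t1": t1,
            "t2_healthy": t2_healthy,
            "t2": t2,
            "u_i": u[:, 0],
            "u_m0": u[:, 1],
            "u_m1": u[:, 2],
            "sex": sex.astype(int),
            "censor_age": censor,
        }
    )[keep].reset_index(drop=True)
    return dataset, truth


def generate(scen: Scenario, seed=None) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Generate one cohort; returns ``(dataset, truth)``.

    ``seed`` may be an int or a numpy Generator/SeedSequence; defaults to the
    scenario's own seed, so repeated calls are bit-identical.
    """
    if isinstance(seed, np.random.Generator):
        rng = seed
    else:
        rng = np.random.default_rng(scen.seed if seed is None else seed)
    latents = draw_latent(scen.n_initial, scen, rng)
    dataset, truth = apply_observation(latents, scen, rng)
    counts = (
        dataset.groupby(["delta1", "delta2"]).size().to_dict()
        if len(dataset)
        else {}
    )
    case_names = {(1, 1): "I", (1, 0): "II", (0, 1): "III", (0, 0): "IV"}
    logger.info(
        "scenario %s: %d/%d subjects retained; cases %s",
        scen.name,
        len(dataset),
        scen.n_initial,
        {case_names[k]: v for k, v in counts.items()},
    )
    return dataset, truth
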