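"""Maximum-likelihood fitting and inference for the joint model.

Estimation runs on an unconstrained parameterization: positivity- and
unit-interval-constrained quantities are mapped to the real line (log and
logit transforms) before a quasi-Newton (BFGS) search, so no constrained
optimizer is needed.  Starting values come from a sequential scheme — fit
the marginal time mixture first, then the behavior submodel holding the
posterior membership probabilities fixed — after which the full joint
likelihood is maximized from that start.

Inference is Wald-type.  The observed information is a finite-difference
Hessian of the negative log-likelihood at the optimum; confidence
intervals are formed on the unconstrained scale and back-transformed, so
they always respect the parameter constraints.  For clustered data a
Huber sandwich estimator with cluster-summed scores replaces the naive
inverse information.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from typing import Dict, List, Optional, Tuple

import numpy as np
import pandas as pd
from scipy import optimize, stats
from scipy.special import expit, logit

from . import distributions as dist
from .distributions import ComponentParams, DomainError
from .joint_model import (
    ModelSpec,
    ObservationSet,
    ParamSet,
    canonical_order,
    joint_loglik,
    loglik_contributions,
    marginal_logdensity,
    posterior_pi,
)

__all__ = [
    "FitResult",
    "pack",
    "unpack",
    "param_names",
    "param_transforms",
    "initialize_sequential",
    "fit_mle",
    "wald_ci",
    "robust_vcov",
    "lrt",
    "aic",
]

_BOUNDARY_LOGIT = 15.0  # |logit| beyond this is effectively a degenerate weight


# ---------------------------------------------------------------------------
# packing

def pack(spec: ModelSpec, params: ParamSet) -> np.ndarray:
    """Concatenate component transforms, weight coefficients and gammas."""
    parts = [dist.to_unconstrained(cp) for cp in params.components]
    parts.append(params.beta.ravel())
    parts.append(params.gamma)
    theta = np.concatenate(parts)
    if theta.shape[0] != spec.n_params:
        raise DomainError(f"packed length {theta.shape[0]} != spec.n_params {spec.n_params}")
    return theta


def unpack(spec: ModelSpec, theta: np.ndarray) -> ParamSet:
    theta = np.asarray(theta, dtype=float).ravel()
    if theta.shape[0] != spec.n_params:
        raise DomainError(f"expected {spec.n_params} packed parameters, got {theta.shape[0]}")
    comps = [
        dist.from_unconstrained(spec.family, theta[2 * k : 2 * k + 2]) for k in range(spec.m)
    ]
    off = 2 * spec.m
    nb = (spec.m - 1) * spec.n_beta_cols
    beta = theta[off : off + nb].reshape(spec.m - 1, spec.n_beta_cols)
    gamma = theta[off + nb :]
    return ParamSet(components=comps, beta=beta, gamma=gamma)


def param_names(spec: ModelSpec) -> List[str]:
    """Human-readable names in packed order.

    The intercept-only two-component model names its single weight
    coefficient ``alpha_logit`` (the logit of the first component's
    weight); richer designs use ``beta{k}_{col}``.
    """
    names: List[str] = []
    pn = dist.PARAM_NAMES[spec.family]
    for k in range(spec.m):
        names += [f"{pn[0]}{k + 1}", f"{pn[1]}{k + 1}"]
    if spec.m == 2 and spec.n_beta_cols == 1:
        names.append("alpha_logit")
    else:
        cols = (["const"] if spec.intercept else []) + [f"z{j + 1}" for j in range(spec.n_covariates)]
        for k in range(spec.m - 1):
            names += [f"beta{k + 1}_{c}" for c in cols]
    names += [f"gamma{k + 1}" for k in range(spec.m)]
    return names


def param_transforms(spec: ModelSpec) -> List[str]:
    """Back-transform per packed entry: 'log' (exp back) or 'identity'."""
    per_comp = ["identity", "log"] if spec.family == "lognormal" else ["log", "log"]
    return per_comp * spec.m + ["identity"] * ((spec.m - 1) * spec.n_beta_cols + spec.m)


def _back(values: np.ndarray, transforms: List[str]) -> np.ndarray:
    out = np.array(values, dtype=float)
    mask = np.array([t == "log" for t in transforms])
    out[mask] = np.exp(out[mask])
    return out


# ---------------------------------------------------------------------------
# fit result

@dataclass
class FitResult:
    """Estimates and inference for one maximum-likelihood fit."""

    spec: ModelSpec
    params: ParamSet
    theta: np.ndarray            # packed, canonical order
    loglik: float
    vcov_naive: np.ndarray       # unconstrained scale
    converged: bool
    n_obs: int
    grad_norm: float
    message: str = ""
    vcov_robust: Optional[np.ndarray] = None
    n_clusters: Optional[int] = None
    names: List[str] = field(default_factory=list)
    transforms: List[str] = field(default_factory=list)

    @property
    def n_params(self) -> int:
        return self.spec.n_params

    def se(self, robust: bool = False) -> np.ndarray:
        """Standard errors on the unconstrained scale."""
        V = self._vcov(robust)
        return np.sqrt(np.clip(np.diag(V), 0.0, None))

    def _vcov(self, robust: bool) -> np.ndarray:
        if robust:
            if self.vcov_robust is None:
                raise ValueError("no robust covariance computed; call robust_vcov first")
            return self.vcov_robust
        return self.vcov_naive

    def summary(self, level: float = 0.95, robust: bool = False) -> pd.DataFrame:
        """Per-parameter table on the constrained scale.

        SEs are delta-method transformed; CI endpoints are back-transformed
        from the unconstrained Wald interval so constraints always hold.
        """
        ci = wald_ci(self, level=level, robust=robust)
        est_u = self.theta
        se_u = self.se(robust)
        est_c = _back(est_u, self.transforms)
        jac = np.where([t == "log" for t in self.transforms], est_c, 1.0)
        out = pd.DataFrame(
            {
                "estimate": est_c,
                "se": jac * se_u,
                "lower": ci[:, 0],
                "upper": ci[:, 1],
                "estimate_unconstrained": est_u,
                "se_unconstrained": se_u,
            },
            index=self.names,
        )
        if self.spec.m == 2 and self.spec.n_beta_cols == 1:
            i = self.names.index("alpha_logit")
            row = pd.DataFrame(
                {
                    "estimate": [expit(est_u[i])],
                    "se": [expit(est_u[i]) * (1 - expit(est_u[i])) * se_u[i]],
                    "lower": [expit(ci[i, 0])],
                    "upper": [expit(ci[i, 1])],
                    "estimate_unconstrained": [est_u[i]],
                    "se_unconstrained": [se_u[i]],
                },
                index=["alpha"],
            )
            out = pd.concat([out, row])
        return out


# ---------------------------------------------------------------------------
# numerics

from contextlib import contextmanager


@contextmanager
def _quiet_eval():
    """Silence warnings from optimizer excursions (k<1 Weibull shapes,
    transient overflow); invalid regions surface as +inf objective values."""
    with warnings.catch_warnings(), np.errstate(all="ignore"):
        warnings.filterwarnings("ignore", message="weibull shape")
        yield


def _safe_negloglik(spec: ModelSpec, obs: ObservationSet):
    def f(theta: np.ndarray) -> float:
        try:
            with _quiet_eval():
                return -joint_loglik(spec, unpack(spec, theta), obs)
        except (DomainError, ArithmeticError, OverflowError):
            return np.inf

    return f


def _fd_gradient(f, x: np.ndarray) -> np.ndarray:
    h = 1e-6 * (1.0 + np.abs(x))
    g = np.empty_like(x)
    for i in range(x.size):
        e = np.zeros_like(x)
        e[i] = h[i]
        g[i] = (f(x + e) - f(x - e)) / (2.0 * h[i])
    return g


def _fd_hessian(f, x: np.ndarray) -> np.ndarray:
    """Central-difference Hessian with per-coordinate step 1e-5*(1+|x|)."""
    d = x.size
    h = 1e-5 * (1.0 + np.abs(x))
    H = np.empty((d, d))
    f0 = f(x)
    for i in range(d):
        ei = np.zeros(d)
        ei[i] = h[i]
        H[i, i] = (f(x + ei) - 2.0 * f0 + f(x - ei)) / h[i] ** 2
        for j in range(i + 1, d):
            ej = np.zeros(d)
            ej[j] = h[j]
            H[i, j] = H[j, i] = (
                f(x + ei + ej) - f(x + ei - ej) - f(x - ei + ej) + f(x - ei - ej)
            ) / (4.0 * h[i] * h[j])
    return 0.5 * (H + H.T)


def _invert_information(H: np.ndarray) -> np.ndarray:
    """Invert the observed information, falling back to a pseudo-inverse."""
    try:
        V = np.linalg.inv(H)
    except np.linalg.LinAlgError:
        V = np.linalg.pinv(H)
    return 0.5 * (V + V.T)


# ---------------------------------------------------------------------------
# sequential initialization

def _slice_start(family: str, y: np.ndarray) -> ComponentParams:
    """Moment-matching start for one component from one quantile slice."""
    mean = float(np.mean(y))
    sd = float(np.std(y)) or 0.1 * mean
    if family == "lognormal":
        ly = np.log(y)
        return ComponentParams("lognormal", (float(np.mean(ly)), max(float(np.var(ly)), 1e-4)))
    if family == "weibull":
        cv = min(max(sd / mean, 0.02), 1.5)
        k = float(np.clip(cv ** -1.086, 0.3, 60.0))
        lam = mean / _gamma1p(1.0 / k)
        return ComponentParams("weibull", (k, float(lam)))
    # bass: match spread through the logistic-tail scale 1/(p+q), center via the mode
    s = float(np.pi / (np.sqrt(3.0) * sd))
    s = float(np.clip(s, 1e-2, 1e3))
    center = float(np.median(y))
    ratio = float(np.exp(np.clip(s * center, -30.0, 30.0)))  # q/p from the mode formula
    p = s / (1.0 + ratio)
    q = s - p
    return ComponentParams("bass", (max(p, 1e-8), max(q, 1e-8)))


def _gamma1p(x: float) -> float:
    from scipy.special import gamma as _g

    return float(_g(1.0 + x))


def _moment_start(spec: ModelSpec, obs: ObservationSet) -> ParamSet:
    """Quantile-partition start: slice times at empirical m-quantiles."""
    y = np.sort(obs.time)
    edges = np.linspace(0, y.size, spec.m + 1).astype(int)
    comps = [_slice_start(spec.family, y[edges[k] : max(edges[k + 1], edges[k] + 2)]) for k in range(spec.m)]
    beta = np.zeros((spec.m - 1, spec.n_beta_cols))
    xbar = float(np.clip(np.mean(obs.event), 1e-3, 1 - 1e-3))
    gamma = np.full(spec.m, logit(xbar))
    return ParamSet(components=comps, beta=beta, gamma=gamma)


def initialize_sequential(spec: ModelSpec, obs: ObservationSet, options: Optional[Dict] = None) -> ParamSet:
    """Two-stage starting values for the joint fit.

    Stage 1 maximizes the marginal mixture likelihood of the times alone,
    started from quantile-partition moment matching.  Stage 2 fits the
    behavior weights gamma by Bernoulli ML with the posterior membership
    probabilities held fixed at the stage-1 values.  If stage 1 fails the
    moment-matching start itself is returned with a warning.
    """
    opts = {"gtol": 1e-6, "maxiter": 300, **(options or {})}
    start = _moment_start(spec, obs)
    if obs.n < 10 * spec.n_params:
        warnings.warn(
            f"only {obs.n} observations for {spec.n_params} parameters; "
            "estimates may be unstable",
            UserWarning,
            stacklevel=2,
        )
    n_marg = 2 * spec.m + (spec.m - 1) * spec.n_beta_cols
    theta0 = pack(spec, start)

    def neg_marginal(tm: np.ndarray) -> float:
        th = np.concatenate([tm, start.gamma])
        try:
            with _quiet_eval():
                ps = unpack(spec, th)
                val = -float(np.sum(marginal_logdensity(spec, ps, obs.time, obs.covariates)))
            return val if np.isfinite(val) else np.inf
        except (DomainError, ArithmeticError, OverflowError):
            return np.inf

    try:
        res1 = optimize.minimize(
            neg_marginal, theta0[:n_marg], method="BFGS",
            options={"gtol": opts["gtol"], "maxiter": opts["maxiter"]},
        )
        if not np.isfinite(res1.fun):
            raise ArithmeticError("marginal stage diverged")
        stage1 = unpack(spec, np.concatenate([res1.x, start.gamma]))
    except (DomainError, ArithmeticError) as err:
        warnings.warn(f"marginal-stage fit failed ({err}); using moment-matching start",
                      UserWarning, stacklevel=2)
        return start

    pi = posterior_pi(spec, stage1, obs.time, obs.covariates)
    x = obs.event

    def neg_bernoulli(g: np.ndarray) -> float:
        eta = pi @ g
        return float(np.sum(np.where(x == 1, np.logaddexp(0.0, -eta), np.logaddexp(0.0, eta))))

    res2 = optimize.minimize(neg_bernoulli, np.zeros(spec.m), method="BFGS",
                             options={"gtol": opts["gtol"], "maxiter": opts["maxiter"]})
    gamma = res2.x if np.all(np.isfinite(res2.x)) else start.gamma
    return ParamSet(components=stage1.components, beta=stage1.beta, gamma=gamma)


# ---------------------------------------------------------------------------
# the fit

def fit_mle(
    spec: ModelSpec,
    obs: ObservationSet,
    start: Optional[ParamSet] = None,
    options: Optional[Dict] = None,
) -> FitResult:
    """Joint maximum likelihood via BFGS on the unconstrained scale.

    Sequential initialization runs first unless an explicit ``start`` is
    given.  The result is reported in canonical component order; the
    observed information is a finite-difference Hessian at the canonical
    optimum.  Nonconvergence is flagged on the result, never raised.
    """
    opts = {"gtol": 1e-6, "maxiter": 500, **(options or {})}
    if start is None:
        start = initialize_sequential(spec, obs, options=options)
    theta0 = pack(spec, start)
    nll = _safe_negloglik(spec, obs)

    with warnings.catch_warnings():
        warnings.filterwarnings("ignore", message=".*line search.*")
        warnings.filterwarnings("ignore", message=".*precision loss.*")
        res = optimize.minimize(
            nll, theta0, method="BFGS",
            options={"gtol": opts["gtol"], "maxiter": opts["maxiter"]},
        )

    params_hat = canonical_order(spec, unpack(spec, res.x))
    theta_hat = pack(spec, params_hat)
    grad = _fd_gradient(nll, theta_hat)
    grad_ok = float(np.max(np.abs(grad))) < 1e-3 * (1.0 + abs(res.fun))
    converged = bool(res.success or grad_ok) and np.isfinite(res.fun)

    H = _fd_hessian(nll, theta_hat)
    V = _invert_information(H)
    if np.any(np.diag(V) < -1e-8):
        converged = False

    if np.any(np.abs(params_hat.beta) > _BOUNDARY_LOGIT):
        warnings.warn(
            "a mixture-weight coefficient is at the boundary (a component's "
            "weight is numerically 0 or 1); the mixture may be degenerate",
            UserWarning,
            stacklevel=2,
        )

    return FitResult(
        spec=spec,
        params=params_hat,
        theta=theta_hat,
        loglik=-float(res.fun),
        vcov_naive=V,
        converged=converged,
        n_obs=obs.n,
        grad_norm=float(np.max(np.abs(grad))),
        message=str(res.message),
        names=param_names(spec),
        transforms=param_transforms(spec),
    )


def wald_ci(fit: FitResult, level: float = 0.95, robust: bool = False) -> np.ndarray:
    """(d, 2) interval endpoints on the constrained scale.

    Intervals are ``estimate +/- z * SE`` on the unconstrained scale, then
    back-transformed, which keeps positive parameters positive and
    mixture weights inside the unit interval.
    """
    if not 0 < level < 1:
        raise DomainError(f"level must be in (0,1), got {level}")
    se = fit.se(robust)
    if robust is False and np.any(~np.isfinite(se)):
        raise ArithmeticError(
            "observed information is not positive definite; consider the robust "
            "covariance or refitting from new starting values"
        )
    z = stats.norm.ppf(0.5 + level / 2.0)
    lo = _back(fit.theta - z * se, fit.transforms)
    hi = _back(fit.theta + z * se, fit.transforms)
    return np.column_stack([lo, hi])


def robust_vcov(fit: FitResult, obs: ObservationSet) -> np.ndarray:
    """Cluster-robust sandwich covariance H^-1 (sum_g s_g s_g') H^-1.

    Per-observation scores are central finite differences of the
    individual log-likelihood contributions at the optimum, summed within
    clusters.  Without cluster labels every observation is its own
    cluster, which reduces the estimator to the heteroscedasticity-robust
    (Huber-White) sandwich.  The result is stored on ``fit.vcov_robust``.
    """
    labels = obs.cluster if obs.cluster is not None else np.arange(obs.n)
    _, inverse = np.unique(labels, return_inverse=True)
    G = int(inverse.max()) + 1
    if G < 2:
        raise DomainError("cluster-robust variance needs at least 2 clusters")

    spec = fit.spec

    def contribs(theta: np.ndarray) -> np.ndarray:
        with _quiet_eval():
            return loglik_contributions(spec, unpack(spec, theta), obs)

    x = fit.theta
    d = x.size
    h = 1e-5 * (1.0 + np.abs(x))
    scores = np.empty((obs.n, d))
    for j in range(d):
        e = np.zeros(d)
        e[j] = h[j]
        scores[:, j] = (contribs(x + e) - contribs(x - e)) / (2.0 * h[j])

    S = np.zeros((G, d))
    np.add.at(S, inverse, scores)
    meat = S.T @ S
    bread = fit.vcov_naive  # inverse observed information
    V = bread @ meat @ bread
    V = 0.5 * (V + V.T)
    fit.vcov_robust = V
    fit.n_clusters = G
    return V


def lrt(fit_null: FitResult, fit_alt: FitResult) -> Tuple[float, int, float]:
    """Likelihood-ratio test of nested fits: (statistic, df, p-value)."""
    df = fit_alt.n_params - fit_null.n_params
    if df < 0:
        raise DomainError("the null must not have more free parameters than the alternative")
    if fit_null.n_obs != fit_alt.n_obs:
        raise DomainError("fits compare different data (observation counts differ)")
    stat = 2.0 * (fit_alt.loglik - fit_null.loglik)
    if stat < -1e-6:
        raise ArithmeticError(
            f"alternative log-likelihood below the null by {-stat / 2:.3g}: "
            "one of the optimizations failed to reach its optimum"
        )
    stat = max(stat, 0.0)
    if df == 0:  # identical models: no evidence either way
        return stat, 0, 1.0
    return stat, df, float(stats.chi2.sf(stat, df))


def aic(fit: FitResult) -> float:
    """Akaike information criterion 2k - 2 logL."""
    return 2.0 * fit.n_params - 2.0 * fit.loglik
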