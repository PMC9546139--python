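"""Joint likelihood for mixed continuous-binary prescribing data.

The model couples two submodels for each patient i:

* a marginal finite mixture for the first-prescription time
  ``Y_i ~ sum_k alpha_ik F_k(theta_k)``, with all m components drawn from
  one family (bass / lognormal / weibull) and mixture weights following a
  multinomial-logit in covariates Z_i (the last component is the
  reference category);

* a conditional Bernoulli for the binary behavior indicator
  ``X_i | Y_i ~ Bernoulli(logit^-1(sum_k gamma_k pi_k(Y_i)))``,

where ``pi_k(Y_i) = alpha_ik f_k(Y_i) / sum_c alpha_ic f_c(Y_i)`` is the
posterior probability of component membership given the observed time.
The posterior weights are the only channel through which the continuous
and binary responses communicate: covariates enter the mixture weights
only, never the behavior weights gamma.

A mixture likelihood is invariant to permuting component labels; the
canonical ordering used throughout (ascending component mode, mean as
tie-break) pins the labels down so that estimates are comparable across
fits and replications.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import List, Optional

import numpy as np
from scipy.special import expit

from . import distributions as dist
from .distributions import ComponentParams, DomainError

__all__ = [
    "ModelSpec",
    "ParamSet",
    "ObservationSet",
    "design_matrix",
    "mixture_weights",
    "marginal_logdensity",
    "posterior_pi",
    "event_probability",
    "joint_loglik",
    "loglik_contributions",
    "canonical_order",
]


@dataclass(frozen=True)
class ModelSpec:
    """Structure of a joint model: family, component count, covariate count.

    ``n_covariates`` counts mixture-weight covariate columns beyond the
    intercept, which is always included by construction (set
    ``intercept=False`` only for fully dummy-coded designs).  The last
    component is the multinomial-logit reference category.
    """

    family: str
    m: int = 2
    n_covariates: int = 0
    intercept: bool = True

    def __post_init__(self) -> None:
        if self.family not in dist.FAMILIES:
            raise DomainError(f"unknown family {self.family!r}")
        if self.m < 2:
            raise DomainError(f"a mixture needs m >= 2 components, got m={self.m}")
        if self.n_covariates < 0:
            raise DomainError("n_covariates must be >= 0")
        if not self.intercept and self.n_covariates == 0:
            raise DomainError("a model without intercept needs at least one covariate")

    @property
    def n_beta_cols(self) -> int:
        return int(self.intercept) + self.n_covariates

    @property
    def n_params(self) -> int:
        """Free parameters: 2 per component + (m-1) weight rows + m gammas."""
        return 2 * self.m + (self.m - 1) * self.n_beta_cols + self.m


@dataclass(frozen=True)
class ParamSet:
    """Full parameterization: component params, weight coefficients, gammas.

    ``beta`` has one row per non-reference component (m-1 rows) and one
    column per design column; for the intercept-only two-component model
    it is the scalar logit of the first component's weight alpha.
    ``gamma`` holds the m behavior weights on the logit scale.
    """

    components: List[ComponentParams]
    beta: np.ndarray
    gamma: np.ndarray

    def __post_init__(self) -> None:
        object.__setattr__(self, "beta", np.atleast_2d(np.asarray(self.beta, dtype=float)))
        object.__setattr__(self, "gamma", np.asarray(self.gamma, dtype=float).ravel())
        m = len(self.components)
        if self.gamma.shape != (m,):
            raise DomainError(f"gamma must have length m={m}, got {self.gamma.shape}")
        if self.beta.shape[0] != m - 1:
            raise DomainError(f"beta needs {m - 1} rows (reference = last component), got {self.beta.shape[0]}")
        fams = {cp.family for cp in self.components}
        if len(fams) != 1:
            raise DomainError(f"all components must share one family, got {sorted(fams)}")

    @property
    def m(self) -> int:
        return len(self.components)


@dataclass
class ObservationSet:
    """Per-patient data: positive times, binary events, optional Z and clusters."""

    time: np.ndarray
    event: np.ndarray
    covariates: Optional[np.ndarray] = None
    cluster: Optional[np.ndarray] = None
    patient_id: Optional[np.ndarray] = field(default=None, repr=False)

    def __post_init__(self) -> None:
        self.time = np.asarray(self.time, dtype=float).ravel()
        self.event = np.asarray(self.event).ravel()
        if np.any(self.time <= 0) or not np.all(np.isfinite(self.time)):
            bad = np.flatnonzero((self.time <= 0) | ~np.isfinite(self.time))
            raise DomainError(f"times must be finite and > 0; offending rows {bad[:10].tolist()}")
        if not np.isin(self.event, (0, 1)).all():
            raise DomainError("event indicator must be 0/1")
        self.event = self.event.astype(int)
        if self.event.shape != self.time.shape:
            raise DomainError("time and event must have equal length")
        if self.covariates is not None:
            self.covariates = np.atleast_2d(np.asarray(self.covariates, dtype=float))
            if self.covariates.shape[0] != self.time.shape[0]:
                raise DomainError("covariate rows must align with times")
            if not np.all(np.isfinite(self.covariates)):
                raise DomainError("covariates must be finite")
        if self.cluster is not None:
            self.cluster = np.asarray(self.cluster).ravel()
            if self.cluster.shape != self.time.shape:
                raise DomainError("cluster labels must align with times")

    @property
    def n(self) -> int:
        return self.time.shape[0]

    def subset(self, idx) -> "ObservationSet":
        return ObservationSet(
            time=self.time[idx],
            event=self.event[idx],
            covariates=None if self.covariates is None else self.covariates[idx],
            cluster=None if self.cluster is None else self.cluster[idx],
            patient_id=None if self.patient_id is None else self.patient_id[idx],
        )


def _lse_rows(a: np.ndarray) -> np.ndarray:
    """Row-wise log-sum-exp by max shift (hot path; avoids scipy overhead)."""
    mx = np.max(a, axis=1, keepdims=True)
    mx_safe = np.where(np.isfinite(mx), mx, 0.0)
    return mx_safe[:, 0] + np.log(np.sum(np.exp(a - mx_safe), axis=1))


def design_matrix(spec: ModelSpec, covariates: Optional[np.ndarray], n: Optional[int] = None) -> np.ndarray:
    """Build the (n, n_beta_cols) mixture-weight design, prepending the intercept."""
    if covariates is None or np.size(covariates) == 0:
        if spec.n_covariates:
            raise DomainError(f"spec expects {spec.n_covariates} covariates but none were supplied")
        if n is None:
            raise DomainError("need n to build an intercept-only design")
        return np.ones((n, 1))
    Z = np.atleast_2d(np.asarray(covariates, dtype=float))
    if Z.shape[1] != spec.n_covariates:
        raise DomainError(f"expected {spec.n_covariates} covariate columns, got {Z.shape[1]}")
    if spec.intercept:
        Z = np.column_stack([np.ones(Z.shape[0]), Z])
    return Z


def mixture_weights(spec: ModelSpec, params: ParamSet, covariates=None, n: Optional[int] = None) -> np.ndarray:
    """Per-individual component probabilities alpha_ik, rows summing to 1.

    Multinomial-logit: alpha_ik proportional to exp(Z_i beta_k') for k < m
    and to 1 for the reference (last) component.
    """
    if (covariates is None or np.size(covariates) == 0) and spec.n_covariates == 0:
        # intercept-only: one weight vector shared by all rows
        if n is None:
            raise DomainError("need n to build an intercept-only design")
        logits = np.append(params.beta[:, 0], 0.0)
        logits -= logits.max()
        w = np.exp(logits)
        return np.broadcast_to(w / w.sum(), (n, spec.m))
    Z = design_matrix(spec, covariates, n=n)
    eta = Z @ params.beta.T  # (n, m-1)
    logits = np.column_stack([eta, np.zeros(Z.shape[0])])
    logits -= _lse_rows(logits)[:, None]
    return np.exp(logits)


def _component_logpdfs(params: ParamSet, y: np.ndarray) -> np.ndarray:
    """(n, m) matrix of log f_k(y_i)."""
    return np.column_stack([dist.logpdf(cp, y) for cp in params.components])


def marginal_logdensity(spec: ModelSpec, params: ParamSet, y, covariates=None) -> np.ndarray:
    """log of the mixture density sum_k alpha_ik f_k(y_i), via log-sum-exp."""
    y = np.asarray(y, dtype=float).ravel()
    alpha = mixture_weights(spec, params, covariates, n=y.shape[0])
    logf = _component_logpdfs(params, y)
    with np.errstate(divide="ignore"):
        return _lse_rows(logf + np.log(alpha))


def posterior_pi(spec: ModelSpec, params: ParamSet, y, covariates=None) -> np.ndarray:
    """Posterior membership probabilities pi_k(Y_i); rows sum to 1."""
    y = np.asarray(y, dtype=float).ravel()
    alpha = mixture_weights(spec, params, covariates, n=y.shape[0])
    logf = _component_logpdfs(params, y)
    with np.errstate(divide="ignore"):
        logw = logf + np.log(alpha)
    norm = _lse_rows(logw)[:, None]
    if np.any(~np.isfinite(norm)):
        bad = np.flatnonzero(~np.isfinite(norm.ravel()))
        raise ArithmeticError(
            f"all component densities vanish at observations {bad[:10].tolist()}; "
            "posterior membership is undefined there"
        )
    return np.exp(logw - norm)


def event_probability(spec: ModelSpec, params: ParamSet, y, covariates=None) -> np.ndarray:
    """P(X=1 | Y): inverse-logit of the gamma-weighted posterior probabilities."""
    pi = posterior_pi(spec, params, y, covariates)
    return expit(pi @ params.gamma)


def loglik_contributions(spec: ModelSpec, params: ParamSet, obs: ObservationSet) -> np.ndarray:
    """Per-patient log-likelihood: marginal log-density of Y plus Bernoulli
    log-mass of X|Y, sharing one evaluation of the component densities."""
    alpha = mixture_weights(spec, params, obs.covariates, n=obs.n)
    logf = _component_logpdfs(params, obs.time)
    with np.errstate(divide="ignore"):
        logw = logf + np.log(alpha)
    ll_y = _lse_rows(logw)
    pi = np.exp(logw - ll_y[:, None])
    eta = pi @ params.gamma
    # Bernoulli log-mass via logaddexp for stability at extreme eta
    ll_x = np.where(obs.event == 1, -np.logaddexp(0.0, -eta), -np.logaddexp(0.0, eta))
    return ll_y + ll_x


def joint_loglik(spec: ModelSpec, params: ParamSet, obs: ObservationSet) -> float:
    """Sum over patients of marginal log-density of Y plus Bernoulli log-mass of X|Y."""
    terms = loglik_contributions(spec, params, obs)
    total = float(np.sum(terms))
    if not np.isfinite(total):
        bad = np.flatnonzero(~np.isfinite(terms))
        raise ArithmeticError(f"non-finite log-likelihood contribution at rows {bad[:10].tolist()}")
    return total


def _sort_key(cp: ComponentParams) -> tuple:
    return (dist.mode(cp), dist.moments(cp)[0])


def canonical_order(spec: ModelSpec, params: ParamSet) -> ParamSet:
    """Re-label components by ascending mode (mean breaks ties).

    The multinomial-logit coefficients are re-expressed against the new
    reference component and gamma is permuted alongside, leaving the
    likelihood unchanged.
    """
    order = sorted(range(params.m), key=lambda k: _sort_key(params.components[k]))
    if order == list(range(params.m)):
        return params
    full_beta = np.vstack([params.beta, np.zeros((1, params.beta.shape[1]))])
    permuted = full_beta[order]
    new_beta = permuted[:-1] - permuted[-1]
    return ParamSet(
        components=[params.components[k] for k in order],
        beta=new_beta,
        gamma=params.gamma[order],
    )
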