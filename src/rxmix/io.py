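"""Claims-table ingestion, validation and synthetic cohort fixtures.

The expected input is a CSV with one row per patient: a unique
``patient_id``, a positive first-prescription time (years since the
drug's marketing date by default), a 0/1 behavior indicator, optional
covariate columns (categorical columns are expanded to dummies) and an
optional cluster identifier (e.g. prescriber).  Times equal to zero are
outside the model's support and rejected at load time rather than
nudged.

``make_fixture`` writes synthetic cohorts whose statistical shape —
adoption waves, behavior rates, payer mix, prescriber clusters — mimics
real claims cohorts; the generating truth is stored in a JSON sidecar so
round-trip recovery can be checked.
"""

from __future__ import annotations

import json
from pathlib import Path
from typing import Dict, List, Optional, Sequence

import numpy as np
import pandas as pd
from scipy.special import expit

from . import distributions as dist
from .distributions import ComponentParams, DomainError
from .joint_model import ModelSpec, ObservationSet, ParamSet, mixture_weights, posterior_pi
from .simulation import SimConfig, generate_clustered, study_truth

__all__ = ["ValidationError", "read_claims", "make_fixture", "FIXTURE_SCENARIOS"]

_TIME_FACTORS = {"years": 1.0, "months": 1.0 / 12.0, "days": 1.0 / 365.25}


class ValidationError(ValueError):
    """Raised when a claims table violates the input contract."""


def read_claims(
    path,
    time_col: str = "time_years",
    event_col: str = "event",
    covariate_cols: Optional[Sequence[str]] = None,
    categorical_cols: Optional[Sequence[str]] = None,
    cluster_col: Optional[str] = None,
    id_col: str = "patient_id",
    time_unit: str = "years",
    drop_last_level: bool = True,
) -> ObservationSet:
    """Load and validate a claims CSV into an :class:`ObservationSet`.

    Categorical covariates are expanded to one-hot dummy columns; with
    ``drop_last_level`` (the default, appropriate when the mixture-weight
    design carries an intercept) the last level is the reference and its
    dummy is omitted.  ``time_unit`` rescales the time column to years on
    load; this affects only the scale of the time parameters, not the fit.
    """
    if time_unit not in _TIME_FACTORS:
        raise ValidationError(f"unknown time unit {time_unit!r}; use years/months/days")
    df = pd.read_csv(path)
    needed = [c for c in (id_col, time_col, event_col) if c not in df.columns]
    needed += [c for c in (covariate_cols or []) if c not in df.columns]
    needed += [c for c in (categorical_cols or []) if c not in df.columns]
    if cluster_col and cluster_col not in df.columns:
        needed.append(cluster_col)
    if needed:
        raise ValidationError(f"missing required columns: {needed}")

    problems: List[str] = []
    dup = df[id_col][df[id_col].duplicated()]
    if len(dup):
        problems.append(f"duplicate patient_id values: {dup.unique()[:5].tolist()}")
    t = pd.to_numeric(df[time_col], errors="coerce") * _TIME_FACTORS[time_unit]
    bad_t = df.index[~np.isfinite(t) | (t <= 0)]
    if len(bad_t):
        problems.append(
            f"rows {bad_t[:10].tolist()} have non-positive or non-numeric {time_col} "
            "(the support is strictly positive: a time of 0 is not admissible)"
        )
    ev = pd.to_numeric(df[event_col], errors="coerce")
    bad_e = df.index[~ev.isin([0, 1])]
    if len(bad_e):
        problems.append(f"rows {bad_e[:10].tolist()} have non-binary {event_col}")

    cols: List[np.ndarray] = []
    for c in covariate_cols or []:
        v = pd.to_numeric(df[c], errors="coerce")
        bad = df.index[~np.isfinite(v)]
        if len(bad):
            problems.append(f"rows {bad[:10].tolist()} have non-finite covariate {c}")
        cols.append(v.to_numpy(dtype=float))
    for c in categorical_cols or []:
        dummies = pd.get_dummies(df[c].astype(str), prefix=c)
        if drop_last_level and dummies.shape[1] > 1:
            dummies = dummies.iloc[:, :-1]
        cols.extend(dummies.to_numpy(dtype=float).T)

    if problems:
        raise ValidationError("claims table rejected:\n  " + "\n  ".join(problems))

    Z = np.column_stack(cols) if cols else None
    return ObservationSet(
        time=t.to_numpy(dtype=float),
        event=ev.to_numpy(dtype=int),
        covariates=Z,
        cluster=df[cluster_col].to_numpy() if cluster_col else None,
        patient_id=df[id_col].to_numpy(),
    )


# ---------------------------------------------------------------------------
# synthetic fixtures

# A three-wave cohort (synthetic; emulates a drug prescribed in three
# adoption waves around 0.8, 2 and 3 years, each with modest spread).
_THREE_WAVE = dict(
    components=[(-0.25, 0.08), (0.69, 0.02), (1.10, 0.01)],  # lognormal (mu, sigma2)
    beta=[[-0.3], [0.4]],
    gamma=[1.5, 0.4, 2.2],
)

_PAYER_LEVELS = ("medicare", "medicaid", "commercial")
_PAYER_PROBS = (0.275, 0.269, 0.456)
# payer effect on the logit of the early-wave weight (dummy-coded, last level reference)
_PAYER_EFFECTS = (0.6, 0.3)

FIXTURE_SCENARIOS = ("two_wave", "three_wave", "clustered", "covariate")


def _truth_to_dict(spec: ModelSpec, params: ParamSet) -> Dict:
    return {
        "family": spec.family,
        "m": spec.m,
        "components": [list(cp.params) for cp in params.components],
        "beta": params.beta.tolist(),
        "gamma": params.gamma.tolist(),
    }


def make_fixture(scenario: str, seed: int, path, family: str = "lognormal", n: Optional[int] = None) -> pd.DataFrame:
    """Write a synthetic claims CSV (plus a ``.truth.json`` sidecar) and return it.

    Scenarios: ``two_wave`` (n=305) and ``three_wave`` (n=1202) mirror the
    scale of small and large single-drug cohorts; ``clustered`` adds
    prescriber clusters of 10 with strong within-cluster dependence;
    ``covariate`` adds a 3-level payer column that shifts the early-wave
    weight.  All randomness flows from ``seed``.
    """
    if scenario not in FIXTURE_SCENARIOS:
        raise DomainError(f"unknown scenario {scenario!r}; choose from {FIXTURE_SCENARIOS}")
    rng = np.random.default_rng(seed)
    path = Path(path)
    cluster = None
    payer = None

    if scenario == "two_wave":
        n = n or 305
        spec, truth = study_truth(family)
        alpha = mixture_weights(spec, truth, None, n=1)[0]
        c = rng.choice(spec.m, size=n, p=alpha)
        y = np.empty(n)
        for k in range(spec.m):
            idx = c == k
            y[idx] = dist.sample(truth.components[k], int(idx.sum()), rng)
        x = _bern_events(spec, truth, y, None, rng)
    elif scenario == "three_wave":
        n = n or 1202
        spec = ModelSpec(family="lognormal", m=3)
        truth = ParamSet(
            components=[ComponentParams("lognormal", tuple(p)) for p in _THREE_WAVE["components"]],
            beta=np.array(_THREE_WAVE["beta"]),
            gamma=np.array(_THREE_WAVE["gamma"]),
        )
        alpha = mixture_weights(spec, truth, None, n=1)[0]
        c = rng.choice(spec.m, size=n, p=alpha)
        y = np.empty(n)
        for k in range(spec.m):
            idx = c == k
            y[idx] = dist.sample(truth.components[k], int(idx.sum()), rng)
        x = _bern_events(spec, truth, y, None, rng)
    elif scenario == "clustered":
        n = n or 300
        spec, truth = study_truth(family)
        cfg = SimConfig(spec=spec, truth=truth, n=n, design="clustered",
                        cluster_size=10, rho=0.9, seed=seed)
        obs = generate_clustered(cfg, rng)
        y, x = obs.time, obs.event
        cluster = np.array([f"prescriber_{g:03d}" for g in obs.cluster])
    else:  # covariate: payer mix shifting the early-wave weight
        n = n or 305
        spec = ModelSpec(family=family, m=2, n_covariates=2)
        base_spec, base_truth = study_truth(family)
        truth = ParamSet(
            components=base_truth.components,
            beta=np.array([[-0.5, *_PAYER_EFFECTS]]),
            gamma=base_truth.gamma,
        )
        payer = rng.choice(len(_PAYER_LEVELS), size=n, p=_PAYER_PROBS)
        Z = np.column_stack([(payer == j).astype(float) for j in range(2)])  # last level = reference
        alpha = mixture_weights(spec, truth, Z)
        u = rng.uniform(size=n)
        c = (u[:, None] > np.cumsum(alpha, axis=1)).sum(axis=1)
        y = np.empty(n)
        for k in range(spec.m):
            idx = c == k
            y[idx] = dist.sample(truth.components[k], int(idx.sum()), rng)
        x = _bern_events(spec, truth, y, Z, rng)

    df = pd.DataFrame(
        {
            "patient_id": [f"pt_{i:05d}" for i in range(n)],
            "time_years": np.round(y, 6),
            "event": x,
        }
    )
    if payer is not None:
        df["payer"] = [_PAYER_LEVELS[j] for j in payer]
    if cluster is not None:
        df["cluster_id"] = cluster
    path.parent.mkdir(parents=True, exist_ok=True)
    df.to_csv(path, index=False)
    sidecar = {"scenario": scenario, "seed": seed, "n": int(n), "truth": _truth_to_dict(spec, truth)}
    Path(str(path) + ".truth.json").write_text(json.dumps(sidecar, indent=2))
    return df


def _bern_events(spec, truth, y, Z, rng) -> np.ndarray:
    p = expit(posterior_pi(spec, truth, y, Z) @ truth.gamma)
    return (rng.uniform(size=y.size) < p).astype(int)
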