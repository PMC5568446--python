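"""Per-subject likelihoods and parameter estimation (MLE and MAP).

The likelihood replays the delta-rule value updates over a subject's
recorded choice/outcome sequence and scores each observed choice under the
softmax rule.  MLE minimises the negative log-likelihood within parameter
bounds; MAP additionally includes the fitting priors (gamma(1.2, scale 5)
on the softmax scaling, beta(1.1, 1.1) on every free learning rate) and is
the estimator used for learning-rate analyses, since it keeps estimates off
the boundary.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import optimize, stats

from .models import ModelSpec, ParameterSet, free_values, resolve_parameters

__all__ = [
    "FitResult",
    "FitOptions",
    "negative_log_likelihood",
    "log_posterior",
    "bic",
    "fit_mle",
    "fit_map",
    "fit_per_condition",
    "replay_choice_probabilities",
]

BETA_MAX = 100.0  # practical optimisation cap for the softmax scaling
PI_BOUND = 10.0

_GAMMA_SHAPE, _GAMMA_SCALE = 1.2, 5.0
_BETA_A, _BETA_B = 1.1, 1.1


class DataError(ValueError):
    """Raised for malformed trial-level datasets."""


@dataclass(frozen=True)
class FitOptions:
    """Optimiser settings: number of random restarts, RNG seed, objective
    tolerance."""

    n_restarts: int = 10
    seed: int = 0
    tol: float = 1e-7


@dataclass(frozen=True)
class FitResult:
    model: str
    params: ParameterSet
    free: dict
    nll: float
    lpp: float | None
    bic: float
    n_trials: int
    df: int
    n_restarts: int
    converged: bool
    objective: str = "mle"

    def to_row(self) -> dict:
        row = {
            "model": self.model,
            "objective": self.objective,
            "nll": self.nll,
            "lpp": self.lpp,
            "bic": self.bic,
            "n_trials": self.n_trials,
            "df": self.df,
            "converged": self.converged,
        }
        row.update({f"free_{k}": v for k, v in self.free.items()})
        row.update(self.params.as_dict())
        return row


def _dataset_arrays(data: pd.DataFrame):
    """Validate column presence and extract replay arrays in trial order."""
    required = {"session", "context_instance", "context_trial", "choice",
                "outcome_chosen", "outcome_unchosen"}
    missing = required - set(data.columns)
    if missing:
        raise DataError(f"dataset missing columns {sorted(missing)}")
    if len(data) == 0:
        raise DataError("empty dataset")
    choices = data["choice"].to_numpy(dtype=np.int64)
    if not np.isin(choices, (0, 1)).all():
        raise DataError("choice must be 0 or 1")
    r_c = data["outcome_chosen"].to_numpy(dtype=float)
    r_u = data["outcome_unchosen"].to_numpy(dtype=float)
    sessions = data["session"].to_numpy()
    instances = data["context_instance"].to_numpy()
    # contexts as dense integer codes for dict-free state access
    keys = pd.MultiIndex.from_arrays([sessions, instances])
    codes = keys.factorize()[0]
    return codes, choices, r_c, r_u


def replay_choice_probabilities(
    data: pd.DataFrame, params: ParameterSet, has_perseveration: bool = False
) -> np.ndarray:
    """Replay value updates over the dataset and return, per trial, the
    model's probability of choosing option 0 (before seeing that trial's
    choice).  The single source of truth for likelihoods and model-estimate
    curves.
    """
    codes, choices, r_c, r_u = _dataset_arrays(data)
    n_ctx = codes.max() + 1
    q = np.zeros((n_ctx, 2))
    last = np.full(n_ctx, -1, dtype=np.int64)
    acp, acm = params.alpha_c_plus, params.alpha_c_minus
    aup, aum = params.alpha_u_plus, params.alpha_u_minus
    beta, pi = params.beta, params.pi
    p0 = np.empty(len(choices))
    for t in range(len(choices)):
        k = codes[t]
        qa, qb = q[k, 0], q[k, 1]
        x = beta * (qa - qb)
        if has_perseveration and last[k] >= 0:
            x += beta * (pi if last[k] == 0 else -pi)
        if x >= 0:
            p0[t] = 1.0 / (1.0 + math.exp(-x))
        else:
            ex = math.exp(x)
            p0[t] = ex / (1.0 + ex)
        c = choices[t]
        pe = r_c[t] - q[k, c]
        q[k, c] += (acp if pe > 0 else acm) * pe
        ru = r_u[t]
        if not math.isnan(ru):
            pe_u = ru - q[k, 1 - c]
            q[k, 1 - c] += (aup if pe_u > 0 else aum) * pe_u
        last[k] = c
    return p0


def negative_log_likelihood(
    data: pd.DataFrame, model: ModelSpec, params: ParameterSet
) -> float:
    """Summed -log softmax probability of each observed choice under the
    replayed value trajectory.  Counterfactual updates run on every trial
    whose forgone outcome is present (complete feedback); otherwise only the
    factual update runs."""
    p0 = replay_choice_probabilities(data, params, model.has_perseveration)
    choices = data["choice"].to_numpy(dtype=np.int64)
    p_chosen = np.where(choices == 0, p0, 1.0 - p0)
    with np.errstate(divide="ignore"):
        return float(-np.sum(np.log(np.clip(p_chosen, 1e-300, None))))


def log_prior(model: ModelSpec, free: np.ndarray) -> float:
    """Log prior density of a free-parameter vector: gamma(1.2, scale 5) on
    beta, beta(1.1, 1.1) on each free learning rate, flat on pi."""
    lp = 0.0
    for name, value in zip(model.free_names, free):
        if name == "beta":
            lp += stats.gamma.logpdf(value, a=_GAMMA_SHAPE, scale=_GAMMA_SCALE)
        elif name == "pi":
            continue
        else:
            lp += stats.beta.logpdf(value, _BETA_A, _BETA_B)
    return float(lp)


def log_posterior(data: pd.DataFrame, model: ModelSpec, params: ParameterSet) -> float:
    """Log joint: log-likelihood plus log prior of the model's free
    parameters (the MAP objective)."""
    free = np.asarray(free_values(model, params), dtype=float)
    return -negative_log_likelihood(data, model, params) + log_prior(model, free)


def bic(nll: float, n_trials: int, df: int) -> float:
    """log(n_trials) * df + 2 * nll (natural log)."""
    if n_trials < 1:
        raise ValueError("n_trials must be >= 1")
    if df < 0:
        raise ValueError("df must be >= 0")
    return math.log(n_trials) * df + 2.0 * nll


def _bounds(model: ModelSpec, objective: str) -> list[tuple[float, float]]:
    eps = 1e-4 if objective == "map" else 0.0
    bounds = []
    for name in model.free_names:
        if name == "beta":
            bounds.append((1e-6, BETA_MAX))
        elif name == "pi":
            bounds.append((-PI_BOUND, PI_BOUND))
        else:
            bounds.append((eps, 1.0 - eps))
    return bounds


def _starts(model: ModelSpec, n: int, rng: np.random.Generator) -> list[np.ndarray]:
    """One fixed mid-range start plus n-1 random interior starts."""
    fixed = []
    for name in model.free_names:
        fixed.append(3.0 if name == "beta" else 0.0 if name == "pi" else 0.5)
    starts = [np.array(fixed)]
    for _ in range(n - 1):
        pt = []
        for name in model.free_names:
            if name == "beta":
                pt.append(math.exp(rng.uniform(math.log(0.1), math.log(30.0))))
            elif name == "pi":
                pt.append(rng.uniform(-2.0, 2.0))
            else:
                pt.append(rng.uniform(0.05, 0.95))
        starts.append(np.array(pt))
    return starts


def _fit(data: pd.DataFrame, model: ModelSpec, options: FitOptions, objective: str) -> FitResult:
    codes_check = _dataset_arrays(data)  # validate once up front
    del codes_check
    n_trials = len(data)
    rng = np.random.default_rng(options.seed)
    bounds = _bounds(model, objective)

    def fun(x: np.ndarray) -> float:
        params = resolve_parameters(model, x)
        nll = negative_log_likelihood(data, model, params)
        if objective == "map":
            return nll - log_prior(model, x)
        return nll

    best = None
    any_converged = False
    for x0 in _starts(model, options.n_restarts, rng):
        res = optimize.minimize(
            fun, x0, method="L-BFGS-B", bounds=bounds, options={"ftol": options.tol}
        )
        any_converged = any_converged or bool(res.success)
        if best is None or res.fun < best.fun:
            best = res
    x = np.clip(best.x, [b[0] for b in bounds], [b[1] for b in bounds])
    params = resolve_parameters(model, x)
    nll = negative_log_likelihood(data, model, params)
    lpp = log_posterior(data, model, params) if objective == "map" else None
    return FitResult(
        model=model.name,
        params=params,
        free=dict(zip(model.free_names, (float(v) for v in x))),
        nll=nll,
        lpp=lpp,
        bic=bic(nll, n_trials, model.df),
        n_trials=n_trials,
        df=model.df,
        n_restarts=options.n_restarts,
        converged=any_converged,
        objective=objective,
    )


def fit_mle(data: pd.DataFrame, model: ModelSpec, options: FitOptions | None = None) -> FitResult:
    """Bounded maximum-likelihood fit with multi-restart; feeds BIC-based
    model comparison."""
    return _fit(data, model, options or FitOptions(), "mle")


def fit_map(data: pd.DataFrame, model: ModelSpec, options: FitOptions | None = None) -> FitResult:
    """Maximum a posteriori fit under the fitting priors; feeds learning-rate
    analyses."""
    return _fit(data, model, options or FitOptions(), "map")


def fit_per_condition(
    data: pd.DataFrame,
    model: ModelSpec,
    options: FitOptions | None = None,
    objective: str = "map",
) -> dict[str, FitResult]:
    """Fit each task condition (context label) independently; the two
    Asymmetric context instances are pooled under one label."""
    if "context_label" not in data.columns:
        raise DataError("dataset missing column 'context_label'")
    fits: dict[str, FitResult] = {}
    fitter = fit_map if objective == "map" else fit_mle
    for label, subset in data.groupby("context_label", sort=True):
        if len(subset) == 0:
            raise DataError(f"empty condition partition {label!r}")
        fits[str(label)] = fitter(subset.reset_index(drop=True), model, options)
    if not fits:
        raise DataError("no conditions found in dataset")
    return fits


def fits_to_frame(fits: dict | list) -> pd.DataFrame:
    """Serialise FitResults (keyed by subject or listed) to a tidy frame."""
    if isinstance(fits, dict):
        rows = [{"subject": k, **v.to_row()} for k, v in fits.items()]
    else:
        rows = [f.to_row() for f in fits]
    return pd.DataFrame(rows)
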