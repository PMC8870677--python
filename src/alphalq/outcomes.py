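"""Arm-level logistic dose-response models for survival and toxicity.

Each study arm contributes a grouped-binomial observation: ``events`` of
``n`` patients experiencing the endpoint (two-year overall survival, or
grade >= 2 neutropenia), at the arm's combined dose EQD2_TOT. Two model
variants are fitted by maximum likelihood:

``fixed``
    the ordinary grouped-binomial logistic GLM,
    ``events_i ~ Binomial(n_i, expit(b0 + b1 * dose_i))``. Weighting by
    arm size is exact here: the binomial likelihood of grouped counts
    equals the Bernoulli likelihood of the arm expanded to n_i patients.

``random_intercept``
    the binomial-normal mixed model,
    ``logit p_i = b0 + b1 * dose_i + u_g(i)``, ``u_g ~ N(0, tau^2)``,
    integrated out by adaptive Gauss-Hermite quadrature. By default every
    arm is its own group, which makes ``tau`` an arm-level residual
    heterogeneity (overdispersion) term — the standard mixed-effects
    logistic meta-regression for arm-level proportions. A coarser grouping
    (e.g. per study) can be supplied.

Inference is Wald: standard errors from the inverse observed information
of the fixed effects (variance parameter held at its estimate, the usual
mixed-model convention), z = beta/SE, two-sided normal p-values.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
import statsmodels.api as sm
from scipy import optimize, special, stats

__all__ = [
    "OutcomeDataset",
    "LogisticFit",
    "NonConvergedFitError",
    "fit_logistic",
    "predict",
    "compare_schedule_effect",
]

_GH_NODES = 25


class NonConvergedFitError(RuntimeError):
    """Prediction or comparison requested from a fit flagged non-converged."""


@dataclass(frozen=True)
class OutcomeDataset:
    """Arm-level grouped-binomial outcome data at assigned doses."""

    study_ids: tuple[str, ...]
    doses: tuple[float, ...]
    events: tuple[int, ...]
    n: tuple[int, ...]
    endpoint: str = "os_2y"

    def __post_init__(self) -> None:
        k = len(self.doses)
        if not (len(self.study_ids) == len(self.events) == len(self.n) == k):
            raise ValueError("dataset columns have mismatched lengths")
        for e, m in zip(self.events, self.n):
            if m <= 0 or not 0 <= e <= m:
                raise ValueError(f"invalid counts: {e} events of {m}")

    @classmethod
    def from_arms(cls, arms, summaries, endpoint: str) -> "OutcomeDataset":
        """Join study arms with a dose table; arms lacking the outcome drop out.

        Doses are taken from the (report-rounded) dose summaries, matched by
        (study_id, activity) — published fits were run on the printed tables.
        """
        dose_by_key = {(s.study_id, s.activity_per_kg): s.rounded().eqd2_tot for s in summaries}
        ids, doses, events, n = [], [], [], []
        for arm in arms:
            e = arm.os_2y_events if endpoint == "os_2y" else arm.tox_events
            if e is None:
                continue
            ids.append(arm.study_id)
            doses.append(dose_by_key[(arm.study_id, arm.activity_per_kg)])
            events.append(e)
            n.append(arm.n_patients)
        return cls(tuple(ids), tuple(doses), tuple(events), tuple(n), endpoint)

    def __len__(self) -> int:
        return len(self.doses)


@dataclass(frozen=True)
class LogisticFit:
    """A fitted two-parameter logistic dose-response model."""

    intercept: float
    slope: float
    se_intercept: float
    se_slope: float
    z_intercept: float
    z_slope: float
    p_intercept: float
    p_slope: float
    covariance: tuple[tuple[float, float], tuple[float, float]]
    variant: str
    converged: bool
    endpoint: str = ""
    tau: float | None = None  # random-intercept SD (mixed variant only)
    loglik: float | None = None
    diagnostics: str = ""

    def as_dict(self) -> dict:
        return {
            "endpoint": self.endpoint,
            "variant": self.variant,
            "converged": self.converged,
            "intercept": self.intercept,
            "slope": self.slope,
            "se_intercept": self.se_intercept,
            "se_slope": self.se_slope,
            "z_intercept": self.z_intercept,
            "z_slope": self.z_slope,
            "p_intercept": self.p_intercept,
            "p_slope": self.p_slope,
            "covariance": [list(r) for r in self.covariance],
            "tau": self.tau,
            "loglik": self.loglik,
            "diagnostics": self.diagnostics,
        }


def _wald(beta: np.ndarray, cov: np.ndarray) -> dict:
    se = np.sqrt(np.diag(cov))
    with np.errstate(divide="ignore", invalid="ignore"):
        z = beta / se
    p = 2.0 * stats.norm.sf(np.abs(z))
    return {"se": se, "z": z, "p": p}


def _check_degenerate(events: np.ndarray, n: np.ndarray, doses: np.ndarray) -> str:
    """Return a diagnostics string for data that cannot identify the model."""
    if events.sum() == 0:
        return "all arms have zero events; intercept diverges to -inf"
    if (events == n).all():
        return "all arms have all events; intercept diverges to +inf"
    # complete separation: an ordering of doses splits 0%-arms from 100%-arms
    props = events / n
    order = np.argsort(doses)
    po = props[order]
    boundary = np.flatnonzero(np.diff((po > 0).astype(int)) != 0)
    if ((po == 0) | (po == 1)).all() and len(boundary) <= 1:
        return "complete separation between zero- and full-event arms"
    return ""


def _fit_fixed(data: OutcomeDataset) -> LogisticFit:
    events = np.asarray(data.events, float)
    n = np.asarray(data.n, float)
    doses = np.asarray(data.doses, float)
    diag = _check_degenerate(events, n, doses)
    X = np.column_stack([np.ones_like(doses), doses])
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        res = sm.GLM(
            np.column_stack([events, n - events]), X, family=sm.families.Binomial()
        ).fit(maxiter=200)
    beta = np.asarray(res.params)
    cov = np.asarray(res.cov_params())
    converged = bool(res.converged and np.isfinite(cov).all() and not diag)
    if np.abs(beta[0]) > 30:
        converged = False
        diag = diag or "intercept escaped to the boundary (quasi-separation)"
    w = _wald(beta, cov)
    return LogisticFit(
        intercept=float(beta[0]), slope=float(beta[1]),
        se_intercept=float(w["se"][0]), se_slope=float(w["se"][1]),
        z_intercept=float(w["z"][0]), z_slope=float(w["z"][1]),
        p_intercept=float(w["p"][0]), p_slope=float(w["p"][1]),
        covariance=tuple(map(tuple, cov)), variant="fixed",
        converged=converged, endpoint=data.endpoint,
        loglik=float(res.llf), diagnostics=diag,
    )


# ---------------------------------------------------------------------------
# binomial-normal mixed model via adaptive Gauss-Hermite quadrature


def _group_loglik(x, n, logc, eta, tau, z_q, log_w):
    """Marginal log-likelihood of one group: log int prod_i Binom * N(0,1) du.

    The conditional mode is found by damped Newton with analytic
    derivatives, then the integrand is re-centred and scaled (adaptive GH).
    """

    def logf(u):
        le = eta + tau * u
        return float(
            np.sum(logc + x * special.log_expit(le) + (n - x) * special.log_expit(-le))
            - 0.5 * u * u - 0.5 * np.log(2.0 * np.pi)
        )

    u = 0.0
    for _ in range(100):
        p = special.expit(eta + tau * u)
        g1 = tau * np.sum(x - n * p) - u
        g2 = -(tau * tau) * np.sum(n * p * (1.0 - p)) - 1.0
        step = -g1 / g2
        u += np.clip(step, -4.0, 4.0)
        if abs(step) < 1e-12:
            break
    p = special.expit(eta + tau * u)
    s = 1.0 / np.sqrt((tau * tau) * np.sum(n * p * (1.0 - p)) + 1.0)
    pts = u + np.sqrt(2.0) * s * z_q
    vals = np.array([logf(t) for t in pts])
    return special.logsumexp(vals + z_q**2 + log_w + 0.5 * np.log(2.0) + np.log(s))


def _glmm_nll(params, x, n, logc, X, group_index, z_q, log_w):
    beta, ltau = params[:-1], params[-1]
    tau = float(np.exp(ltau))
    eta = X @ beta
    total = 0.0
    for idx in group_index:
        total += _group_loglik(x[idx], n[idx], logc[idx], eta[idx], tau, z_q, log_w)
    return -total


def _fit_random_intercept(data: OutcomeDataset, groups: Sequence | None) -> LogisticFit:
    x = np.asarray(data.events, float)
    n = np.asarray(data.n, float)
    doses = np.asarray(data.doses, float)
    diag = _check_degenerate(x, n, doses)
    X = np.column_stack([np.ones_like(doses), doses])
    logc = special.gammaln(n + 1) - special.gammaln(x + 1) - special.gammaln(n - x + 1)
    if groups is None:
        group_index = [np.array([i]) for i in range(len(x))]
    else:
        labels = np.asarray(groups)
        group_index = [np.flatnonzero(labels == g) for g in pd.unique(labels)]
    z_q, w_q = np.polynomial.hermite.hermgauss(_GH_NODES)
    log_w = np.log(w_q)
    args = (x, n, logc, X, group_index, z_q, log_w)

    start = _fit_fixed(data)
    best = None
    for tau0 in (0.2, 0.6, 1.5):
        p0 = np.array([start.intercept, start.slope, np.log(tau0)])
        if not np.isfinite(p0).all():
            p0 = np.array([0.0, 0.0, np.log(tau0)])
        res = optimize.minimize(
            _glmm_nll, p0, args=args, method="Nelder-Mead",
            options=dict(xatol=1e-9, fatol=1e-11, maxiter=20000, maxfev=20000),
        )
        if best is None or res.fun < best.fun:
            best = res
    beta = best.x[:2]
    tau = float(np.exp(best.x[2]))

    # Wald covariance of the fixed effects: beta block of the inverse of the
    # full observed information over (b0, b1, log tau), central differences.
    # Falls back to the fixed-tau 2x2 information if tau sits on the boundary
    # and makes the full matrix singular.
    def _hessian(idx: list[int]) -> np.ndarray:
        h_all = np.array([1e-4 * max(1.0, abs(best.x[0])), 2e-5, 1e-4])
        k = len(idx)
        H = np.empty((k, k))
        for a, i in enumerate(idx):
            for b, j in enumerate(idx):
                ei = np.zeros(3); ei[i] = h_all[i]
                ej = np.zeros(3); ej[j] = h_all[j]
                H[a, b] = (
                    _glmm_nll(best.x + ei + ej, *args)
                    - _glmm_nll(best.x + ei - ej, *args)
                    - _glmm_nll(best.x - ei + ej, *args)
                    + _glmm_nll(best.x - ei - ej, *args)
                ) / (4.0 * h_all[i] * h_all[j])
        return 0.5 * (H + H.T)

    cov = np.full((2, 2), np.nan)
    cov_ok = False
    for idx in ([0, 1, 2], [0, 1]):
        try:
            full = np.linalg.inv(_hessian(idx))
        except np.linalg.LinAlgError:
            continue
        cand = full[:2, :2]
        if np.isfinite(cand).all() and (np.diag(cand) > 0).all():
            cov, cov_ok = cand, True
            break
    converged = bool(best.success and cov_ok and not diag and abs(beta[0]) < 30)
    w = _wald(beta, cov)
    return LogisticFit(
        intercept=float(beta[0]), slope=float(beta[1]),
        se_intercept=float(w["se"][0]), se_slope=float(w["se"][1]),
        z_intercept=float(w["z"][0]), z_slope=float(w["z"][1]),
        p_intercept=float(w["p"][0]), p_slope=float(w["p"][1]),
        covariance=tuple(map(tuple, cov)), variant="random_intercept",
        converged=converged, endpoint=data.endpoint,
        tau=tau, loglik=float(-best.fun), diagnostics=diag,
    )


def fit_logistic(
    data: OutcomeDataset,
    variant: str = "fixed",
    groups: Sequence | None = None,
) -> LogisticFit:
    """Fit the dose-response model; see module docstring for the variants.

    ``groups`` (random_intercept only) assigns rows to random-effect
    groups; the default gives every arm its own group.
    """
    if len(data) < 3:
        raise ValueError(f"need at least 3 arms, got {len(data)}")
    if len(set(data.doses)) < 2:
        raise ValueError("need at least two distinct dose values")
    if variant == "fixed":
        return _fit_fixed(data)
    if variant == "random_intercept":
        return _fit_random_intercept(data, groups)
    raise ValueError(f"unknown variant {variant!r}")


def predict(fit: LogisticFit, eqd2_grid: Sequence[float]) -> pd.DataFrame:
    """Dose-response curve with pointwise 95% confidence band.

    The band is the delta-method normal interval on the linear predictor,
    transformed through the inverse logit (so it always lies in (0, 1) and
    contains the point estimate).
    """
    if not fit.converged:
        raise NonConvergedFitError(
            f"fit is flagged non-converged ({fit.diagnostics or 'no diagnostics'}); "
            "predictions would not be meaningful"
        )
    grid = np.asarray(eqd2_grid, float)
    cov = np.asarray(fit.covariance)
    eta = fit.intercept + fit.slope * grid
    var_eta = cov[0, 0] + 2.0 * grid * cov[0, 1] + grid**2 * cov[1, 1]
    half = 1.959963984540054 * np.sqrt(var_eta)
    return pd.DataFrame(
        {
            "eqd2_tot_gy": grid,
            "probability": special.expit(eta),
            "lower95": special.expit(eta - half),
            "upper95": special.expit(eta + half),
        }
    )


def compare_schedule_effect(fits: Mapping[str, LogisticFit]) -> pd.DataFrame:
    """Tabulate slope inference across EBRT-schedule scenarios.

    All fits must address the same endpoint; the table reports each
    scenario's slope, SE, z and p so schedule sensitivity can be judged.
    Interpretation is left to the reader.
    """
    if len(fits) < 2:
        raise ValueError("need fits for at least 2 scenarios to compare")
    endpoints = {f.endpoint for f in fits.values()}
    if len(endpoints) != 1:
        raise ValueError(f"fits address different endpoints: {sorted(endpoints)}")
    rows = []
    for label, f in fits.items():
        rows.append(
            {
                "scenario": label,
                "endpoint": f.endpoint,
                "variant": f.variant,
                "intercept": f.intercept,
                "slope": f.slope,
                "se_slope": f.se_slope,
                "z_slope": f.z_slope,
                "p_slope": f.p_slope,
                "converged": f.converged,
            }
        )
    return pd.DataFrame(rows)
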