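"""Weighted Cox proportional-hazards estimation with delayed entry.

This module provides the estimation machinery shared by the recurrence and
death models: a weighted Cox partial likelihood with left truncation
(delayed entry), Breslow handling of ties, the Breslow estimator of the
baseline cumulative hazard, interval survival prediction, and a robust
(sandwich) covariance built from per-subject weighted score residuals.

Conventions
-----------
* Risk intervals are half-open ``(entry, exit]``: a subject is in the risk
  set of an event at time ``t`` iff ``entry < t <= exit``.  An event falling
  exactly at a subject's own entry time therefore excludes that subject.
* The hazard for covariates ``z`` is ``lambda_0(t) * exp(beta @ z)``.
* Weights are sampling weights: the estimating equations are weighted
  per-subject, and the robust covariance ``I^-1 (sum_i U_i U_i^T) I^-1``
  accounts for the within-subject correlation the weights induce.

Rows that share identical ``(entry, exit, event, x)`` are aggregated (their
weights summed) before optimisation, so a fit with an integer weight ``w``
is bit-identical in the coefficients to a fit on ``w`` duplicated records.
Score residuals for the sandwich are always computed on the original rows:
distinct subjects with coincidentally identical data must contribute
separate residuals.
"""
from __future__ import annotations

import dataclasses
import json
import logging
from dataclasses import dataclass
from typing import Sequence

import numpy as np

logger = logging.getLogger(__name__)

#: coefficient magnitude past which the likelihood is treated as monotone
MONOTONE_BOUND = 20.0

_Z975 = 1.959963984540054


@dataclass
class CoxFit:
    """Result of a (possibly weighted) Cox proportional-hazards fit."""

    coefficients: np.ndarray
    covariance_model: np.ndarray
    covariance_robust: np.ndarray | None
    baseline_times: np.ndarray
    baseline_cumhaz: np.ndarray
    n_subjects: int
    n_events: int
    converged: bool
    log_partial_likelihood: float
    covariate_names: tuple[str, ...] | None = None
    diagnostics: str = ""

    @property
    def se_model(self) -> np.ndarray:
        return np.sqrt(np.diag(self.covariance_model))

    @property
    def se_robust(self) -> np.ndarray | None:
        if self.covariance_robust is None:
            return None
        return np.sqrt(np.diag(self.covariance_robust))

    def standard_errors(self, robust: bool = False) -> np.ndarray:
        if robust:
            if self.covariance_robust is None:
                raise ValueError("no robust covariance attached to this fit")
            return self.se_robust
        return self.se_model

    def hazard_ratios(self) -> np.ndarray:
        return np.exp(self.coefficients)

    def confidence_intervals(self, robust: bool = False) -> tuple[np.ndarray, np.ndarray]:
        """95% hazard-ratio confidence bounds (lower, upper)."""
        se = self.standard_errors(robust=robust)
        lo = np.exp(self.coefficients - _Z975 * se)
        hi = np.exp(self.coefficients + _Z975 * se)
        return lo, hi

    def cumulative_hazard_at(self, t) -> np.ndarray:
        """Breslow baseline cumulative hazard H0(t), a right-continuous step
        function with H0(0) = 0 and zero increment outside the observed
        event-time support."""
        t = np.asarray(t, dtype=float)
        cum = np.concatenate([[0.0], self.baseline_cumhaz])
        idx = np.searchsorted(self.baseline_times, t, side="right")
        return cum[idx]

    def to_dict(self) -> dict:
        return {
            "coefficients": self.coefficients.tolist(),
            "covariance_model": self.covariance_model.tolist(),
            "covariance_robust": (
                None if self.covariance_robust is None else self.covariance_robust.tolist()
            ),
            "baseline": [
                [float(t), float(h)]
                for t, h in zip(self.baseline_times, self.baseline_cumhaz)
            ],
            "n_subjects": int(self.n_subjects),
            "n_events": int(self.n_events),
            "converged": bool(self.converged),
            "log_partial_likelihood": float(self.log_partial_likelihood),
            "covariate_names": (
                None if self.covariate_names is None else list(self.covariate_names)
            ),
            "diagnostics": self.diagnostics,
        }

    def to_json(self, path) -> None:
        with open(path, "w") as fh:
            json.dump(self.to_dict(), fh, indent=2)

    @classmethod
    def from_dict(cls, d: dict) -> "CoxFit":
        baseline = np.asarray(d["baseline"], dtype=float).reshape(-1, 2)
        return cls(
            coefficients=np.asarray(d["coefficients"], dtype=float),
            covariance_model=np.asarray(d["covariance_model"], dtype=float),
            covariance_robust=(
                None
                if d.get("covariance_robust") is None
                else np.asarray(d["covariance_robust"], dtype=float)
            ),
            baseline_times=baseline[:, 0],
            baseline_cumhaz=baseline[:, 1],
            n_subjects=int(d["n_subjects"]),
            n_events=int(d["n_events"]),
            converged=bool(d["converged"]),
            log_partial_likelihood=float(d["log_partial_likelihood"]),
            covariate_names=(
                None
                if d.get("covariate_names") is None
                else tuple(d["covariate_names"])
            ),
            diagnostics=d.get("diagnostics", ""),
        )

    @classmethod
    def from_json(cls, path) -> "CoxFit":
        with open(path) as fh:
            return cls.from_dict(json.load(fh))

    def replace(self, **changes) -> "CoxFit":
        return dataclasses.replace(self, **changes)


def _as_arrays(entry, exit_, event, X, weights):
    entry = np.asarray(entry, dtype=float).ravel()
    exit_ = np.asarray(exit_, dtype=float).ravel()
    event = np.asarray(event).ravel().astype(bool)
    X = np.asarray(X, dtype=float)
    if X.ndim == 1:
        X = X[:, None]
    n = entry.size
    if not (exit_.size == n and event.size == n and X.shape[0] == n):
        raise ValueError("entry, exit, event and X must have matching lengths")
    if np.any(~np.isfinite(entry)) or np.any(~np.isfinite(exit_)):
        raise ValueError("non-finite interval bounds")
    if np.any(entry >= exit_):
        raise ValueError("risk intervals require entry < exit")
    if weights is None:
        w = np.ones(n)
    else:
        w = np.asarray(weights, dtype=float).ravel()
        if w.size != n:
            raise ValueError("weights length mismatch")
        if np.any(~(w > 0)):
            raise ValueError("non-positive weight")
    return entry, exit_, event, X, w


def _aggregate(entry, exit_, event, X, w):
    """Merge rows identical in (entry, exit, event, x), summing weights."""
    key = np.column_stack([entry, exit_, event.astype(float), X])
    uniq, inverse = np.unique(key, axis=0, return_inverse=True)
    wa = np.bincount(inverse.ravel(), weights=w)
    return uniq[:, 0], uniq[:, 1], uniq[:, 2] > 0.5, uniq[:, 3:], wa


def _suffix_sum(v):
    c = np.cumsum(v[::-1], axis=0)[::-1]
    pad = np.zeros((1,) + v.shape[1:])
    return np.concatenate([c, pad], axis=0)


def _pl_quantities(entry, exit_, event, X, w, beta, need_hessian=True):
    """Log partial likelihood, score, information and risk-set summaries.

    Returns ``(loglik, score, info, event_times, d, S0, xbar)`` where for
    each distinct event time ``d`` is the weighted event count, ``S0`` the
    weighted risk-set sum of exp(eta) and ``xbar`` the risk-set weighted
    covariate mean.  Risk sets respect the (entry, exit] convention via
    suffix sums over exit- and entry-sorted rows (every row with
    entry >= t also has exit > t, so the difference is exactly the sum
    over {entry < t <= exit}).
    """
    n, p = X.shape
    eta = X @ beta if p else np.zeros(n)
    r = w * np.exp(eta)
    ev_t = exit_[event]
    et = np.unique(ev_t)
    order_ev = np.argsort(ev_t, kind="mergesort")
    starts = np.searchsorted(ev_t[order_ev], et, side="left")
    d = np.add.reduceat(w[event][order_ev], starts)

    def risk_sums(sort_key):
        o = np.argsort(sort_key, kind="mergesort")
        idx = np.searchsorted(sort_key[o], et, side="left")
        ro, Xo = r[o], X[o]
        s0 = _suffix_sum(ro)[idx]
        s1 = _suffix_sum(ro[:, None] * Xo)[idx] if p else np.zeros((et.size, 0))
        s2 = None
        if need_hessian and p:
            s2 = _suffix_sum(ro[:, None, None] * (Xo[:, :, None] * Xo[:, None, :]))[idx]
        return s0, s1, s2

    a0, a1, a2 = risk_sums(exit_)
    b0, b1, b2 = risk_sums(entry)
    S0 = a0 - b0
    if np.any(S0 <= 0):
        raise ValueError("empty risk set at an event time (corrupted input)")
    S1 = a1 - b1
    loglik = float(np.sum(w[event] * eta[event]) - np.sum(d * np.log(S0)))
    if p == 0:
        return loglik, np.zeros(0), np.zeros((0, 0)), et, d, S0, S1
    xbar = S1 / S0[:, None]
    score = w[event] @ X[event] - d @ xbar
    info = None
    if need_hessian:
        S2 = a2 - b2
        info = np.einsum("k,kij->ij", d / S0, S2) - (xbar * d[:, None]).T @ xbar
    return loglik, score, info, et, d, S0, xbar


def _score_residuals(entry, exit_, event, X, w, beta, et, d, S0, xbar):
    """Per-row weighted score residuals (Breslow ties).

    U_i = w_i [ delta_i (x_i - xbar(t_i))
                - exp(eta_i) * (x_i dG0_i - dG1_i) ]
    where dG0_i, dG1_i accumulate d_k/S0_k and (d_k/S0_k) xbar_k over event
    times in (entry_i, exit_i].  They sum to the total score, hence to ~0 at
    the maximum.
    """
    n, p = X.shape
    inc = d / S0
    G0 = np.concatenate([[0.0], np.cumsum(inc)])
    G1 = np.vstack([np.zeros(p), np.cumsum(inc[:, None] * xbar, axis=0)])
    i_exit = np.searchsorted(et, exit_, side="right")
    i_entry = np.searchsorted(et, entry, side="right")
    dG0 = G0[i_exit] - G0[i_entry]
    dG1 = G1[i_exit] - G1[i_entry]
    expeta = np.exp(X @ beta)
    U = -expeta[:, None] * (X * dG0[:, None] - dG1)
    k = np.searchsorted(et, exit_[event])
    U[event] += X[event] - xbar[k]
    return w[:, None] * U


def fit_cox(
    entry,
    exit_,
    event,
    X,
    weights=None,
    *,
    covariate_names: Sequence[str] | None = None,
    tol: float = 1e-9,
    coef_tol: float = 1e-8,
    max_iter: int = 50,
    max_step_halvings: int = 10,
) -> CoxFit:
    """Fit a weighted Cox model on left-truncated ``(entry, exit]`` data.

    Newton-Raphson with step-halving; convergence when the relative change
    in the log partial likelihood drops below ``tol`` or the max-norm
    coefficient update below ``coef_tol``.  Coefficients drifting past
    ``MONOTONE_BOUND`` flag a monotone likelihood and stop the iteration
    with ``converged=False`` and a diagnostic message.
    """
    entry, exit_, event, X, w = _as_arrays(entry, exit_, event, X, weights)
    n, p = X.shape
    if p == 0:
        raise ValueError("at least one covariate is required")
    if not event.any():
        raise ValueError("no events")
    if np.any(np.ptp(X, axis=0) == 0):
        raise ValueError("constant covariate (zero variance)")

    # aggregate identical rows so integer-weight and duplicated-record
    # representations are numerically indistinguishable to the optimizer
    ae, ax, av, aX, aw = _aggregate(entry, exit_, event, X, w)
    mu = aw @ aX / aw.sum()
    aXc = aX - mu

    beta = np.zeros(p)
    loglik, score, info, et, d, S0, xbar = _pl_quantities(ae, ax, av, aXc, aw, beta)
    converged = False
    diagnostics = ""
    for _ in range(max_iter):
        try:
            delta = np.linalg.solve(info, score)
        except np.linalg.LinAlgError as exc:
            raise ValueError("singular information matrix") from exc
        step = 1.0
        for _ in range(max_step_halvings + 1):
            cand = beta + step * delta
            new = _pl_quantities(ae, ax, av, aXc, aw, cand)
            if new[0] >= loglik - 1e-12:
                break
            step *= 0.5
        change = np.max(np.abs(cand - beta))
        prev_loglik = loglik
        beta = cand
        loglik, score, info, et, d, S0, xbar = new
        if np.max(np.abs(beta)) > MONOTONE_BOUND:
            diagnostics = (
                "monotone likelihood suspected: a coefficient exceeded "
                f"{MONOTONE_BOUND} in absolute value"
            )
            logger.warning(diagnostics)
            break
        if abs(loglik - prev_loglik) <= tol * (abs(prev_loglik) + tol) or change < coef_tol:
            converged = True
            break
    else:
        diagnostics = f"did not converge within {max_iter} iterations"
        logger.warning(diagnostics)

    try:
        cov_model = np.linalg.inv(info)
    except np.linalg.LinAlgError:
        cov_model = np.linalg.pinv(info)
    cov_model = 0.5 * (cov_model + cov_model.T)

    # Breslow baseline: increments from the centred fit, rescaled to x = 0
    increments = (d / S0) * np.exp(-beta @ mu)
    baseline_cumhaz = np.cumsum(increments)

    # sandwich from per-original-row residuals (centred consistently)
    U = _score_residuals(entry, exit_, event, X - mu, w, beta, et, d, S0, xbar)
    cov_robust = cov_model @ (U.T @ U) @ cov_model
    cov_robust = 0.5 * (cov_robust + cov_robust.T)

    return CoxFit(
        coefficients=beta,
        covariance_model=cov_model,
        covariance_robust=cov_robust,
        baseline_times=et,
        baseline_cumhaz=baseline_cumhaz,
        n_subjects=n,
        n_events=int(event.sum()),
        converged=converged,
        log_partial_likelihood=loglik,
        covariate_names=None if covariate_names is None else tuple(covariate_names),
        diagnostics=diagnostics,
    )


def breslow_baseline(beta, entry, exit_, event, X=None, weights=None):
    """Breslow baseline cumulative hazard at a fixed coefficient vector.

    Returns ``(event_times, cumulative_hazard)``.  With ``beta = 0`` this is
    the (weighted) Nelson-Aalen estimator on left-truncated data.
    """
    beta = np.atleast_1d(np.asarray(beta, dtype=float))
    if X is None:
        X = np.zeros((np.asarray(entry).size, beta.size))
    entry, exit_, event, X, w = _as_arrays(entry, exit_, event, X, weights)
    if not event.any():
        raise ValueError("no events")
    if not np.all(np.isfinite(beta)):
        raise ValueError("beta must be finite")
    _, _, _, et, d, S0, _ = _pl_quantities(entry, exit_, event, X, w, beta, need_hessian=False)
    return et, np.cumsum(d / S0)


def predict_interval_survival(fit: CoxFit, z, t_start, t_end):
    """Survival probability over ``(t_start, t_end]`` for covariates ``z``.

    ``s = exp(-(H0(t_end) - H0(t_start)) * exp(beta @ z))`` with the Breslow
    baseline; times outside the event-time support contribute no hazard.
    Accepts a single covariate vector or a matrix of rows with matching
    time arrays.
    """
    z = np.asarray(z, dtype=float)
    t_start = np.asarray(t_start, dtype=float)
    t_end = np.asarray(t_end, dtype=float)
    if np.any(t_start > t_end):
        raise ValueError("t_start must not exceed t_end")
    dH = fit.cumulative_hazard_at(t_end) - fit.cumulative_hazard_at(t_start)
    risk = np.exp(z @ fit.coefficients)
    s = np.exp(-dH * risk)
    if s.ndim == 0:
        return float(s)
    return s


def robust_variance(fit: CoxFit, entry, exit_, event, X, weights=None) -> np.ndarray:
    """Sandwich covariance ``I^-1 (sum_i U_i U_i^T) I^-1`` at the fitted
    coefficients, with per-subject (one row per subject) weighted score
    residuals ``U_i``."""
    if not fit.converged:
        raise ValueError("robust variance requires a converged fit")
    entry, exit_, event, X, w = _as_arrays(entry, exit_, event, X, weights)
    mu = w @ X / w.sum()
    Xc = X - mu
    beta = fit.coefficients
    _, _, info, et, d, S0, xbar = _pl_quantities(entry, exit_, event, Xc, w, beta)
    try:
        A = np.linalg.inv(info)
    except np.linalg.LinAlgError as exc:
        raise ValueError("singular information matrix") from exc
    U = _score_residuals(entry, exit_, event, Xc, w, beta, et, d, S0, xbar)
    V = A @ (U.T @ U) @ A
    return 0.5 * (V + V.T)
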