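"""Recurrence fits, fixed-effect meta-analysis and weight-uncertainty
Monte-Carlo sensitivity analysis.

The recurrence model is a Cox model with delay since the first VT as the
time scale.  In the prospective design it has delayed entry at inclusion
and uses only post-inclusion follow-up (Cases 1-2); in the ambispective
design every at-risk period starts at the first VT and pre-inclusion
recurrences (Case 4) and pre-inclusion survival (Case 3) contribute.
When a :class:`~ambicox.weighting.WeightSet` is supplied, coefficients are
estimated from the weighted partial likelihood and the robust sandwich
variance accounts for the weights.
"""
from __future__ import annotations

import logging
from dataclasses import dataclass
from typing import Sequence

import numpy as np
import pandas as pd
from scipy import stats

from .cohort import (
    ABO_NON_REFERENCE,
    AMBISPECTIVE,
    DESIGNS,
    SubjectRecord,
    make_intervals,
)
from .cox import CoxFit, breslow_baseline, fit_cox
from .weighting import WeightSet, _death_arrays, compute_weights

logger = logging.getLogger(__name__)

_Z975 = 1.959963984540054

#: default adjustment set: additive ABO coding (O1 reference), sex,
#: provoked first VT, age at first VT per 10 years, DVT (vs PE) and the
#: first four principal components
DEFAULT_RECURRENCE_COVARIATES = (
    "A1", "A2", "B", "O2",
    "sex", "provoked", "age10", "dvt",
    "pc1", "pc2", "pc3", "pc4",
)


def _covariate_value(r: SubjectRecord, name: str) -> float:
    if name in ABO_NON_REFERENCE:
        return float(r.abo_dosages[name])
    if name == "sex":
        return float(r.sex)
    if name == "provoked":
        return float(r.provoked_first_vt)
    if name == "age10":
        return r.age_first_vt / 10.0
    if name == "age_first_vt":
        return float(r.age_first_vt)
    if name == "dvt":
        return float(r.dvt_first_vt)
    if name.startswith("pc") and name[2:] in "1234":
        return float(r.pcs[int(name[2:]) - 1])
    raise KeyError(f"unknown covariate {name!r}")


def covariate_matrix(
    records: Sequence[SubjectRecord], covariates: Sequence[str]
) -> np.ndarray:
    return np.array(
        [[_covariate_value(r, c) for c in covariates] for r in records], dtype=float
    )


def fit_recurrence(
    records: Sequence[SubjectRecord],
    design: str,
    weights: WeightSet | None = None,
    covariates: Sequence[str] | None = None,
    **fit_kwargs,
) -> CoxFit:
    """Cox model for first VT recurrence under either design.

    Records lacking a resolved ABO coding are excluded (with a logged
    count) when ABO covariates are requested.  Weights, when given, are
    looked up by subject id.
    """
    if design not in DESIGNS:
        raise ValueError(f"design must be one of {DESIGNS}")
    covariates = tuple(covariates) if covariates is not None else DEFAULT_RECURRENCE_COVARIATES
    needs_abo = any(c in ABO_NON_REFERENCE for c in covariates)
    usable = [r for r in records if not needs_abo or r.abo_dosages is not None]
    n_no_abo = len(list(records)) - len(usable)
    if n_no_abo:
        logger.info(
            "recurrence fit: excluded %d subjects without resolved ABO diplotype",
            n_no_abo,
        )
    contributing, intervals = [], []
    for r in usable:
        iv = make_intervals(r, design)
        if iv is not None:
            contributing.append(r)
            intervals.append(iv)
    if not intervals:
        raise ValueError(f"no subjects contribute to the {design} design")
    entry = np.array([iv.entry for iv in intervals])
    exit_ = np.array([iv.exit for iv in intervals])
    event = np.array([iv.event for iv in intervals], dtype=bool)
    X = covariate_matrix(contributing, covariates)
    w = None
    if weights is not None:
        w = weights.for_ids([r.subject_id for r in contributing])
    return fit_cox(entry, exit_, event, X, w, covariate_names=covariates, **fit_kwargs)


# ---------------------------------------------------------------------------
# Fixed-effect meta-analysis

@dataclass
class MetaResult:
    """Inverse-variance fixed-effect combination of study hazard ratios."""

    study_log_hr: np.ndarray
    study_se: np.ndarray
    log_hr: float
    se: float
    z: float
    p: float
    labels: tuple[str, ...] | None = None

    @property
    def hr(self) -> float:
        return float(np.exp(self.log_hr))

    @property
    def ci(self) -> tuple[float, float]:
        return (
            float(np.exp(self.log_hr - _Z975 * self.se)),
            float(np.exp(self.log_hr + _Z975 * self.se)),
        )

    def as_dict(self) -> dict:
        lo, hi = self.ci
        return {
            "hr": self.hr,
            "ci_low": lo,
            "ci_high": hi,
            "log_hr": self.log_hr,
            "se": self.se,
            "z": self.z,
            "p": self.p,
        }


def meta_fixed(
    studies: Sequence[tuple[float, float, float]],
    labels: Sequence[str] | None = None,
) -> MetaResult:
    """Fixed-effect meta-analysis of study-level hazard ratios.

    Each study supplies ``(hr, ci_low, ci_high)``; the log-scale standard
    error is recovered from the 95% interval width, studies are combined
    with inverse-variance weights on the log scale, and the p-value comes
    from the standard normal.
    """
    if not studies:
        raise ValueError("at least one study is required")
    hr = np.array([s[0] for s in studies], dtype=float)
    lo = np.array([s[1] for s in studies], dtype=float)
    hi = np.array([s[2] for s in studies], dtype=float)
    if np.any(lo <= 0):
        raise ValueError("confidence bounds must be positive")
    if np.any((hr < lo) | (hr > hi)):
        raise ValueError("HR must lie within its confidence interval")
    if np.any(lo >= hi):
        raise ValueError("degenerate confidence interval (ci_low >= ci_high)")
    log_hr = np.log(hr)
    se = (np.log(hi) - np.log(lo)) / (2.0 * _Z975)
    w = 1.0 / se**2
    combined = float(np.sum(w * log_hr) / np.sum(w))
    combined_se = float(1.0 / np.sqrt(np.sum(w)))
    z = combined / combined_se
    p = 2.0 * float(stats.norm.sf(abs(z)))
    return MetaResult(
        study_log_hr=log_hr,
        study_se=se,
        log_hr=combined,
        se=combined_se,
        z=z,
        p=p,
        labels=None if labels is None else tuple(labels),
    )


# ---------------------------------------------------------------------------
# Monte-Carlo sensitivity to weight uncertainty

@dataclass
class SensitivitySummary:
    """Distribution of recurrence coefficients across weight-perturbation
    replicates."""

    n_replicates: int
    seed: int
    covariate_names: tuple[str, ...]
    estimates: np.ndarray  # (B, p) replicate log-HRs
    mean: np.ndarray
    sd: np.ndarray
    q025: np.ndarray
    q975: np.ndarray

    def as_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            {
                "covariate": self.covariate_names,
                "mean": self.mean,
                "sd": self.sd,
                "q025": self.q025,
                "q975": self.q975,
            }
        )


def _psd_factor(cov: np.ndarray) -> np.ndarray:
    """Square-root factor of a symmetric matrix, projecting small negative
    eigenvalues to zero (with a warning) so degenerate covariances can
    still be sampled."""
    vals, vecs = np.linalg.eigh(0.5 * (cov + cov.T))
    if vals.min() < -1e-10 * max(1.0, vals.max()):
        logger.warning(
            "death-model covariance not positive semi-definite "
            "(min eigenvalue %.3e); projecting to the nearest PSD matrix",
            vals.min(),
        )
    vals = np.clip(vals, 0.0, None)
    return vecs * np.sqrt(vals)


def mc_weight_sensitivity(
    records: Sequence[SubjectRecord],
    death_fit: CoxFit,
    B: int,
    seed: int,
    *,
    design: str = AMBISPECTIVE,
    covariates: Sequence[str] | None = None,
    covariance_scale: float = 1.0,
) -> SensitivitySummary:
    """Propagate death-model uncertainty through the weights.

    For each replicate, draw death-model coefficients from a multivariate
    normal centred at the fitted values with the model-based covariance
    (optionally rescaled), rebuild the Breslow baseline and the weights at
    the drawn coefficients, refit the recurrence model, and summarize the
    replicate coefficient distribution.
    """
    if B < 1:
        raise ValueError("B must be >= 1")
    if not death_fit.converged:
        raise ValueError("sensitivity analysis requires a converged death fit")
    rng = np.random.default_rng(seed)
    L = _psd_factor(covariance_scale * death_fit.covariance_model)
    entry, exit_, event, X, _ = _death_arrays(records)
    p = death_fit.coefficients.size
    estimates = []
    names = None
    for _ in range(B):
        beta_b = death_fit.coefficients + L @ rng.standard_normal(p)
        times_b, cum_b = breslow_baseline(beta_b, entry, exit_, event, X)
        fit_b = death_fit.replace(
            coefficients=beta_b, baseline_times=times_b, baseline_cumhaz=cum_b
        )
        ws = compute_weights(fit_b, records)
        rec_fit = fit_recurrence(records, design, weights=ws, covariates=covariates)
        estimates.append(rec_fit.coefficients)
        names = rec_fit.covariate_names
    est = np.asarray(estimates)
    return SensitivitySummary(
        n_replicates=B,
        seed=seed,
        covariate_names=names,
        estimates=est,
        mean=est.mean(axis=0),
        sd=est.std(axis=0, ddof=1) if B > 1 else np.zeros(est.shape[1]),
        q025=np.percentile(est, 2.5, axis=0),
        q975=np.percentile(est, 97.5, axis=0),
    )
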