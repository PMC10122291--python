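"""Selection weights from a delayed-entry death model on the age scale.

Recurrence information is only observed for patients who survived long
enough for it to be collected: up to the recontact date for responders
(Cases 1-2), up to inclusion for the others (Cases 3-4).  Patients at high
risk of death before that point are under-represented, which biases any
analysis using pre-inclusion events.  The correction weights each observed
patient by the inverse of their probability of surviving from the first VT
to their own collection age, estimated from a Cox model for death with age
as the time scale and delayed entry at the age of inclusion (patients are
only observed conditional on being alive at inclusion).

Weights are standardized so that they sum to the analysed sample size N:

    w_i = N * (1/s_i) / sum_j (1/s_j)
"""
from __future__ import annotations

import logging
from dataclasses import dataclass
from typing import Sequence

import numpy as np
import pandas as pd

from .cohort import CaseLabel, SubjectRecord, classify_case
from .cox import CoxFit, fit_cox, predict_interval_survival

logger = logging.getLogger(__name__)

#: covariates of the death model (age itself is the time scale)
DEATH_COVARIATES = ("sex", "provoked", "age_first_vt", "pc1", "pc2", "pc3", "pc4")

MAX_WEIGHT_WARN = 10.0


def death_covariate_matrix(records: Sequence[SubjectRecord]) -> np.ndarray:
    """Design matrix of the death model, one row per record."""
    return np.array(
        [
            [r.sex, r.provoked_first_vt, r.age_first_vt, *r.pcs]
            for r in records
        ],
        dtype=float,
    )


def _death_arrays(records: Sequence[SubjectRecord]):
    """Entry/exit ages, death indicator and covariates for the subjects the
    death model can use (known vital status, positive follow-up)."""
    usable, n_unknown, n_zero = [], 0, 0
    for r in records:
        if r.vital_status == "unknown" or r.t_last_vital is None:
            n_unknown += 1
            continue
        if not r.t_last_vital > r.t_inclusion:
            n_zero += 1
            continue
        usable.append(r)
    if n_unknown:
        logger.info("death model: excluded %d subjects with unknown vital status", n_unknown)
    if n_zero:
        logger.info("death model: excluded %d subjects with zero follow-up", n_zero)
    if not usable:
        raise ValueError("no subjects with usable vital-status follow-up")
    entry = np.array([r.age_first_vt + r.t_inclusion for r in usable])
    exit_ = np.array([r.age_first_vt + r.t_last_vital for r in usable])
    event = np.array([r.vital_status == "dead" for r in usable])
    X = death_covariate_matrix(usable)
    return entry, exit_, event, X, usable


def fit_death_model(records: Sequence[SubjectRecord], **fit_kwargs) -> CoxFit:
    """Delayed-entry Cox model for death on the age time scale.

    Entry at age of inclusion, exit at age of death or last vital
    information; covariates: sex, provoked first VT, age at first VT and
    the first four principal components.
    """
    entry, exit_, event, X, _ = _death_arrays(records)
    if not event.any():
        raise ValueError("no deaths observed: cannot fit the death model")
    return fit_cox(
        entry, exit_, event, X, covariate_names=DEATH_COVARIATES, **fit_kwargs
    )


def collection_age(record: SubjectRecord) -> float:
    """Age up to which the patient had to survive for their recurrence
    information to be collected: the recontact age for responders
    (Cases 1-2), the inclusion age otherwise (Cases 3-4)."""
    case = classify_case(record)
    if case in (CaseLabel.CASE1, CaseLabel.CASE2):
        return record.age_first_vt + record.t_collection
    return record.age_first_vt + record.t_inclusion


@dataclass
class WeightSet:
    """Per-subject survival probabilities and standardized weights."""

    subject_ids: tuple[str, ...]
    survival: np.ndarray
    weights: np.ndarray
    n: int

    @property
    def effective_sample_size(self) -> float:
        return float(self.weights.sum() ** 2 / (self.weights**2).sum())

    @property
    def diagnostics(self) -> dict:
        return {
            "n": self.n,
            "min_weight": float(self.weights.min()),
            "max_weight": float(self.weights.max()),
            "effective_sample_size": self.effective_sample_size,
        }

    def for_ids(self, ids: Sequence[str]) -> np.ndarray:
        lookup = {sid: w for sid, w in zip(self.subject_ids, self.weights)}
        try:
            return np.array([lookup[i] for i in ids])
        except KeyError as exc:
            raise KeyError(f"no weight for subject {exc.args[0]}") from None

    def as_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            {
                "subject_id": self.subject_ids,
                "survival_probability": self.survival,
                "weight": self.weights,
            }
        )

    @classmethod
    def unit(cls, records: Sequence[SubjectRecord]) -> "WeightSet":
        n = len(records)
        return cls(
            subject_ids=tuple(r.subject_id for r in records),
            survival=np.ones(n),
            weights=np.ones(n),
            n=n,
        )


def compute_weights(death_fit: CoxFit, records: Sequence[SubjectRecord]) -> WeightSet:
    """Inverse-survival-probability weights, standardized to sum N.

    ``s_i`` is the fitted probability of surviving from the age at first VT
    to the subject's own collection age; every record receives a weight
    (prediction needs only covariates, not vital status).
    """
    records = list(records)
    if not records:
        raise ValueError("empty cohort")
    X = death_covariate_matrix(records)
    start = np.array([r.age_first_vt for r in records])
    stop = np.array([collection_age(r) for r in records])
    s = predict_interval_survival(death_fit, X, start, stop)
    s = np.atleast_1d(s)
    if np.any(s <= 0):
        raise ValueError("zero survival probability encountered")
    inv = 1.0 / s
    n = len(records)
    w = n * inv / inv.sum()
    if w.max() > MAX_WEIGHT_WARN:
        logger.warning(
            "max standardized weight %.2f exceeds %.0f: weight distribution "
            "is highly dispersed", w.max(), MAX_WEIGHT_WARN,
        )
    return WeightSet(
        subject_ids=tuple(r.subject_id for r in records),
        survival=s,
        weights=w,
        n=n,
    )
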