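"""Ridge-penalized logistic diagnostic model on selected marker sites.

The classifier is a plain logistic regression on the markers' beta values
(optionally M-values), fitted by Newton/IRLS on the L2-penalized Bernoulli
log-likelihood with the penalty on the coefficients only — the intercept is
free, so the model can absorb class imbalance.  A small ridge keeps the fit
well-defined when planted markers make the classes linearly separable.

Discrimination is summarized by the Mann-Whitney AUC: the probability that a
random tumor sample scores above a random normal sample, with ties counted
half.
"""

from __future__ import annotations

import json
import math
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy.stats import rankdata

from .core_io import BetaMatrix, SampleSheet

__all__ = [
    "DiagnosticModel",
    "CohortMetrics",
    "fit_logistic",
    "predict_proba",
    "compute_auc",
    "evaluate_cohort",
]

MAX_ITER = 200
PARAM_TOL = 1e-8
M_VALUE_CLIP = (0.01, 0.99)


@dataclass(frozen=True)
class DiagnosticModel:
    marker_ids: tuple
    intercept: float
    coefficients: tuple
    ridge_lambda: float
    training_cohort: str
    value_scale: str = "beta"  # or "m_value"
    training_means: tuple = ()  # per-marker feature means, for imputation

    def __post_init__(self):
        if len(self.coefficients) != len(self.marker_ids):
            raise ValueError("one coefficient per marker required")
        if self.ridge_lambda < 0:
            raise ValueError("ridge_lambda must be >= 0")

    def to_json(self, path) -> None:
        with open(path, "w") as fh:
            json.dump(
                {
                    "marker_ids": list(self.marker_ids),
                    "intercept": self.intercept,
                    "coefficients": list(self.coefficients),
                    "ridge_lambda": self.ridge_lambda,
                    "training_cohort": self.training_cohort,
                    "value_scale": self.value_scale,
                    "training_means": list(self.training_means),
                },
                fh,
                indent=2,
            )

    @classmethod
    def from_json(cls, path) -> "DiagnosticModel":
        with open(path) as fh:
            d = json.load(fh)
        return cls(
            marker_ids=tuple(d["marker_ids"]),
            intercept=float(d["intercept"]),
            coefficients=tuple(d["coefficients"]),
            ridge_lambda=float(d["ridge_lambda"]),
            training_cohort=d["training_cohort"],
            value_scale=d["value_scale"],
            training_means=tuple(d["training_means"]),
        )


@dataclass(frozen=True)
class CohortMetrics:
    cohort_id: str
    auc: float
    sensitivity: float
    specificity: float
    n_tumor: int
    n_normal: int


def _to_scale(x: np.ndarray, value_scale: str) -> np.ndarray:
    if value_scale == "beta":
        return x
    if value_scale == "m_value":
        p = np.clip(x, *M_VALUE_CLIP)
        return np.log2(p / (1.0 - p))
    raise ValueError(f"unknown value_scale {value_scale!r}")


def _feature_matrix(matrix: BetaMatrix, marker_ids, sample_ids, value_scale, means=None):
    """Samples x markers feature array; missing entries imputed by the given
    (or column) means on the model's feature scale."""
    sub = matrix.subset(sites=marker_ids, samples=sample_ids)
    X = _to_scale(sub.values.to_numpy().T, value_scale)
    if means is None:
        means = np.nanmean(X, axis=0)
    means = np.asarray(means, dtype=float)
    nan = np.isnan(X)
    if nan.any():
        X = np.where(nan, np.broadcast_to(means, X.shape), X)
    return X, means


def _penalized_nll(theta: np.ndarray, X1: np.ndarray, y: np.ndarray, lam: float) -> float:
    eta = X1 @ theta
    # log(1 + exp(eta)) - y*eta, computed stably
    nll = np.sum(np.logaddexp(0.0, eta) - y * eta)
    return float(nll + 0.5 * lam * np.sum(theta[1:] ** 2))


def fit_logistic(
    matrix: BetaMatrix,
    sheet: SampleSheet,
    marker_ids,
    training_cohort: str,
    ridge_lambda: float = 1e-3,
    value_scale: str = "beta",
) -> DiagnosticModel:
    """Fit the diagnostic logistic model on one cohort by Newton/IRLS.

    Maximizes the Bernoulli log-likelihood minus (lambda/2)*||coef||^2
    (intercept unpenalized), with step halving so the penalized objective
    never increases; converges when the largest parameter change drops below
    1e-8, capped at 200 iterations.
    """
    marker_ids = list(marker_ids)
    sample_ids = sheet.select(cohort_id=training_cohort)
    states = dict(zip(sheet.table["sample_id"], sheet.table["tissue_state"]))
    y = np.array([1.0 if states[s] == "tumor" else 0.0 for s in sample_ids])
    if len(sample_ids) == 0 or y.min() == y.max():
        raise ValueError(f"training cohort {training_cohort!r} must contain both classes")

    X, means = _feature_matrix(matrix, marker_ids, sample_ids, value_scale)
    n, k = X.shape
    X1 = np.hstack([np.ones((n, 1)), X])
    lam = float(ridge_lambda)
    pen = np.zeros(k + 1)
    pen[1:] = lam

    theta = np.zeros(k + 1)
    obj = _penalized_nll(theta, X1, y, lam)
    converged = False
    for _ in range(MAX_ITER):
        eta = X1 @ theta
        p = 1.0 / (1.0 + np.exp(-eta))
        grad = X1.T @ (p - y) + pen * theta
        w = p * (1.0 - p)
        H = (X1 * w[:, None]).T @ X1 + np.diag(pen)
        try:
            step = np.linalg.solve(H, grad)
        except np.linalg.LinAlgError:
            step = np.linalg.lstsq(H, grad, rcond=None)[0]
        # step halving: the penalized objective must not increase
        t = 1.0
        for _half in range(60):
            cand = theta - t * step
            new_obj = _penalized_nll(cand, X1, y, lam)
            if new_obj <= obj + 1e-12:
                break
            t /= 2.0
        else:
            cand, new_obj = theta, obj
        delta = np.max(np.abs(cand - theta))
        theta, obj = cand, new_obj
        if delta < PARAM_TOL:
            converged = True
            break
    if not converged:
        if lam == 0.0:
            raise RuntimeError(
                "IRLS did not converge at lambda=0 (data may be linearly "
                "separable); refit with ridge_lambda > 0"
            )
        raise RuntimeError("IRLS did not converge within 200 iterations")

    return DiagnosticModel(
        marker_ids=tuple(marker_ids),
        intercept=float(theta[0]),
        coefficients=tuple(float(c) for c in theta[1:]),
        ridge_lambda=lam,
        training_cohort=training_cohort,
        value_scale=value_scale,
        training_means=tuple(float(m) for m in means),
    )


def predict_proba(model: DiagnosticModel, matrix: BetaMatrix, sample_ids) -> pd.Series:
    """Predicted colon-cancer probability per sample,
    p = 1 / (1 + exp(-(intercept + sum coef * x)))."""
    sample_ids = list(sample_ids)
    X, _ = _feature_matrix(
        matrix, list(model.marker_ids), sample_ids, model.value_scale,
        means=model.training_means if model.training_means else None,
    )
    eta = model.intercept + X @ np.asarray(model.coefficients)
    return pd.Series(1.0 / (1.0 + np.exp(-eta)), index=sample_ids)


def compute_auc(scores, labels) -> float:
    """Mann-Whitney AUC: fraction of tumor-normal pairs ranked correctly,
    ties counted 0.5.  ``labels`` is boolean-like, True/1 = tumor."""
    s = np.asarray(scores, dtype=float)
    y = np.asarray(labels).astype(bool)
    n1, n0 = int(y.sum()), int((~y).sum())
    if n1 == 0 or n0 == 0:
        raise ValueError("both classes must be present to compute AUC")
    r = rankdata(s)
    u = r[y].sum() - n1 * (n1 + 1) / 2.0
    return float(u / (n1 * n0))


def evaluate_cohort(
    model: DiagnosticModel,
    matrix: BetaMatrix,
    sheet: SampleSheet,
    cohort_id: str,
    threshold: float = 0.5,
) -> CohortMetrics:
    """AUC plus sensitivity/specificity at the probability call threshold on
    one cohort's tumor and normal samples."""
    sample_ids = sheet.select(cohort_id=cohort_id)
    if not sample_ids:
        raise ValueError(f"cohort {cohort_id!r} has no samples")
    states = dict(zip(sheet.table["sample_id"], sheet.table["tissue_state"]))
    y = np.array([states[s] == "tumor" for s in sample_ids])
    p = predict_proba(model, matrix, sample_ids).to_numpy()
    auc = compute_auc(p, y)
    called = p >= threshold
    n1, n0 = int(y.sum()), int((~y).sum())
    return CohortMetrics(
        cohort_id=cohort_id,
        auc=auc,
        sensitivity=float(called[y].sum() / n1),
        specificity=float((~called[~y]).sum() / n0),
        n_tumor=n1,
        n_normal=n0,
    )
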