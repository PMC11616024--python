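"""Cross-cancer misclassification profiling and marker-set comparison.

A tissue-specific diagnostic model should rarely call samples from other
tumor types "colon cancer".  `misclassification_profile` measures, for each
non-colorectal cancer type, the percentage of samples the model calls colon
cancer at a probability threshold; `compare_marker_sets` fits one model per
named marker set under identical training and reports validation metrics
plus tumor- and normal-scope profiles side by side.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .core_io import COLORECTAL_TYPES, REFERENCE_TYPES, BetaMatrix, SampleSheet
from .diagnostic_model import (
    CohortMetrics,
    DiagnosticModel,
    evaluate_cohort,
    fit_logistic,
    predict_proba,
)

__all__ = ["SpecificityReport", "MarkerSetEvaluation", "misclassification_profile", "compare_marker_sets"]

SCOPES = ("tumor", "normal", "both")


@dataclass(frozen=True)
class SpecificityReport:
    """Per-cancer-type colon-call proportions (percent) for one marker set.

    per_type maps cancer_type -> (n_samples, n_called_colon, proportion %);
    proportion is None when the scope selects no samples of that type, and
    such types are excluded from the (min, max, median) summary.
    """

    marker_set_name: str
    per_type: dict
    summary: tuple  # (min %, max %, median %) over types with n > 0
    sample_scope: str


def misclassification_profile(
    model: DiagnosticModel,
    matrix: BetaMatrix,
    sheet: SampleSheet,
    scope: str = "both",
    threshold: float = 0.5,
    exclude_types=COLORECTAL_TYPES | REFERENCE_TYPES,
    name: str = "markers",
) -> SpecificityReport:
    """Percentage of each other cancer type's samples called colon cancer."""
    if scope not in SCOPES:
        raise ValueError(f"scope must be one of {SCOPES}")
    t = sheet.table
    types = sorted(set(t["cancer_type"]) - set(exclude_types))
    if not types:
        raise ValueError("no non-colon cancer types present in the sample sheet")
    per_type, props = {}, []
    for ct in types:
        if scope == "both":
            ids = sheet.select(cancer_type=ct)
        else:
            ids = sheet.select(cancer_type=ct, tissue_state=scope)
        if not ids:
            per_type[ct] = (0, 0, None)
            continue
        p = predict_proba(model, matrix, ids).to_numpy()
        n_called = int((p >= threshold).sum())
        prop = 100.0 * n_called / len(ids)
        per_type[ct] = (len(ids), n_called, prop)
        props.append(prop)
    if not props:
        raise ValueError(f"scope {scope!r} selects zero samples for every type")
    summary = (float(min(props)), float(max(props)), float(np.median(props)))
    return SpecificityReport(
        marker_set_name=name, per_type=per_type, summary=summary, sample_scope=scope
    )


@dataclass(frozen=True)
class MarkerSetEvaluation:
    name: str
    model: DiagnosticModel
    metrics: tuple  # CohortMetrics per validation cohort
    profile_tumor: SpecificityReport
    profile_normal: SpecificityReport


def _validation_cohorts(sheet: SampleSheet, training_cohort: str) -> list:
    t = sheet.table
    out = []
    for cid in dict.fromkeys(t["cohort_id"]):
        if cid == training_cohort:
            continue
        sub = t[t["cohort_id"] == cid]
        if not set(sub["cancer_type"]) <= COLORECTAL_TYPES:
            continue
        if (sub["tissue_state"] == "tumor").any() and (sub["tissue_state"] == "normal").any():
            out.append(cid)
    return out


def compare_marker_sets(
    marker_sets: dict,
    bundle,
    training_cohort: str,
    ridge_lambda: float = 1e-3,
    threshold: float = 0.5,
) -> dict:
    """Fit and evaluate one model per named marker set under identical
    training; returns name -> :class:`MarkerSetEvaluation`."""
    matrix, sheet = bundle.matrix, bundle.sheet
    for name, ids in marker_sets.items():
        if not ids:
            raise ValueError(f"marker set {name!r} is empty")
        absent = [m for m in ids if m not in matrix.values.index]
        if absent:
            raise KeyError(f"marker set {name!r}: id(s) absent from matrix: {absent[:5]}")
    cohorts = _validation_cohorts(sheet, training_cohort)
    out = {}
    for name, ids in marker_sets.items():
        model = fit_logistic(matrix, sheet, ids, training_cohort, ridge_lambda)
        metrics = tuple(
            evaluate_cohort(model, matrix, sheet, cid, threshold) for cid in cohorts
        )
        out[name] = MarkerSetEvaluation(
            name=name,
            model=model,
            metrics=metrics,
            profile_tumor=misclassification_profile(
                model, matrix, sheet, "tumor", threshold, name=name
            ),
            profile_normal=misclassification_profile(
                model, matrix, sheet, "normal", threshold, name=name
            ),
        )
    return out
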