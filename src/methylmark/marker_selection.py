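"""Three-stage marker-selection cascade for tissue-specific hypermethylation.

Stage 1 screens candidate-gene CpG sites for hypermethylation in the paired
colon training cohort (two-sided Wilcoxon rank-sum, Benjamini-Hochberg FDR,
plus a delta-beta effect-size gate).  Stage 2 discards sites whose mean beta
exceeds a background ceiling in any normal-tissue or blood reference cohort
— sites already methylated in healthy tissue cannot be specific.  Stage 3
discards sites whose mean beta exceeds a ceiling in the tumor samples of any
other cancer type, leaving markers hypermethylated only in colorectal
tumors.

The rank-sum p-value is exact (full permutation distribution over midranks,
computed by a count-polynomial dynamic program equivalent to enumerating all
C(n, n1) group assignments) whenever the smaller group has <= 10 samples,
and a tie- and continuity-corrected normal approximation otherwise.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass

import numpy as np
from scipy.stats import rankdata
from scipy.special import ndtr
from statsmodels.stats.multitest import multipletests

from .core_io import (
    COLORECTAL_TYPES,
    REFERENCE_TYPES,
    BetaMatrix,
    CascadeParams,
)

logger = logging.getLogger(__name__)

__all__ = [
    "DifferentialResult",
    "StageRecord",
    "MarkerCascadeResult",
    "ranksum_test",
    "bh_adjust",
    "test_hypermethylation",
    "background_filter",
    "specificity_filter",
    "run_cascade",
]

EXACT_MAX_GROUP = 10


# ---------------------------------------------------------------------------
# rank-sum engine


def _exact_ranksum_p(x: np.ndarray, y: np.ndarray) -> float:
    """Exact two-sided rank-sum p over the full permutation distribution.

    Ties get midranks.  Doubling the midranks makes them integers; the
    distribution of the rank-sum of the smaller group over all C(n, n1)
    equally likely assignments is then built by dynamic programming on
    (subset size, rank total).  Two-sided: P(|W - E W| >= |w_obs - E W|).
    """
    if len(x) > len(y):  # symmetric; track the smaller group
        x, y = y, x
    pooled = np.concatenate([x, y])
    ranks2 = np.rint(2.0 * rankdata(pooled)).astype(np.int64)
    n, n1 = len(pooled), len(x)
    w_obs = int(ranks2[:n1].sum())
    total = ranks2.sum()
    # counts[k, s] = number of k-subsets with doubled-rank total s
    counts = np.zeros((n1 + 1, total + 1))
    counts[0, 0] = 1.0
    for r in ranks2:
        counts[1:, r:] += counts[:-1, : total + 1 - r]
    dist = counts[n1]
    mu = n1 * (n + 1.0)  # doubled-rank expectation: n1 * 2*(n+1)/2
    dev = np.abs(np.arange(total + 1) - mu)
    n_extreme = dist[dev >= abs(w_obs - mu) - 1e-9].sum()
    return float(min(1.0, n_extreme / math.comb(n, n1)))


def _approx_ranksum_p(x: np.ndarray, y: np.ndarray) -> float:
    """Normal approximation with midranks, tie-corrected variance and a
    0.5 continuity correction."""
    n1, n2 = len(x), len(y)
    n = n1 + n2
    pooled = np.concatenate([x, y])
    ranks = rankdata(pooled)
    w = ranks[:n1].sum()
    mu = n1 * (n + 1) / 2.0
    _, t = np.unique(pooled, return_counts=True)
    tie_term = (t**3 - t).sum() / ((n) * (n - 1.0)) if n > 1 else 0.0
    var = n1 * n2 / 12.0 * ((n + 1.0) - tie_term)
    if var <= 0.0:  # all values identical
        return 1.0
    z = (abs(w - mu) - 0.5) / math.sqrt(var)
    z = max(z, 0.0)
    return float(min(1.0, 2.0 * (1.0 - ndtr(z))))


def ranksum_test(x, y, exact_max: int = EXACT_MAX_GROUP) -> float:
    """Two-sided Wilcoxon rank-sum p-value.

    Exact permutation distribution when min(|x|, |y|) <= ``exact_max``,
    normal approximation otherwise.
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if len(x) == 0 or len(y) == 0:
        raise ValueError("both groups must be non-empty")
    if min(len(x), len(y)) <= exact_max:
        return _exact_ranksum_p(x, y)
    return _approx_ranksum_p(x, y)


def bh_adjust(p_values) -> np.ndarray:
    """Benjamini-Hochberg step-up adjusted q-values, in input order."""
    p = np.asarray(list(p_values), dtype=float)
    if p.size == 0:
        return np.empty(0)
    if ((p < 0) | (p > 1)).any():
        raise ValueError("p-values must lie in [0, 1]")
    _, q, _, _ = multipletests(p, method="fdr_bh")
    return q


# ---------------------------------------------------------------------------
# cascade stages


@dataclass(frozen=True)
class DifferentialResult:
    site_id: str
    mean_tumor: float
    mean_normal: float
    delta: float
    p: float
    q: float
    is_hyper: bool


@dataclass(frozen=True)
class StageRecord:
    stage_name: str
    n_candidates_in: int
    n_removed: int
    survivors: frozenset

    def __post_init__(self):
        if self.n_candidates_in - self.n_removed != len(self.survivors):
            raise AssertionError(
                f"stage {self.stage_name}: {self.n_candidates_in} in - "
                f"{self.n_removed} removed != {len(self.survivors)} out"
            )


@dataclass(frozen=True)
class MarkerCascadeResult:
    stages: tuple
    final_markers: frozenset

    def __post_init__(self):
        prev = None
        for st in self.stages:
            if prev is not None and not st.survivors <= prev.survivors:
                raise AssertionError(
                    f"stage {st.stage_name} survivors not contained in {prev.stage_name}"
                )
            prev = st
        if prev is not None and self.final_markers != prev.survivors:
            raise AssertionError("final_markers != last stage survivors")


def _group_values(matrix: BetaMatrix, sample_ids) -> np.ndarray:
    return matrix.values[list(sample_ids)].to_numpy()


def test_hypermethylation(
    matrix: BetaMatrix,
    tumor_samples,
    normal_samples,
    params: CascadeParams,
) -> list:
    """Per-site tumor-vs-normal differential methylation screen.

    Returns one :class:`DifferentialResult` per site whose missing fraction
    is within ``params.missing_max`` in both groups; a site is called
    hypermethylated when delta >= delta_min and BH q <= q_max.
    """
    tumor_samples, normal_samples = list(tumor_samples), list(normal_samples)
    if not tumor_samples or not normal_samples:
        raise ValueError("tumor and normal sample sets must be non-empty")
    if set(tumor_samples) & set(normal_samples):
        raise ValueError("tumor and normal sample sets must be disjoint")
    tvals = _group_values(matrix, tumor_samples)
    nvals = _group_values(matrix, normal_samples)

    rows, ps = [], []
    for i, site in enumerate(matrix.site_ids):
        t = tvals[i][~np.isnan(tvals[i])]
        nn = nvals[i][~np.isnan(nvals[i])]
        miss_t = 1.0 - len(t) / len(tumor_samples)
        miss_n = 1.0 - len(nn) / len(normal_samples)
        if len(t) == 0 or len(nn) == 0:
            logger.warning("site %s: all values missing in one group; excluded", site)
            continue
        if miss_t > params.missing_max or miss_n > params.missing_max:
            logger.warning("site %s: missing fraction exceeds %.2f; excluded", site, params.missing_max)
            continue
        rows.append((site, float(t.mean()), float(nn.mean())))
        ps.append(ranksum_test(t, nn))
    qs = bh_adjust(ps)
    out = []
    for (site, mt, mn), p, q in zip(rows, ps, qs):
        delta = mt - mn
        out.append(
            DifferentialResult(
                site_id=site,
                mean_tumor=mt,
                mean_normal=mn,
                delta=delta,
                p=float(p),
                q=float(q),
                is_hyper=bool(delta >= params.delta_min and q <= params.q_max),
            )
        )
    return out


def _cohort_means(matrix: BetaMatrix, candidates, sample_ids) -> "np.ndarray":
    sub = matrix.values.loc[list(candidates), list(sample_ids)]
    return sub.mean(axis=1, skipna=True)  # NaN when no usable values


def background_filter(candidates, matrix: BetaMatrix, reference_cohorts, tau_bg: float):
    """Retain candidates whose mean beta is <= tau_bg in EVERY reference
    cohort (normal tissue / blood); 'higher than tau_bg' anywhere removes.
    """
    candidates = list(candidates)
    missing = [c for c in candidates if c not in matrix.values.index]
    if missing:
        raise KeyError(f"candidate site(s) absent from matrix: {missing[:5]}")
    for cohort in reference_cohorts:
        if not len(cohort):
            raise ValueError("reference cohorts must be non-empty")
    keep = set(candidates)
    for cohort in reference_cohorts:
        means = _cohort_means(matrix, candidates, cohort)
        for site in candidates:
            m = means[site]
            if np.isnan(m):
                logger.warning("site %s: no usable values in a reference cohort; excluded", site)
                keep.discard(site)
            elif m > tau_bg:
                keep.discard(site)
    return keep


def specificity_filter(candidates, matrix: BetaMatrix, other_tumor_cohorts, tau_spec: float):
    """Retain candidates whose mean beta is <= tau_spec in the tumor samples
    of EVERY other cancer type."""
    if not other_tumor_cohorts:
        raise ValueError("at least one other-tumor cohort is required")
    candidates = list(candidates)
    missing = [c for c in candidates if c not in matrix.values.index]
    if missing:
        raise KeyError(f"candidate site(s) absent from matrix: {missing[:5]}")
    keep = set(candidates)
    for cancer_type, cohort in other_tumor_cohorts.items():
        means = _cohort_means(matrix, candidates, cohort)
        for site in candidates:
            m = means[site]
            if np.isnan(m):
                logger.warning(
                    "site %s: no usable values in %s tumors; excluded", site, cancer_type
                )
                keep.discard(site)
            elif m > tau_spec:
                keep.discard(site)
    return keep


def run_cascade(bundle, params: CascadeParams, training_cohort: str | None = None) -> MarkerCascadeResult:
    """Run the full selection cascade on a study bundle.

    Stage 1 (hypermethylation screen) is restricted to sites flagged
    eligible_gene and uses the paired colon training cohort; stage 2 uses the
    training normals plus every NORMAL_TISSUE / BLOOD reference cohort;
    stage 3 uses tumor samples of every non-colorectal cancer type.
    """
    sheet, matrix, ann = bundle.sheet, bundle.matrix, bundle.annotation
    t = sheet.table
    if training_cohort is None:
        colon = t[t["cancer_type"].isin(COLORECTAL_TYPES)]
        for cid in dict.fromkeys(colon["cohort_id"]):
            sub = colon[colon["cohort_id"] == cid]
            if (sub["tissue_state"] == "tumor").any() and (sub["tissue_state"] == "normal").any():
                training_cohort = cid
                break
        if training_cohort is None:
            raise ValueError("no colon cohort with both tumor and normal samples")
    tumor = sheet.select(cohort_id=training_cohort, tissue_state="tumor")
    normal = sheet.select(cohort_id=training_cohort, tissue_state="normal")

    eligible = [s for s in ann.eligible_sites() if s in matrix.values.index]
    sub = matrix.subset(sites=eligible)
    results = test_hypermethylation(sub, tumor, normal, params)
    s1 = frozenset(r.site_id for r in results if r.is_hyper)
    stages = [StageRecord("hypermethylation_screen", len(eligible), len(eligible) - len(s1), s1)]
    logger.info("stage 1 hypermethylation_screen: %d -> %d", len(eligible), len(s1))

    reference_cohorts = [normal]
    for ref_type in sorted(REFERENCE_TYPES):
        for cid in dict.fromkeys(t.loc[t["cancer_type"] == ref_type, "cohort_id"]):
            reference_cohorts.append(sheet.select(cohort_id=cid))
    s2 = frozenset(background_filter(s1, matrix, reference_cohorts, params.tau_bg))
    stages.append(StageRecord("background_filter", len(s1), len(s1) - len(s2), s2))
    logger.info("stage 2 background_filter: %d -> %d", len(s1), len(s2))

    other_types = sorted(
        set(t["cancer_type"]) - COLORECTAL_TYPES - REFERENCE_TYPES
    )
    other_cohorts = {
        ct: sheet.select(cancer_type=ct, tissue_state="tumor") for ct in other_types
    }
    other_cohorts = {ct: ids for ct, ids in other_cohorts.items() if ids}
    s3 = frozenset(specificity_filter(s2, matrix, other_cohorts, params.tau_spec))
    stages.append(StageRecord("specificity_filter", len(s2), len(s2) - len(s3), s3))
    logger.info("stage 3 specificity_filter: %d -> %d", len(s2), len(s3))

    return MarkerCascadeResult(stages=tuple(stages), final_markers=s3)
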