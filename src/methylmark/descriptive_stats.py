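"""Descriptive analyses: neighbor co-methylation, clustering separation, and
subgroup differential tests.

Neighboring CpG sites tend to be co-methylated, so a credible marker should
correlate with the sites around it; `neighbor_correlation` reports Pearson
(or Spearman) r between each anchor site and every annotated site within a
genomic window on the same chromosome.  `cluster_separation` quantifies how
cleanly unsupervised hierarchical clustering on a set of sites recovers the
tumor/normal split, as an adjusted Rand index.  `subgroup_test` compares
site methylation between two sample groups (CIMP-H vs CIMP-L, stage-I tumors
vs normals, ...) with the same exact/approximate rank-sum engine as the
marker screen, BH-corrected across the tested sites.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy.cluster.hierarchy import fcluster, linkage
from scipy.stats import pearsonr, spearmanr
from sklearn.metrics import adjusted_rand_score

from .core_io import BetaMatrix, SampleSheet, SiteAnnotation
from .marker_selection import bh_adjust, ranksum_test

__all__ = [
    "NeighborCorrelation",
    "SubgroupTestResult",
    "neighbor_correlation",
    "cluster_separation",
    "subgroup_test",
]

MIN_PAIRS = 3


@dataclass(frozen=True)
class NeighborCorrelation:
    anchor_site: str
    neighbor_site: str
    distance: int  # bp
    r: float | None  # None when fewer than MIN_PAIRS complete sample pairs
    n_pairs: int


@dataclass(frozen=True)
class SubgroupTestResult:
    site_id: str
    group_a: str
    group_b: str
    delta: float  # mean_a - mean_b
    p: float
    q: float


def neighbor_correlation(
    matrix: BetaMatrix,
    annotation: SiteAnnotation,
    anchor_sites,
    window: int = 2000,
    sample_ids=None,
    method: str = "pearson",
) -> list:
    """Correlate each anchor with every annotated site within ``window`` bp
    (inclusive) on the same chromosome, over samples non-missing in both."""
    if method not in ("pearson", "spearman"):
        raise ValueError("method must be 'pearson' or 'spearman'")
    corr = pearsonr if method == "pearson" else spearmanr
    ann = annotation.table.set_index("site_id")
    if sample_ids is None:
        sample_ids = matrix.sample_ids
    vals = matrix.values[list(sample_ids)]
    out = []
    for anchor in anchor_sites:
        if anchor not in ann.index:
            raise KeyError(f"anchor site {anchor!r} lacks annotation")
        chrom, pos = ann.loc[anchor, "chrom"], int(ann.loc[anchor, "pos"])
        near = ann[(ann["chrom"] == chrom) & ((ann["pos"] - pos).abs() <= window)]
        for neighbor, row in near.iterrows():
            if neighbor == anchor or neighbor not in vals.index:
                continue
            a = vals.loc[anchor].to_numpy(dtype=float)
            b = vals.loc[neighbor].to_numpy(dtype=float)
            ok = ~(np.isnan(a) | np.isnan(b))
            n = int(ok.sum())
            if n < MIN_PAIRS:
                r = None
            else:
                r = float(corr(a[ok], b[ok]).statistic)
            out.append(
                NeighborCorrelation(
                    anchor_site=anchor,
                    neighbor_site=neighbor,
                    distance=int(abs(int(row["pos"]) - pos)),
                    r=r,
                    n_pairs=n,
                )
            )
    return out


def cluster_separation(matrix: BetaMatrix, sample_ids, labels, site_ids) -> float:
    """Adjusted Rand index between a 2-cut average-linkage clustering of the
    samples (Euclidean distance on the selected sites' beta values) and the
    given tumor/normal labels."""
    sample_ids, site_ids = list(sample_ids), list(site_ids)
    labels = list(labels)
    if len(site_ids) < 1:
        raise ValueError("at least one site is required")
    if len(sample_ids) < 2 or len(set(labels)) < 2:
        raise ValueError("need >= 2 samples and both labels present")
    X = matrix.subset(sites=site_ids, samples=sample_ids).values.to_numpy().T
    # impute per-site mean over the selected samples
    col_means = np.nanmean(X, axis=0)
    nan = np.isnan(X)
    if nan.any():
        X = np.where(nan, np.broadcast_to(col_means, X.shape), X)
    Z = linkage(X, method="average", metric="euclidean")
    assign = fcluster(Z, t=2, criterion="maxclust")
    return float(adjusted_rand_score(labels, assign))


def _resolve_selector(selector, sheet: SampleSheet, which: str) -> list:
    if callable(selector):
        ids = list(selector(sheet))
    elif isinstance(selector, dict):
        ids = sheet.select(**selector)
    else:
        ids = list(selector)
    if not ids:
        raise ValueError(f"selector for group {which} yields no samples")
    return ids


def subgroup_test(
    matrix: BetaMatrix,
    sheet: SampleSheet,
    site_ids,
    group_a,
    group_b,
    label_a: str = "A",
    label_b: str = "B",
) -> list:
    """Per-site two-sided rank-sum comparison between two sample groups.

    Selectors may be sample-id iterables, dicts of sample-sheet criteria
    (e.g. ``{"cimp": "H"}``), or callables mapping the sheet to sample ids.
    q-values are BH-adjusted across the tested sites.
    """
    ids_a = _resolve_selector(group_a, sheet, label_a)
    ids_b = _resolve_selector(group_b, sheet, label_b)
    if set(ids_a) & set(ids_b):
        raise ValueError("subgroup selectors must yield disjoint groups")
    sub = matrix.subset(sites=list(site_ids))
    va = sub.values[ids_a].to_numpy()
    vb = sub.values[ids_b].to_numpy()
    deltas, ps = [], []
    for i in range(len(site_ids)):
        a = va[i][~np.isnan(va[i])]
        b = vb[i][~np.isnan(vb[i])]
        if len(a) == 0 or len(b) == 0:
            raise ValueError(f"site {list(site_ids)[i]!r}: no usable values in a group")
        deltas.append(float(a.mean() - b.mean()))
        ps.append(ranksum_test(a, b))
    qs = bh_adjust(ps)
    return [
        SubgroupTestResult(
            site_id=s, group_a=label_a, group_b=label_b, delta=d, p=float(p), q=float(q)
        )
        for s, d, p, q in zip(site_ids, deltas, ps, qs)
    ]
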