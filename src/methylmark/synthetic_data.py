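"""Synthetic multi-cohort beta-value studies with planted ground truth.

The generator emulates the statistical structure a tissue-specific
methylation screen assumes: a paired colon training cohort, several
tumor/normal colon validation cohorts, normal-tissue and blood reference
cohorts, a rectal (READ) transfer cohort, and many other-tumor-type cohorts.
Sites belong to one of four planted classes:

``specific``
    hypermethylated only in colorectal tumors — the markers the cascade
    should recover;
``pancancer``
    hypermethylated in tumors of every type — removed by the pan-cancer
    specificity filter;
``background``
    elevated in normal tissue and blood as well as tumors — removed by the
    normal-background filter;
``neutral``
    low everywhere — removed by the hypermethylation screen.

Beta values are drawn from class-and-context Beta marginals coupled through
a Gaussian copula: sites sit on one synthetic chromosome at fixed spacing,
and blocks of adjacent sites share a latent factor so that neighboring sites
are co-methylated with latent correlation ``rho``.  CIMP-H colon tumors get
an additive shift on the specific sites (clamped to [0, 1]); stage labels
are assigned round-robin I-IV to colorectal tumors.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd
from scipy.special import betaincinv, ndtr

from .core_io import (
    COLORECTAL_TYPES,
    BetaMatrix,
    SampleSheet,
    SiteAnnotation,
    ValidationError,
)

__all__ = [
    "SyntheticConfig",
    "CohortSpec",
    "SiteTruth",
    "StudyBundle",
    "simulate_study",
    "default_config",
    "OTHER_TUMOR_TYPES",
    "SITE_CLASSES",
    "CONTEXTS",
]

SITE_CLASSES = ("specific", "pancancer", "background", "neutral")
CONTEXTS = ("colon_tumor", "other_tumor", "normal_tissue", "blood")

#: the 28 non-colorectal TCGA tumor-type abbreviations used by default
OTHER_TUMOR_TYPES = (
    "ACC", "BLCA", "BRCA", "CESC", "ESCA", "HNSC", "GBM", "KICH", "KIRC",
    "KIRP", "LAML", "LGG", "LIHC", "LUAD", "LUSC", "MESO", "PAAD", "PCPG",
    "PRAD", "SARC", "SKCM", "STAD", "TGCT", "THCA", "THYM", "UCEC", "UCS",
    "UVM",
)

# default Beta-shape vocabulary: high ~ mean 0.75, low ~ mean 0.048,
# background ~ mean 0.25
_HIGH = (6.0, 2.0)
_LOW = (1.0, 20.0)
_BG = (2.0, 6.0)


def _default_beta_params() -> dict:
    p = {}
    for ctx in CONTEXTS:
        p[("specific", ctx)] = _HIGH if ctx == "colon_tumor" else _LOW
        p[("pancancer", ctx)] = _HIGH if ctx in ("colon_tumor", "other_tumor") else _LOW
        p[("background", ctx)] = _HIGH if ctx == "colon_tumor" else _BG
        p[("neutral", ctx)] = _LOW
    return p


@dataclass(frozen=True)
class CohortSpec:
    cohort_id: str
    cancer_type: str
    n_tumor: int
    n_normal: int


@dataclass(frozen=True)
class SyntheticConfig:
    """Full description of a synthetic study; `simulate_study` is a pure
    function of this object (determinism comes from ``seed``)."""

    n_specific: int = 3
    n_pancancer: int = 5
    n_background: int = 30
    n_neutral: int = 162
    beta_params: dict = field(default_factory=_default_beta_params)
    cohorts: tuple = ()
    n_other_types: int = 28
    block_size: int = 5
    rho: float = 0.7
    spacing: int = 500
    cimp_frac: float = 0.5
    cimp_shift: float = 0.2
    eligible_frac: float = 0.5
    seed: int = 0

    def __post_init__(self):
        for name in ("n_specific", "n_pancancer", "n_background", "n_neutral"):
            if getattr(self, name) < 0:
                raise ValidationError(f"{name} must be >= 0")
        for (cls, ctx), (a, b) in self.beta_params.items():
            if a <= 0 or b <= 0:
                raise ValidationError(f"Beta shape for {(cls, ctx)} must be > 0")
        if not (0.0 <= self.rho < 1.0):
            raise ValidationError("rho must be in [0, 1)")
        if self.block_size < 1 or self.spacing < 1:
            raise ValidationError("block_size and spacing must be >= 1")
        for c in self.cohorts:
            if c.n_tumor < 0 or c.n_normal < 0:
                raise ValidationError(f"cohort {c.cohort_id}: negative size")

    @property
    def n_sites(self) -> int:
        return self.n_specific + self.n_pancancer + self.n_background + self.n_neutral


@dataclass(frozen=True)
class SiteTruth:
    """Ground-truth planted class per generated site."""

    classes: dict  # site_id -> class label

    def sites_of(self, cls: str) -> frozenset:
        return frozenset(s for s, c in self.classes.items() if c == cls)


@dataclass(frozen=True)
class StudyBundle:
    matrix: BetaMatrix
    sheet: SampleSheet
    annotation: SiteAnnotation
    truth: SiteTruth


def default_config(seed: int = 0) -> SyntheticConfig:
    """Study layout mirroring the source cohort design: one paired training
    cohort (38 tumor + 38 normal), five validation cohorts totaling 230
    tumor / 212 normal, a 43-sample normal-tissue and a 184-sample blood
    reference cohort, one rectal transfer cohort, and 28 other-tumor-type
    cohorts of 20 tumor + 10 normal each."""
    cohorts = [
        CohortSpec("TRAIN", "COAD", 38, 38),
        CohortSpec("VAL1", "COAD", 46, 43),
        CohortSpec("VAL2", "COAD", 46, 43),
        CohortSpec("VAL3", "COAD", 46, 42),
        CohortSpec("VAL4", "COAD", 46, 42),
        CohortSpec("VAL5", "COAD", 46, 42),
        CohortSpec("NORMALS", "NORMAL_TISSUE", 0, 43),
        CohortSpec("BLOOD", "BLOOD", 0, 184),
        CohortSpec("RECTAL", "READ", 40, 20),
    ]
    for t in OTHER_TUMOR_TYPES:
        cohorts.append(CohortSpec(f"OT_{t}", t, 20, 10))
    return SyntheticConfig(cohorts=tuple(cohorts), seed=seed)


def _context(cancer_type: str, tissue_state: str) -> str:
    if tissue_state == "tumor":
        return "colon_tumor" if cancer_type in COLORECTAL_TYPES else "other_tumor"
    return "blood" if cancer_type == "BLOOD" else "normal_tissue"


def _build_sheet(config: SyntheticConfig) -> pd.DataFrame:
    rows = []
    stage_cycle = ("I", "II", "III", "IV")
    n_colon_tumors = 0
    for c in config.cohorts:
        for j in range(c.n_tumor):
            if c.cancer_type in COLORECTAL_TYPES:
                stage = stage_cycle[n_colon_tumors % 4]
                k = n_colon_tumors
                cimp = (
                    "H"
                    if math.floor((k + 1) * config.cimp_frac) > math.floor(k * config.cimp_frac)
                    else "L"
                )
                n_colon_tumors += 1
            else:
                stage, cimp = "NA", "NA"
            rows.append((f"{c.cohort_id}_T{j:03d}", c.cohort_id, c.cancer_type, "tumor", stage, cimp))
        for j in range(c.n_normal):
            rows.append((f"{c.cohort_id}_N{j:03d}", c.cohort_id, c.cancer_type, "normal", "NA", "NA"))
    return pd.DataFrame(
        rows, columns=["sample_id", "cohort_id", "cancer_type", "tissue_state", "stage", "cimp"]
    )


def simulate_study(config: SyntheticConfig) -> StudyBundle:
    """Draw a full study (matrix + sheet + annotation + truth) from ``config``.

    Deterministic given ``config.seed``.  Sites are laid out class-by-class
    (specific, pancancer, background, neutral) along one synthetic chromosome
    at ``spacing`` bp; consecutive runs of ``block_size`` sites share a latent
    Gaussian factor with loading sqrt(rho), so any two sites in a block have
    latent correlation rho (beta-scale Pearson correlation is close to rho
    for the marginals used here).
    """
    if config.n_sites == 0:
        raise ValidationError("configuration yields zero sites")
    sheet_df = _build_sheet(config)
    n_colon = (
        sheet_df["cancer_type"].isin(COLORECTAL_TYPES) & (sheet_df["tissue_state"] == "tumor")
    ).sum()
    if n_colon == 0:
        raise ValidationError("configuration yields zero colon tumor samples")

    rng = np.random.default_rng(config.seed)
    n_sites, n_samples = config.n_sites, len(sheet_df)

    site_classes = np.repeat(
        SITE_CLASSES,
        [config.n_specific, config.n_pancancer, config.n_background, config.n_neutral],
    )
    site_ids = [f"cg{i:08d}" for i in range(n_sites)]

    # annotation: one synthetic chromosome, fixed spacing, gene per block
    eligible = np.isin(site_classes, ("specific", "pancancer"))
    other = ~eligible
    eligible = eligible | (other & (rng.random(n_sites) < config.eligible_frac))
    ann_df = pd.DataFrame(
        {
            "site_id": site_ids,
            "chrom": "chr1",
            "pos": 1 + config.spacing * np.arange(n_sites),
            "gene": [f"G{i // config.block_size:05d}" for i in range(n_sites)],
            "eligible_gene": eligible,
        }
    )

    # latent Gaussian field with block factors, mapped through Beta quantiles
    z = np.empty((n_sites, n_samples))
    sr, se = math.sqrt(config.rho), math.sqrt(1.0 - config.rho)
    for start in range(0, n_sites, config.block_size):
        stop = min(start + config.block_size, n_sites)
        g = rng.standard_normal(n_samples)
        e = rng.standard_normal((stop - start, n_samples))
        z[start:stop] = sr * g + se * e
    u = ndtr(z)
    # keep the quantile map away from the exact endpoints
    np.clip(u, 1e-12, 1.0 - 1e-12, out=u)

    contexts = np.array(
        [_context(t, s) for t, s in zip(sheet_df["cancer_type"], sheet_df["tissue_state"])]
    )
    beta = np.empty_like(u)
    for cls in SITE_CLASSES:
        ridx = site_classes == cls
        if not ridx.any():
            continue
        for ctx in CONTEXTS:
            cidx = contexts == ctx
            if not cidx.any():
                continue
            a, b = config.beta_params[(cls, ctx)]
            beta[np.ix_(ridx, cidx)] = betaincinv(a, b, u[np.ix_(ridx, cidx)])

    if config.cimp_shift != 0.0:
        cimp_h = (
            (sheet_df["cimp"] == "H")
            & (sheet_df["tissue_state"] == "tumor")
            & sheet_df["cancer_type"].isin(COLORECTAL_TYPES)
        ).to_numpy()
        spec = site_classes == "specific"
        block = beta[np.ix_(spec, cimp_h)] + config.cimp_shift
        beta[np.ix_(spec, cimp_h)] = np.clip(block, 0.0, 1.0)

    matrix = BetaMatrix(
        pd.DataFrame(beta, index=site_ids, columns=list(sheet_df["sample_id"]))
    )
    truth = SiteTruth(dict(zip(site_ids, site_classes)))
    return StudyBundle(
        matrix=matrix,
        sheet=SampleSheet(sheet_df),
        annotation=SiteAnnotation(ann_df),
        truth=truth,
    )
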