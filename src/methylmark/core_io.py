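"""Domain types and TSV readers/writers for methylation-array studies.

The central object is the beta-value matrix: CpG sites in rows, samples in
columns, entries the methylation level beta = M / (M + U) in [0, 1], with
"NA" marking missing entries.  Sample sheets and site annotations carry the
per-sample and per-site metadata the downstream screens need (cohort
membership, tumor/normal state, CIMP and stage labels; genomic coordinates
and candidate-gene eligibility).

Files are plain tab-separated text.  Beta values are written with fixed
6-decimal formatting so that write -> read -> write is byte-stable.
"""

from __future__ import annotations

import dataclasses
import io
import os
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

__all__ = [
    "ValidationError",
    "BetaMatrix",
    "SampleSheet",
    "SiteAnnotation",
    "CascadeParams",
    "read_beta_matrix",
    "write_beta_matrix",
    "read_sample_sheet",
    "write_sample_sheet",
    "read_site_annotation",
    "write_site_annotation",
]

NA_TOKEN = "NA"
TISSUE_STATES = frozenset({"tumor", "normal"})
STAGES = frozenset({"I", "II", "III", "IV", NA_TOKEN})
CIMP_LEVELS = frozenset({"H", "L", NA_TOKEN})
#: cancer_type labels reserved for non-cancer reference cohorts
REFERENCE_TYPES = frozenset({"NORMAL_TISSUE", "BLOOD"})
#: colorectal cancer_type labels (colon context in screens and profiling)
COLORECTAL_TYPES = frozenset({"COAD", "READ"})

SHEET_COLUMNS = ["sample_id", "cohort_id", "cancer_type", "tissue_state", "stage", "cimp"]
ANNOTATION_COLUMNS = ["site_id", "chrom", "pos", "gene", "eligible_gene"]


class ValidationError(ValueError):
    """A file or in-memory object violates a domain invariant."""


def _check_unique(ids, what: str) -> None:
    seen = set()
    for x in ids:
        if x in seen:
            raise ValidationError(f"duplicate {what}: {x!r}")
        seen.add(x)


class BetaMatrix:
    """Sites x samples matrix of beta values in [0, 1], NaN = missing.

    Wraps a float ``pandas.DataFrame`` whose index is the ordered site ids
    and whose columns are the ordered sample ids; both must be unique and
    every non-missing entry must lie in [0, 1].
    """

    def __init__(self, values: pd.DataFrame):
        if values.index.has_duplicates:
            dup = values.index[values.index.duplicated()][0]
            raise ValidationError(f"duplicate site_id: {dup!r}")
        if values.columns.has_duplicates:
            dup = values.columns[values.columns.duplicated()][0]
            raise ValidationError(f"duplicate sample_id: {dup!r}")
        vals = values.astype(float)
        arr = vals.to_numpy()
        bad = (arr < 0.0) | (arr > 1.0)
        if bad.any():
            i, j = np.argwhere(bad)[0]
            raise ValidationError(
                f"beta value {arr[i, j]!r} outside [0, 1] at site "
                f"{vals.index[i]!r}, sample {vals.columns[j]!r}"
            )
        self.values = vals

    @property
    def site_ids(self) -> list:
        return list(self.values.index)

    @property
    def sample_ids(self) -> list:
        return list(self.values.columns)

    @property
    def shape(self) -> tuple[int, int]:
        return self.values.shape

    def subset(self, sites=None, samples=None) -> "BetaMatrix":
        df = self.values
        if sites is not None:
            missing = [s for s in sites if s not in df.index]
            if missing:
                raise KeyError(f"site id(s) absent from matrix: {missing[:5]}")
            df = df.loc[list(sites)]
        if samples is not None:
            missing = [s for s in samples if s not in df.columns]
            if missing:
                raise KeyError(f"sample id(s) absent from matrix: {missing[:5]}")
            df = df[list(samples)]
        return BetaMatrix(df.copy())

    def equals(self, other: "BetaMatrix") -> bool:
        return self.values.equals(other.values)


@dataclass(frozen=True)
class SampleSheet:
    """Per-sample metadata table.

    One row per sample: cohort_id, cancer_type (COAD, READ, one of the other
    TCGA-style tumor abbreviations, or the reference labels NORMAL_TISSUE /
    BLOOD), tissue_state in {tumor, normal}, stage in {I..IV, NA}, cimp in
    {H, L, NA}.  Reference cohorts may contain only normal samples.
    """

    table: pd.DataFrame

    def __post_init__(self):
        df = self.table
        missing_cols = [c for c in SHEET_COLUMNS if c not in df.columns]
        if missing_cols:
            raise ValidationError(f"sample sheet missing column(s): {missing_cols}")
        _check_unique(df["sample_id"], "sample_id")
        bad_state = set(df["tissue_state"]) - TISSUE_STATES
        if bad_state:
            raise ValidationError(
                f"tissue_state must be one of {sorted(TISSUE_STATES)}; got {sorted(bad_state)}"
            )
        bad_stage = set(df["stage"]) - STAGES
        if bad_stage:
            raise ValidationError(f"stage must be in {sorted(STAGES)}; got {sorted(bad_stage)}")
        bad_cimp = set(df["cimp"]) - CIMP_LEVELS
        if bad_cimp:
            raise ValidationError(f"cimp must be in {sorted(CIMP_LEVELS)}; got {sorted(bad_cimp)}")
        ref = df[df["cancer_type"].isin(REFERENCE_TYPES)]
        if (ref["tissue_state"] != "normal").any():
            bad = ref.loc[ref["tissue_state"] != "normal", "sample_id"].iloc[0]
            raise ValidationError(
                f"reference-cohort sample {bad!r} has tissue_state != normal"
            )
        object.__setattr__(self, "table", df.reset_index(drop=True))

    def select(self, **criteria) -> list:
        """Sample ids matching column == value for every given criterion.

        A criterion value may be a scalar or a collection (membership test).
        """
        mask = pd.Series(True, index=self.table.index)
        for col, val in criteria.items():
            if col not in self.table.columns:
                raise KeyError(f"unknown sample-sheet column: {col!r}")
            if isinstance(val, (list, tuple, set, frozenset)):
                mask &= self.table[col].isin(val)
            else:
                mask &= self.table[col] == val
        return list(self.table.loc[mask, "sample_id"])

    @property
    def cohort_ids(self) -> list:
        return list(dict.fromkeys(self.table["cohort_id"]))


@dataclass(frozen=True)
class SiteAnnotation:
    """Per-site genomic annotation: chromosome, 1-based position, gene symbol
    (or NA) and a boolean flag marking membership in the candidate gene set."""

    table: pd.DataFrame

    def __post_init__(self):
        df = self.table
        missing_cols = [c for c in ANNOTATION_COLUMNS if c not in df.columns]
        if missing_cols:
            raise ValidationError(f"site annotation missing column(s): {missing_cols}")
        _check_unique(df["site_id"], "site_id")
        pos = pd.to_numeric(df["pos"], errors="raise")
        if (pos < 1).any():
            bad = df.loc[pos < 1, "site_id"].iloc[0]
            raise ValidationError(f"position must be 1-based (>= 1); site {bad!r}")
        df = df.assign(pos=pos.astype(int), eligible_gene=df["eligible_gene"].astype(bool))
        object.__setattr__(self, "table", df.reset_index(drop=True))

    @property
    def site_ids(self) -> list:
        return list(self.table["site_id"])

    def eligible_sites(self) -> list:
        t = self.table
        return list(t.loc[t["eligible_gene"], "site_id"])

    def coords(self, site_id):
        row = self.table.loc[self.table["site_id"] == site_id]
        if row.empty:
            raise KeyError(f"site {site_id!r} not annotated")
        r = row.iloc[0]
        return r["chrom"], int(r["pos"])


@dataclass(frozen=True)
class CascadeParams:
    """Thresholds of the marker-selection cascade.

    delta_min : minimum tumor-normal mean-beta difference to call a site
        hypermethylated (effect-size gate).
    q_max : Benjamini-Hochberg FDR ceiling for the rank-sum screen.
    tau_bg : background ceiling — a candidate whose mean beta exceeds this in
        any normal-tissue/blood reference cohort is discarded (strict >).
    tau_spec : pan-cancer ceiling — same rule against the tumor samples of
        every other cancer type.
    missing_max : maximum tolerated missing fraction per site per group.
    """

    delta_min: float = 0.2
    q_max: float = 0.05
    tau_bg: float = 0.1
    tau_spec: float = 0.1
    missing_max: float = 0.2

    def __post_init__(self):
        for f in dataclasses.fields(self):
            v = getattr(self, f.name)
            if not (0.0 <= v <= 1.0):
                raise ValidationError(f"{f.name}={v} outside [0, 1]")


# ---------------------------------------------------------------------------
# readers / writers


def read_beta_matrix(path) -> BetaMatrix:
    """Read a sites x samples TSV (first column site ids, header sample ids,
    missing token "NA") into a validated :class:`BetaMatrix`."""
    df = pd.read_csv(
        path, sep="\t", index_col=0, na_values=[NA_TOKEN], keep_default_na=False
    )
    try:
        df = df.astype(float)
    except ValueError as e:
        raise ValidationError(f"non-numeric beta value in {path}: {e}") from e
    return BetaMatrix(df)


def write_beta_matrix(matrix: BetaMatrix, path) -> None:
    """Write a beta matrix as TSV with fixed 6-decimal values, "NA" missing."""
    matrix.values.to_csv(
        path,
        sep="\t",
        index_label="site_id",
        float_format="%.6f",
        na_rep=NA_TOKEN,
        lineterminator="\n",
    )


def _read_tsv(path, required, what):
    df = pd.read_csv(path, sep="\t", dtype=str, keep_default_na=False)
    missing = [c for c in required if c not in df.columns]
    if missing:
        raise ValidationError(f"{what} file {path} missing column(s): {missing}")
    return df


def read_sample_sheet(path) -> SampleSheet:
    return SampleSheet(_read_tsv(path, SHEET_COLUMNS, "sample sheet")[SHEET_COLUMNS])


def write_sample_sheet(sheet: SampleSheet, path) -> None:
    sheet.table[SHEET_COLUMNS].to_csv(path, sep="\t", index=False, lineterminator="\n")


_BOOL_TOKENS = {"true": True, "false": False, "1": True, "0": False}


def read_site_annotation(path) -> SiteAnnotation:
    df = _read_tsv(path, ANNOTATION_COLUMNS, "site annotation")[ANNOTATION_COLUMNS]
    flags = []
    for raw in df["eligible_gene"]:
        key = str(raw).strip().lower()
        if key not in _BOOL_TOKENS:
            raise ValidationError(f"eligible_gene value {raw!r} is not boolean")
        flags.append(_BOOL_TOKENS[key])
    df = df.assign(eligible_gene=flags)
    return SiteAnnotation(df)


def write_site_annotation(annotation: SiteAnnotation, path) -> None:
    df = annotation.table[ANNOTATION_COLUMNS].copy()
    df["eligible_gene"] = np.where(df["eligible_gene"], "TRUE", "FALSE")
    df.to_csv(path, sep="\t", index=False, lineterminator="\n")
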