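"""File formats: peak-table CSV, cohort CSV, results TSV.

Conventions: UTF-8 CSV with header and "." decimals.  In peak tables a
below-LOD cell is an *empty* cell; in cohort files a missing covariate is
the string ``NA`` — the two kinds of missingness carry different
downstream semantics (instrument censoring vs. unobserved covariate).
Readers validate and reject rather than silently coerce; every writer
produces files its reader accepts.
"""
from __future__ import annotations

import logging
from pathlib import Path

import numpy as np
import pandas as pd

from .config import (CATEGORICAL_LEVELS, COHORT_COLUMNS, OUTCOMES)
from .preprocess import PeakTable

logger = logging.getLogger("mwaskit")

PEAK_META_COLUMNS = ["sample_id", "injection_order", "batch", "sample_type"]
RESULT_COLUMNS = ["metabolite", "target", "beta", "se", "ci_low", "ci_high",
                  "p", "q", "tier", "model", "n_used"]


class ParseError(ValueError):
    """A file violated the expected schema."""


# --------------------------------------------------------------------------
# peak tables
# --------------------------------------------------------------------------

def read_peak_table(path) -> PeakTable:
    """Read ``peak_table.csv``: metadata, ``IS_*`` channels, then features.

    Empty abundance cells are below-LOD.  ``sample_type`` is canonicalized
    (case/whitespace) before validation; violations are reported with the
    offending column or value.
    """
    df = pd.read_csv(path, dtype={"sample_id": str, "batch": str})
    for col in PEAK_META_COLUMNS:
        if col not in df.columns:
            raise ParseError(f"peak table missing required column {col!r}")
    if df["sample_id"].duplicated().any():
        dup = df.loc[df["sample_id"].duplicated(), "sample_id"].iloc[0]
        raise ParseError(f"duplicate sample_id {dup!r}")
    raw_type = df["sample_type"].astype(str)
    canon = raw_type.str.strip().str.lower()
    changed = (canon != raw_type)
    if changed.any():
        logger.warning("canonicalized %d sample_type values "
                       "(case/whitespace)", int(changed.sum()))
    bad = set(canon) - {"study", "qc", "blank"}
    if bad:
        raise ParseError(f"unknown sample_type values: {sorted(bad)}")
    order = df["injection_order"].to_numpy()
    if not (np.diff(order) > 0).all():
        raise ParseError("injection_order must be strictly increasing")

    is_cols = [c for c in df.columns if c.startswith("IS_")]
    feat_cols = [c for c in df.columns
                 if c not in PEAK_META_COLUMNS and c not in is_cols]
    df = df.set_index("sample_id")
    samples = df[["injection_order", "batch"]].copy()
    samples["sample_type"] = canon.to_numpy()
    samples["injection_order"] = samples["injection_order"].astype(int)
    return PeakTable(samples=samples,
                     abundance=df[feat_cols].astype(float),
                     is_channels=df[is_cols].astype(float))


def write_peak_table(pt: PeakTable, path) -> None:
    out = pd.concat([pt.samples, pt.is_channels, pt.abundance], axis=1)
    out.index.name = "sample_id"
    out.reset_index().to_csv(path, index=False)  # NaN -> empty cell


# --------------------------------------------------------------------------
# cohort tables
# --------------------------------------------------------------------------

def read_cohort(path) -> pd.DataFrame:
    """Read ``cohort.csv``; missing covariates are ``NA`` (empty also
    accepted); categorical levels validated against the configured coding;
    outcome columns must be complete."""
    df = pd.read_csv(path, dtype={"subject_id": str},
                     na_values=["NA"], keep_default_na=True)
    missing_cols = [c for c in COHORT_COLUMNS if c not in df.columns]
    if missing_cols:
        raise ParseError(f"cohort file missing columns: {missing_cols}")
    if df["subject_id"].duplicated().any():
        raise ParseError("duplicate subject_id values")
    for col, levels in CATEGORICAL_LEVELS.items():
        vals = df[col].dropna()
        bad = set(vals) - set(levels)
        if bad:
            raise ParseError(
                f"column {col!r} has unknown level(s) {sorted(bad)}; "
                f"allowed: {levels}")
        if len(vals) == 0 and len(df):
            logger.warning("column %r is entirely missing", col)
    for col in OUTCOMES:
        if df[col].isna().any() and len(df):
            raise ParseError(f"outcome column {col!r} has missing values")
    return df[COHORT_COLUMNS]


def write_cohort(df: pd.DataFrame, path) -> None:
    df[COHORT_COLUMNS].to_csv(path, index=False, na_rep="NA")


# --------------------------------------------------------------------------
# association results
# --------------------------------------------------------------------------

def write_results(results: pd.DataFrame, path) -> None:
    """Write association results as TSV with 12 significant digits.

    Row order is deterministic: target, then q ascending, then metabolite
    id (the tie-break on equal q).
    """
    df = results.copy()
    for col in RESULT_COLUMNS:
        if col not in df.columns:
            df[col] = np.nan
    df = df[RESULT_COLUMNS].sort_values(
        ["target", "q", "metabolite"], kind="mergesort")
    df.to_csv(path, sep="\t", index=False, float_format="%.12g")


def read_results(path) -> pd.DataFrame:
    df = pd.read_csv(path, sep="\t")
    missing = [c for c in RESULT_COLUMNS if c not in df.columns]
    if missing:
        raise ParseError(f"results file missing columns: {missing}")
    return df


def write_zscores(z: pd.DataFrame, path) -> None:
    z.rename_axis("subject_id").to_csv(path, float_format="%.12g")


def read_zscores(path) -> pd.DataFrame:
    return pd.read_csv(path, index_col="subject_id")


def write_qc_report(report: pd.DataFrame, path) -> None:
    report.rename_axis("feature").to_csv(path, sep="\t")


def ensure_dir(path) -> Path:
    p = Path(path)
    p.mkdir(parents=True, exist_ok=True)
    return p
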