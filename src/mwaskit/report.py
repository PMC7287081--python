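"""Multiplicity control, significance tiers, descriptive quintile tables,
and end-to-end run orchestration.

BH q-values are computed per outcome (one family of tests per outcome
block); q < 0.05 is "significant", 0.05 ≤ q < 0.10 a "trend".  The
descriptive engine summarizes maternal characteristics across outcome
quintiles, testing trend by regressing each continuous characteristic on
the subject's quintile-median outcome value and categorical
characteristics by a generalized Cochran–Mantel–Haenszel test.
"""
from __future__ import annotations

import dataclasses
import json
import logging
from dataclasses import dataclass
from pathlib import Path

import numpy as np
import pandas as pd
from scipy import stats

from . import io as mio
from .associate import (
    derive_clinical_flags, profile_characteristics, run_sensitivity,
    screen_metabolites_vs_outcome, test_ethnic_interaction,
)
from .config import CATEGORICAL_LEVELS, RunConfig
from .impute import generate_imputations
from .preprocess import run_preprocess

logger = logging.getLogger("mwaskit")

TIER_SIG = "significant"
TIER_TREND = "trend"
TIER_NULL = "null"


# --------------------------------------------------------------------------
# multiplicity
# --------------------------------------------------------------------------

def bh_adjust(pvalues) -> np.ndarray:
    """Benjamini–Hochberg step-up q-values.

    q_(i) = min_{j >= i} (m / j) p_(j) on the sorted vector, mapped back
    to input order and capped at 1.
    """
    p = np.asarray(pvalues, float)
    if p.size == 0:
        return p.copy()
    if np.any((p < 0) | (p > 1) | ~np.isfinite(p)):
        raise ValueError("p-values must lie in [0, 1]")
    m = p.size
    order = np.argsort(p, kind="mergesort")
    ranked = p[order] * m / np.arange(1, m + 1)
    q_sorted = np.minimum.accumulate(ranked[::-1])[::-1]
    q = np.empty(m)
    q[order] = np.minimum(q_sorted, 1.0)
    return q


def classify_significance(q, sig: float = 0.05, trend: float = 0.10):
    """Tier per q-value: significant below ``sig``, trend from ``sig``
    (inclusive) up to ``trend`` (exclusive), otherwise null."""
    qa = np.asarray(q, float)
    scalar = qa.ndim == 0
    qa = np.atleast_1d(qa)
    if np.any((qa < 0) | (qa > 1)):
        raise ValueError("q-values must lie in [0, 1]")
    out = np.where(qa < sig, TIER_SIG,
                   np.where(qa < trend, TIER_TREND, TIER_NULL))
    return out[0] if scalar else out


# --------------------------------------------------------------------------
# quintile machinery
# --------------------------------------------------------------------------

def quintile_assign(values: pd.Series) -> pd.Series:
    """Rank-based quintiles 1–5; tied outcome values share the lower
    quintile (groups of near-equal size when values are distinct)."""
    v = values.astype(float)
    n = v.notna().sum()
    if n < 5:
        raise ValueError("need at least 5 subjects for quintiles")
    rank = v.rank(method="min")
    return (((rank - 1) * 5) // n + 1).astype("Int64")


def trend_test(characteristic: pd.Series, outcome: pd.Series,
               assignment: pd.Series) -> tuple[float, float]:
    """P-trend for a continuous characteristic across outcome quintiles.

    Each subject is scored with the median outcome of their quintile and
    the characteristic is regressed on that single continuous regressor;
    returns (slope, two-sided p of the slope).
    """
    med = outcome.groupby(assignment).median()
    x = assignment.map(med).astype(float)
    keep = characteristic.notna() & x.notna()
    xv = x[keep].to_numpy(float)
    yv = characteristic[keep].to_numpy(float)
    if np.var(xv) == 0:
        raise ValueError("quintile medians have zero variance")
    if np.var(yv) == 0:
        return 0.0, 1.0           # constant characteristic: no trend
    fit = stats.linregress(xv, yv)
    return float(fit.slope), float(fit.pvalue)


def cmh_test(tables) -> tuple[float, float, int]:
    """Generalized Cochran–Mantel–Haenszel test of general association.

    Accepts one R×C contingency table or a list of them (strata).  Empty
    rows/columns (zero total across strata) are collapsed with a warning.
    No continuity correction; the statistic is compared to chi-square with
    (R−1)(C−1) df.  With a single stratum it equals (n−1)/n times the
    Pearson chi-square statistic.
    """
    if isinstance(tables, (np.ndarray, pd.DataFrame)) or (
            hasattr(tables, "__len__") and len(tables) and
            np.ndim(tables[0]) == 1):
        tables = [np.asarray(tables, float)]
    strata = [np.asarray(t, float) for t in tables]
    if any((t < 0).any() for t in strata):
        raise ValueError("contingency counts must be non-negative")
    total = sum(strata)
    keep_r = total.sum(axis=1) > 0
    keep_c = total.sum(axis=0) > 0
    if not keep_r.all() or not keep_c.all():
        logger.warning("cmh_test: collapsing %d empty row(s)/column(s)",
                       int((~keep_r).sum() + (~keep_c).sum()))
        strata = [t[np.ix_(keep_r, keep_c)] for t in strata]
    R, C = strata[0].shape
    if R < 2 or C < 2:
        raise ValueError("CMH needs at least 2 rows and 2 columns")
    df = (R - 1) * (C - 1)
    G = np.zeros(df)
    V = np.zeros((df, df))
    for t in strata:
        n = t.sum()
        if n < 2:
            continue
        r = t.sum(axis=1)
        c = t.sum(axis=0)
        expected = np.outer(r, c) / n
        diff = (t - expected)[: R - 1, : C - 1].ravel()
        vr = (n * np.diag(r[: R - 1]) - np.outer(r[: R - 1], r[: R - 1]))
        vc = (n * np.diag(c[: C - 1]) - np.outer(c[: C - 1], c[: C - 1]))
        V += np.kron(vr, vc) / (n ** 2 * (n - 1))
        G += diff
    stat = float(G @ np.linalg.solve(V, G))
    return stat, float(stats.chi2.sf(stat, df)), df


@dataclass
class QuintileTable:
    outcome: str
    boundaries: pd.Series          # per-quintile outcome median (IQR rows)
    summary: pd.DataFrame          # characteristic × quintile + p_trend


#: Characteristics summarized in the descriptive table and their kind.
TABLE1_CHARACTERISTICS = [
    ("age", "continuous"), ("weight_gain", "continuous"),
    ("height", "continuous"), ("diet_score", "continuous"),
    ("ethnicity", "categorical"), ("education", "categorical"),
    ("physical_activity", "categorical"),
    ("tobacco_exposure", "categorical"), ("overweight", "binary"),
    ("parity", "categorical"), ("alcohol", "binary"), ("gdm", "binary"),
    ("hypertensive_disorders", "binary"), ("sex", "categorical"),
]


def quintile_table(cohort: pd.DataFrame, outcome: str,
                   flags: pd.DataFrame | None = None) -> QuintileTable:
    """Characteristics of participants across quintiles of one outcome."""
    coh = cohort.set_index("subject_id") if "subject_id" in cohort else cohort
    if flags is None:
        flags = derive_clinical_flags(coh)
    y = coh[outcome].astype(float)
    qq = quintile_assign(y)
    quintiles = [1, 2, 3, 4, 5]

    med = y.groupby(qq).median()
    q1 = y.groupby(qq).quantile(0.25)
    q3 = y.groupby(qq).quantile(0.75)
    boundaries = pd.Series(
        {k: f"{med[k]:.4g} ({q1[k]:.4g}-{q3[k]:.4g})" for k in quintiles},
        name=outcome)

    rows = []
    for char, kind in TABLE1_CHARACTERISTICS:
        src = flags[char] if char in flags.columns else coh[char]
        if kind == "continuous":
            vals = src.astype(float)
            cells = {f"Q{k}": f"{vals[qq == k].mean():.4g} ± "
                              f"{vals[qq == k].std(ddof=1):.3g}"
                     for k in quintiles}
            try:
                _, p = trend_test(vals, y, qq)
            except ValueError:
                p = np.nan
            rows.append({"characteristic": char, "level": "", **cells,
                         "p_trend": p, "test": "trend"})
        else:
            if kind == "binary":
                levels = [1.0, 0.0]
                obs = src.astype(float)
            else:
                levels = CATEGORICAL_LEVELS[char]
                obs = src
            keep = obs.notna()
            tab = np.zeros((len(levels), 5))
            for i, lev in enumerate(levels):
                for j, k in enumerate(quintiles):
                    tab[i, j] = int(((obs == lev) & (qq == k) & keep).sum())
            if obs[keep].nunique() < 2:
                p = 1.0            # constant characteristic: no association
            else:
                _stat, p, _ = cmh_test(tab)
            show = levels[:1] if kind == "binary" else levels
            for i, lev in enumerate(show):
                colsum = tab.sum(axis=0)
                cells = {f"Q{j + 1}": (f"{100 * tab[i, j] / colsum[j]:.3g}%"
                                       if colsum[j] else "")
                         for j in range(5)}
                rows.append({"characteristic": char, "level": str(lev),
                             **cells, "p_trend": p, "test": "cmh"})
    return QuintileTable(outcome=outcome, boundaries=boundaries,
                         summary=pd.DataFrame(rows))


# --------------------------------------------------------------------------
# orchestration
# --------------------------------------------------------------------------

def attach_tiers(res: pd.DataFrame, target: str, sig: float,
                 trend: float) -> pd.DataFrame:
    out = res.copy()
    out["q"] = bh_adjust(out["p"].to_numpy())
    out["tier"] = classify_significance(out["q"].to_numpy(), sig, trend)
    out["target"] = target
    out = out.reset_index()
    return out


def run_pipeline(cfg: RunConfig) -> dict:
    """Execute the full chain from files to result tables.

    preprocess → per-outcome MI-pooled screen → BH/tier per outcome →
    select q < fdr_select → characteristic profiling → ethnicity
    interaction/strata → sensitivity scenarios → quintile tables; writes
    TSV outputs and a machine-readable manifest.
    """
    outdir = mio.ensure_dir(cfg.outdir)
    manifest: dict = {"seed": cfg.seed, "thresholds": {
        "prevalence_min": cfg.prevalence_min, "r2_min": cfg.r2_min,
        "cv_max": cfg.cv_max, "fdr_select": cfg.fdr_select,
        "fdr_sig": cfg.fdr_sig}, "stages": []}

    def stage(name, **counts):
        manifest["stages"].append({"stage": name, **counts})

    try:
        pt = mio.read_peak_table(cfg.peak_table)
        cohort = mio.read_cohort(cfg.cohort)
        stage("read", n_injections=len(pt.samples), n_features=len(pt.features),
              n_subjects=len(cohort))

        norm = run_preprocess(pt, cfg)
        mio.write_zscores(norm.z, outdir / "zscores.csv")
        mio.write_qc_report(norm.feature_report, outdir / "qc_report.tsv")
        stage("preprocess", n_features_out=int(norm.z.shape[1]),
              **{f"n_{k}": int(v) for k, v in
                 norm.feature_report["fate"].value_counts().items()})

        coh_idx = cohort.set_index("subject_id")
        any_missing = coh_idx.isna().any().any()
        imputations = None
        if any_missing:
            imputations = generate_imputations(
                cohort, m=cfg.n_imputations, iterations=cfg.mi_iterations,
                seed=cfg.seed)
            stage("impute", m=imputations.m,
                  n_vars=len(imputations.variable_models))

        selected: list[str] = []
        per_outcome = {}
        for outcome in cfg.outcome_list:
            res = screen_metabolites_vs_outcome(
                norm.z, cohort, outcome, covariates=cfg.covariates,
                imputations=imputations)
            res = attach_tiers(res, outcome, cfg.fdr_sig, cfg.fdr_select)
            per_outcome[outcome] = res
            mio.write_results(res, outdir / f"results_{outcome}.tsv")
            picked = res.loc[res["q"] < cfg.fdr_select, "metabolite"]
            selected.extend(picked)
            stage(f"screen:{outcome}", n_tests=len(res),
                  n_significant=int((res["tier"] == TIER_SIG).sum()),
                  n_trend=int((res["tier"] == TIER_TREND).sum()),
                  n_selected=int(len(picked)))
        selected = sorted(set(selected))

        prof = profile_characteristics(norm.z, cohort, selected,
                                       imputations=imputations)
        prof_path = outdir / "fig1_matrix.tsv"
        mat = prof.assign(sign=np.sign(prof["beta"]))[
            ["metabolite", "characteristic", "beta", "sign", "q"]]
        mat.sort_values(["characteristic", "metabolite"]).to_csv(
            prof_path, sep="\t", index=False, float_format="%.12g")
        stage("profile", n_metabolites=len(selected),
              n_cells=len(prof),
              n_significant=int((prof["q"] < cfg.fdr_sig).sum())
              if len(prof) else 0)

        for outcome in cfg.outcome_list:
            inter, strata = test_ethnic_interaction(
                norm.z, cohort, outcome, covariates=cfg.covariates,
                q_threshold=cfg.fdr_sig, stratum_floor=cfg.stratum_floor)
            inter.reset_index().sort_values(["q", "metabolite"]).to_csv(
                outdir / f"interactions_{outcome}.tsv", sep="\t",
                index=False, float_format="%.12g")
            for lev, grp in strata.groupby("ethnicity"):
                grp.sort_values("metabolite").to_csv(
                    outdir / f"strata_{outcome}_{lev}.tsv", sep="\t",
                    index=False, float_format="%.12g")
            stage(f"interaction:{outcome}",
                  n_flagged=int((inter["q"] < cfg.fdr_sig).sum()),
                  n_strata_rows=len(strata))

        for scenario in cfg.sensitivity_scenarios:
            res = run_sensitivity(norm.z, cohort, cfg.sensitivity_outcome,
                                  scenario, covariates=cfg.covariates,
                                  imputations=imputations)
            res = attach_tiers(res, cfg.sensitivity_outcome, cfg.fdr_sig,
                               cfg.fdr_select)
            mio.write_results(res, outdir / f"sensitivity_{scenario}.tsv")
            stage(f"sensitivity:{scenario}",
                  n_used=int(res["n_used"].iloc[0]) if len(res) else 0,
                  n_significant=int((res["tier"] == TIER_SIG).sum()))

        flags = derive_clinical_flags(coh_idx)
        for outcome in cfg.outcome_list:
            qt = quintile_table(cohort, outcome, flags)
            qt.summary.to_csv(outdir / f"table1_{outcome}.tsv", sep="\t",
                              index=False, float_format="%.6g")
            stage(f"table1:{outcome}", n_rows=len(qt.summary))
    except Exception as err:
        manifest["failed_stage"] = f"after {manifest['stages'][-1]['stage']}" \
            if manifest["stages"] else "read"
        manifest["error"] = str(err)
        with open(outdir / "manifest.json", "w", encoding="utf-8") as fh:
            json.dump(manifest, fh, indent=2, default=str)
        raise RuntimeError(
            f"pipeline failed at stage {manifest['failed_stage']}: {err}"
        ) from err

    with open(outdir / "manifest.json", "w", encoding="utf-8") as fh:
        json.dump(manifest, fh, indent=2, default=str)
    return manifest
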