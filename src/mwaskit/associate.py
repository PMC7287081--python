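"""Adjusted per-metabolite regression screens and companion analyses.

The main screen fits, for one birth outcome, a separate linear model per
metabolite: outcome ~ metabolite z-score + the shared adjustment set
(infant sex, maternal age, parity, education, ethnicity, pre-pregnancy
BMI, weight gain to 26–28 wk, height, tobacco exposure, physical
activity, diet quality, gestational diabetes).  The per-metabolite
coefficient is obtained by exact Frisch–Waugh–Lovell residualization
(identical to full OLS, but one QR for all metabolites), which keeps
large replicate simulations cheap.  When covariates carry missingness the
screen runs once per imputed table and combines by Rubin's rules.
"""
from __future__ import annotations

import logging

import numpy as np
import pandas as pd
from scipy import stats

from .config import CATEGORICAL_LEVELS, DEFAULT_ADJUSTMENT
from .impute import ImputationSet

logger = logging.getLogger("mwaskit")

SCENARIOS = ("complete-case", "term-only", "no-hdp-gdm", "glucose-adjusted",
             "bwz-outcome")

#: Maternal characteristics used when profiling metabolites (the reverse
#: direction: metabolite z as response).  BMI enters as the overweight /
#: underweight clinical flags; ethnicity is handled one-vs-rest.
PROFILE_CHARACTERISTICS = [
    "age", "parity", "education", "overweight", "underweight",
    "weight_gain", "height", "diet_score", "physical_activity",
    "tobacco_exposure", "alcohol", "gdm",
]

_CONDITION_MAX = 1e8


class CollinearityError(ValueError):
    """Covariate block numerically collinear."""


# --------------------------------------------------------------------------
# derived clinical flags
# --------------------------------------------------------------------------

def derive_clinical_flags(cohort: pd.DataFrame) -> pd.DataFrame:
    """Deterministic clinical indicator variables.

    GDM by the WHO cutoffs (fasting ≥ 7.0 or 2-h post-load ≥ 7.8 mmol/L);
    pre-pregnancy overweight at BMI ≥ 23 kg/m² (Asian cutoff, boundary
    inclusive) and underweight below 18.5; preterm birth below 37
    completed weeks.  The birth-weight-for-GA z-score is an internal
    standardization — the residual of birth weight regressed on
    gestational age within infant sex, scaled to unit SD — substituting
    for an external population reference.
    """
    for col in ("fasting_glucose", "glucose_2h", "bmi"):
        if (cohort[col].dropna() < 0).any():
            raise ValueError(f"negative values in {col!r}")
    f, g2 = cohort["fasting_glucose"], cohort["glucose_2h"]
    pos = (f >= 7.0) | (g2 >= 7.8)           # True if either observed high
    both_obs = f.notna() & g2.notna()
    gdm = pd.Series(np.nan, index=cohort.index)
    gdm[pos.fillna(False)] = 1.0
    gdm[both_obs & ~pos.fillna(False)] = 0.0

    flags = pd.DataFrame({
        "gdm": gdm,
        "overweight": (cohort["bmi"] >= 23.0).astype(float
                                                     ).where(cohort["bmi"].notna()),
        "underweight": (cohort["bmi"] < 18.5).astype(float
                                                     ).where(cohort["bmi"].notna()),
        "preterm": (cohort["gestational_age"] < 37.0).astype(float),
    }, index=cohort.index)

    z = pd.Series(np.nan, index=cohort.index)
    for sex in cohort["sex"].dropna().unique():
        rows = cohort.index[cohort["sex"] == sex]
        ga = cohort.loc[rows, "gestational_age"].to_numpy(float)
        bw = cohort.loc[rows, "birth_weight"].to_numpy(float)
        X = np.column_stack([np.ones(len(rows)), ga])
        beta, *_ = np.linalg.lstsq(X, bw, rcond=None)
        resid = bw - X @ beta
        sd = resid.std(ddof=1) if len(rows) > 1 else 0.0
        z.loc[rows] = resid / sd if sd > 0 else 0.0
    flags["bw_for_ga_z"] = z
    return flags


# --------------------------------------------------------------------------
# design matrices
# --------------------------------------------------------------------------

def build_design(cohort: pd.DataFrame, covariates: list[str],
                 flags: pd.DataFrame | None = None) -> pd.DataFrame:
    """Numeric design for the adjustment set (no intercept column).

    Categoricals are dummy-coded against their first configured level;
    ``gdm``/``overweight``/``underweight`` come from the derived flags.
    Missing covariate cells propagate as NaN for the caller to handle.
    """
    if flags is None:
        flags = derive_clinical_flags(cohort)
    cols: dict[str, pd.Series] = {}
    for term in covariates:
        if term in CATEGORICAL_LEVELS:
            levels = CATEGORICAL_LEVELS[term]
            vals = cohort[term]
            for lev in levels[1:]:
                d = (vals == lev).astype(float)
                d[vals.isna()] = np.nan
                cols[f"{term}[{lev}]"] = d
        elif term in flags.columns:
            cols[term] = flags[term].astype(float)
        else:
            cols[term] = cohort[term].astype(float)
    return pd.DataFrame(cols, index=cohort.index)


def _prune_and_check(D: pd.DataFrame, label: str) -> np.ndarray:
    """Drop design columns constant on the analysis rows (an unobserved
    category level), then reject a genuinely collinear block."""
    sd = D.std(axis=0, ddof=0)
    dead = list(sd.index[sd == 0])
    if dead:
        logger.warning("dropping constant design column(s) %s in %s block",
                       dead, label)
        D = D.drop(columns=dead)
    X = D.to_numpy(float)
    cond = np.linalg.cond((X - X.mean(axis=0)) / X.std(axis=0))
    if cond > _CONDITION_MAX:
        raise CollinearityError(
            f"covariate block {label!r} is collinear (condition number "
            f"{cond:.3g} > {_CONDITION_MAX:g})")
    return X


# --------------------------------------------------------------------------
# Frisch–Waugh–Lovell multi-response screen
# --------------------------------------------------------------------------

def _fwl_screen(y: np.ndarray, Z: np.ndarray, X: np.ndarray, alpha=0.05):
    """Per-column slope of y on [X, Z[:, j]] for every j, by exact FWL.

    Returns arrays (beta, variance, se, p, ci_low, ci_high, df).
    """
    n = len(y)
    Xi = np.column_stack([np.ones(n), X])
    Q, _ = np.linalg.qr(Xi)
    r_y = y - Q @ (Q.T @ y)
    R_Z = Z - Q @ (Q.T @ Z)
    d = (R_Z ** 2).sum(axis=0)
    df = n - Xi.shape[1] - 1
    with np.errstate(divide="ignore", invalid="ignore"):
        beta = (R_Z.T @ r_y) / d
        rss = np.maximum((r_y @ r_y) - beta ** 2 * d, 0.0)
        sigma2 = rss / df
        var = sigma2 / d
        se = np.sqrt(var)
        tval = beta / se
    p = 2 * stats.t.sf(np.abs(tval), df)
    crit = stats.t.ppf(1 - alpha / 2, df)
    return beta, var, se, p, beta - crit * se, beta + crit * se, df


def screen_metabolites_vs_outcome(
        z: pd.DataFrame, cohort: pd.DataFrame, outcome: str,
        covariates: list[str] | None = None,
        imputations: ImputationSet | None = None,
        outcome_values: pd.Series | None = None,
        model_tag: str = "main") -> pd.DataFrame:
    """Adjusted per-metabolite linear screen against one birth outcome.

    Without imputations, rows with any missing covariate are dropped
    (complete case).  With an :class:`ImputationSet`, the screen is fitted
    on every completed table and Rubin-pooled per metabolite.  Returns a
    frame indexed by metabolite with beta (outcome units per SD), se, CI,
    p, n_used, df and the model tag.
    """
    covariates = covariates or DEFAULT_ADJUSTMENT
    cohort = cohort.set_index("subject_id") if "subject_id" in cohort else cohort
    common = z.index.intersection(cohort.index)
    if len(common) == 0:
        raise ValueError("no subjects shared between z-scores and cohort")
    z = z.loc[common]
    cohort = cohort.loc[common]
    y_all = (outcome_values.loc[common] if outcome_values is not None
             else cohort[outcome]).astype(float)

    if imputations is None:
        D = build_design(cohort, covariates)
        keep = D.notna().all(axis=1) & y_all.notna()
        X = _prune_and_check(D.loc[keep], ",".join(covariates))
        beta, var, se, p, lo, hi, df = _fwl_screen(
            y_all.loc[keep].to_numpy(float), z.loc[keep].to_numpy(float), X)
        return pd.DataFrame({
            "beta": beta, "se": se, "ci_low": lo, "ci_high": hi, "p": p,
            "df": float(df), "n_used": int(keep.sum()), "model": model_tag,
        }, index=z.columns.rename("metabolite"))

    est, var = [], []
    n_used = None
    for table in imputations.tables:
        t = table.set_index("subject_id") if "subject_id" in table else table
        t = t.loc[common]
        D = build_design(t, covariates)
        if D.isna().any().any():
            raise ValueError("imputed tables must be complete for the "
                             "covariate set")
        X = _prune_and_check(D, ",".join(covariates))
        y = (outcome_values.loc[common] if outcome_values is not None
             else t[outcome]).to_numpy(float)
        b, v, *_ = _fwl_screen(y, z.to_numpy(float), X)
        est.append(b)
        var.append(v)
        n_used = len(t)
    est = np.vstack(est)          # m × n_metabolites
    var = np.vstack(var)
    m = est.shape[0]
    qbar = est.mean(axis=0)
    w = var.mean(axis=0)
    b_var = est.var(axis=0, ddof=1)
    t_var = w + (1 + 1 / m) * b_var
    se = np.sqrt(t_var)
    with np.errstate(divide="ignore", invalid="ignore"):
        dfree = np.where(b_var > 0,
                         (m - 1) * (1 + w / ((1 + 1 / m) * b_var)) ** 2,
                         np.inf)
        tstat = qbar / se
    p = 2 * stats.t.sf(np.abs(tstat), dfree)
    crit = stats.t.ppf(0.975, dfree)
    return pd.DataFrame({
        "beta": qbar, "se": se, "ci_low": qbar - crit * se,
        "ci_high": qbar + crit * se, "p": p, "df": dfree,
        "n_used": n_used, "model": model_tag,
    }, index=z.columns.rename("metabolite"))


# --------------------------------------------------------------------------
# metabolite ~ characteristics profiling
# --------------------------------------------------------------------------

def _multifit(Y: np.ndarray, X: np.ndarray):
    """OLS of every column of Y on X; returns beta (p×k), se (p×k), p."""
    n, p = X.shape
    XtX_inv = np.linalg.inv(X.T @ X)
    B = XtX_inv @ X.T @ Y
    resid = Y - X @ B
    df = n - p
    sigma2 = (resid ** 2).sum(axis=0) / df
    se = np.sqrt(np.outer(np.diag(XtX_inv), sigma2))
    with np.errstate(divide="ignore", invalid="ignore"):
        tval = B / se
    pval = 2 * stats.t.sf(np.abs(tval), df)
    return B, se, pval, df


def profile_characteristics(z: pd.DataFrame, cohort: pd.DataFrame,
                            metabolites: list[str] | None = None,
                            imputations: ImputationSet | None = None,
                            ) -> pd.DataFrame:
    """Model each selected metabolite's z-score on maternal characteristics.

    One multivariable model per metabolite with all characteristics as
    predictors; ethnicity is profiled through three one-vs-rest refits,
    each replacing the 3-level factor by a single indicator while keeping
    the other characteristics.  Characteristics with a single observed
    level are dropped (logged).  q-values are BH-adjusted within each
    characteristic across metabolites.
    """
    from .report import bh_adjust  # local import avoids a module cycle

    metabolites = list(metabolites if metabolites is not None else z.columns)
    if not metabolites:
        return pd.DataFrame(columns=["metabolite", "characteristic", "beta",
                                     "se", "p", "q", "n_used", "model"])
    cohort = cohort.set_index("subject_id") if "subject_id" in cohort else cohort
    common = z.index.intersection(cohort.index)
    z = z.loc[common, metabolites]
    cohort = cohort.loc[common]

    tables = (imputations.tables if imputations is not None else [cohort])
    per_imp: list[pd.DataFrame] = []
    for table in tables:
        t = table.set_index("subject_id") if "subject_id" in table else table
        t = t.loc[common]
        flags = derive_clinical_flags(t)
        chars = []
        for c in PROFILE_CHARACTERISTICS:
            src = flags[c] if c in flags.columns else t[c]
            if src.dropna().nunique() < 2:
                logger.info("profiling: characteristic %r has a single "
                            "observed level; dropped", c)
                continue
            chars.append(c)
        D = build_design(t, chars + ["ethnicity"], flags)
        keep = D.notna().all(axis=1)
        Dk = D.loc[keep]
        const = Dk.columns[Dk.std(axis=0, ddof=0) == 0]
        if len(const):
            logger.warning("profiling: dropping constant design column(s) %s",
                           list(const))
            Dk = Dk.drop(columns=const)
        base_cols = [c for c in Dk.columns if not c.startswith("ethnicity[")]
        Y = z.loc[keep].to_numpy(float)
        rows = []
        Xb = np.column_stack([np.ones(len(Dk)), Dk.to_numpy(float)])
        names = ["(Intercept)"] + list(Dk.columns)
        B, SE, P, _ = _multifit(Y, Xb)
        for j, name in enumerate(names):
            if name == "(Intercept)" or name.startswith("ethnicity["):
                continue
            for k, met in enumerate(metabolites):
                rows.append((met, name, B[j, k], SE[j, k], P[j, k]))
        # one-vs-rest ethnicity refits
        for lev in CATEGORICAL_LEVELS["ethnicity"]:
            ind = (t["ethnicity"] == lev).astype(float)
            Xe = np.column_stack([
                np.ones(len(Dk)), ind.loc[keep].to_numpy(),
                Dk[base_cols].to_numpy(float)])
            Be, SEe, Pe, _ = _multifit(Y, Xe)
            for k, met in enumerate(metabolites):
                rows.append((met, f"ethnicity:{lev}", Be[1, k], SEe[1, k],
                             Pe[1, k]))
        per_imp.append(pd.DataFrame(
            rows, columns=["metabolite", "characteristic", "beta", "se", "p"]
        ).assign(n_used=int(keep.sum())))

    if len(per_imp) == 1:
        res = per_imp[0]
    else:
        stacked = pd.concat(per_imp, keys=range(len(per_imp)))
        grp = stacked.groupby(["metabolite", "characteristic"], sort=False)
        m = len(per_imp)
        qbar = grp["beta"].mean()
        w = grp["se"].apply(lambda s: (s ** 2).mean())
        b = grp["beta"].var(ddof=1)
        t_var = w + (1 + 1 / m) * b
        se = np.sqrt(t_var)
        dfree = np.where(b > 0, (m - 1) * (1 + w / ((1 + 1 / m) * b)) ** 2,
                         np.inf)
        p = 2 * stats.t.sf(np.abs(qbar / se), dfree)
        res = pd.DataFrame({"beta": qbar, "se": se, "p": p}).reset_index()
        res["n_used"] = per_imp[0]["n_used"].iloc[0]
    res["q"] = np.nan
    for char, idx in res.groupby("characteristic").groups.items():
        res.loc[idx, "q"] = bh_adjust(res.loc[idx, "p"].to_numpy())
    res["model"] = "profile"
    return res.reset_index(drop=True)


# --------------------------------------------------------------------------
# ethnicity interaction and stratification
# --------------------------------------------------------------------------

def test_ethnic_interaction(z: pd.DataFrame, cohort: pd.DataFrame,
                            outcome: str,
                            covariates: list[str] | None = None,
                            q_threshold: float = 0.05,
                            stratum_floor: int = 30,
                            ) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Joint 2-df test of ethnicity × metabolite product terms.

    Per metabolite, the main model is extended with the two products of
    the metabolite z-score and the non-reference ethnicity dummies; the
    interaction block is tested jointly (F statistic, the finite-sample
    Wald test).  Metabolites with BH-adjusted interaction q below
    ``q_threshold`` are refitted within each ethnic stratum (ethnicity
    removed from the covariates); strata below ``stratum_floor`` subjects
    are skipped with a log message.
    """
    from .report import bh_adjust

    covariates = covariates or DEFAULT_ADJUSTMENT
    cohort = cohort.set_index("subject_id") if "subject_id" in cohort else cohort
    common = z.index.intersection(cohort.index)
    z = z.loc[common]
    cohort = cohort.loc[common]
    if cohort["ethnicity"].dropna().nunique() < 2:
        raise ValueError("interaction test needs >= 2 ethnic groups")

    D = build_design(cohort, covariates)
    y_all = cohort[outcome].astype(float)
    keep = D.notna().all(axis=1) & y_all.notna()
    X = np.column_stack([
        np.ones(int(keep.sum())),
        _prune_and_check(D.loc[keep], ",".join(covariates))])
    y = y_all.loc[keep].to_numpy(float)
    eth = cohort.loc[keep, "ethnicity"]
    dums = [(eth == lev).astype(float).to_numpy()
            for lev in CATEGORICAL_LEVELS["ethnicity"][1:]]

    rows = []
    for met in z.columns:
        zz = z.loc[keep, met].to_numpy(float)
        Xf = np.column_stack([X, zz] + [zz * d for d in dums])
        n, pdim = Xf.shape
        XtX_inv = np.linalg.inv(Xf.T @ Xf)
        beta = XtX_inv @ Xf.T @ y
        resid = y - Xf @ beta
        df = n - pdim
        sigma2 = resid @ resid / df
        k = len(dums)
        sel = slice(pdim - k, pdim)
        V = sigma2 * XtX_inv[sel, sel]
        b_int = beta[sel]
        F = float(b_int @ np.linalg.solve(V, b_int)) / k
        p = float(stats.f.sf(F, k, df))
        rows.append((met, F, p, int(n)))
    res = pd.DataFrame(rows, columns=["metabolite", "F", "p", "n_used"]
                       ).set_index("metabolite")
    res["q"] = bh_adjust(res["p"].to_numpy())

    strata_rows = []
    cov_no_eth = [c for c in covariates if c != "ethnicity"]
    for met in res.index[res["q"] < q_threshold]:
        for lev in CATEGORICAL_LEVELS["ethnicity"]:
            sub = cohort.index[cohort["ethnicity"] == lev]
            if len(sub) < stratum_floor:
                logger.info("stratum %s has n=%d < floor %d; skipped",
                            lev, len(sub), stratum_floor)
                continue
            scr = screen_metabolites_vs_outcome(
                z.loc[z.index.intersection(sub), [met]],
                cohort.loc[sub].reset_index(), outcome,
                covariates=cov_no_eth, model_tag=f"stratum:{lev}")
            r = scr.iloc[0]
            strata_rows.append((met, lev, r["beta"], r["se"], r["ci_low"],
                                r["ci_high"], r["p"], r["n_used"]))
    strata = pd.DataFrame(strata_rows, columns=[
        "metabolite", "ethnicity", "beta", "se", "ci_low", "ci_high", "p",
        "n_used"])
    return res, strata


# --------------------------------------------------------------------------
# sensitivity battery
# --------------------------------------------------------------------------

def run_sensitivity(z: pd.DataFrame, cohort: pd.DataFrame, outcome: str,
                    scenario: str, covariates: list[str] | None = None,
                    imputations: ImputationSet | None = None,
                    ) -> pd.DataFrame:
    """Re-run the screen under one sensitivity scenario.

    ``complete-case``: subjects with no missing covariate, no imputation.
    ``term-only``: births at ≥ 37 wk (never applied to the gestational-age
    outcome itself).  ``no-hdp-gdm``: excludes hypertensive disorders and
    gestational diabetes (missing GDM excluded too).  ``glucose-adjusted``:
    fasting and 2-h glucose replace the GDM flag.  ``bwz-outcome``: the
    internally standardized birth-weight-for-GA z-score as outcome.
    """
    covariates = list(covariates or DEFAULT_ADJUSTMENT)
    if scenario not in SCENARIOS:
        raise ValueError(f"unknown scenario {scenario!r}; "
                         f"choose from {SCENARIOS}")
    coh = cohort.set_index("subject_id") if "subject_id" in cohort else cohort
    flags = derive_clinical_flags(coh)
    outcome_values = None
    imp = imputations

    if scenario == "complete-case":
        D = build_design(coh, covariates, flags)
        coh = coh.loc[D.notna().all(axis=1)]
        imp = None
    elif scenario == "term-only":
        if outcome != "gestational_age":
            coh = coh.loc[coh["gestational_age"] >= 37.0]
    elif scenario == "no-hdp-gdm":
        ok = (coh["hypertensive_disorders"] == 0) & (flags["gdm"] == 0)
        coh = coh.loc[ok.fillna(False)]
    elif scenario == "glucose-adjusted":
        covariates = [c for c in covariates if c != "gdm"] + \
            ["fasting_glucose", "glucose_2h"]
    elif scenario == "bwz-outcome":
        outcome_values = flags["bw_for_ga_z"]

    if imp is not None:
        sub = coh.index
        tables = []
        for t in imp.tables:
            ti = t.set_index("subject_id") if "subject_id" in t else t
            tables.append(ti.loc[ti.index.intersection(sub)].reset_index())
        imp = ImputationSet(tables=tables, iterations=imp.iterations,
                            seed=imp.seed,
                            variable_models=imp.variable_models)
    res = screen_metabolites_vs_outcome(
        z.loc[z.index.intersection(coh.index)], coh.reset_index(), outcome,
        covariates=covariates, imputations=imp,
        outcome_values=outcome_values, model_tag=f"sensitivity:{scenario}")
    return res
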