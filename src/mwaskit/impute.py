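"""Multiple imputation of maternal covariates and Rubin's-rules pooling.

A chained-equations sampler fills missing covariate cells: a Bayesian
linear draw for continuous variables, and logistic / multinomial-logistic
category draws for binary / multi-level variables.  Parameter uncertainty
is propagated by fitting each variable's model on a bootstrap resample of
the observed rows (the "boot" flavour of chained equations), and
predictive noise is always included, so draws are posterior-predictive
rather than conditional means.  The imputation model uses all analysis
covariates plus the outcomes as predictors, keeping it congenial with the
analysis models.
"""
from __future__ import annotations

import logging
import math
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats

from .config import (BINARY_COVARIATES, CATEGORICAL_LEVELS,
                     COVARIATE_COLUMNS, OUTCOMES, seed_sequence)

logger = logging.getLogger("mwaskit")


@dataclass
class ImputationSet:
    tables: list[pd.DataFrame]
    iterations: int
    seed: int
    variable_models: dict[str, str] = field(default_factory=dict)

    @property
    def m(self) -> int:
        return len(self.tables)


@dataclass
class PooledEstimate:
    """Rubin's-rules combination of m per-imputation fits.

    Q̄ = mean estimate, W = mean within-imputation variance, B = sample
    variance of the estimates, T = W + (1 + 1/m)B, SE = √T, and
    ν = (m−1)(1 + W/((1+1/m)B))² degrees of freedom (normal limit when
    B = 0).
    """
    estimate: float
    within: float
    between: float
    total: float
    df: float
    se: float
    ci_low: float
    ci_high: float
    p: float
    m: int


def pool_rubin(fits: list[tuple[float, float]], alpha: float = 0.05,
               ) -> PooledEstimate:
    """Pool ``(estimate, variance)`` pairs from m analyses of imputed data."""
    if len(fits) < 2:
        raise ValueError("Rubin pooling needs at least 2 fits")
    est = np.array([f[0] for f in fits], float)
    var = np.array([f[1] for f in fits], float)
    if not (np.isfinite(est).all() and np.isfinite(var).all()):
        raise ValueError("non-finite estimates or variances")
    m = len(est)
    qbar = float(est.mean())
    w = float(var.mean())
    b = float(est.var(ddof=1))
    t = w + (1 + 1 / m) * b
    se = math.sqrt(t)
    if b > 0:
        df = (m - 1) * (1 + w / ((1 + 1 / m) * b)) ** 2
        crit = stats.t.ppf(1 - alpha / 2, df)
        p = 2 * stats.t.sf(abs(qbar) / se, df) if se > 0 else (
            0.0 if qbar != 0 else 1.0)
    else:
        df = math.inf
        crit = stats.norm.ppf(1 - alpha / 2)
        p = 2 * stats.norm.sf(abs(qbar) / se) if se > 0 else (
            0.0 if qbar != 0 else 1.0)
    return PooledEstimate(estimate=qbar, within=w, between=b, total=t,
                          df=df, se=se, ci_low=qbar - crit * se,
                          ci_high=qbar + crit * se, p=float(p), m=m)


# --------------------------------------------------------------------------
# chained equations
# --------------------------------------------------------------------------

_MULTILEVEL = {k: v for k, v in CATEGORICAL_LEVELS.items() if len(v) > 2}
_TWOLEVEL = {k: v for k, v in CATEGORICAL_LEVELS.items() if len(v) == 2}


def _model_type(var: str) -> str:
    if var in _MULTILEVEL:
        return "multinomial"
    if var in _TWOLEVEL or var in BINARY_COVARIATES:
        return "logistic"
    return "linear"


def _encode(df: pd.DataFrame, columns: list[str]) -> np.ndarray:
    """Reference-coded numeric design from a complete working table."""
    parts = [np.ones((len(df), 1))]
    for col in columns:
        if col in CATEGORICAL_LEVELS:
            levels = CATEGORICAL_LEVELS[col]
            for lev in levels[1:]:
                parts.append((df[col].to_numpy() == lev
                              ).astype(float)[:, None])
        else:
            parts.append(df[col].to_numpy(float)[:, None])
    return np.hstack(parts)


def _softmax(a: np.ndarray) -> np.ndarray:
    a = a - a.max(axis=1, keepdims=True)
    e = np.exp(a)
    return e / e.sum(axis=1, keepdims=True)


def _fit_multinomial(X: np.ndarray, y_idx: np.ndarray, n_classes: int,
                     n_iter: int = 30, ridge: float = 1e-4) -> np.ndarray:
    """Ridge-regularized multinomial logistic fit by Newton steps
    (per-class diagonal-block approximation); returns coef (p × K)."""
    n, p = X.shape
    W = np.zeros((p, n_classes))
    Y = np.eye(n_classes)[y_idx]
    for _ in range(n_iter):
        P = _softmax(X @ W)
        G = X.T @ (P - Y) / n + ridge * W
        if np.abs(G).max() < 1e-8:
            break
        step = np.empty_like(W)
        for k in range(n_classes):
            wk = P[:, k] * (1 - P[:, k]) + 1e-9
            H = (X * wk[:, None]).T @ X / n + ridge * np.eye(p)
            step[:, k] = np.linalg.solve(H, G[:, k])
        W -= step
    return W


def _draw_continuous(Xo, yo, Xm, rng):
    # Xo/yo are a bootstrap resample, so the fitted coefficients are
    # themselves a draw from the approximate parameter posterior; the
    # min-norm lstsq solution stays bounded on aliased designs.
    n, p = Xo.shape
    beta, *_ = np.linalg.lstsq(Xo, yo, rcond=None)
    resid = yo - Xo @ beta
    dof = max(n - p, 1)
    sigma2 = float(resid @ resid) / dof
    sigma2_draw = sigma2 * dof / rng.chisquare(dof)
    return Xm @ beta + rng.normal(0.0, math.sqrt(sigma2_draw), len(Xm))


def _draw_categorical(Xo, yo_idx, Xm, n_classes, rng):
    W = _fit_multinomial(Xo, yo_idx, n_classes)
    P = _softmax(Xm @ W)
    u = rng.random(len(Xm))
    return (P.cumsum(axis=1) > u[:, None]).argmax(axis=1)


def generate_imputations(cohort: pd.DataFrame, m: int = 20,
                         iterations: int = 10, seed: int = 0,
                         ) -> ImputationSet:
    """Produce ``m`` completed cohort tables by chained equations.

    Observed cells are invariant across imputations; with no missing cells
    the m tables are identical to the input.  Each imputation is an
    independent chain (own child seed) with ``iterations`` burn-in sweeps.
    """
    miss_cols = [c for c in COVARIATE_COLUMNS if cohort[c].isna().any()]
    for c in miss_cols:
        if cohort[c].notna().sum() == 0:
            raise ValueError(f"variable {c!r} is 100% missing")
    if cohort[OUTCOMES].isna().any().any():
        raise ValueError("outcomes must be complete before imputation")
    models = {c: _model_type(c) for c in miss_cols}
    if not miss_cols:
        return ImputationSet(tables=[cohort.copy() for _ in range(m)],
                             iterations=iterations, seed=seed,
                             variable_models=models)

    rngs = [np.random.default_rng(s)
            for s in seed_sequence(seed).spawn(m)]
    predictors = COVARIATE_COLUMNS + OUTCOMES
    tables = []
    for chain, rng in enumerate(rngs):
        work = cohort.copy()
        # initialize missing cells from the observed marginal
        for c in miss_cols:
            obs = work[c].dropna().to_numpy()
            hole = work[c].isna()
            work.loc[hole, c] = rng.choice(obs, size=int(hole.sum()))
        trace_prev: dict[str, float] = {}
        for sweep in range(iterations):
            for c in miss_cols:
                hole = cohort[c].isna().to_numpy()
                others = [p for p in predictors if p != c]
                X = _encode(work, others)
                obs_rows = np.where(~hole)[0]
                boot = rng.choice(obs_rows, size=len(obs_rows), replace=True)
                Xm = X[hole]
                if models[c] == "linear":
                    yo = work[c].to_numpy(float)[boot]
                    work.loc[hole, c] = _draw_continuous(
                        X[boot], yo, Xm, rng)
                else:
                    levels = (CATEGORICAL_LEVELS.get(c)
                              or [0.0, 1.0])  # binary numeric
                    lut = {lev: i for i, lev in enumerate(levels)}
                    yo = np.array([lut[v] for v in work[c].to_numpy()[boot]])
                    draw = _draw_categorical(X[boot], yo, Xm,
                                             len(levels), rng)
                    work.loc[hole, c] = [levels[i] for i in draw]
            # crude convergence trace on continuous means
            if sweep == iterations - 1:
                for c in miss_cols:
                    if models[c] == "linear":
                        cur = float(work.loc[cohort[c].isna(), c].astype(
                            float).mean())
                        prev = trace_prev.get(c)
                        if prev is not None and abs(prev) > 1e-12 and \
                                abs(cur - prev) / abs(prev) > 0.5:
                            logger.warning(
                                "imputation chain %d: variable %r mean moved "
                                "%.3g -> %.3g on the final sweep", chain, c,
                                prev, cur)
            else:
                for c in miss_cols:
                    if models[c] == "linear":
                        trace_prev[c] = float(
                            work.loc[cohort[c].isna(), c].astype(float).mean())
        tables.append(work)
    return ImputationSet(tables=tables, iterations=iterations, seed=seed,
                         variable_models=models)
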