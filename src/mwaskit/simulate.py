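"""Synthetic mother–offspring cohorts with a GC-MS instrument model.

The generator mirrors the data structure the analysis assumes: ~940
mother–offspring pairs from three ethnic groups, 134 plasma metabolites
measured by GC-MS in batches with pooled-QC injections every seventh
sample and negative-control blanks at the start of each batch, seven
internal-standard channels, multiplicative batch effects, below-LOD
censoring, blank-only contaminant features, rare (<5% prevalence)
features, and planted linear metabolite→outcome effects.  All ground
truth (IS map, batch offsets, censoring, planted betas) is retained in
the peak table's provenance so preprocessing can be scored against it.

One global seed expands into independent per-stage child streams
(covariates, metabolome, outcomes, instrument, missingness) via
``numpy.random.SeedSequence.spawn``, so each stage is reproducible on
its own.
"""
from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import optimize, stats

from .config import (
    CATEGORICAL_LEVELS, COHORT_COLUMNS, COVARIATE_COLUMNS, OUTCOMES,
    ConfigError, SimulationConfig, seed_sequence,
)
from .preprocess import PeakTable

_STAGES = {"covariates": 0, "metabolome": 1, "outcomes": 2,
           "instrument": 3, "missingness": 4}


def _stage_rng(config: SimulationConfig, stage: str) -> np.random.Generator:
    children = seed_sequence(config.seed).spawn(len(_STAGES))
    return np.random.default_rng(children[_STAGES[stage]])


@dataclass
class LatentMetabolome:
    """True subject × metabolite log-concentrations plus generating pieces."""
    log_conc: pd.DataFrame
    baselines: pd.Series
    covariate_effects: pd.DataFrame   # subject × metabolite contribution

    def zscores(self) -> pd.DataFrame:
        """Sample-standardized log-concentrations (columns with zero
        variance map to all-zero columns)."""
        x = self.log_conc
        sd = x.std(axis=0, ddof=1)
        z = (x - x.mean(axis=0)).div(sd.where(sd > 0, 1.0), axis=1)
        return z


# --------------------------------------------------------------------------
# covariates
# --------------------------------------------------------------------------

def simulate_covariates(config: SimulationConfig) -> pd.DataFrame:
    """Draw maternal covariates and infant sex for ``n_subjects`` mothers."""
    config.validate()
    cp = config.covariates
    rng = _stage_rng(config, "covariates")
    n = config.n_subjects
    if n == 0:
        return pd.DataFrame(columns=COHORT_COLUMNS)

    eth = rng.choice(CATEGORICAL_LEVELS["ethnicity"], size=n,
                     p=cp.ethnic_proportions)
    bmi_mu = np.array([cp.bmi_by_ethnicity[e][0] for e in eth])
    bmi_sd = np.array([cp.bmi_by_ethnicity[e][1] for e in eth])
    df = pd.DataFrame({
        "subject_id": [f"S{i + 1:04d}" for i in range(n)],
        "age": rng.normal(cp.age_mean, cp.age_sd, n),
        "ethnicity": eth,
        "education": rng.choice(CATEGORICAL_LEVELS["education"], size=n,
                                p=cp.education_probs),
        "parity": rng.choice(CATEGORICAL_LEVELS["parity"], size=n,
                             p=[cp.parity_nulliparous,
                                1 - cp.parity_nulliparous]),
        "bmi": np.maximum(rng.normal(bmi_mu, bmi_sd), 14.0),
        "weight_gain": rng.normal(cp.weight_gain_mean, cp.weight_gain_sd, n),
        "height": rng.normal(cp.height_mean, cp.height_sd, n),
        "diet_score": rng.normal(cp.diet_mean, cp.diet_sd, n),
        "physical_activity": rng.choice(
            CATEGORICAL_LEVELS["physical_activity"], size=n,
            p=cp.physical_activity_probs),
        "tobacco_exposure": rng.choice(
            CATEGORICAL_LEVELS["tobacco_exposure"], size=n,
            p=cp.tobacco_probs),
        "alcohol": rng.binomial(1, cp.alcohol_p, n).astype(float),
        "fasting_glucose": np.maximum(
            rng.normal(cp.fasting_glucose_mean, cp.fasting_glucose_sd, n), 2.5),
        "glucose_2h": np.maximum(
            rng.normal(cp.glucose_2h_mean, cp.glucose_2h_sd, n), 2.5),
        "hypertensive_disorders": rng.binomial(1, cp.hypertensive_p, n
                                               ).astype(float),
        "sex": rng.choice(CATEGORICAL_LEVELS["sex"], size=n,
                          p=[cp.male_p, 1 - cp.male_p]),
    })
    for col in OUTCOMES:
        df[col] = np.nan
    return df[COHORT_COLUMNS]


# --------------------------------------------------------------------------
# latent metabolome
# --------------------------------------------------------------------------

def _term_vector(cov: pd.DataFrame, term: str, center: bool) -> np.ndarray:
    """Evaluate an effect term: ``"ethnicity:Level"`` indicator or a
    continuous covariate (sample-centred when ``center``)."""
    if ":" in term:
        col, level = term.split(":", 1)
        v = (cov[col].to_numpy() == level).astype(float)
        return v
    v = cov[term].to_numpy(float)
    return v - v.mean() if center else v


def simulate_metabolome(covariates: pd.DataFrame,
                        config: SimulationConfig) -> LatentMetabolome:
    """Generate true log-concentrations: baseline + covariate effects +
    exchangeable-correlation noise (shared subject factor)."""
    mp = config.metabolome
    rng = _stage_rng(config, "metabolome")
    n, m = len(covariates), config.n_metabolites
    if covariates[COVARIATE_COLUMNS].isna().any().any():
        raise ValueError("metabolome simulation requires complete covariates")
    names = [f"M{j + 1:03d}" for j in range(m)]
    baselines = pd.Series(
        rng.normal(mp.baseline_log_mean, mp.baseline_log_sd, m), index=names)

    effects = np.zeros((n, m))
    for term, idx, beta in mp.covariate_effects:
        idx = [j for j in idx if j < m]
        if not idx:
            continue
        effects[:, idx] += np.outer(
            _term_vector(covariates, term, center=False), np.full(len(idx), beta))

    noise_sd = mp.noise_sd
    u = rng.normal(size=n)
    e = rng.normal(size=(n, m))
    noise = noise_sd * (np.sqrt(mp.rho) * u[:, None]
                        + np.sqrt(1 - mp.rho) * e)
    log_conc = pd.DataFrame(baselines.to_numpy() + effects + noise,
                            index=covariates["subject_id"], columns=names)
    return LatentMetabolome(
        log_conc=log_conc, baselines=baselines,
        covariate_effects=pd.DataFrame(
            effects, index=covariates["subject_id"], columns=names))


# --------------------------------------------------------------------------
# outcomes
# --------------------------------------------------------------------------

def _ga_location(preterm_rate: float, sd: float,
                 bounds: tuple[float, float]) -> float:
    """Mean of the truncated normal on ``bounds`` such that
    P(GA < 37) equals ``preterm_rate``."""
    lo, hi = bounds

    def f(mu):
        a, b = (lo - mu) / sd, (hi - mu) / sd
        return stats.truncnorm.cdf(37.0, a, b, loc=mu, scale=sd) - preterm_rate

    return float(optimize.brentq(f, 37.0, hi - 0.5))


def simulate_outcomes(covariates: pd.DataFrame, metabolome: LatentMetabolome,
                      config: SimulationConfig) -> pd.DataFrame:
    """Fill the four birth outcomes.

    Each outcome = calibration mean + sample-centred covariate effects +
    planted per-SD metabolite effects + Gaussian noise, so the sample mean
    tracks the calibration target.  Gestational age is drawn from a
    truncated normal whose location is solved to hit the preterm rate;
    with ``ga_sd = 0`` it degenerates to the constant 39 wk.
    """
    op = config.outcomes
    rng = _stage_rng(config, "outcomes")
    n = len(covariates)
    if len(metabolome.log_conc) != n:
        raise ValueError("metabolome and covariates are not aligned")
    out = covariates.copy()
    z = metabolome.zscores().to_numpy()

    planted: dict[str, np.ndarray] = {o: np.zeros(n) for o in OUTCOMES}
    for entry in config.effect_spec:
        idx, outcome, beta = entry[0], entry[1], entry[2]
        if idx >= z.shape[1]:
            raise ConfigError(f"effect_spec metabolite {idx} out of range")
        contrib = beta * z[:, idx]
        if len(entry) == 4 and entry[3] is not None:
            # ethnicity-restricted effect (for interaction studies)
            contrib = contrib * (covariates["ethnicity"].to_numpy()
                                 == entry[3]).astype(float)
        planted[outcome] += contrib

    # gestational age first (it feeds the size outcomes)
    if op.ga_sd > 0:
        mu = _ga_location(op.preterm_rate, op.ga_sd, op.ga_bounds)
        a = (op.ga_bounds[0] - mu) / op.ga_sd
        b = (op.ga_bounds[1] - mu) / op.ga_sd
        ga = stats.truncnorm.rvs(a, b, loc=mu, scale=op.ga_sd, size=n,
                                 random_state=rng)
    else:
        ga = np.full(n, 39.0)
    lp_ga = _linear_predictor(out, op.covariate_effects.get(
        "gestational_age", {}), ga=None)
    out["gestational_age"] = ga + lp_ga + planted["gestational_age"]

    specs = [("birth_weight", op.birth_weight_mean, op.birth_weight_noise_sd),
             ("birth_length", op.birth_length_mean, op.birth_length_noise_sd),
             ("skinfold_sum", op.skinfold_mean, op.skinfold_noise_sd)]
    for name, mean, noise_sd in specs:
        lp = _linear_predictor(out, op.covariate_effects.get(name, {}),
                               ga=out["gestational_age"].to_numpy())
        eps = rng.normal(0.0, noise_sd, n) if noise_sd > 0 else 0.0
        out[name] = mean + lp + planted[name] + eps
    return out


def _linear_predictor(cov: pd.DataFrame, effects: dict[str, float],
                      ga: np.ndarray | None) -> np.ndarray:
    lp = np.zeros(len(cov))
    for term, beta in effects.items():
        if term == "gestational_age":
            if ga is None:
                continue
            v = ga - ga.mean()
        else:
            v = _term_vector(cov, term, center=True)
            if ":" in term:
                v = v - v.mean()
        lp += beta * v
    return lp


# --------------------------------------------------------------------------
# instrument model
# --------------------------------------------------------------------------

def apply_instrument_model(metabolome: LatentMetabolome,
                           config: SimulationConfig) -> PeakTable:
    """Turn true log-concentrations into a raw GC-MS peak table.

    Injection sequence per batch: negative-control blanks first, then
    study samples with a pooled-QC injection after every ``qc_interval``
    study samples (plus a trailing QC when a partial block remains, so
    every batch carries at least one QC).  Measured abundance =
    exp(latent + feature×batch offset + IS-group injection factor +
    noise); IS channels share the injection factor of their group, which
    is what makes each metabolite maximally QC-correlated with exactly
    one IS.  Per-feature censoring at the ``lod_quantile`` of non-blank
    abundances, contaminant features visible in blanks, and rare features
    present in <5% of samples complete the emulation.
    """
    ip = config.instrument
    if ip.n_batches < 1:
        raise ConfigError("n_batches must be >= 1")
    if ip.qc_interval <= 1:
        raise ConfigError("qc_interval must be > 1")
    rng = _stage_rng(config, "instrument")
    subjects = list(metabolome.log_conc.index)
    feats = list(metabolome.log_conc.columns)
    n_is = config.n_internal_standards
    is_names = [f"IS_{k + 1}" for k in range(n_is)]
    is_map = {f: is_names[j % n_is] for j, f in enumerate(feats)}
    group = np.array([j % n_is for j in range(len(feats))])

    # --- injection sequence ----------------------------------------------
    chunks = np.array_split(np.arange(len(subjects)), ip.n_batches)
    rows = []  # (sample_id, batch, sample_type, subject_pos or None)
    for b, chunk in enumerate(chunks, start=1):
        batch = f"B{b:02d}"
        for j in range(ip.blanks_per_batch):
            rows.append((f"BLK_{b:02d}_{j + 1}", batch, "blank", None))
        n_qc = 0
        for pos, i in enumerate(chunk, start=1):
            rows.append((subjects[i], batch, "study", i))
            if pos % ip.qc_interval == 0:
                n_qc += 1
                rows.append((f"QC_{b:02d}_{n_qc:02d}", batch, "qc", None))
        if len(chunk) % ip.qc_interval != 0 or (n_qc == 0 and len(chunk)):
            n_qc += 1
            rows.append((f"QC_{b:02d}_{n_qc:02d}", batch, "qc", None))

    samples = pd.DataFrame(rows, columns=["sample_id", "batch", "sample_type",
                                          "_pos"]).set_index("sample_id")
    samples.insert(0, "injection_order", np.arange(1, len(samples) + 1))
    n_inj = len(samples)
    is_blank = (samples["sample_type"] == "blank").to_numpy()

    # --- latent per injection --------------------------------------------
    latent = metabolome.log_conc.to_numpy()
    qc_latent = np.log(np.exp(latent).mean(axis=0))  # pooled-sample mean
    pos = samples["_pos"].to_numpy()
    latent_rows = np.where(
        is_blank[:, None], np.nan,
        np.where((samples["sample_type"] == "qc").to_numpy()[:, None],
                 qc_latent[None, :],
                 latent[np.where(pd.isna(pos), 0, pos).astype(int), :]))

    # --- instrument noise -------------------------------------------------
    batches = pd.unique(samples["batch"])
    b_idx = samples["batch"].map({b: i for i, b in enumerate(batches)}
                                 ).to_numpy()
    off_feat = rng.normal(0.0, ip.feature_batch_sd, (len(batches), len(feats)))
    off_is = rng.normal(0.0, ip.is_batch_sd, (len(batches), n_is))
    eta = rng.normal(0.0, ip.injection_sd, (n_inj, n_is))
    eps = rng.normal(0.0, ip.feature_noise_sd, (n_inj, len(feats)))

    log_ab = latent_rows + off_feat[b_idx] + eta[:, group] + eps
    abundance = pd.DataFrame(np.exp(log_ab), index=samples.index,
                             columns=feats)
    abundance[is_blank] = np.nan  # plasma features are absent from blanks

    is_levels = 11.0 + 0.1 * np.arange(n_is)
    log_is = (is_levels[None, :] + off_is[b_idx] + eta
              + rng.normal(0.0, ip.is_noise_sd, (n_inj, n_is)))
    is_channels = pd.DataFrame(np.exp(log_is), index=samples.index,
                               columns=is_names)
    is_channels[is_blank] = np.nan  # blanks receive no IS spike

    # --- LOD censoring ----------------------------------------------------
    censored = pd.DataFrame(False, index=samples.index, columns=feats)
    if ip.lod_quantile > 0:
        nb = abundance.loc[~is_blank]
        thr = nb.quantile(ip.lod_quantile, axis=0)
        low = nb.lt(thr, axis=1)
        censored.loc[~is_blank] = low
        abundance = abundance.mask(censored)

    # --- contaminant and rare features -----------------------------------
    cont_names = [f"C{j + 1:02d}" for j in range(ip.n_contaminant_features)]
    rare_names = [f"L{j + 1:02d}"
                  for j in range(ip.n_low_prevalence_features)]
    extra = {}
    for name in cont_names:
        base = rng.normal(11.0, 0.5)
        col = np.exp(base + rng.normal(0.0, 0.3, n_inj))
        col[is_blank] = np.exp(base + ip.contaminant_blank_log_ratio
                               + rng.normal(0.0, 0.1, int(is_blank.sum())))
        extra[name] = col
    for name in rare_names:
        present = rng.random(n_inj) < ip.low_prevalence_rate
        col = np.where(present & ~is_blank,
                       np.exp(rng.normal(10.0, 0.5, n_inj)), np.nan)
        extra[name] = col
    if extra:
        abundance = pd.concat(
            [abundance, pd.DataFrame(extra, index=samples.index)], axis=1)

    net_offsets = pd.DataFrame(
        off_feat.T - off_is.T[group, :], index=feats, columns=batches)
    provenance = {
        "is_map": is_map,
        "batch_offsets": pd.DataFrame(off_feat.T, index=feats,
                                      columns=batches),
        "is_batch_offsets": pd.DataFrame(off_is.T, index=is_names,
                                         columns=batches),
        "net_log_batch_offsets": net_offsets,
        "contaminant_features": cont_names,
        "low_prevalence_features": rare_names,
        "n_censored": censored.sum().to_dict(),
        "effect_spec": list(config.effect_spec),
    }
    return PeakTable(samples=samples.drop(columns="_pos"),
                     abundance=abundance, is_channels=is_channels,
                     provenance=provenance)


# --------------------------------------------------------------------------
# missingness
# --------------------------------------------------------------------------

def inject_missingness(covariates: pd.DataFrame,
                       config: SimulationConfig) -> pd.DataFrame:
    """Mask exactly the configured number of cells per covariate.

    MCAR masks uniformly; MAR weights selection by observed ethnicity and
    education (weight exp(coef·(non-Chinese + lowest education))).  The
    ``glucose`` entry masks fasting and 2-h glucose jointly.  Outcomes are
    never masked.
    """
    ms = config.missingness
    rng = _stage_rng(config, "missingness")
    out = covariates.copy()
    n = len(out)
    for var, count in ms.counts.items():
        if count > n:
            raise ConfigError(f"missing count for {var!r} exceeds n={n}")
        if count == 0:
            continue
        if ms.mechanism.upper() == "MAR":
            w = np.exp(ms.mar_coef * (
                (out["ethnicity"].to_numpy() != "Chinese").astype(float)
                + (out["education"].to_numpy() == "secondary_or_below"
                   ).astype(float)))
            keys = np.log(w) + rng.gumbel(size=n)
        else:
            keys = rng.random(n)
        chosen = np.argsort(keys)[-count:]
        cols = (["fasting_glucose", "glucose_2h"] if var == "glucose"
                else [var])
        for col in cols:
            if out[col].dtype == object:
                out.loc[out.index[chosen], col] = np.nan
            else:
                out.loc[out.index[chosen], col] = np.nan
    return out


# --------------------------------------------------------------------------
# convenience
# --------------------------------------------------------------------------

def simulate_cohort(config: SimulationConfig) -> dict:
    """Run every stage; returns complete/observed cohorts, the latent
    metabolome, the raw peak table, and the ground-truth dict."""
    cov = simulate_covariates(config)
    met = simulate_metabolome(cov, config)
    full = simulate_outcomes(cov, met, config)
    pt = apply_instrument_model(met, config)
    observed = inject_missingness(full, config)
    truth = dict(pt.provenance or {})
    truth["planted_effects"] = list(config.effect_spec)
    return {"cohort_complete": full, "cohort": observed, "metabolome": met,
            "peak_table": pt, "truth": truth}
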