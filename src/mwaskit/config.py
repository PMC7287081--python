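"""Shared schema, run configuration, and seed handling.

The cohort schema mirrors a multi-ethnic Asian mother–offspring study:
maternal covariates collected at recruitment and at the 26–28 week visit,
plus four birth outcomes (gestational age, birth weight, birth length and
the triceps+subscapular skinfold sum used as a neonatal adiposity proxy).
"""
from __future__ import annotations

import dataclasses
import logging
from dataclasses import dataclass, field
from typing import Sequence

import numpy as np
import yaml

logger = logging.getLogger("mwaskit")

# --------------------------------------------------------------------------
# Cohort schema
# --------------------------------------------------------------------------

#: Ordered levels for every categorical covariate; the first level is the
#: dummy-coding reference in all regression models.
CATEGORICAL_LEVELS: dict[str, list[str]] = {
    "ethnicity": ["Chinese", "Malay", "Indian"],
    "education": ["secondary_or_below", "postsecondary", "university"],
    "parity": ["nulliparous", "multiparous"],
    "physical_activity": ["inactive", "sufficiently_active", "highly_active"],
    "tobacco_exposure": [
        "no_exposure",        # cotinine < 0.17 ng/mL, no ETS
        "environmental",      # cotinine < 0.17 ng/mL, self-reported ETS
        "low_cotinine",       # cotinine 0.17–13.99 ng/mL
        "high_cotinine",      # cotinine >= 14 ng/mL
    ],
    "sex": ["male", "female"],
}

CONTINUOUS_COVARIATES = [
    "age", "bmi", "weight_gain", "height", "diet_score",
    "fasting_glucose", "glucose_2h",
]
BINARY_COVARIATES = ["alcohol", "hypertensive_disorders"]
OUTCOMES = ["gestational_age", "birth_weight", "birth_length", "skinfold_sum"]

#: All covariate columns that may carry missing values.
COVARIATE_COLUMNS = (
    ["age", "ethnicity", "education", "parity", "bmi", "weight_gain",
     "height", "diet_score", "physical_activity", "tobacco_exposure",
     "alcohol", "fasting_glucose", "glucose_2h", "hypertensive_disorders",
     "sex"]
)
COHORT_COLUMNS = ["subject_id"] + COVARIATE_COLUMNS + OUTCOMES

#: Adjustment set of the main per-metabolite outcome models (infant sex plus
#: maternal age, parity, education, ethnicity, pre-pregnancy BMI, weight gain
#: to 26–28 wk, height, tobacco exposure, physical activity, diet quality and
#: gestational diabetes).  ``gdm`` is derived from the two glucose columns.
DEFAULT_ADJUSTMENT = [
    "sex", "age", "parity", "education", "ethnicity", "bmi", "weight_gain",
    "height", "tobacco_exposure", "physical_activity", "diet_score", "gdm",
]

SAMPLE_TYPES = ("study", "qc", "blank")


def seed_sequence(seed: int) -> np.random.SeedSequence:
    return np.random.SeedSequence(int(seed))


def child_rngs(seed: int, n: int) -> list[np.random.Generator]:
    """Expand one global seed into independent per-stage generators."""
    return [np.random.default_rng(s) for s in seed_sequence(seed).spawn(n)]


# --------------------------------------------------------------------------
# Simulation configuration
# --------------------------------------------------------------------------

@dataclass
class CovariateParams:
    """Marginal distributions of the maternal covariates.

    Defaults reproduce the printed cohort marginals: 55/26/19% ethnic mix,
    age 30.5 ± 5.1 y, ethnicity-specific pre-pregnancy BMI (Chinese
    21.6 ± 3.4, Malay 24.2 ± 5.4, Indian 23.9 ± 4.5 kg/m², which yields
    ≈43% overweight at the BMI ≥ 23 cutoff), and glucose levels giving a
    GDM prevalence near one in six under the WHO fasting/2-h cutoffs.
    """
    ethnic_proportions: tuple[float, float, float] = (0.55, 0.26, 0.19)
    age_mean: float = 30.5
    age_sd: float = 5.1
    education_probs: tuple[float, float, float] = (0.33, 0.36, 0.31)
    parity_nulliparous: float = 0.43
    bmi_by_ethnicity: dict[str, tuple[float, float]] = field(
        default_factory=lambda: {
            "Chinese": (21.6, 3.4), "Malay": (24.2, 5.4), "Indian": (23.9, 4.5)
        })
    weight_gain_mean: float = 9.3
    weight_gain_sd: float = 4.5
    height_mean: float = 158.3
    height_sd: float = 5.7
    diet_mean: float = 52.0
    diet_sd: float = 13.0
    physical_activity_probs: tuple[float, float, float] = (0.30, 0.51, 0.19)
    tobacco_probs: tuple[float, float, float, float] = (0.50, 0.30, 0.15, 0.05)
    alcohol_p: float = 0.02
    fasting_glucose_mean: float = 4.35
    fasting_glucose_sd: float = 0.50
    glucose_2h_mean: float = 6.5
    glucose_2h_sd: float = 1.3
    hypertensive_p: float = 0.06
    male_p: float = 0.52


@dataclass
class MetabolomeParams:
    """Latent log-concentration model.

    Each metabolite is baseline + covariate effects + a shared subject
    factor inducing exchangeable correlation ``rho`` + idiosyncratic noise;
    the noise part has unit SD so planted outcome effects are per-SD.
    ``covariate_effects`` entries are (term, metabolite indices, effect per
    unit/indicator on the log scale); terms are either a continuous
    covariate name or ``"ethnicity:Level"`` indicators.
    """
    rho: float = 0.2
    noise_sd: float = 1.0
    baseline_log_mean: float = 11.5
    baseline_log_sd: float = 0.8
    covariate_effects: list[tuple[str, tuple[int, ...], float]] = field(
        default_factory=lambda: [
            ("ethnicity:Chinese", tuple(range(0, 10)), 0.30),
            ("ethnicity:Indian", tuple(range(0, 10)), -0.25),
            ("bmi", tuple(range(10, 20)), 0.03),
            ("diet_score", tuple(range(20, 28)), -0.01),
        ])


@dataclass
class OutcomeParams:
    """Marginal calibration and covariate effects of the birth outcomes.

    Outcomes are linear in mean-centred covariates plus planted per-SD
    metabolite effects plus Gaussian noise, so the marginal mean equals the
    calibration target by construction.  Gestational age is a truncated
    normal on [30, 42] wk whose mean is solved to hit ``preterm_rate``.
    """
    birth_weight_mean: float = 3094.0
    birth_weight_noise_sd: float = 395.0
    birth_length_mean: float = 48.6
    birth_length_noise_sd: float = 1.84
    skinfold_mean: float = 10.3
    skinfold_noise_sd: float = 1.58
    ga_sd: float = 1.4
    ga_bounds: tuple[float, float] = (30.0, 42.0)
    preterm_rate: float = 0.076
    # covariate effects: outcome -> {term: beta per unit (centred)}
    covariate_effects: dict[str, dict[str, float]] = field(
        default_factory=lambda: {
            "birth_weight": {"gestational_age": 150.0, "sex:male": 120.0,
                             "bmi": 15.0},
            "birth_length": {"gestational_age": 0.9, "sex:male": 0.9,
                             "height": 0.06},
            "skinfold_sum": {"gestational_age": 0.25, "sex:male": -0.4,
                             "bmi": 0.06},
            "gestational_age": {},
        })


def default_effect_spec() -> list[tuple[int, str, float]]:
    """28 planted skinfold effects of |β| = 0.3 mm/SD with balanced signs."""
    return [(i, "skinfold_sum", -0.3 if i % 2 == 0 else 0.3)
            for i in range(28)]


@dataclass
class InstrumentParams:
    """GC-MS instrument emulation on the log-abundance scale.

    Injection-level variation is shared within internal-standard groups
    (``injection_sd``), which is what makes IS normalization informative;
    batch offsets are feature- and channel-specific multiplicative shifts.
    """
    n_batches: int = 10
    blanks_per_batch: int = 2
    qc_interval: int = 7
    feature_batch_sd: float = 0.10
    is_batch_sd: float = 0.10
    injection_sd: float = 0.40
    feature_noise_sd: float = 0.05
    is_noise_sd: float = 0.05
    lod_quantile: float = 0.02
    n_contaminant_features: int = 4
    n_low_prevalence_features: int = 6
    low_prevalence_rate: float = 0.03
    contaminant_blank_log_ratio: float = 0.2


@dataclass
class MissingnessSpec:
    """Exact per-covariate missing-cell counts (calibrated to n = 940).

    ``glucose`` masks fasting and 2-h glucose jointly so the derived GDM
    flag goes missing for those subjects.  Mechanism is MCAR (uniform) or
    MAR (selection weights depend on observed ethnicity/education through
    ``mar_coef``).
    """
    counts: dict[str, int] = field(default_factory=lambda: {
        "height": 9, "diet_score": 9, "physical_activity": 10,
        "education": 11, "alcohol": 25, "glucose": 36, "bmi": 66,
        "weight_gain": 73, "tobacco_exposure": 73,
    })
    mechanism: str = "MCAR"
    mar_coef: float = 1.0


@dataclass
class SimulationConfig:
    n_subjects: int = 940
    n_metabolites: int = 134
    n_internal_standards: int = 7
    covariates: CovariateParams = field(default_factory=CovariateParams)
    metabolome: MetabolomeParams = field(default_factory=MetabolomeParams)
    outcomes: OutcomeParams = field(default_factory=OutcomeParams)
    effect_spec: list[tuple[int, str, float]] = field(
        default_factory=default_effect_spec)
    instrument: InstrumentParams = field(default_factory=InstrumentParams)
    missingness: MissingnessSpec = field(default_factory=MissingnessSpec)
    seed: int = 0

    def __post_init__(self) -> None:
        self.validate()

    def validate(self) -> None:
        p = np.asarray(self.covariates.ethnic_proportions, float)
        if p.min() < 0 or abs(p.sum() - 1.0) > 1e-8:
            raise ConfigError(
                f"ethnic_proportions must be a probability vector, got {p}")
        for name in ("n_subjects", "n_metabolites", "n_internal_standards"):
            if getattr(self, name) < 0:
                raise ConfigError(f"{name} must be >= 0")
        if self.instrument.qc_interval < 2:
            raise ConfigError("qc_interval must be >= 2")
        if not (0.0 <= self.instrument.lod_quantile < 1.0):
            raise ConfigError("lod_quantile must be in [0, 1)")
        for entry in self.effect_spec:
            idx, outcome = entry[0], entry[1]
            if not (0 <= idx < self.n_metabolites):
                raise ConfigError(f"effect_spec metabolite {idx} out of range")
            if outcome not in OUTCOMES:
                raise ConfigError(f"effect_spec outcome {outcome!r} unknown")
            if len(entry) == 4 and entry[3] is not None and \
                    entry[3] not in CATEGORICAL_LEVELS["ethnicity"]:
                raise ConfigError(
                    f"effect_spec ethnicity {entry[3]!r} unknown")
        for var, cnt in self.missingness.counts.items():
            if cnt < 0 or cnt > self.n_subjects:
                raise ConfigError(
                    f"missing count for {var!r} must be in [0, n_subjects]")


class ConfigError(ValueError):
    """Invalid configuration value."""


# --------------------------------------------------------------------------
# Run configuration
# --------------------------------------------------------------------------

@dataclass
class RunConfig:
    """End-to-end pipeline settings.

    Thresholds follow the analysis defaults: 5% detection-prevalence floor,
    IS assignment requires R² ≥ 0.75, QC CV ceiling 30%, metabolites carried
    to profiling at q < 0.10, significance at q < 0.05, 20 imputations.
    """
    peak_table: str = "peak_table.csv"
    cohort: str = "cohort.csv"
    outdir: str = "results"
    prevalence_min: float = 0.05
    r2_min: float = 0.75
    cv_max: float = 30.0
    blank_ratio_max: float = 0.5
    fdr_select: float = 0.10
    fdr_sig: float = 0.05
    n_imputations: int = 20
    mi_iterations: int = 10
    stratum_floor: int = 30
    seed: int = 0
    covariates: list[str] = field(
        default_factory=lambda: list(DEFAULT_ADJUSTMENT))
    outcome_list: list[str] = field(default_factory=lambda: list(OUTCOMES))
    sensitivity_scenarios: list[str] = field(default_factory=lambda: [
        "complete-case", "term-only", "no-hdp-gdm", "glucose-adjusted",
        "bwz-outcome",
    ])
    sensitivity_outcome: str = "skinfold_sum"

    def __post_init__(self) -> None:
        if self.n_imputations < 2:
            raise ConfigError("n_imputations must be >= 2")
        if not self.covariates:
            raise ConfigError("covariate list must be non-empty")
        for name, lo, hi in [("prevalence_min", 0, 1), ("r2_min", 0, 1),
                             ("fdr_select", 0, 1), ("fdr_sig", 0, 1)]:
            v = getattr(self, name)
            if not (lo <= v <= hi):
                raise ConfigError(f"{name} must be in [{lo}, {hi}], got {v}")
        if self.cv_max <= 0:
            raise ConfigError("cv_max must be positive")


def _to_plain(obj):
    if dataclasses.is_dataclass(obj) and not isinstance(obj, type):
        return {k: _to_plain(v) for k, v in dataclasses.asdict(obj).items()}
    if isinstance(obj, dict):
        return {k: _to_plain(v) for k, v in obj.items()}
    if isinstance(obj, (list, tuple)):
        return [_to_plain(v) for v in obj]
    if isinstance(obj, np.generic):
        return obj.item()
    return obj


def save_run_config(cfg: RunConfig, path) -> None:
    with open(path, "w", encoding="utf-8") as fh:
        yaml.safe_dump(_to_plain(cfg), fh, sort_keys=False)


def load_run_config(path) -> RunConfig:
    with open(path, encoding="utf-8") as fh:
        raw = yaml.safe_load(fh) or {}
    known = {f.name for f in dataclasses.fields(RunConfig)}
    unknown = set(raw) - known
    if unknown:
        raise ConfigError(f"unknown configuration keys: {sorted(unknown)}")
    return RunConfig(**raw)
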