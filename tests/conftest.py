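import numpy as np
import pandas as pd
import pytest

from mwaskit import SimulationConfig, simulate_cohort
from mwaskit.config import MissingnessSpec
from mwaskit.preprocess import PeakTable


def make_peak_table(abundance: dict, is_channels: dict, sample_types: list,
                    batches: list | None = None) -> PeakTable:
    """Hand-built peak table; rows named by position, injection order 1..n."""
    n = len(sample_types)
    idx = pd.Index([f"inj{i + 1:02d}" for i in range(n)], name="sample_id")
    samples = pd.DataFrame({
        "injection_order": np.arange(1, n + 1),
        "batch": batches if batches is not None else ["B1"] * n,
        "sample_type": sample_types,
    }, index=idx)
    ab = pd.DataFrame(abundance, index=idx, dtype=float)
    isc = pd.DataFrame(is_channels, index=idx, dtype=float)
    return PeakTable(samples=samples, abundance=ab, is_channels=isc)


@pytest.fixture(scope="session")
def small_config() -> SimulationConfig:
    """A compact but fully featured study: 200 subjects, 30 metabolites,
    default 28 planted skinfold effects, moderate covariate missingness."""
    return SimulationConfig(
        n_subjects=200, n_metabolites=30, seed=7,
        missingness=MissingnessSpec(counts={
            "bmi": 14, "height": 2, "education": 3, "glucose": 8,
            "weight_gain": 16, "tobacco_exposure": 16, "alcohol": 5,
            "physical_activity": 2, "diet_score": 2}))


@pytest.fixture(scope="session")
def small_sim(small_config):
    return simulate_cohort(small_config)


@pytest.fixture(scope="session")
def clean_config() -> SimulationConfig:
    """No missingness, no planted effects: a null study for calibration and
    preprocessing-recovery checks."""
    return SimulationConfig(n_subjects=400, n_metabolites=40, seed=21,
                            effect_spec=[],
                            missingness=MissingnessSpec(counts={}))


@pytest.fixture(scope="session")
def clean_sim(clean_config):
    return simulate_cohort(clean_config)
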