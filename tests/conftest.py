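import numpy as np
import pandas as pd
import pytest

from sleepphen import (FEATURES, GeneratorConfig, PhenotypeSpec,
                       default_phenotypes, generate_dataset)


@pytest.fixture(scope="session")
def small_cohort():
    """A small generated cohort shared across read-only tests."""
    cfg = GeneratorConfig(n_plwd=12, n_gp_pool=24, n_nights=120, seed=11)
    participants, nights = generate_dataset(cfg, default_phenotypes())
    return cfg, participants, nights


@pytest.fixture()
def rng():
    return np.random.default_rng(20240917)


def make_night_frame(values_by_feature, participant_id="P0001",
                     start="2022-10-31"):
    """Build a nightly-record frame from per-feature value lists (NaN = missing)."""
    n = len(next(iter(values_by_feature.values())))
    df = pd.DataFrame({
        "participant_id": participant_id,
        "night_date": pd.date_range(start, periods=n, freq="D"),
    })
    for f in FEATURES:
        df[f] = values_by_feature.get(f, values_by_feature.get("all"))
    return df


def constant_phenotype(pid=1, mean=None, between=0.0, within=0.0):
    """A degenerate phenotype with controllable noise, for oracle tests."""
    if mean is None:
        mean = np.array([4000, 5000, 14000, 3500, 50, 60, 75, 12, 15, 19], float)
    return PhenotypeSpec(
        phenotype_id=pid, nightly_mean=mean,
        between_participant_sd=np.full(10, float(between)),
        within_participant_sd=np.full(10, float(within)),
        age_mean=75.0, age_sd=5.0, prob_plwd=0.5, prob_female=0.5)
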