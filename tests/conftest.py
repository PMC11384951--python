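import pandas as pd
import pytest

from tdmstate import CohortConfig, StateSpaceEncoder, generate_cohort, prepare_cohort


@pytest.fixture(scope="session")
def small_config() -> CohortConfig:
    return CohortConfig(n_tdm=25, n_control=25, seed=11)


@pytest.fixture(scope="session")
def small_cohort(small_config) -> pd.DataFrame:
    return generate_cohort(small_config)


@pytest.fixture(scope="session")
def clean_cohort(small_cohort):
    clean, schema, _ = prepare_cohort(small_cohort)
    return clean, schema


@pytest.fixture(scope="session")
def encoded_cohort(clean_cohort):
    clean, schema = clean_cohort
    cols = [f for f in schema.all_features if f in clean.columns]
    discrete = [f for f in cols if f in set(schema.discrete) | set(schema.pathogen)]
    enc = StateSpaceEncoder(discrete_columns=discrete).fit(
        clean[cols], clean["sofa_total"]
    )
    return enc.transform(clean[cols]), clean, schema
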