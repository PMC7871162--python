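import numpy as np
import pandas as pd
import pytest

from cigdemand.synthetic import default_dgp_params, generate_households


@pytest.fixture(scope="session")
def q3_params():
    return default_dgp_params(3, n_per_quintile=20_000, seed=7)


@pytest.fixture(scope="session")
def q3_table(q3_params):
    return generate_households(q3_params)


@pytest.fixture()
def tiny_survey():
    """Six hand-built households in one quintile, three of them smokers."""
    rng = np.random.default_rng(0)
    n = 6
    df = pd.DataFrame(
        {
            "year": [2010] * n,
            "province_id": [1, 2, 3, 1, 2, 3],
            "expenditure_pea": np.linspace(1e6, 6e6, n),
            "quintile": [1] * n,
            "ln_income": rng.normal(16, 0.5, n),
            "ln_price": rng.normal(11, 0.3, n),
            "divorce_rate": rng.uniform(1, 3, n),
            "unemployment_rate": rng.uniform(5, 15, n),
            "share_15_18": rng.uniform(0, 0.2, n),
            "share_gt64": rng.uniform(0, 0.2, n),
            "share_male_19_64": rng.uniform(0.2, 0.4, n),
            "share_female_19_64": rng.uniform(0.2, 0.4, n),
            "share_jobless": rng.uniform(0, 0.3, n),
            "share_primary_edu": rng.uniform(0.1, 0.5, n),
            "share_univ_edu": rng.uniform(0, 0.3, n),
            "head_age": [30, 40, 50, 60, 45, 35],
            "head_sex": [1, 1, 1, 0, 1, 1],
            "head_education": [
                "none",
                "elementary",
                "diploma",
                "none",
                "bachelor",
                "junior_high",
            ],
            "smoke": [1, 0, 1, 0, 1, 0],
            "sticks_month": [300.0, np.nan, 450.0, np.nan, 150.0, np.nan],
        }
    )
    return df
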