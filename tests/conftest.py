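import numpy as np
import pandas as pd
import pytest

import coldharvest as ch


def make_daily(n_days=400, start="1949-10-02", tmean=None, deaths=None, seed=0):
    """Small daily frame for unit tests."""
    rng = np.random.default_rng(seed)
    dates = pd.date_range(start, periods=n_days, freq="D")
    if tmean is None:
        doy = dates.dayofyear.to_numpy(dtype=float)
        tmean = 11 + 7 * np.cos(2 * np.pi * (doy - 201) / 365.25) + rng.normal(0, 2, n_days)
    if deaths is None:
        deaths = rng.poisson(150, n_days).astype(float)
    return pd.DataFrame({"tmean": tmean, "deaths_all": deaths}, index=dates)


@pytest.fixture(scope="session")
def expectation_dataset():
    """57-year expectation-mode series with a known acute cold effect and no
    displacement; shared across recovery tests."""
    tcfg = ch.TempSimConfig(n_years=57, seed=1)
    hv = ch.HarvestConfig(beta_cold=0.02, beta_heat=0.013, lag_cold=14, lag_heat=3)
    mcfg = ch.MortSimConfig(baseline=170.0, harvest=hv, seed=2, expectation_mode=True)
    daily, truth = ch.generate_dataset(tcfg, mcfg)
    return daily, truth


@pytest.fixture(scope="session")
def expectation_tables(expectation_dataset):
    daily, truth = expectation_dataset
    weeks, annual = ch.build_tables(daily)
    return weeks, annual, truth
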