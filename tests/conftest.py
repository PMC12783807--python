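import numpy as np
import pandas as pd
import pytest
from hypothesis import settings

from npsi.synthetic import SyntheticConfig, generate

settings.register_profile("repro", derandomize=True, deadline=None)
settings.load_profile("repro")


@pytest.fixture(scope="session")
def small_network():
    """A small noisy synthetic network: (samples, sites, truth)."""
    cfg = SyntheticConfig(n_sites=8, noise_cv=0.3)
    return generate(cfg, seed=11)


@pytest.fixture()
def single_site_year() -> pd.DataFrame:
    """Twelve monthly samples for one site in one year, fixed round values.

    DIN split 10:2 between nitrate+nitrite and ammonium; Si carries a mild
    seasonal dip so the minimum-Si month is unambiguous (May).
    """
    months = np.arange(1, 13)
    si = 2800.0 - 400.0 * np.cos(2 * np.pi * (months - 5) / 12.0)
    return pd.DataFrame({
        "site_id": "R1",
        "date": [f"2020-{m:02d}-15" for m in months],
        "no3_no2": 500.0 + 10.0 * months,
        "nh4": 100.0 + 2.0 * months,
        "totp": 30.0 + 1.0 * months,
        "si": si,
    })
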