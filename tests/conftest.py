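import numpy as np
import pytest

from railbat.event_processing import TrainPass
from railbat.synthetic_data import (SiteConfig, SuppressionConfig,
                                    TrainScheduleConfig)


@pytest.fixture
def site_cfg():
    return SiteConfig()


@pytest.fixture
def quiet_sup():
    """No suppression, no overdispersion: a plain Poisson stream."""
    return SuppressionConfig(factor_s=1.0, duration_tau=0.0,
                             dispersion_theta=float("inf"))


@pytest.fixture
def three_trains():
    return [
        TrainPass(start_s=100.0, end_s=105.0, track=1, n_cars=4),
        TrainPass(start_s=400.0, end_s=404.0, track=2, n_cars=8),
        TrainPass(start_s=900.0, end_s=906.0, track=1, n_cars=12),
    ]


@pytest.fixture
def small_count_table():
    """Deterministic NB-ish count table with one covariate and groups."""
    rng = np.random.default_rng(42)
    import pandas as pd
    n = 400
    x = rng.normal(size=n)
    g = np.repeat([f"s{i}" for i in range(8)], n // 8)
    mu = np.exp(0.4 + 0.5 * x)
    y = rng.poisson(mu * rng.gamma(2.0, 0.5, size=n))
    return pd.DataFrame({"count": y, "x": x, "site_id": g})
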