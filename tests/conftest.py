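import numpy as np
import pandas as pd
import pytest

from laycurve import SimulationConfig, simulate_egg_records
from laycurve.datasets import CURVE_ESTIMATES

NC_YANG = CURVE_ESTIMATES["NC"]["yang"]
NC_SEGPOLY = CURVE_ESTIMATES["NC"]["segpoly"]
NC_PERSISTENCY = CURVE_ESTIMATES["NC"]["persistency"]
LY_YANG = CURVE_ESTIMATES["LY"]["yang"]


@pytest.fixture
def noise_free_yang_records() -> pd.DataFrame:
    """Exact Yang-curve tabulation over weeks 17-50 for 10 hens."""
    cfg = SimulationConfig(
        family="yang", group_params={"NC": NC_YANG}, n_hens={"NC": 10},
        noise="gaussian", gaussian_sd=0.0, seed=0,
    )
    return simulate_egg_records(cfg)


@pytest.fixture
def binomial_yang_records() -> pd.DataFrame:
    """Binomially noisy records from the NC Yang truth, 91 hens, one seed."""
    cfg = SimulationConfig(
        family="yang", group_params={"NC": NC_YANG}, n_hens={"NC": 91}, seed=42,
    )
    return simulate_egg_records(cfg)


@pytest.fixture
def two_group_linear_records() -> pd.DataFrame:
    """Small two-group dataset with distinct linear trends (closed-form oracle)."""
    rng = np.random.default_rng(7)
    rows = []
    for group, (alpha, beta) in (("A", (0.2, 0.010)), ("B", (0.3, 0.004))):
        for hen in range(6):
            for week in range(17, 31):
                rate = alpha + beta * week + rng.normal(0, 0.05)
                rows.append(
                    {"hen_id": f"{group}{hen}", "group": group, "week": week,
                     "eggs": rate * 7, "rate": rate}
                )
    return pd.DataFrame(rows)
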