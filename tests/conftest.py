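import numpy as np
import pandas as pd
import pytest
from hypothesis import HealthCheck, settings

import locustgam as lg
from locustgam.density import sample_densities
from locustgam.gam import NegativeBinomialGAM, SmoothSpec

settings.register_profile(
    "suite",
    derandomize=True,
    max_examples=50,
    deadline=None,
    suppress_health_check=[HealthCheck.too_slow],
)
settings.load_profile("suite")


@pytest.fixture(scope="session")
def sim_cfg():
    return lg.SimulationConfig(seed=7, n_surveys=2500)


@pytest.fixture(scope="session")
def env(sim_cfg):
    return lg.generate_env_grid(sim_cfg)


@pytest.fixture(scope="session")
def surveys(sim_cfg, env):
    sv = lg.generate_surveys(sim_cfg, env)
    rng = np.random.default_rng(70)
    sv["sampled_density"] = sample_densities(
        sv["density_class"].to_numpy(), sim_cfg.class_scheme, rng
    )
    return sv


@pytest.fixture(scope="session")
def table(surveys, env):
    return lg.build_feature_table(surveys, env)


@pytest.fixture(scope="session")
def fitted_gam(table):
    """A small fitted model shared by prediction/mapping tests: three
    covariate smooths plus a compact space-time tensor."""
    specs = [
        SmoothSpec(("ndvi",), "cubic_spline", 8),
        SmoothSpec(("vp_mean_60d",), "cubic_spline", 8),
        SmoothSpec(("tmax_mean_60d",), "cubic_spline", 8),
        SmoothSpec(("lon", "lat", "doy"), "tensor3", (6, 6, 4)),
    ]
    model = NegativeBinomialGAM(specs, n_sweeps=1)
    return model.fit(table, table["response"].to_numpy())
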