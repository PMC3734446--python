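import numpy as np
import pandas as pd
import pytest
from hypothesis import HealthCheck, settings

settings.register_profile(
    "suite", deadline=None, derandomize=True,
    suppress_health_check=[HealthCheck.too_slow])
settings.load_profile("suite")

from growthmap import (SimulationParams, add_supplementary_edges,  # noqa: E402
                       contiguity_adjacency, generate_geography, generate_ses,
                       simulate_counts)
from growthmap.cohort import standardize_ses  # noqa: E402

LOGIT_5PCT = float(np.log(0.05 / 0.95))


def make_suburb_data(n_rows, n_cols, *, beta0=LOGIT_5PCT, beta1=0.0,
                     sigma_u=0.0, sigma_v=0.0, births=None, mean_births=330.0,
                     smoothness=0.8, seed=0, river=False):
    """Simulate a complete (table, adjacency) pair for model tests."""
    geog = generate_geography(n_rows, n_cols, river=river, seed=seed)
    adj = contiguity_adjacency(geog)
    if river:
        adj = add_supplementary_edges(adj, geog, 0.5)
    ses = generate_ses(geog, smoothness, seed=seed + 1)
    tab = pd.DataFrame({"suburb_id": list(geog.ids),
                        "ses_raw": ses.to_numpy()})
    tab["ses_std"] = standardize_ses(tab["ses_raw"])
    if births is not None:
        tab["births"] = births
    params = SimulationParams(beta0=beta0, beta1=beta1, sigma_u=sigma_u,
                              sigma_v=sigma_v, mean_births=mean_births,
                              seed=seed + 2)
    return simulate_counts(tab, adj, params), adj


@pytest.fixture(scope="session")
def lattice3():
    geog = generate_geography(3, 3)
    return geog, contiguity_adjacency(geog)


@pytest.fixture(scope="session")
def small_full_fit():
    """A full-model fit on an 8x8 lattice shared across summary tests."""
    from growthmap.bym import BYMModel, McmcConfig

    tab, adj = make_suburb_data(8, 8, beta1=-0.3, sigma_u=0.3, sigma_v=0.2,
                                births=500, seed=40)
    res = BYMModel(tab, adj, "full").fit(
        McmcConfig(iterations=12_000, burn_in=4_000, thin=10, seed=41))
    return tab, adj, res
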