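import numpy as np
import pandas as pd
import pytest

from stcar import (
    MCMCSettings,
    ModelSpec,
    STCARModel,
    SyntheticScenario,
    simulate_study,
)


@pytest.fixture(scope="session")
def small_study():
    """Desk-scale synthetic study shared across test modules."""
    return simulate_study(SyntheticScenario(rows=3, cols=3, T=12, cells_per_area=2), seed=42)


@pytest.fixture(scope="session")
def default_study():
    """Default-condition study (6x6 lattice, 24 months)."""
    return simulate_study(SyntheticScenario(), seed=7)


@pytest.fixture(scope="session")
def small_fit(small_study):
    """A short but usable MCMC fit on the small study."""
    spec = ModelSpec(mcmc=MCMCSettings(n_iter=2500, burn_in=500, thin=4, seed=11))
    return STCARModel(small_study.panel, small_study.adjacency, spec).fit()


def make_panel(Y, E, area_ids, T, covariates=None):
    """Assemble a valid panel DataFrame from (K, T) arrays."""
    K = len(area_ids)
    Y = np.asarray(Y, dtype=float).reshape(K, T)
    E = np.asarray(E, dtype=float).reshape(K, T)
    df = pd.DataFrame(
        {
            "area_id": np.tile(area_ids, T),
            "month_index": np.repeat(np.arange(1, T + 1), K),
            "calendar_month": np.repeat(((np.arange(T)) % 12) + 1, K),
            "observed": Y.T.reshape(-1),
            "expected": E.T.reshape(-1),
        }
    )
    if covariates:
        for name, arr in covariates.items():
            df[name] = np.asarray(arr, dtype=float).reshape(K, T).T.reshape(-1)
    return df
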