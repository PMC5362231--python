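import numpy as np
import pandas as pd
import pytest

from occufit.prep import DetectionDataset
from occufit.simulate import RecordSimConfig, ScenarioConfig, simulate_opportunistic_records


@pytest.fixture(scope="session")
def record_table() -> pd.DataFrame:
    """Small opportunistic record table with a reasonably common target."""
    cfg = RecordSimConfig(
        n_sites=40,
        n_species=6,
        n_years=4,
        activity_windows=((14, 39), (14, 39), (18, 30), (20, 26), (14, 39), (25, 39)),
        commonness=(0.5, 0.4, 0.3, 0.25, 0.35, 0.2),
        visit_rate=8.0,
        seed=42,
    )
    return simulate_opportunistic_records(cfg)


@pytest.fixture(scope="session")
def small_scenario() -> ScenarioConfig:
    return ScenarioConfig(
        n_sites=200, n_years=4, n_visits=5, p_detect=0.3, missing_fraction=0.2, seed=7
    )


def make_dataset(y, x=None, visit_covariates=None, year=1) -> DetectionDataset:
    """Assemble a DetectionDataset directly from arrays for model tests."""
    y = np.asarray(y, dtype=float)
    kwargs = {}
    if x is not None:
        x = np.asarray(x, dtype=float)
        kwargs.update(
            W=x[:, None],
            occupancy_covariate_names=["x"],
            standardisation={"x": (0.0, 1.0)},
        )
    return DetectionDataset(
        year=year,
        site_ids=list(range(y.shape[0])),
        y=y,
        visit_covariates=visit_covariates or {},
        **kwargs,
    )


def simulate_simple(rng, S, T, psi, p, x=None, beta1=0.0):
    """Constant-parameter (or single-covariate) occupancy data generator.

    Independent of the model module: direct Bernoulli sampling.
    """
    from scipy.special import expit, logit

    if x is None:
        psi_i = np.full(S, psi)
    else:
        psi_i = expit(logit(psi) + beta1 * x)
    z = rng.random(S) < psi_i
    y = (rng.random((S, T)) < p) & z[:, None]
    return y.astype(float), z
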