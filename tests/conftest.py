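import numpy as np
import pandas as pd
import pytest

from lhfi.data import AMBI_SCHEME, BenthicDataset, CovariateTable, build_centered_design
from lhfi.model import ModelSpec, ParamState
from lhfi.synthetic import SyntheticScenario, simulate_dataset


@pytest.fixture(scope="session")
def scheme():
    return AMBI_SCHEME


@pytest.fixture(scope="session")
def richibucto_like():
    """One default synthetic survey: (counts, covariates, truth)."""
    return simulate_dataset(SyntheticScenario(seed=42))


@pytest.fixture
def tiny_counts():
    """Three sites, two replicates each, hand-sized totals."""
    rows = []
    rng = np.random.default_rng(7)
    for s in range(1, 4):
        for r in (1, 2):
            m = rng.integers(0, 8, size=5)
            rows.append(
                {"site": s, "month": "Sep", "replicate": r,
                 **{f"m{i + 1}": int(m[i]) for i in range(5)},
                 "total": int(m.sum() + rng.integers(5, 20))}
            )
    return BenthicDataset(pd.DataFrame(rows))


@pytest.fixture
def tiny_covariates():
    return CovariateTable(pd.DataFrame({
        "site": [1, 2, 3],
        "month": ["Sep", "Sep", "Sep"],
        "depth_m": [2.0, 3.5, 5.0],
        "temp_c": [15.0, 14.0, 16.0],
        "salinity_ppt": [18.0, 21.0, 24.0],
        "silt_clay": [0.3, 0.5, 0.7],
        "median_grain": [120.0, 100.0, 90.0],
        "sorting": [1.4, 1.6, 1.5],
        "organic_pct": [2.0, 2.5, 3.0],
        "dd_km": [0.0, 2.0, 5.0],
    }))


def random_state(spec: ModelSpec, n_sites: int, rng: np.random.Generator) -> ParamState:
    """A random interior ParamState consistent with a model spec."""
    state = ParamState(
        H=rng.normal(0, 1, n_sites),
        delta_minus=float(rng.normal()),
        gamma=rng.normal(0, 0.5, 5),
        beta0=float(rng.normal()),
        beta=rng.normal(0, 0.5, spec.n_beta),
        sigma_eps=float(rng.uniform(0.5, 1.5)),
        sigma_gamma=float(rng.uniform(0.5, 1.5)) if spec.metric_cov_structure == "iid" else None,
    )
    if spec.metric_cov_structure != "iid":
        A = rng.normal(size=(5, 5))
        full = A @ A.T / 5 + np.eye(5)
        state.Sigma_pp = full[:2, :2]
        state.Sigma_mm = full[2:, 2:]
        if spec.metric_cov_structure == "unstructured":
            state.Sigma_pm = full[:2, 2:]
    if spec.two_level:
        state.b0 = float(rng.normal())
        state.b1 = float(rng.normal())
        state.sigma_s = float(rng.uniform(0.5, 1.5))
        if spec.b_bivariate:
            state.rho = float(rng.uniform(-0.9, 0.9))
    return state


@pytest.fixture
def make_state():
    return random_state
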