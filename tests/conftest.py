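import numpy as np
import pandas as pd
import pytest

import migsim as ms


@pytest.fixture(scope="session")
def tiny_panel() -> ms.FlowPanel:
    """2 locations x 2 years, complete."""
    df = pd.DataFrame(
        {
            "origin": ["A", "B", "A", "B"],
            "destination": ["B", "A", "B", "A"],
            "year": [2002, 2002, 2003, 2003],
            "flow": [5.0, 3.0, 7.0, 2.0],
        }
    )
    return ms.FlowPanel(df)


@pytest.fixture(scope="session")
def synth_truth() -> ms.SyntheticTruth:
    return ms.SyntheticTruth(seed=3)


@pytest.fixture(scope="session")
def synth_panel(synth_truth) -> ms.FlowPanel:
    return ms.generate_panel(synth_truth)


@pytest.fixture(scope="session")
def full_spec() -> ms.ModelSpec:
    return ms.ModelSpec(
        predictors={"log_distance": "none", "tie": "none", "log_ratio": "none"},
        fixed_effects=("origin", "destination", "year"),
        clusters=("origin", "destination", "year"),
    )


@pytest.fixture(scope="session")
def robust_spec() -> ms.ModelSpec:
    return ms.ModelSpec(
        predictors={"log_distance": "none", "tie": "none", "log_ratio": "none"},
        fixed_effects=("origin", "destination", "year"),
        clusters=(),
    )


@pytest.fixture(scope="session")
def fitted_model(synth_panel, full_spec) -> ms.FittedModel:
    """One three-way-clustered PPML fit shared across tests."""
    import warnings

    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        return ms.fit_ppml(synth_panel, full_spec)


def random_matrix(rng: np.random.Generator, n: int) -> np.ndarray:
    """Random nonnegative flow matrix with zero diagonal (test helper)."""
    m = rng.gamma(1.0, 10.0, size=(n, n))
    zeros = rng.uniform(size=(n, n)) < 0.2
    m[zeros] = 0.0
    np.fill_diagonal(m, 0.0)
    return m
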