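import numpy as np
import pytest

import raasid


@pytest.fixture(scope="session")
def default_cohort():
    """One default synthetic cohort shared across tests (seed 7)."""
    return raasid.generate_cohort(raasid.default_config(seed=7))


@pytest.fixture(scope="session")
def standardized_panel(default_cohort):
    raw = raasid.BiomarkerMatrix(
        default_cohort[list(raasid.BIOMARKERS)].to_numpy(float)
    )
    logm = raasid.log_transform(raw)
    return raasid.standardize(logm), logm


@pytest.fixture(scope="session")
def canonical_solution(default_cohort, standardized_panel):
    std, logm = standardized_panel
    sol = raasid.kmeans_fit(std.values, 3, seed=7)
    return raasid.canonical_relabel(sol, logm.values)


def three_blobs(n_per=50, spread=0.3, seed=0):
    """Three well-separated Gaussian blobs in 3-D."""
    rng = np.random.default_rng(seed)
    centers = np.array([[0, 0, 0], [4, 0, 0], [0, 4, 4]], dtype=float)
    X = np.vstack(
        [c + spread * rng.standard_normal((n_per, 3)) for c in centers]
    )
    truth = np.repeat([1, 2, 3], n_per)
    return X, truth
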