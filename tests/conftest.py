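import numpy as np
import pytest

import activelife as al


@pytest.fixture(scope="session")
def grid():
    return al.AgeGrid()


@pytest.fixture(scope="session")
def three_level_params():
    return al.default_params(al.THREE_LEVEL, n=30_000)


@pytest.fixture(scope="session")
def three_level_panel(three_level_params):
    return al.generate_cohort(three_level_params, seed=42)


@pytest.fixture(scope="session")
def three_level_lifetable(three_level_params, grid):
    return al.implied_reference_lifetable(three_level_params, grid.reported_ages)


@pytest.fixture(scope="session")
def three_level_fit(three_level_panel, three_level_lifetable):
    return al.estimate_expectancies(
        three_level_panel, three_level_lifetable, al.THREE_LEVEL
    )


def constant_probabilities(p_matrix, q_vector, ages):
    """TransitionProbabilities with identical rows at every grid age."""
    p = np.asarray(p_matrix, dtype=float)
    q = np.asarray(q_vector, dtype=float)
    k = len(q)
    tp = al.TransitionProbabilities(
        ages=np.asarray(ages, dtype=float),
        k=k,
        p=np.repeat(p[None, :, :], len(ages), axis=0),
        q=np.repeat(q[None, :], len(ages), axis=0),
    )
    return tp
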