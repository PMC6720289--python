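import numpy as np
import pytest
from hypothesis import settings

settings.register_profile("deterministic", database=None, derandomize=True, deadline=None)
settings.load_profile("deterministic")

from mepgp import DeviationConfig, IndicatorPanel, epi2018_hierarchy


def make_random_panel(rng: np.random.Generator, n: int, m: int) -> IndicatorPanel:
    """Uniform(0, 100) panel with generic (continuous) entries."""
    return IndicatorPanel(
        country_ids=[f"C{i}" for i in range(n)],
        indicator_codes=[f"X{j}" for j in range(m)],
        scores=rng.uniform(0.0, 100.0, size=(n, m)),
    )


def assert_solution_identities(sol, panel, tol=1e-6):
    """Structural identities every goal-programming solve must satisfy."""
    scale = max(1.0, float(np.abs(panel.scores).max()))
    assert (sol.weights >= 0).all()
    assert abs(sol.weights.sum() - 1.0) <= tol
    # goal equations with closed-form deviations
    resid = sol.mep[:, None] + sol.dev_neg - sol.dev_pos - panel.scores
    assert np.abs(resid).max() <= tol * scale
    # complementarity after post-processing
    assert (np.minimum(sol.dev_neg, sol.dev_pos) <= tol).all()
    # accounting: Z is the sum of per-indicator disagreements
    assert abs(sol.z - sol.disagreements.sum()) <= tol * max(1.0, sol.z)
    if (sol.config.alpha == 1).all() and (sol.config.beta == 1).all():
        assert abs(sol.z_weighted - sol.z) <= tol * max(1.0, sol.z)
    # composite scores are convex combinations of each country's scores
    assert (sol.mep >= panel.scores.min(axis=1) - tol * scale).all()
    assert (sol.mep <= panel.scores.max(axis=1) + tol * scale).all()


@pytest.fixture(scope="session")
def epi_hierarchy():
    return epi2018_hierarchy()


@pytest.fixture
def rng():
    return np.random.default_rng(20240901)


@pytest.fixture
def small_panel(rng):
    return make_random_panel(rng, 5, 3)


@pytest.fixture
def all_ones():
    return lambda m: DeviationConfig.all_ones(m)
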