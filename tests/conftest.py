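import numpy as np
import pytest

from revaci.presets import simulate_tone_session


@pytest.fixture(scope="session")
def small_session():
    """300-trial closed-loop tone-in-noise session (coarse 1-ERB frontend)."""
    return simulate_tone_session(n_presentation=150, master_seed=3, bwmul=1.0)


@pytest.fixture(scope="session")
def planted_session():
    """Full-scale 4,000-trial simulated session at 0.5-ERB resolution.

    The observer's internal template is the planted ground truth that the
    estimators should recover.
    """
    return simulate_tone_session(n_presentation=2000, master_seed=7, bwmul=0.5)


@pytest.fixture(scope="session")
def planted_lambda_path(planted_session):
    """Cross-validated lambda search on the planted-template session."""
    from revaci.estimation import search_lambda
    _, tensor, r, _ = planted_session
    lam, path = search_lambda(tensor, r, "l1_basis",
                              rng=np.random.default_rng(1))
    return lam, path
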