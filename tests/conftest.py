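import numpy as np
import pandas as pd
import pytest

from discountlab.agents import PopulationParams, generate_study
from discountlab.task import EXPERIENTIAL, HYPOTHETICAL


@pytest.fixture(scope="session")
def experiential():
    return EXPERIENTIAL


@pytest.fixture(scope="session")
def hypothetical():
    return HYPOTHETICAL


@pytest.fixture(scope="session")
def small_study():
    """Deterministic 6-agent study used by reader/pipeline tests."""
    return generate_study(PopulationParams(n=6, seed=7, tau=0.0), seed=7)


@pytest.fixture(scope="session")
def full_study():
    """Deterministic 44-agent study at the default population anchors."""
    return generate_study(PopulationParams(n=44, seed=5), seed=5)


def elicit_points(agents, config, seed0):
    """Session-per-agent helper returning a tidy indifference-point table."""
    from discountlab.task import run_session

    rows = []
    for i, ag in enumerate(agents):
        rng = np.random.default_rng(seed0 + 7919 * i)
        _, points = run_session(config, ag.policy(config, rng),
                                seed0 + 104729 * i, f"p{i:03d}")
        rows += [{"participant_id": p.participant_id, "delay": p.delay,
                  "value": p.value, "at_boundary": p.at_boundary.value}
                 for p in points]
    return pd.DataFrame(rows)
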