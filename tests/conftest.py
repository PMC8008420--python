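import numpy as np
import pytest

from swgee import (
    ClusterSizeSpec,
    CorrelationSpec,
    MarginalSpec,
    build_design,
    simulate_trial,
)


@pytest.fixture(scope="session")
def design3():
    return build_design(3, 18)


@pytest.fixture(scope="session")
def design6():
    return build_design(6, 18)


@pytest.fixture(scope="session")
def small_trial():
    """One simulated 12-cluster trial, exchangeable ICC 0.05, constant size."""
    design = build_design(3, 12)
    return simulate_trial(
        design,
        MarginalSpec(),
        CorrelationSpec.from_name("exchangeable", 0.05),
        ClusterSizeSpec(mean_total=24, cv=0.0),
        seed=20260920,
    )


@pytest.fixture()
def rng():
    return np.random.default_rng(915)
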