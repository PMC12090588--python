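import numpy as np
import pytest

from priorelicit import (CONSENSUS_ADA, CONSENSUS_SEC, BetaPrior, JointPrior,
                         NormalPrior, TrialDesign, solve_log_or_prior)


@pytest.fixture(scope="session")
def consensus_ada() -> BetaPrior:
    """Consensus control-arm (adalimumab) beta prior: mean 0.67, ESS 15.7."""
    return CONSENSUS_ADA


@pytest.fixture(scope="session")
def consensus_sec() -> BetaPrior:
    """Consensus experimental-arm (secukinumab) beta prior: mean 0.55, ESS 13.1."""
    return CONSENSUS_SEC


@pytest.fixture(scope="session")
def consensus_log_or(consensus_ada, consensus_sec) -> NormalPrior:
    """Log-OR prior whose pushforward of the control prior matches the
    experimental consensus beta in mean and variance."""
    return solve_log_or_prior(consensus_ada, consensus_sec)


@pytest.fixture(scope="session")
def consensus_joint(consensus_ada, consensus_log_or) -> JointPrior:
    return JointPrior(consensus_ada, consensus_log_or)


@pytest.fixture
def default_design() -> TrialDesign:
    return TrialDesign()


@pytest.fixture
def rng() -> np.random.Generator:
    return np.random.default_rng(20231010)
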