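import numpy as np
import pytest

from fcnet import CohortConfig, ConnectomeStudy, simulate_cohort
from fcnet.synth import EffectSpec


@pytest.fixture
def rng():
    return np.random.default_rng(12345)


@pytest.fixture(scope="session")
def tiny_cohort():
    """Small two-group cohort (4 IS / 5 NIS, 120 volumes) for pipeline tests."""
    cfg = CohortConfig(n_is=4, n_nis=5, n_volumes=120)
    return simulate_cohort(cfg, seed=7)


@pytest.fixture(scope="session")
def tiny_results(tiny_cohort):
    """A fitted study on the tiny cohort (reduced nulls/permutations)."""
    study = ConnectomeStudy.from_cohort(tiny_cohort)
    return study.fit(n_random=5, n_perm=200, seed=7)


@pytest.fixture(scope="session")
def single_effect_config():
    """Cohort config with the planted weakening confined to AAL node 13."""
    return CohortConfig(
        weaken=EffectSpec((13,), 0.6, "weaken"),
        strengthen=EffectSpec((74,), 1.0, "strengthen"),
    )
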