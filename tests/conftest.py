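import pytest

from orbench.qa import generate_for_case
from orbench.simulate import SimConfig, assign_splits, simulate_corpus


@pytest.fixture(scope="session")
def small_config():
    return SimConfig(n_cases_per_source=3, timepoints_per_case=20, seed=11)


@pytest.fixture(scope="session")
def small_corpus(small_config):
    return simulate_corpus(small_config)


@pytest.fixture(scope="session")
def small_splits(small_corpus):
    return assign_splits([(tl.case_id, tl.source_tag) for tl in small_corpus], (0.4, 0.3, 0.3), seed=5)


@pytest.fixture(scope="session")
def small_pool(small_corpus, small_splits):
    pool = []
    for tl in small_corpus:
        for qa in generate_for_case(tl):
            qa.split = small_splits[tl.case_id]
            pool.append(qa)
    return pool
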