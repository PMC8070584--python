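import pytest

import regmra as r


@pytest.fixture(scope="session")
def truth():
    """Default planted truth: 7 MRs in clusters of 2 and 5, 3 decoy TFs."""
    return r.generate_truth(r.TruthConfig(seed=11))


@pytest.fixture(scope="session")
def cohort(truth):
    """One reference expression cohort of 120 samples."""
    return r.simulate_cohort(truth, 120, seed=7, label="c")


@pytest.fixture(scope="session")
def tnet(truth):
    """The planted truth expressed as a network (noise-free modes)."""
    return r.truth_network(truth)


@pytest.fixture(scope="session")
def inferred(truth, cohort):
    """A network inferred from the reference cohort (shared across tests)."""
    return r.infer_network(cohort.expression, truth.tf_ids, seed=3)
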