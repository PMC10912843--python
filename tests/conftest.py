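import numpy as np
import pytest

from hmmdyn.simulate import simulate_cohort
from hmmdyn.validation import k3_recovery_spec


@pytest.fixture(scope="session")
def k3_syn():
    """A well-separated 3-state synthetic cohort (20 subjects, T=220)."""
    return simulate_cohort(k3_recovery_spec(seed=11))


@pytest.fixture(scope="session")
def k3_fit(k3_syn):
    """One fitted 3-state model + decoded paths on the session cohort."""
    from hmmdyn.hmm import fit_hmm

    model, paths = fit_hmm(k3_syn.cohort, 3, n_restarts=2, seed=11,
                           tol=1e-6, max_iter=300)
    return model, paths


@pytest.fixture()
def toy_path():
    """The worked 10-timepoint, 3-state path used across metric examples."""
    return [1, 1, 2, 2, 2, 1, 3, 3, 1, 1]


@pytest.fixture()
def rng():
    return np.random.default_rng(0)
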