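"""Shared synthetic fixtures for the loopnet test suite."""

import pytest

from loopnet import priors, synthetic


@pytest.fixture(scope="session")
def truth30():
    """30-gene / 5-regulator ground-truth DAG."""
    return synthetic.generate_true_network(30, 5, 3.0, seed=7)


@pytest.fixture(scope="session")
def landscape30(truth30):
    """Landscape over truth30 with a 0.3 decoy binding rate."""
    return synthetic.generate_landscape(truth30, decoy_binding_rate=0.3, seed=1)


@pytest.fixture(scope="session")
def clean_landscape30(truth30):
    """Decoy-free landscape: implied prior pairs equal the truth edges."""
    return synthetic.generate_landscape(truth30, decoy_binding_rate=0.0, seed=2)


@pytest.fixture(scope="session")
def prior30(landscape30):
    return priors.build_tf_priors(landscape30)


@pytest.fixture(scope="session")
def expr30(truth30):
    return synthetic.simulate_expression(truth30, n_samples=300, noise_sd=0.5, seed=3)


@pytest.fixture(scope="session")
def data30(expr30):
    return expr30.discretize()
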