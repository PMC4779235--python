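import pytest

from alertminer import FixtureSpec, generate_categorical_set, generate_continuous_set


@pytest.fixture(scope="session")
def categorical_spec():
    return FixtureSpec(n_molecules=200, p_frag_given_active=0.4,
                       p_frag_given_inactive=0.02, seed=11)


@pytest.fixture(scope="session")
def categorical_train(categorical_spec):
    return generate_categorical_set(categorical_spec)


@pytest.fixture(scope="session")
def continuous_spec():
    return FixtureSpec(n_molecules=300, carrier_fraction=0.2, shift=1.0,
                       noise_sd=0.3, baseline=6.0, seed=11)


@pytest.fixture(scope="session")
def continuous_train(continuous_spec):
    return generate_continuous_set(continuous_spec)
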