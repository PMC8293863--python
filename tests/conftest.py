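import pytest

from evidfn import bernoulli, bernoulli_closed_forms

# the worked Bernoulli comparison used throughout: candidates at 0.75 / 0.50,
# truth at 0.65 (slightly closer to the first candidate)
P1, P2, PG = 0.75, 0.50, 0.65


@pytest.fixture(scope="session")
def bern_triple():
    return bernoulli(PG), bernoulli(P1), bernoulli(P2)


@pytest.fixture(scope="session")
def ds_misspec():
    """Divergence set of the misspecified worked example."""
    return bernoulli_closed_forms(P1, P2, PG)


@pytest.fixture(scope="session")
def ds_correct():
    """Divergence set with truth equal to the first candidate."""
    return bernoulli_closed_forms(P1, P2, P1)
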