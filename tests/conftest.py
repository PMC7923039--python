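import pytest

from fluxnode import make_fixture, random_model

RANDOM_SIZES = [(5, 8), (6, 9), (7, 10), (8, 12), (10, 15)]


@pytest.fixture
def toy(request):
    return make_fixture(request.param)


def random_suite(n_models: int = 20, seed0: int = 1234):
    """Deterministic collection of feasible random models."""
    out = []
    for k in range(n_models):
        n_met, n_rxn = RANDOM_SIZES[k % len(RANDOM_SIZES)]
        out.append(random_model(n_met, n_rxn, seed=seed0 + k))
    return out


@pytest.fixture(scope="session")
def random_models():
    return random_suite(20)
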