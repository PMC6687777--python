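import pytest
from hypothesis import HealthCheck, settings

from pangem import fixtures as fx

settings.register_profile(
    "ci",
    derandomize=True,
    max_examples=60,
    deadline=None,
    suppress_health_check=[HealthCheck.too_slow],
)
settings.load_profile("ci")


@pytest.fixture
def toy_model():
    return fx.make_toy_gem()


@pytest.fixture
def toy_medium(toy_model):
    return fx.minimal_medium(toy_model)


@pytest.fixture
def toy_ec(toy_model):
    from pangem import build_ec_model

    kcats = fx.make_kcat_table(toy_model, seed=1)
    enzymes = fx.make_enzyme_table(toy_model, seed=1)
    return build_ec_model(toy_model, kcats, enzymes)


@pytest.fixture
def synthetic_genes():
    return fx.make_synthetic_genes(seed=2, n_genes=4, protein_length=40)
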