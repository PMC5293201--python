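import pytest

from ferronet import CompiledModel, build_iron_model, toy_catalog


@pytest.fixture(scope="session")
def iron_model():
    return build_iron_model()


@pytest.fixture(scope="session")
def iron_compiled(iron_model):
    return CompiledModel(iron_model)


@pytest.fixture(scope="session")
def toys():
    return {toy.name: toy for toy in toy_catalog()}
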