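import pytest

from medcea import list_packaged_configs, load_packaged_config
from medcea.parameters import ModelConfig


@pytest.fixture(scope="session")
def epi_config() -> ModelConfig:
    return load_packaged_config("epinephrine_2019")


@pytest.fixture(scope="session")
def all_configs() -> list[ModelConfig]:
    return [load_packaged_config(name) for name in list_packaged_configs()]


def make_all_fixed(config: ModelConfig) -> ModelConfig:
    """Copy of a scenario with every distribution degenerate at its mean."""
    raw = config.model_dump(mode="json")

    def strip(node):
        if isinstance(node, dict):
            for key, value in node.items():
                if key == "distribution":
                    node[key] = {"kind": "fixed"}
                else:
                    strip(value)
        elif isinstance(node, list):
            for item in node:
                strip(item)

    strip(raw)
    return ModelConfig.model_validate(raw)
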