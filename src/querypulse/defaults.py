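"""Packaged default fixtures: taxonomy, domain registry, generator config."""

from __future__ import annotations

from importlib import resources

from .config import GeneratorConfig
from .taxonomy import KeywordTaxonomy
from .urls import DomainRegistry

CONTROL_CATEGORY = "control"


def _data_path(name: str):
    return resources.files("querypulse.data").joinpath(name)


def default_taxonomy() -> KeywordTaxonomy:
    with resources.as_file(_data_path("taxonomy.yaml")) as p:
        return KeywordTaxonomy.from_yaml(p)


def default_registry() -> DomainRegistry:
    with resources.as_file(_data_path("registry.yaml")) as p:
        return DomainRegistry.from_yaml(p)


def default_generator_config() -> GeneratorConfig:
    """The study-condition fixture: scaled daily baselines, decaying event
    effect calibrated to the published category deltas, spikes at days −6
    and −11, event-agnostic control."""
    with resources.as_file(_data_path("generator.yaml")) as p:
        return GeneratorConfig.from_yaml(p)
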