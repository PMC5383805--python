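import math

import pytest

from querypulse import (
    CategoryProfile,
    GeneratorConfig,
    Spike,
    default_generator_config,
    default_registry,
    default_taxonomy,
)


@pytest.fixture(scope="session")
def taxonomy():
    return default_taxonomy()


@pytest.fixture(scope="session")
def registry():
    return default_registry()


@pytest.fixture(scope="session")
def fixture_config():
    return default_generator_config()


def small_config(
    baseline: float = 50.0,
    multiplier: float = 2.0,
    halflife: float = math.inf,
    spikes: list | None = None,
    control_baseline: float = 50.0,
    window_days: int = 14,
    seed: int = 0,
) -> GeneratorConfig:
    """Compact two-category config used across tests: one firearm category
    with a configurable event effect plus the bicycle control."""
    return GeneratorConfig(
        profiles=[
            CategoryProfile(
                name="gun_type",
                baseline_rate=baseline,
                event_multiplier=multiplier,
                decay_halflife_days=halflife,
                query_templates=["buy handgun online", "rifle reviews"],
                domain_weights={
                    "armslockerusa.com": 0.40,
                    "nationalnewswire.com": 0.25,
                    "dailymixdigest.com": 0.15,
                    "shootersalliance.org": 0.12,
                    "safercommunitiesfund.org": 0.08,
                },
            ),
        ],
        control_profile=CategoryProfile(
            name="control",
            baseline_rate=control_baseline,
            query_templates=["bicycle shop near me", "kids bike sale"],
            domain_weights={"bikebarn.com": 0.6, "dailymixdigest.com": 0.4},
        ),
        spikes=[Spike(*s) for s in (spikes or [])],
        window_days=window_days,
        seed=seed,
    )
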