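import numpy as np
import pytest

from landscape_forge.landscape import (
    ADDITIVE_CONFIG,
    GroundTruthLandscape,
    LandscapeConfig,
    make_landscape,
)


@pytest.fixture(scope="session")
def flat_landscape() -> GroundTruthLandscape:
    """Small near-additive landscape (no epistatic terms)."""
    return make_landscape(40, LandscapeConfig(), seed=7)


@pytest.fixture(scope="session")
def additive_landscape() -> GroundTruthLandscape:
    """Strict additive null: fluorescence-additive transform, no epistatic terms."""
    return make_landscape(40, LandscapeConfig(**ADDITIVE_CONFIG), seed=7)


@pytest.fixture(scope="session")
def sharp_landscape() -> GroundTruthLandscape:
    """Small epistasis-dense landscape."""
    cfg = LandscapeConfig(
        neutral_fraction=0.30,
        deleterious_scale=0.9,
        epistatic_density=3.0,
        epistatic_scale=0.6,
    )
    return make_landscape(40, cfg, seed=11)


def toy_landscape(effects: dict, terms: dict | None = None, seed: int = 3, length: int = 40):
    """Landscape with handcrafted additive effects (all others neutral)."""
    base = make_landscape(length, LandscapeConfig(neutral_fraction=1.0, neutral_sd=0.0), seed=seed)
    for key, val in effects.items():
        base.additive_effects[key] = val
    base.epistatic_terms = dict(terms or {})
    return base
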