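import pytest

from auxogem import ViabilityPolicy
from auxogem.fixtures import (
    PrecursorFlags,
    ToyGemConfig,
    make_toy_gem,
    yeast9_skeleton,
)

TRAP_FEATURES = (
    PrecursorFlags(),
    PrecursorFlags(bypass=True),
    PrecursorFlags(no_exchange=True),
    PrecursorFlags(isoenzyme=True),
    PrecursorFlags(medium_conditional=True),
)


@pytest.fixture(scope="session")
def basic_toy():
    """Three clean one-step pathways: every pathway gene essential and
    rescuable through its precursor exchange."""
    return make_toy_gem(ToyGemConfig(seed=11))


@pytest.fixture(scope="session")
def trap_toy():
    """Five precursors exercising every planted trap and GPR motif."""
    return make_toy_gem(
        ToyGemConfig(n_precursors=5, features=TRAP_FEATURES, seed=23)
    )


@pytest.fixture(scope="session")
def trap_policy(trap_toy):
    model, _ = trap_toy
    return ViabilityPolicy.from_model(model)


@pytest.fixture(scope="session")
def skeleton():
    return yeast9_skeleton()
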