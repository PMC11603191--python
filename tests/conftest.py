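import numpy as np
import pytest

from hoxscan import (
    build_all_profiles,
    simulate_reference_alignment,
)


@pytest.fixture(scope="session")
def ref_alignment():
    """Session-wide labelled homeodomain reference alignment (seeded)."""
    return simulate_reference_alignment(11)


@pytest.fixture(scope="session")
def profiles(ref_alignment):
    """Calibrated profiles for all nine orthology groups."""
    return build_all_profiles(ref_alignment, seed=0)


@pytest.fixture(scope="session")
def profiles_by_group(profiles):
    return {p.group: p for p in profiles}


@pytest.fixture
def rng():
    return np.random.default_rng(0)
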