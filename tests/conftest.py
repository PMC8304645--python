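import numpy as np
import pytest
from hypothesis import settings

settings.register_profile("ci", derandomize=True, max_examples=25, deadline=None)
settings.load_profile("ci")

from ifacedyn import ToyComplexSpec, make_toy_complex


@pytest.fixture
def toy_complex():
    """A saturated 5x5 toy complex (every cross pair is a true contact)."""
    return make_toy_complex(ToyComplexSpec(contact_fraction=1.0, seed=42))


@pytest.fixture
def toy_factory():
    """Factory for toy complexes with arbitrary spec overrides."""

    def build(**kwargs):
        return make_toy_complex(ToyComplexSpec(**kwargs))

    return build
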