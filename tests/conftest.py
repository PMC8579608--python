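import numpy as np
import pytest

from gfrval.stats import GFRPair


@pytest.fixture
def rng():
    return np.random.default_rng(20240917)


def make_pairs(egfr, mgfr, prefix="P"):
    """Build GFRPair lists from two aligned arrays."""
    return [
        GFRPair(f"{prefix}{i}", float(e), float(m))
        for i, (e, m) in enumerate(zip(egfr, mgfr))
    ]


@pytest.fixture
def pair_factory():
    return make_pairs


@pytest.fixture
def random_pairs(rng):
    """A noisy but realistic paired cohort (n=60)."""
    mgfr = rng.lognormal(3.9, 0.8, 60)
    egfr = mgfr * np.exp(rng.normal(0.05, 0.25, 60))
    return make_pairs(egfr, mgfr)
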