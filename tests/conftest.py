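import numpy as np
import pytest
from hypothesis import settings

from eradev.landscapes import (
    FitnessLandscape,
    SyntheticSpec,
    generate_synthetic_landscape,
    scale_landscape,
)
from eradev.synthetic_fixtures import make_biased_reference_policy

settings.register_profile("ci", derandomize=True, max_examples=50)
settings.load_profile("ci")


@pytest.fixture
def toy_two_by_two():
    """2 positions x 2 letters with fitnesses (w00, w10, w01, w11) = (0,1,1,3)."""
    return FitnessLandscape(
        positions=(1, 2),
        parent="AA",
        alphabet="AC",
        table={"AA": 0.0, "CA": 1.0, "AC": 1.0, "CC": 3.0},
        name="toy2x2",
    )


@pytest.fixture
def small_epistatic():
    """Complete 2x3 landscape with pairwise couplings, plus its scaling."""
    l = generate_synthetic_landscape(
        SyntheticSpec(n_positions=2, alphabet_size=3, pairwise_scale=0.8, seed=3)
    )
    return scale_landscape(l)


@pytest.fixture
def additive_landscape():
    """Purely additive 3x4 landscape: no couplings, no noise, linear link so
    additivity holds in fitness space, not just in latent-score space."""
    return generate_synthetic_landscape(
        SyntheticSpec(
            n_positions=3,
            alphabet_size=4,
            pairwise_scale=0.0,
            higher_order_scale=0.0,
            noise_sd=0.0,
            seed=1,
            link="linear",
        )
    )


@pytest.fixture
def rugged_landscape():
    """3x8 landscape with couplings and an idiosyncratic term."""
    return generate_synthetic_landscape(
        SyntheticSpec(
            n_positions=3, alphabet_size=8, pairwise_scale=1.0, higher_order_scale=0.5, seed=2
        )
    )


@pytest.fixture
def biased_reference(small_epistatic):
    return make_biased_reference_policy(small_epistatic.base, bias=0.2, seed=4)
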