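import numpy as np
import pytest

from icdquant import ChannelSpec, SyntheticFieldSpec, make_field


@pytest.fixture
def small_field():
    """A small field with 10 disjoint nuclei and its planted truth."""
    spec = SyntheticFieldSpec(
        width=384,
        height=384,
        n_cells=10,
        channels=(
            ChannelSpec("dna", background=100, per_cell_level=2000, noise_sd=10),
            ChannelSpec("signal", background=50, per_cell_level=1000, noise_sd=10),
        ),
        seed=11,
    )
    field, labels, truth = make_field(spec)
    return spec, field, labels, truth


@pytest.fixture
def rng():
    return np.random.default_rng(1234)
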