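import numpy as np
import pytest

from cfdna_fragscore import synthgen


@pytest.fixture
def healthy_pop():
    """10,000-fragment healthy-donor population, fixed seed."""
    return synthgen.simulate_fragments(
        synthgen.healthy_spec(10_000, seed=42), sample_id="healthy"
    )


@pytest.fixture
def mono170_pop():
    """Degenerate population: every fragment exactly 170 bp."""
    return synthgen.FragmentPopulation(np.full(1000, 170), sample_id="mono170")


@pytest.fixture
def hmw_pop():
    """High molecular weight genomic DNA pool (~15 kb median)."""
    return synthgen.simulate_fragments(synthgen.hmw_spec(2000, seed=7), sample_id="hmw")
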