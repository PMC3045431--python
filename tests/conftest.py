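import pytest

from poolscreen.pileup import Amplicon
from poolscreen.simulate import PoolDesign


@pytest.fixture
def error_only_design():
    """A small pure-error pool: 600 positions, no variants, default rates."""
    return PoolDesign(
        n_individuals=311,
        amplicons=[Amplicon("chr1", 3_000_000, 3_000_600, 0, 0)],
        mean_depth_per_strand=500.0,
        seed=2000,
    )
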