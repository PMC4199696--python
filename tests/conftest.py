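import sys
from pathlib import Path

import pytest

sys.path.insert(0, str(Path(__file__).parent))  # make oracles importable

from homeosnp import simulate_rnaseq, simulate_tetraploid
from homeosnp.transcriptome import call_transcriptome


@pytest.fixture(scope="session")
def small_dataset():
    """20-kb, 3-variety dataset used by several unit tests."""
    return simulate_tetraploid(length=20_000, n_varieties=3, seed=11)


@pytest.fixture(scope="session")
def recovery_run():
    """The full-scale error-free parameter-recovery run (shared: expensive).

    200-kb reference, 1% subgenome divergence, 4 varieties at varietal rate
    5e-4, 40x error-free coverage per variety, no expression bias.
    """
    ds = simulate_tetraploid(length=200_000, n_varieties=4,
                             subgenome_rate=0.01, varietal_rate=5e-4, seed=1)
    reads, origins = simulate_rnaseq(ds.varieties, depth=40, error_rate=0.0,
                                     seed=2)
    calls, anchors, stats = call_transcriptome(
        reads, {ds.reference.name: len(ds.reference)})
    return ds, reads, calls, anchors, stats
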