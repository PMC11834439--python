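import sys
from pathlib import Path

import numpy as np
import pytest

sys.path.insert(0, str(Path(__file__).parent))  # makes `oracles` importable


@pytest.fixture
def rng():
    return np.random.default_rng(20240917)


@pytest.fixture(scope="session")
def warm_kernels():
    """Trigger numba compilation once per session on a tiny alignment."""
    from anifrac import GenomeRecord, seed_and_extend
    from anifrac.align_engine import KmerIndex
    from anifrac.scoring import ACCURATE, ScoringScheme

    g = GenomeRecord("warm", "ACGTACGTACGTACGTACGTACGTACGT")
    idx = KmerIndex([g], 11, "nt")
    seed_and_extend(g, idx, ScoringScheme.preset("UNIT"), ACCURATE)
    return True
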