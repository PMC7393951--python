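import sys
from pathlib import Path

import numpy as np
import pytest

sys.path.insert(0, str(Path(__file__).parent))  # make oracles importable

from hadalpan.simulate import CladeConfig, simulate_clade


@pytest.fixture(scope="session")
def small_clade():
    """A 4-genome clade with planted families, unique genes and 5%
    per-genome divergence — shared across tests that only read it."""
    cfg = CladeConfig(
        n_focal=2,
        n_background=2,
        n_core_genes=100,
        gene_length_codons=(120, 250),
        ani_targets=[0.05] * 4,
        unique_genes_per_focal=10,
        seed=3,
    )
    return cfg, *simulate_clade(cfg)


@pytest.fixture()
def rng():
    return np.random.default_rng(42)
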