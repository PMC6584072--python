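import numpy as np
import pytest

from helix_ieg import synthetic_data as synth


@pytest.fixture(scope="session")
def small_sim():
    """A small planted-effect simulation shared by read-only tests."""
    params = synth.SimParams(n_proteins=60, frac_ieg=0.25, effect_fc=3.0,
                             n_orphan_contigs=15, frac_consistent_homology=0.8,
                             seed=42)
    counts, design, truth, blastx, blastp, _ = synth.simulate_all(params)
    return params, counts, design, truth, blastx, blastp


@pytest.fixture
def rng():
    return np.random.default_rng(1234)
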