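import numpy as np
import pytest

from transpoly.alignment import AlleleAlignment


def make_alignment(seqs, species=None, genus=None, labels=None, **kw):
    n = len(seqs)
    labels = labels or [f"a{i}" for i in range(n)]
    species = species or ["sp1"] * n
    genus = genus or ["g1"] * n
    return AlleleAlignment(labels, seqs, species, genus, **kw)


@pytest.fixture
def rng():
    return np.random.default_rng(42)


@pytest.fixture
def small_alignment():
    """Four 12-nt alleles with a couple of substitutions."""
    return make_alignment(
        [
            "ATGGCTACTGCA",
            "ATGGCTACTGCA",
            "ATGGCAACTGCA",
            "ATGACTACTGCA",
        ]
    )


@pytest.fixture(scope="session")
def default_sim():
    """One full default simulation shared by read-only tests."""
    from transpoly.simulate import SimConfig, simulate_dataset

    cfg = SimConfig(seed=7)
    aln, reads, truth = simulate_dataset(cfg)
    return cfg, aln, reads, truth
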