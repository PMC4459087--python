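import pytest
from hypothesis import settings

settings.register_profile("ci", derandomize=True, max_examples=50)
settings.load_profile("ci")

import satclock as sc
from satclock.simulate import simulate_stylized_distances


@pytest.fixture(scope="session")
def model():
    return sc.SaturationModel()


@pytest.fixture(scope="session")
def reference_tree():
    return sc.make_reference_chronogram(0)


@pytest.fixture(scope="session")
def exact_stylized_distances(reference_tree):
    """Noise-free pairwise distances from the default saturation law."""
    return simulate_stylized_distances(reference_tree)


@pytest.fixture(scope="session")
def nuclear_alignments(reference_tree):
    return [
        sc.simulate_alignment(reference_tree, locus, seed=i)
        for i, locus in enumerate(sc.DEFAULT_NUCLEAR_LOCI)
    ]
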