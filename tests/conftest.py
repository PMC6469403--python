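import itertools

import pytest

from auanema.orthology import build_families, rbh
from auanema.synth import gen_species_set


@pytest.fixture(scope="session")
def fig9_dataset():
    """Default five-species synthetic genome set (seed 11)."""
    genes, hits, truth = gen_species_set(seed=11)
    return genes, hits, truth


@pytest.fixture(scope="session")
def fig9_families(fig9_dataset):
    """Ortholog families assembled from the default synthetic set."""
    genes, hits, _ = fig9_dataset
    species = sorted(genes)
    pairs = [
        rbh(hits[(a, b)], hits[(b, a)], a, b)
        for a, b in itertools.combinations(species, 2)
    ]
    return build_families(pairs, genes)


@pytest.fixture(scope="session")
def clean_dataset():
    """Noise-free synthetic genome set: no dropout, no spurious hits."""
    from auanema.synth import fig9_history

    history = fig9_history(
        shuffle_intensity=0.0, ortholog_dropout=0.0, spurious_hit_rate=0.0
    )
    genes, hits, truth = gen_species_set(history, genes_per_element=40, seed=5)
    return genes, hits, truth
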