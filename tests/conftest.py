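import sys
from pathlib import Path

import pytest

sys.path.insert(0, str(Path(__file__).parent))

from strainspec.orthology import cluster_orthologs, pairwise_similarity
from strainspec.simulate import PanGenomeSpec, PlantedDirective, simulate_pangenome


@pytest.fixture(scope="session")
def small_pangenome():
    """3 strains, 5 core groups, one 4-gene block planted in two strains."""
    spec = PanGenomeSpec(
        n_strains=3,
        core_size=5,
        accessory_size=6,
        planted_specific=[PlantedDirective(("Fp01", "Fp02"), 4)],
        mutation_rate=0.01,
        seed=1,
    )
    return simulate_pangenome(spec)


@pytest.fixture(scope="session")
def small_edges(small_pangenome):
    genomes, _ = small_pangenome
    return pairwise_similarity(genomes)


@pytest.fixture(scope="session")
def small_clusterings(small_pangenome, small_edges):
    genomes, _ = small_pangenome
    return (
        cluster_orthologs(small_edges, genomes, "A"),
        cluster_orthologs(small_edges, genomes, "B"),
    )


def partition_of(clustering):
    return {frozenset(m) for m in clustering.groups.values()}


def truth_partition(truth):
    return {frozenset(m) for m in truth.og_membership.values() if m}
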