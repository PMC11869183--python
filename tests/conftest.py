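import sys
from pathlib import Path

import pytest

sys.path.insert(0, str(Path(__file__).parent))  # for oracles.py

from phasepan.sim import SimulationConfig, simulate_pangenome, load_simulated


@pytest.fixture(scope="session")
def small_sim(tmp_path_factory):
    """2 genomes x ploidy 2 x 2 chromosomes with mild loss; general-purpose."""
    cfg = SimulationConfig(
        seed=101,
        n_genomes=2,
        ploidy=2,
        n_chromosomes=2,
        genes_per_chromosome=25,
        gene_length_codons=60,
        gene_loss_rate=0.1,
        genome_gene_loss_rate=0.1,
        haplotype_snp_rate=0.002,
    )
    return simulate_pangenome(cfg, tmp_path_factory.mktemp("small_sim"))


@pytest.fixture(scope="session")
def small_store(small_sim):
    return load_simulated(small_sim)


@pytest.fixture(scope="session")
def small_groups(small_store):
    from phasepan.homology import group_proteins

    return group_proteins(small_store, mode=2)


@pytest.fixture(scope="session")
def inversion_sim(tmp_path_factory):
    """Single genome, two haplotypes, one planted 15-gene inversion, no loss."""
    cfg = SimulationConfig(
        seed=55,
        n_genomes=1,
        ploidy=2,
        n_chromosomes=1,
        genes_per_chromosome=60,
        gene_length_codons=60,
        gene_loss_rate=0.0,
        genome_gene_loss_rate=0.0,
        haplotype_snp_rate=0.001,
        n_inversions=1,
        inversion_size_range=(15, 15),
    )
    return simulate_pangenome(cfg, tmp_path_factory.mktemp("inversion_sim"))


@pytest.fixture(scope="session")
def inversion_store(inversion_sim):
    return load_simulated(inversion_sim)


@pytest.fixture(scope="session")
def inversion_groups(inversion_store):
    from phasepan.homology import group_proteins

    return group_proteins(inversion_store, mode=2)


def write_fasta(path, records):
    with open(path, "w") as fh:
        for name, seq in records:
            fh.write(f">{name}\n{seq}\n")
    return path
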