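import numpy as np
import pytest

from metacompare import CommunitySpec, Genome, generate_genome, simulate_reads
from metacompare.community import RANKS


def lineage(*names):
    return dict(zip(RANKS, names))


@pytest.fixture(scope="session")
def ref_genome():
    return generate_genome(
        20_000,
        0.5,
        seed=11,
        genome_id="refA",
        taxon_lineage=lineage("Bacteria", "Firmicutes", "Clostridia",
                              "Clostridiales", "Clostridiaceae", "Clostridium"),
    )


@pytest.fixture(scope="session")
def second_genome():
    return generate_genome(
        20_000,
        0.6,
        seed=12,
        genome_id="refB",
        taxon_lineage=lineage("Archaea", "Euryarchaeota", "Methanomicrobia",
                              "Methanomicrobiales", "Methanomicrobiaceae", "Methanoculleus"),
    )


@pytest.fixture(scope="session")
def big_genome():
    """Large enough that unrelated reads almost never share a start coordinate."""
    return generate_genome(500_000, 0.5, seed=13, genome_id="big")


@pytest.fixture(scope="session")
def clean_reads(ref_genome):
    """1,000 error-free 400 bp reads from one genome; no duplicates."""
    spec = CommunitySpec(
        genomes=[ref_genome],
        abundances=[1.0],
        divergences=[0.0],
        n_reads=1000,
        read_length_mean=400,
        read_length_sd=0,
        seed=5,
    )
    return simulate_reads(spec)


@pytest.fixture(scope="session")
def diverged_reads(ref_genome):
    """1,000 reads at 5% divergence, 400 bp fixed length."""
    spec = CommunitySpec(
        genomes=[ref_genome],
        abundances=[1.0],
        divergences=[0.05],
        n_reads=1000,
        read_length_mean=400,
        read_length_sd=0,
        seed=6,
    )
    return simulate_reads(spec)


def mismatches_at_truth(read, genome):
    """Brute-force mismatch count of a read against its true reference window."""
    window = genome.sequence[read.truth_start : read.truth_start + len(read.sequence)]
    return sum(1 for a, b in zip(read.sequence, window) if a != b)
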