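import numpy as np
import pytest

from snipchip import (
    ExactIndex,
    SimConfig,
    StrainGenome,
    build_hybrid_reference,
    derive_snp_map,
    simulate_genome_pair,
)


@pytest.fixture
def toy_pair():
    """4-base single-chromosome pair differing at the last base."""
    test = StrainGenome("a", [("chrI", "ACGT")])
    spike = StrainGenome("b", [("chrI", "ACGA")])
    return test, spike


@pytest.fixture
def small_pair():
    """Random colinear 2 x 10 kb pair at 1% divergence, fixed seed."""
    config = SimConfig(seed=11, n_chromosomes=2, chrom_length=10_000, divergence=0.01)
    test, spike, snpmap = simulate_genome_pair(config)
    return test, spike, snpmap


@pytest.fixture
def small_hybrid(small_pair):
    test, spike, _snpmap = small_pair
    return build_hybrid_reference(test, spike)


@pytest.fixture
def small_index(small_hybrid):
    return ExactIndex(small_hybrid, read_length_hint=100)


def naive_locate(hybrid, query):
    """Brute-force oracle: scan every contig on both strands."""
    from snipchip.classify import revcomp

    hits = []
    for contig in hybrid.contigs:
        for strand, q in (("+", query), ("-", revcomp(query))):
            start = contig.sequence.find(q)
            while start != -1:
                hits.append((contig.name, start, strand))
                start = contig.sequence.find(q, start + 1)
    return sorted(hits)


def random_genome(rng, strain_id, chrom_lengths):
    chroms = [
        (name, "".join(rng.choice(list("ACGT"), size=length)))
        for name, length in chrom_lengths.items()
    ]
    return StrainGenome(strain_id, chroms)
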