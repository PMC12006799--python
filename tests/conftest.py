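from __future__ import annotations

import pytest

from soi.model import GenePair, GeneRecord, OrthologyMap, SyntenyBlock


def make_pairs(n, prefix_a="a", prefix_b="b", genome_a="A", genome_b="B",
               ks=None):
    return [
        GenePair(
            gene_a=f"{prefix_a}{i}", gene_b=f"{prefix_b}{i}",
            genome_a=genome_a, genome_b=genome_b,
            ks=None if ks is None else ks[i],
        )
        for i in range(n)
    ]


def make_block(block_id="blk", n=5, n_orth=None, prefix_a="a", prefix_b="b",
               genome_pair=("A", "B"), chrom_pair=("c1", "c1"), oi=None,
               ks=None):
    block = SyntenyBlock(
        block_id=block_id,
        genome_pair=genome_pair,
        chrom_pair=chrom_pair,
        pairs=make_pairs(n, prefix_a, prefix_b, *genome_pair, ks=ks),
        oi=oi,
    )
    return block


def make_orthology(block, n_orth):
    """OrthologyMap containing the first n_orth pairs of a block."""
    return OrthologyMap(
        (p.gene_a, p.gene_b) for p in block.pairs[:n_orth]
    )


def make_gene_records(genome_id, chrom_sizes):
    """chrom_sizes: {chrom: n_genes}; genes named <genome>_<chrom>_<i>."""
    records = []
    for chrom in sorted(chrom_sizes):
        for i in range(chrom_sizes[chrom]):
            records.append(
                GeneRecord(
                    genome_id=genome_id, chrom=chrom,
                    start=i * 100 + 1, end=i * 100 + 50, strand="+",
                    gene_id=f"{genome_id}_{chrom}_{i}", order_index=i,
                )
            )
    return records


@pytest.fixture
def simple_block():
    return make_block(n=4)
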