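"""Cluster syntenic orthologs into syntenic orthogroups (SOGs).

Builds the orthologous syntenic graph from OI-filtered blocks across
three genomes, partitions it with the Markov Cluster algorithm and
classifies the resulting SOGs.
"""

from soi import (
    GenePair,
    SyntenyBlock,
    build_graph,
    filter_sogs,
    make_sogs,
    mcl,
)


def filtered_block(bid, genome_pair, gene_pairs, oi):
    pairs = [
        GenePair(gene_a=a, gene_b=b, genome_a=genome_pair[0],
                 genome_b=genome_pair[1])
        for a, b in gene_pairs
    ]
    return SyntenyBlock(bid, genome_pair, ("c1", "c1"), pairs, oi=oi)


# three genomes; gene 3 of genome A kept two WGD copies (a3 and a3x)
block_sets = [
    [filtered_block("ab", ("A", "B"),
                    [("a1", "b1"), ("a2", "b2"), ("a3", "b3"), ("a3x", "b3")],
                    oi=0.9)],
    [filtered_block("ac", ("A", "C"),
                    [("a1", "c1"), ("a2", "c2"), ("a3", "c3")], oi=0.95)],
    [filtered_block("bc", ("B", "C"),
                    [("b1", "c1"), ("b2", "c2"), ("b3", "c3")], oi=0.85)],
]

graph = build_graph(block_sets, weight_mode="oi")
result = mcl(graph, inflation=1.5)
print(f"MCL: {len(result.clusters)} clusters after {result.iterations} "
      f"iterations (converged={result.converged})")

node_genomes = {v: d["genome"] for v, d in graph.nodes(data=True)}
sogs = make_sogs(result, node_genomes, ["A", "B", "C"])
for sog in sogs:
    members = {g: v for g, v in sog.members.items()}
    print(f"{sog.sog_id}: {members} class={sog.cls} "
          f"occupancy={sog.taxon_occupancy:.2f}")

single = filter_sogs(sogs, max_missing=0.4, mode="single")
print(f"{len(single)} single-copy SOGs pass the 40% missing-taxa filter "
      f"(multi-copy SOGs retain extra WGD copies)")
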