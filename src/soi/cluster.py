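"""Syntenic orthogroups (SOGs): graph construction, Markov clustering,
classification, outgroup attachment and sequence export.

OI-filtered syntenic-ortholog pairs across all genome pairs form an
orthologous syntenic graph (genes as nodes, pairs as weighted edges).
Markov clustering (MCL) partitions the graph into SOGs, breaking weak
links (spurious pairs bridging unrelated families) and bridging
disrupted links through graph transitivity.  The MCL loop here is
implemented from first principles on a dense column-stochastic matrix:
add self-loops, normalize columns, then alternate expansion (matrix
power) and inflation (entrywise power + renormalization) with pruning
of tiny entries until the matrix is stable.

Edge weights default to the maximum block OI supporting the pair, which
rewards pairs observed in strongly orthologous context; unit weights
are available for ablation.  Inflation defaults to 1.5, the convention
of orthogroup tools built on MCL.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from typing import Iterable, Mapping, Sequence, Union

import networkx as nx
import numpy as np

from .model import SyntenyBlock


def build_graph(
    filtered_block_sets: Iterable[Iterable[SyntenyBlock]],
    weight_mode: str = "oi",
) -> nx.Graph:
    """Build the orthologous syntenic graph from OI-filtered block sets.

    ``filtered_block_sets`` is one iterable of retained blocks per genome
    pair.  Nodes are gene ids tagged with a ``genome`` attribute; one
    edge per distinct syntenic-ortholog pair, weighted by the maximum
    supporting-block OI (``oi`` mode) or 1 (``unit`` mode).
    """
    if weight_mode not in ("oi", "unit"):
        raise ValueError(f"unknown weight_mode {weight_mode!r}")
    graph = nx.Graph()
    for block_set in filtered_block_sets:
        for block in block_set:
            for p in block.pairs:
                if p.genome_a == p.genome_b:
                    raise ValueError(
                        f"within-genome pair ({p.gene_a}, {p.gene_b})"
                    )
                w = 1.0 if weight_mode == "unit" else float(block.oi or 0.0)
                if w <= 0:
                    w = 1e-9  # weights must stay positive for MCL
                graph.add_node(p.gene_a, genome=p.genome_a)
                graph.add_node(p.gene_b, genome=p.genome_b)
                if graph.has_edge(p.gene_a, p.gene_b):
                    old = graph[p.gene_a][p.gene_b]["weight"]
                    graph[p.gene_a][p.gene_b]["weight"] = max(old, w)
                else:
                    graph.add_edge(p.gene_a, p.gene_b, weight=w)
    return graph


@dataclass
class MCLResult:
    clusters: list[set]
    converged: bool
    iterations: int

    def __iter__(self):
        return iter(self.clusters)

    def __len__(self):
        return len(self.clusters)


def mcl(
    graph: nx.Graph,
    inflation: float = 1.5,
    expansion: int = 2,
    max_iter: int = 100,
    tol: float = 1e-6,
    prune: float = 1e-5,
) -> MCLResult:
    """Markov clustering of a weighted graph into a partition of nodes.

    Self-loops are added with weight equal to the node's maximum
    incident edge weight (1 for isolated nodes), columns are normalized,
    and the process alternates expansion (``M**expansion`` as a matrix
    power) with inflation (entrywise power ``inflation`` followed by
    column renormalization), pruning entries below ``prune``, until the
    largest column-wise change drops below ``tol`` or ``max_iter`` is
    reached.  Clusters are read from attractor rows; a node reachable
    from several attractor systems is assigned to the system holding the
    largest steady-state mass, ties broken by lexicographic node id.
    Non-convergence yields the current interpretation with
    ``converged=False`` rather than an exception.
    """
    if inflation <= 1:
        raise ValueError("inflation must be > 1")
    nodes = sorted(graph.nodes)
    n = len(nodes)
    if n == 0:
        return MCLResult(clusters=[], converged=True, iterations=0)
    index = {v: i for i, v in enumerate(nodes)}
    M = np.zeros((n, n))
    for u, v, data in graph.edges(data=True):
        w = float(data.get("weight", 1.0))
        if not np.isfinite(w) or w <= 0:
            raise ValueError(f"edge ({u}, {v}) has non-positive weight {w}")
        M[index[u], index[v]] = w
        M[index[v], index[u]] = w
    # self-loops: max incident weight, 1 for isolated nodes
    loop = M.max(axis=0)
    loop[loop == 0] = 1.0
    M[np.diag_indices(n)] = loop
    M = M / M.sum(axis=0)

    converged = False
    iterations = 0
    for iterations in range(1, max_iter + 1):
        prev = M
        M = np.linalg.matrix_power(M, expansion)
        M = np.power(M, inflation)
        M[M < prune] = 0.0
        colsum = M.sum(axis=0)
        dead = colsum == 0
        if dead.any():
            # a fully pruned column: park the node on itself
            M[np.where(dead)[0], np.where(dead)[0]] = 1.0
            colsum = M.sum(axis=0)
        M = M / colsum
        if np.max(np.abs(M - prev)) < tol:
            converged = True
            break
    if not converged:
        warnings.warn(
            f"MCL did not converge within {max_iter} iterations; "
            f"interpreting the current matrix",
            stacklevel=2,
        )

    clusters = _interpret(M, nodes, prune)
    return MCLResult(clusters=clusters, converged=converged, iterations=iterations)


def _interpret(M: np.ndarray, nodes: Sequence, thresh: float) -> list[set]:
    """Read clusters from a (near-)idempotent MCL matrix.

    Attractors are nodes with mass on their own diagonal; attractors
    sharing mass form one attractor system; every node joins the system
    holding most of its column mass.
    """
    n = len(nodes)
    attractors = [i for i in range(n) if M[i, i] > thresh]
    if not attractors:  # degenerate; treat row-mass maxima as attractors
        attractors = sorted(set(int(np.argmax(M[:, j])) for j in range(n)))
    # group attractors into systems via shared support
    sys_graph = nx.Graph()
    sys_graph.add_nodes_from(attractors)
    for i in attractors:
        for k in attractors:
            if i < k and (M[i, k] > thresh or M[k, i] > thresh):
                sys_graph.add_edge(i, k)
    systems = [sorted(c) for c in nx.connected_components(sys_graph)]
    systems.sort(key=lambda s: nodes[s[0]])
    assignment: dict[int, int] = {}
    for j in range(n):
        masses = [sum(M[i, j] for i in system) for system in systems]
        best = max(masses)
        if best <= 0:
            # no attractor mass (non-converged): follow the strongest row
            i = int(np.argmax(M[:, j]))
            cand = [s for s, system in enumerate(systems) if i in system]
            s_idx = cand[0] if cand else int(np.argmin(
                [abs(system[0] - i) for system in systems]
            ))
        else:
            tied = [s for s, m in enumerate(masses) if m == best]
            # ties broken by lexicographic id of the system's first attractor
            s_idx = min(tied, key=lambda s: nodes[systems[s][0]])
        assignment[j] = s_idx
    out: dict[int, set] = {}
    for j, s_idx in assignment.items():
        out.setdefault(s_idx, set()).add(nodes[j])
    return sorted(out.values(), key=lambda c: sorted(c))


# ---------------------------------------------------------------------------
# SOGs


@dataclass
class SOG:
    """A syntenic orthogroup: syntenic-ortholog genes across >= 2 genomes."""

    sog_id: str
    members: dict  # genome_id -> sorted list of gene_ids (ingroup)
    copy_profile: dict  # genome_id -> count
    cls: str  # 'single_copy' or 'multi_copy'
    taxon_occupancy: float
    outgroup_members: dict = field(default_factory=dict)


def make_sogs(
    partition: Union[MCLResult, Iterable[set]],
    node_genomes: Mapping[str, str],
    genomes: Sequence[str],
) -> list[SOG]:
    """Turn an MCL partition into SOGs over the given genome roster.

    Clusters represented in fewer than two genomes are dropped.  A SOG is
    single-copy iff every represented genome holds exactly one member;
    occupancy is represented genomes / roster size.  sog_ids are assigned
    deterministically after sorting clusters by their member gene ids.
    """
    roster = list(genomes)
    clusters = list(partition)
    keyed = sorted((tuple(sorted(c)) for c in clusters))
    sogs: list[SOG] = []
    for members_sorted in keyed:
        members: dict[str, list[str]] = {}
        for gene in members_sorted:
            genome = node_genomes[gene]
            members.setdefault(genome, []).append(gene)
        if len(members) < 2:
            continue  # singleton-genome cluster: excluded from output
        profile = {g: len(v) for g, v in members.items()}
        cls = "single_copy" if all(c == 1 for c in profile.values()) else "multi_copy"
        occupancy = len(members) / len(roster)
        sogs.append(
            SOG(
                sog_id=f"SOG{len(sogs) + 1:06d}",
                members=members,
                copy_profile=profile,
                cls=cls,
                taxon_occupancy=occupancy,
            )
        )
    return sogs


def filter_sogs(
    sogs: Sequence[SOG], max_missing: float = 0.4, mode: str = "both"
) -> list[SOG]:
    """Retain SOGs with (1 - occupancy) <= max_missing and matching class.

    Boundary kept: a SOG missing exactly ``max_missing`` of the taxa is
    retained.
    """
    if not 0 <= max_missing < 1:
        raise ValueError(f"max_missing {max_missing} outside [0, 1)")
    if mode not in ("single", "multi", "both"):
        raise ValueError(f"unknown mode {mode!r}")
    out = []
    for sog in sogs:
        missing = 1.0 - sog.taxon_occupancy
        if missing > max_missing + 1e-12:
            continue
        if mode == "single" and sog.cls != "single_copy":
            continue
        if mode == "multi" and sog.cls != "multi_copy":
            continue
        out.append(sog)
    return out


def attach_outgroup(
    sogs: Sequence[SOG],
    outgroup_blocks: Iterable[SyntenyBlock],
) -> tuple[list[SOG], list[str]]:
    """Attach outgroup genes to SOGs via their syntenic-ortholog partners.

    ``outgroup_blocks`` are OI-filtered blocks between one or more
    outgroup genomes (absent from the SOGs) and ingroup genomes.  An
    outgroup gene joins the SOG holding its partner; if its partners span
    several SOGs it joins the one with the most supporting pairs (ties:
    highest summed block OI, then lexicographic sog_id).  Outgroup
    membership never alters the single/multi classification or occupancy
    of the ingroup.  Returns (sogs, unattached outgroup gene ids).
    """
    ingroup = set()
    for sog in sogs:
        ingroup.update(sog.members)
    gene_to_sog: dict[str, str] = {}
    sog_by_id = {s.sog_id: s for s in sogs}
    for sog in sogs:
        for genes in sog.members.values():
            for g in genes:
                gene_to_sog[g] = sog.sog_id

    # support[(og_gene, og_genome)][sog_id] = [count, weight]
    support: dict[tuple[str, str], dict[str, list[float]]] = {}
    all_og_genes: set[tuple[str, str]] = set()
    for block in list(outgroup_blocks):
        ga, gb = block.genome_pair
        if ga in ingroup and gb in ingroup:
            raise ValueError(
                f"block {block.block_id}: both genomes {ga}, {gb} already in SOGs"
            )
        if ga not in ingroup and gb not in ingroup:
            continue
        og_side = 0 if ga not in ingroup else 1
        w = float(block.oi or 0.0)
        for p in block.pairs:
            og_gene = p.gene_a if og_side == 0 else p.gene_b
            og_genome = p.genome_a if og_side == 0 else p.genome_b
            partner = p.gene_b if og_side == 0 else p.gene_a
            all_og_genes.add((og_gene, og_genome))
            sog_id = gene_to_sog.get(partner)
            if sog_id is None:
                continue
            entry = support.setdefault((og_gene, og_genome), {})
            cw = entry.setdefault(sog_id, [0, 0.0])
            cw[0] += 1
            cw[1] += w

    unattached = sorted(g for g, _ in all_og_genes - set(support))
    for (og_gene, og_genome), entry in sorted(support.items()):
        # deterministic: max count, then max summed weight, then smallest sog_id
        best_count = max(c for c, _ in entry.values())
        best_weight = max(w for c, w in entry.values() if c == best_count)
        candidates = [
            sid for sid, (c, w) in entry.items()
            if c == best_count and abs(w - best_weight) < 1e-12
        ]
        sog = sog_by_id[sorted(candidates)[0]]
        sog.outgroup_members.setdefault(og_genome, []).append(og_gene)
    for sog in sogs:
        for genes in sog.outgroup_members.values():
            genes.sort()
    return list(sogs), unattached


def export_sog_sequences(
    sogs: Sequence[SOG],
    sequences: Mapping[str, str],
    outdir,
) -> list[str]:
    """Write one FASTA per SOG with records named genome_id|gene_id.

    ``sequences`` maps gene_id to sequence string.  Missing sequences are
    reported (returned and written to ``missing.txt``), not fatal.
    """
    from pathlib import Path

    from Bio.Seq import Seq
    from Bio.SeqIO import write as seqio_write
    from Bio.SeqRecord import SeqRecord

    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    missing: list[str] = []
    for sog in sogs:
        records = []
        roster = dict(sog.members)
        for genome, genes in sog.outgroup_members.items():
            roster.setdefault(genome, [])
            roster[genome] = roster[genome] + [g for g in genes]
        for genome in sorted(roster):
            for gene in sorted(roster[genome]):
                seq = sequences.get(gene)
                if seq is None:
                    missing.append(f"{sog.sog_id}\t{genome}\t{gene}")
                    continue
                records.append(
                    SeqRecord(Seq(seq), id=f"{genome}|{gene}", description="")
                )
        if records:
            seqio_write(records, outdir / f"{sog.sog_id}.fasta", "fasta")
    if missing:
        with open(outdir / "missing.txt", "w") as fh:
            fh.write("\n".join(missing) + "\n")
    return missing
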