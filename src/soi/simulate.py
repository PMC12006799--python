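"""Shared-WGD gene-order simulator and benchmark harness.

The simulator emulates the study design used to validate OI-based
identification of orthologous synteny: an ancestral gene order undergoes
a whole-genome duplication (WGD), the duplicated lineage speciates into
taxa A and B after a time lag ``delta_t`` (substitutions/site), and the
four subgenomes A1, A2, B1, B2 are treated as pseudo-species alongside
an outgroup O.  The species tree is

    (((A1:0.2, B1:0.2):dT, (A2:0.2, B2:0.2):dT):0.2, O:dT+0.4):0.1

Along each branch, Poisson-distributed counts of gene loss, inversion,
transposition, tandem duplication and origination are applied in
randomized order to the gene order; gene identity is tracked through
every event, so ortholog/out-paralog labels between A and B are exact.
Sequences are never evolved: orthology-inference error is emulated
parametrically (a false-negative rate on true orthologs and a
false-positive rate on true out-paralogs, both functions of ``delta_t``
calibrated to the behaviour of modern orthology inference: roughly 15%
hidden paralogs when the WGD barely predates speciation, decaying to
~1% for well-separated events), and per-pair Ks is emitted as the true
divergence times multiplicative gamma noise.

A lineage-specific-WGD scenario (speciation first, then an independent
WGD in each lineage) is provided for testing ploidy-pattern logic.

The benchmark loop chains: simulate -> emulate ortholog calls -> detect
collinear blocks -> annotate OI -> filter -> extract syntenic orthologs
-> score precision/recall/F1 against the simulation truth.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, replace as dc_replace
from typing import Callable, Iterable, Mapping, Optional, Sequence

import numpy as np
import pandas as pd

from .model import GenePair, GeneRecord, OrthologyMap, SyntenyBlock, assign_order_indices
from .oi import annotate_blocks, extract_syntenic_orthologs, filter_blocks, oi_distribution

# ---------------------------------------------------------------------------
# configuration


def default_fp_rate(delta_t: float) -> float:
    """Fraction of true out-paralog pairs miscalled as orthologs.

    Anchored at ~0.15 for delta_t <= 0.05 (hidden paralogs when the WGD
    barely predates speciation) decaying to ~0.01 for delta_t >= 0.5.
    """
    return float(np.interp(delta_t, [0.05, 0.1, 0.2, 0.5], [0.15, 0.10, 0.05, 0.01]))


def default_fn_rate(delta_t: float) -> float:
    """Fraction of true ortholog pairs missed; mirrors the FP model."""
    return default_fp_rate(delta_t)


@dataclass(frozen=True)
class SimulationConfig:
    """Study conditions for one simulated history.

    Branch lengths are in substitutions/site; event rates are per gene
    per unit branch length and are multiplied by ``fold`` (the
    rearrangement-intensity knob; ~1000 yields detected blocks averaging
    about 10 genes at the desk scale of 500 genes).
    """

    n_genes: int = 500
    n_chromosomes: int = 5
    delta_t: float = 0.2
    post_speciation_t: float = 0.2
    pre_wgd_t: float = 0.2
    stem_t: float = 0.1
    fold: float = 1.0
    loss_rate: float = 5e-5
    inversion_rate: float = 3.5e-4
    transposition_rate: float = 1.75e-4
    duplication_rate: float = 2e-5
    origination_rate: float = 2e-5
    segment_mean: float = 5.0
    ks_gamma_shape: float = 4.0
    scenario: str = "shared_wgd"  # or "specific_wgd"
    fp_rate: Optional[Callable[[float], float]] = None
    fn_rate: Optional[Callable[[float], float]] = None
    seed: int = 0

    def __post_init__(self) -> None:
        for name in ("loss_rate", "inversion_rate", "transposition_rate",
                     "duplication_rate", "origination_rate"):
            if getattr(self, name) < 0:
                raise ValueError(f"{name} must be >= 0")
        if self.delta_t <= 0:
            raise ValueError("delta_t must be > 0")
        if self.scenario not in ("shared_wgd", "specific_wgd"):
            raise ValueError(f"unknown scenario {self.scenario!r}")
        if self.fold < 1:
            raise ValueError("fold must be >= 1")


@dataclass(frozen=True)
class ConfusionCounts:
    tp: int
    fp: int
    fn: int

    @property
    def precision(self) -> float:
        return self.tp / (self.tp + self.fp) if self.tp + self.fp else 0.0

    @property
    def recall(self) -> float:
        return self.tp / (self.tp + self.fn) if self.tp + self.fn else 0.0

    @property
    def f1(self) -> float:
        p, r = self.precision, self.recall
        return 2 * p * r / (p + r) if p + r else 0.0


# ---------------------------------------------------------------------------
# gene-order evolution

INGROUP = ("A1", "A2", "B1", "B2")
OUTGROUP = "O"


@dataclass(frozen=True)
class _SimGene:
    uid: int
    family: Optional[int]  # ancestral family; None for originated genes
    s_id: Optional[int]  # ancestor id at the speciation node; truth anchor
    w_id: Optional[int]  # ancestor id at the WGD node (shared across copies)
    sub: int  # subgenome index after the WGD


class _Counter:
    def __init__(self, start: int = 0) -> None:
        self.value = start

    def next(self) -> int:
        self.value += 1
        return self.value


_Genome = list  # list of chromosomes, each a list of _SimGene


def _total_genes(genome: _Genome) -> int:
    return sum(len(c) for c in genome)


def _pick_chrom(genome: _Genome, rng, min_len: int = 1) -> Optional[int]:
    sizes = np.array([len(c) for c in genome], dtype=float)
    ok = sizes >= min_len
    if not ok.any():
        return None
    w = np.where(ok, sizes, 0.0)
    return int(rng.choice(len(genome), p=w / w.sum()))


def _evolve(genome: _Genome, branch_len: float, cfg: SimulationConfig,
            rng, uid_counter: _Counter) -> _Genome:
    """Apply Poisson event counts (rate x fold x branch length x genes)
    in randomized order.  Returns a new genome; input is not modified."""
    genome = [list(c) for c in genome]
    n0 = _total_genes(genome)
    if n0 == 0 or branch_len <= 0:
        return genome
    scale = cfg.fold * branch_len * n0
    events: list[str] = []
    for name, rate in (
        ("loss", cfg.loss_rate),
        ("inversion", cfg.inversion_rate),
        ("transposition", cfg.transposition_rate),
        ("duplication", cfg.duplication_rate),
        ("origination", cfg.origination_rate),
    ):
        events.extend([name] * int(rng.poisson(rate * scale)))
    rng.shuffle(events)

    for ev in events:
        if ev == "loss":
            ci = _pick_chrom(genome, rng)
            if ci is None:
                continue
            gi = int(rng.integers(len(genome[ci])))
            del genome[ci][gi]
        elif ev == "inversion":
            ci = _pick_chrom(genome, rng, min_len=2)
            if ci is None:
                continue
            chrom = genome[ci]
            length = min(int(rng.geometric(1.0 / cfg.segment_mean)), len(chrom))
            start = int(rng.integers(len(chrom) - length + 1))
            chrom[start:start + length] = chrom[start:start + length][::-1]
        elif ev == "transposition":
            ci = _pick_chrom(genome, rng, min_len=2)
            if ci is None:
                continue
            chrom = genome[ci]
            length = min(int(rng.geometric(1.0 / cfg.segment_mean)), len(chrom) - 1)
            start = int(rng.integers(len(chrom) - length + 1))
            segment = chrom[start:start + length]
            del chrom[start:start + length]
            di = _pick_chrom(genome, rng)
            dest = genome[di]
            pos = int(rng.integers(len(dest) + 1))
            dest[pos:pos] = segment
        elif ev == "duplication":
            ci = _pick_chrom(genome, rng)
            if ci is None:
                continue
            chrom = genome[ci]
            gi = int(rng.integers(len(chrom)))
            src = chrom[gi]
            chrom.insert(gi + 1, dc_replace(src, uid=uid_counter.next()))
        else:  # origination
            ci = _pick_chrom(genome, rng)
            if ci is None:
                continue
            chrom = genome[ci]
            pos = int(rng.integers(len(chrom) + 1))
            chrom.insert(
                pos,
                _SimGene(uid=uid_counter.next(), family=None, s_id=None,
                         w_id=None, sub=0),
            )
    return genome


def _assign_s_ids(genome: _Genome, counter: _Counter) -> _Genome:
    return [
        [dc_replace(g, s_id=counter.next()) for g in chrom]
        for chrom in genome
    ]


def _assign_w_ids(genome: _Genome, counter: _Counter) -> _Genome:
    return [
        [dc_replace(g, w_id=counter.next()) for g in chrom]
        for chrom in genome
    ]


def _set_subgenome(genome: _Genome, sub: int, uid_counter: _Counter) -> _Genome:
    return [
        [dc_replace(g, sub=sub, uid=uid_counter.next()) for g in chrom]
        for chrom in genome
    ]


# ---------------------------------------------------------------------------
# truth bookkeeping


@dataclass
class TruthSet:
    """Ground truth for one simulated history."""

    config: SimulationConfig
    genomes: dict  # species -> list[GeneRecord]
    families: dict  # gene_id -> family id (None for originated genes)
    s_ids: dict  # gene_id -> speciation-node ancestor id (ingroup only)
    originated: set  # gene_ids of novel genes
    true_orthologs: set  # frozenset gene-id pairs, A-vs-B, MRCA = speciation
    true_outparalogs: set  # A-vs-B pairs whose MRCA is the WGD node
    dup_pairs: set  # A-vs-B pairs tracing to small-scale duplications;
    #   like originated-gene pairs these belong to neither scored class
    divergence: dict  # frozenset pair -> expected Ks (2 x time to MRCA)
    ks: dict  # frozenset pair -> noisy Ks

    def gene_records(self) -> dict:
        """gene_id -> GeneRecord over all pseudo-species."""
        out = {}
        for recs in self.genomes.values():
            for r in recs:
                out[r.gene_id] = r
        return out

    def homolog_pairs(self, sp_x: str, sp_y: str) -> list[GenePair]:
        """All cross-species pairs sharing an ancestral family, with Ks."""
        byfam_x: dict[int, list[str]] = {}
        for r in self.genomes[sp_x]:
            fam = self.families[r.gene_id]
            if fam is not None:
                byfam_x.setdefault(fam, []).append(r.gene_id)
        pairs = []
        for r in self.genomes[sp_y]:
            fam = self.families[r.gene_id]
            if fam is None:
                continue
            for gx in byfam_x.get(fam, ()):
                key = frozenset((gx, r.gene_id))
                pairs.append(
                    GenePair(
                        gene_a=gx, gene_b=r.gene_id,
                        genome_a=sp_x, genome_b=sp_y,
                        ks=self.ks.get(key),
                    )
                )
        return pairs


def _leaf_records(species: str, genome: _Genome):
    """Name leaf genes and emit gene records plus truth lookups."""
    records, families, s_ids, w_ids, originated = [], {}, {}, {}, set()
    k = 0
    for ci, chrom in enumerate(genome, 1):
        for oi, g in enumerate(chrom):
            k += 1
            gid = f"{species}g{k:05d}"
            start = oi * 1000 + 1
            records.append(
                GeneRecord(
                    genome_id=species,
                    chrom=f"{species}_chr{ci}",
                    start=start,
                    end=start + 500,
                    strand="+",
                    gene_id=gid,
                    order_index=oi,
                )
            )
            families[gid] = g.family
            s_ids[gid] = (g.s_id, g.sub) if g.s_id is not None else None
            w_ids[gid] = g.w_id
            if g.family is None:
                originated.add(gid)
    return records, families, s_ids, w_ids, originated


def simulate_history(config: SimulationConfig) -> TruthSet:
    """Simulate the shared-WGD (or lineage-specific-WGD) history and
    return exact truth labels for all A-vs-B homolog pairs."""
    cfg = config
    rng = np.random.default_rng(cfg.seed)
    # expected survivors along the deepest root-to-leaf path
    path = cfg.stem_t + cfg.pre_wgd_t + cfg.delta_t + cfg.post_speciation_t
    expected = cfg.n_genes * math.exp(-cfg.loss_rate * cfg.fold * path)
    if expected < 10:
        raise ValueError(
            f"expected surviving genes {expected:.1f} < 10; "
            f"reduce fold or loss_rate"
        )

    uid = _Counter()
    s_counter = _Counter()
    per_chrom = cfg.n_genes // cfg.n_chromosomes
    sizes = [per_chrom] * cfg.n_chromosomes
    for i in range(cfg.n_genes - per_chrom * cfg.n_chromosomes):
        sizes[i] += 1
    ancestor: _Genome = []
    fam = 0
    for size in sizes:
        chrom = []
        for _ in range(size):
            fam += 1
            chrom.append(
                _SimGene(uid=uid.next(), family=fam, s_id=None, w_id=None, sub=0)
            )
        ancestor.append(chrom)

    leaves: dict[str, _Genome] = {}
    root = _evolve(ancestor, cfg.stem_t, cfg, rng, uid)
    if cfg.scenario == "shared_wgd":
        # R -> W -> (S1, S2) -> leaves; O branches off at R
        w_node = _evolve(root, cfg.pre_wgd_t, cfg, rng, uid)
        w_node = _assign_w_ids(w_node, _Counter())
        for sub, (leaf_a, leaf_b) in (((1), ("A1", "B1")), ((2), ("A2", "B2"))):
            copy = _set_subgenome(w_node, sub, uid)
            s_node = _evolve(copy, cfg.delta_t, cfg, rng, uid)
            s_node = _assign_s_ids(s_node, s_counter)
            leaves[leaf_a] = _evolve(s_node, cfg.post_speciation_t, cfg, rng, uid)
            leaves[leaf_b] = _evolve(s_node, cfg.post_speciation_t, cfg, rng, uid)
    else:
        # speciation first, then one WGD per lineage
        sp_node = _evolve(root, cfg.pre_wgd_t, cfg, rng, uid)
        sp_node = _assign_s_ids(sp_node, s_counter)
        for taxon in ("A", "B"):
            lineage = _evolve(sp_node, cfg.delta_t, cfg, rng, uid)
            for sub in (1, 2):
                copy = _set_subgenome(lineage, sub, uid)
                leaves[f"{taxon}{sub}"] = _evolve(
                    copy, cfg.post_speciation_t, cfg, rng, uid
                )
    leaves[OUTGROUP] = _evolve(
        root, cfg.delta_t + cfg.pre_wgd_t + cfg.post_speciation_t, cfg, rng, uid
    )

    genomes, families, s_ids, w_ids, originated = {}, {}, {}, {}, set()
    for sp in (*INGROUP, OUTGROUP):
        recs, fams, sids, wids, orig = _leaf_records(sp, leaves[sp])
        genomes[sp] = recs
        families.update(fams)
        s_ids.update(sids)
        w_ids.update(wids)
        originated |= orig

    # truth labels for all A-vs-B same-family pairs
    true_orth: set = set()
    true_outp: set = set()
    dup_pairs: set = set()
    divergence: dict = {}
    if cfg.scenario == "shared_wgd":
        d_orth = 2 * cfg.post_speciation_t
        d_outp = 2 * (cfg.post_speciation_t + cfg.delta_t)
    else:
        d_orth = 2 * (cfg.post_speciation_t + cfg.delta_t)
        d_outp = 2 * (cfg.post_speciation_t + cfg.delta_t + 0.0)  # pre-speciation dups
    d_og = 2 * (cfg.post_speciation_t + cfg.delta_t + cfg.pre_wgd_t)

    byfam: dict[int, dict[str, list[str]]] = {}
    for sp in (*INGROUP, OUTGROUP):
        for r in genomes[sp]:
            fam = families[r.gene_id]
            if fam is not None:
                byfam.setdefault(fam, {}).setdefault(sp, []).append(r.gene_id)
    for fam, by_sp in byfam.items():
        for sa in ("A1", "A2"):
            for sb in ("B1", "B2"):
                for ga in by_sp.get(sa, ()):
                    for gb in by_sp.get(sb, ()):
                        key = frozenset((ga, gb))
                        if cfg.scenario == "shared_wgd":
                            if s_ids[ga] is not None and s_ids[ga] == s_ids[gb]:
                                true_orth.add(key)  # MRCA = speciation
                                divergence[key] = d_orth
                            elif (
                                s_ids[ga] is not None
                                and s_ids[gb] is not None
                                and s_ids[ga][1] != s_ids[gb][1]
                                and w_ids[ga] is not None
                                and w_ids[ga] == w_ids[gb]
                            ):
                                true_outp.add(key)  # MRCA = the WGD itself
                                divergence[key] = d_outp
                            else:
                                # MRCA is a small-scale duplication (before
                                # the WGD or between WGD and speciation)
                                dup_pairs.add(key)
                                divergence[key] = d_outp
                        else:
                            if (
                                s_ids[ga] is not None
                                and s_ids[gb] is not None
                                and s_ids[ga][0] == s_ids[gb][0]
                            ):
                                true_orth.add(key)
                                divergence[key] = d_orth
                            else:
                                dup_pairs.add(key)
                                divergence[key] = d_outp
        for sp in INGROUP:
            for ga in by_sp.get(sp, ()):
                for go in by_sp.get(OUTGROUP, ()):
                    divergence[frozenset((ga, go))] = d_og

    ks = {
        key: d * rng.gamma(cfg.ks_gamma_shape, 1.0 / cfg.ks_gamma_shape)
        for key, d in sorted(divergence.items(), key=lambda kv: sorted(kv[0]))
    }
    return TruthSet(
        config=cfg,
        genomes=genomes,
        families=families,
        s_ids=s_ids,
        originated=originated,
        true_orthologs=true_orth,
        true_outparalogs=true_outp,
        dup_pairs=dup_pairs,
        divergence=divergence,
        ks=ks,
    )


def merged_genome(truth: "TruthSet", species: Sequence[str], genome_id: str) -> list[GeneRecord]:
    """View several pseudo-species (e.g. the two subgenomes A1 and A2) as
    one genome, as an assembled polyploid would present them.  Chromosome
    names stay species-prefixed, so order indices remain valid."""
    out = []
    for sp in species:
        for r in truth.genomes[sp]:
            out.append(dc_replace(r, genome_id=genome_id))
    return out


def family_homolog_pairs(
    genes_x: Sequence[GeneRecord],
    genes_y: Sequence[GeneRecord],
    families: Mapping[str, Optional[int]],
    ks: Optional[Mapping[frozenset, float]] = None,
) -> list[GenePair]:
    """All cross-genome pairs sharing an ancestral family (the homology
    signal a sequence-similarity search would provide)."""
    byfam: dict[int, list[GeneRecord]] = {}
    for r in genes_x:
        fam = families.get(r.gene_id)
        if fam is not None:
            byfam.setdefault(fam, []).append(r)
    pairs = []
    for r in genes_y:
        fam = families.get(r.gene_id)
        if fam is None:
            continue
        for rx in byfam.get(fam, ()):
            key = frozenset((rx.gene_id, r.gene_id))
            pairs.append(
                GenePair(
                    gene_a=rx.gene_id, gene_b=r.gene_id,
                    genome_a=rx.genome_id, genome_b=r.genome_id,
                    ks=None if ks is None else ks.get(key),
                )
            )
    return pairs


# ---------------------------------------------------------------------------
# orthology-inference error emulation


def emulate_orthology_calls(
    truth: TruthSet,
    config: Optional[SimulationConfig] = None,
    seed: Optional[int] = None,
) -> OrthologyMap:
    """Emulate imperfect ortholog inference over the truth pairs.

    Each true ortholog pair is called with probability 1 - fn(delta_t);
    each true out-paralog pair is miscalled with probability
    fp(delta_t).
    """
    cfg = config or truth.config
    fp = cfg.fp_rate or default_fp_rate
    fn = cfg.fn_rate or default_fn_rate
    fp_p, fn_p = fp(cfg.delta_t), fn(cfg.delta_t)
    for name, p in (("fp", fp_p), ("fn", fn_p)):
        if not 0 <= p <= 1:
            raise ValueError(f"{name} rate {p} outside [0, 1]")
    rng = np.random.default_rng(cfg.seed + 1 if seed is None else seed)
    omap = OrthologyMap(source="emulated")
    for key in sorted(truth.true_orthologs, key=sorted):
        if rng.random() >= fn_p:
            a, b = sorted(key)
            omap.add(a, b)
    for key in sorted(truth.true_outparalogs, key=sorted):
        if rng.random() < fp_p:
            a, b = sorted(key)
            omap.add(a, b)
    return omap


# ---------------------------------------------------------------------------
# collinear block detection (anchor chaining)


def detect_blocks(
    homolog_pairs: Iterable[GenePair],
    genes: Mapping[str, GeneRecord],
    min_block: int = 5,
    max_gap: int = 25,
) -> list[SyntenyBlock]:
    """Chain homologous gene pairs into collinear blocks.

    Per chromosome pair, pairs are sorted by (x-rank, y-rank) and chained
    greedily: a pair extends an open chain when its x-rank strictly
    increases by at most ``max_gap``, its y-rank differs by at most
    ``max_gap``, and the step direction matches the chain's orientation;
    among eligible chains the one with the smallest combined rank gap is
    chosen (ties: smaller y gap, then smaller last y).  Chains with at
    least ``min_block`` pairs become blocks.  Deterministic for fixed
    input.
    """
    groups: dict[tuple, list] = {}
    for p in homolog_pairs:
        ra, rb = genes[p.gene_a], genes[p.gene_b]
        key = (ra.genome_id, rb.genome_id, ra.chrom, rb.chrom)
        groups.setdefault(key, []).append((ra.order_index, rb.order_index, p))

    blocks: list[SyntenyBlock] = []
    for key in sorted(groups):
        ga, gb, ca, cb = key
        points = sorted(groups[key], key=lambda t: (t[0], t[1]))
        chains: list[dict] = []  # {'pts': [(x, y, pair)], 'dir': -1|0|1}
        closed: list[list] = []
        for x, y, pair in points:
            # retire chains that can no longer be extended
            still_open = []
            for ch in chains:
                if x - ch["pts"][-1][0] > max_gap:
                    closed.append(ch["pts"])
                else:
                    still_open.append(ch)
            chains = still_open
            best = None
            best_key = None
            for ch in chains:
                lx, ly = ch["pts"][-1][0], ch["pts"][-1][1]
                dx, dy = x - lx, y - ly
                if dx <= 0 or dx > max_gap or dy == 0 or abs(dy) > max_gap:
                    continue
                if ch["dir"] != 0 and (1 if dy > 0 else -1) != ch["dir"]:
                    continue
                k = (dx + abs(dy), abs(dy), ly)
                if best_key is None or k < best_key:
                    best, best_key = ch, k
            if best is None:
                chains.append({"pts": [(x, y, pair)], "dir": 0})
            else:
                ly = best["pts"][-1][1]
                best["pts"].append((x, y, pair))
                if best["dir"] == 0:
                    best["dir"] = 1 if y > ly else -1
        closed.extend(ch["pts"] for ch in chains)
        for pts in closed:
            if len(pts) < min_block:
                continue
            ys = [y for _, y, _ in pts]
            orientation = "same" if ys[-1] >= ys[0] else "inverted"
            blocks.append(
                SyntenyBlock(
                    block_id=f"{ga}-{gb}.{ca}.{cb}.{len(blocks)}",
                    genome_pair=(ga, gb),
                    chrom_pair=(ca, cb),
                    pairs=[p for _, _, p in pts],
                    orientation=orientation,
                )
            )
    return blocks


# ---------------------------------------------------------------------------
# assembly/annotation degradation


def _n50(sizes: Sequence[int]) -> int:
    total = sum(sizes)
    acc = 0
    for s in sorted(sizes, reverse=True):
        acc += s
        if acc * 2 >= total:
            return s
    return 0


def fragment_assembly(
    genome: Sequence[GeneRecord], relative_n50: float, seed: int = 0
) -> list[GeneRecord]:
    """Cut chromosomes at random gene-rank breakpoints until the contig
    N50 (in genes) drops to ``relative_n50`` x the original N50.  Gene
    content is unchanged; order indices are recomputed per contig."""
    if not 0 < relative_n50 <= 1:
        raise ValueError(f"relative_n50 {relative_n50} outside (0, 1]")
    rng = np.random.default_rng(seed)
    chroms: dict[str, list[GeneRecord]] = {}
    for r in sorted(genome, key=lambda r: (r.chrom, r.order_index)):
        chroms.setdefault(r.chrom, []).append(r)
    contigs = [(name, genes) for name, genes in sorted(chroms.items())]
    target = relative_n50 * _n50([len(g) for _, g in contigs])
    counter = 0
    while _n50([len(g) for _, g in contigs]) > target:
        splittable = [i for i, (_, g) in enumerate(contigs) if len(g) >= 2]
        if not splittable:
            break
        sizes = np.array([len(contigs[i][1]) for i in splittable], dtype=float)
        i = splittable[int(rng.choice(len(splittable), p=sizes / sizes.sum()))]
        name, genes = contigs[i]
        cut = int(rng.integers(1, len(genes)))
        counter += 1
        contigs[i] = (f"{name}_f{counter}a", genes[:cut])
        contigs.insert(i + 1, (f"{name}_f{counter}b", genes[cut:]))
    out: list[GeneRecord] = []
    for name, genes in contigs:
        for idx, r in enumerate(genes):
            out.append(dc_replace(r, chrom=name, order_index=idx))
    return out


def subsample_annotation(
    genome: Sequence[GeneRecord], fraction: float, seed: int = 0
) -> tuple[list[GeneRecord], list[str]]:
    """Uniformly retain each gene with probability ``fraction``; order
    indices are recomputed.  Returns (retained, removed gene ids) so
    truth sets can be restricted to the retained annotation."""
    if not 0 < fraction <= 1:
        raise ValueError(f"fraction {fraction} outside (0, 1]")
    rng = np.random.default_rng(seed)
    ordered = sorted(genome, key=lambda r: (r.chrom, r.order_index))
    keep_mask = rng.random(len(ordered)) < fraction
    kept = [r for r, k in zip(ordered, keep_mask) if k]
    removed = [r.gene_id for r, k in zip(ordered, keep_mask) if not k]
    return assign_order_indices(kept), removed


# ---------------------------------------------------------------------------
# scoring


def evaluate(called: Iterable, truth: TruthSet) -> ConfusionCounts:
    """Score called syntenic-ortholog pairs against the simulation truth.

    Pairs involving originated (novel) genes or genes outside the truth
    sets contribute to none of the counts.
    """
    called_set = {frozenset(p) if not isinstance(p, frozenset) else p for p in called}
    tp = len(called_set & truth.true_orthologs)
    fp = len(called_set & truth.true_outparalogs)
    fn = len(truth.true_orthologs - called_set)
    return ConfusionCounts(tp=tp, fp=fp, fn=fn)


# ---------------------------------------------------------------------------
# full benchmark


SPECIES_PAIRS = (("A1", "B1"), ("A1", "B2"), ("A2", "B1"), ("A2", "B2"))


def run_replicate(
    config: SimulationConfig,
    oi_cutoffs: Sequence[float] = (0.6,),
    min_block: int = 5,
    max_gap: int = 25,
) -> list[dict]:
    """One full pipeline pass; returns one result row per OI cutoff."""
    truth = simulate_history(config)
    omap = emulate_orthology_calls(truth)
    genes = truth.gene_records()
    blocks: list[SyntenyBlock] = []
    for sp_x, sp_y in SPECIES_PAIRS:
        pairs = truth.homolog_pairs(sp_x, sp_y)
        blocks.extend(detect_blocks(pairs, genes, min_block=min_block, max_gap=max_gap))
    annotated = annotate_blocks(blocks, omap)
    raw = evaluate(set(frozenset(p) for p in omap), truth)
    if annotated:
        dist = oi_distribution(annotated)
        noise = dist.noise
        mean_block = float(np.mean([b.n_pairs for b in annotated]))
    else:
        noise = float("nan")
        mean_block = 0.0
    rows = []
    for cutoff in oi_cutoffs:
        retained = filter_blocks(annotated, oi_cutoff=cutoff)
        called = extract_syntenic_orthologs(retained)
        counts = evaluate(called, truth)
        rows.append(
            {
                "delta_t": config.delta_t,
                "fold": config.fold,
                "cutoff": cutoff,
                "seed": config.seed,
                "tp": counts.tp,
                "fp": counts.fp,
                "fn": counts.fn,
                "precision": counts.precision,
                "recall": counts.recall,
                "f1": counts.f1,
                "raw_precision": raw.precision,
                "raw_recall": raw.recall,
                "raw_f1": raw.f1,
                "noise": noise,
                "mean_block_size": mean_block,
                "n_blocks": len(annotated),
                "n_retained": len(retained),
            }
        )
    return rows


def derive_seed(master_seed: int, *key: int) -> int:
    """Deterministic per-condition seed below 2**31."""
    ss = np.random.SeedSequence([int(master_seed), *map(int, key)])
    return int(ss.generate_state(1)[0] % (2**31))


def run_benchmark(
    delta_t_grid: Sequence[float] = (0.05, 0.1, 0.2, 0.5, 1.0),
    fold_grid: Sequence[float] = (1000.0,),
    replicates: int = 20,
    oi_cutoffs: Sequence[float] = (0.6,),
    seed: int = 0,
    n_genes: int = 500,
    config: Optional[SimulationConfig] = None,
    return_replicates: bool = False,
):
    """Grid benchmark: medians and percentile 95% intervals per condition.

    Per-replicate seeds derive deterministically from ``seed``, so the
    whole table is reproducible bit-for-bit.  Returns a summary
    DataFrame (one row per delta_t x fold x cutoff) or, with
    ``return_replicates``, the tuple (summary, per-replicate table).
    """
    base = config or SimulationConfig(n_genes=n_genes)
    rows = []
    for ci, delta_t in enumerate(delta_t_grid):
        for fi, fold in enumerate(fold_grid):
            for rep in range(replicates):
                cfg = dc_replace(
                    base,
                    delta_t=float(delta_t),
                    fold=float(fold),
                    n_genes=n_genes,
                    seed=derive_seed(seed, ci, fi, rep),
                )
                rows.extend(run_replicate(cfg, oi_cutoffs=oi_cutoffs))
    reps = pd.DataFrame(rows)
    metrics = [
        "precision", "recall", "f1", "raw_precision", "raw_recall",
        "noise", "mean_block_size",
    ]
    agg: dict = {}
    for m in metrics:
        agg[f"median_{m}"] = (m, "median")
        agg[f"{m}_lo"] = (m, lambda s: float(np.percentile(s, 2.5)))
        agg[f"{m}_hi"] = (m, lambda s: float(np.percentile(s, 97.5)))
    summary = (
        reps.groupby(["delta_t", "fold", "cutoff"]).agg(
            n_replicates=("seed", "size"), **agg
        ).reset_index()
    )
    if return_replicates:
        return summary, reps
    return summary
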