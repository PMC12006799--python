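"""Core in-memory containers for synteny/orthology data.

Conventions used throughout the toolkit:

* genomic coordinates are 1-based inclusive;
* gene order indices ("ranks") are 0-based and contiguous per chromosome,
  assigned by sorting on start coordinate (ties broken by gene id);
* a gene pair is orientation-free: (a, b) and (b, a) denote the same pair.
"""

from __future__ import annotations

import statistics
from dataclasses import dataclass, replace
from typing import Iterable, Iterator, Optional


@dataclass(frozen=True)
class GeneRecord:
    """A gene's location in its genome plus its rank along the chromosome."""

    genome_id: str
    chrom: str
    start: int
    end: int
    strand: str  # '+', '-' or '?'
    gene_id: str
    order_index: int

    def __post_init__(self) -> None:
        if self.start > self.end:
            raise ValueError(
                f"gene {self.gene_id}: start {self.start} > end {self.end}"
            )
        if self.order_index < 0:
            raise ValueError(f"gene {self.gene_id}: negative order_index")


@dataclass
class GenePair:
    """An unordered homologous gene pair across two genomes.

    ``ks`` is synonymous substitutions per synonymous site (a pair-age
    proxy); ``is_ortholog`` is filled in after joining with an
    :class:`OrthologyMap`.
    """

    gene_a: str
    gene_b: str
    genome_a: str = "A"
    genome_b: str = "B"
    ks: Optional[float] = None
    is_ortholog: Optional[bool] = None

    def key(self) -> frozenset:
        """Orientation-free identity of the pair."""
        return frozenset((self.gene_a, self.gene_b))

    def __post_init__(self) -> None:
        if self.genome_a == self.genome_b:
            raise ValueError(
                f"within-genome pair ({self.gene_a}, {self.gene_b}) "
                f"in genome {self.genome_a}"
            )
        if self.ks is not None and self.ks < 0:
            raise ValueError(f"negative Ks for pair ({self.gene_a}, {self.gene_b})")


@dataclass
class SyntenyBlock:
    """An ordered run of cross-genome gene pairs (a collinear block).

    ``oi`` is the Orthology Index n/m once annotated; ``median_ks`` the
    median Ks over pairs with a Ks value.
    """

    block_id: str
    genome_pair: tuple[str, str]
    chrom_pair: tuple[str, str]
    pairs: list[GenePair]
    orientation: str = "same"  # 'same' or 'inverted'
    oi: Optional[float] = None
    median_ks: Optional[float] = None

    @property
    def n_pairs(self) -> int:
        return len(self.pairs)

    def __post_init__(self) -> None:
        if not self.pairs:
            raise ValueError(f"block {self.block_id}: empty block")
        if self.orientation not in ("same", "inverted"):
            raise ValueError(f"block {self.block_id}: bad orientation")

    def copy(self) -> "SyntenyBlock":
        return SyntenyBlock(
            block_id=self.block_id,
            genome_pair=self.genome_pair,
            chrom_pair=self.chrom_pair,
            pairs=[replace(p) for p in self.pairs],
            orientation=self.orientation,
            oi=self.oi,
            median_ks=self.median_ks,
        )

    def compute_median_ks(self) -> Optional[float]:
        vals = [p.ks for p in self.pairs if p.ks is not None]
        return statistics.median(vals) if vals else None


class OrthologyMap:
    """Set of pre-inferred cross-genome ortholog pairs with symmetric lookup."""

    def __init__(self, pairs: Iterable[tuple[str, str]] = (), source: str = "") -> None:
        self.source = source
        self._pairs: set[frozenset] = set()
        for a, b in pairs:
            self.add(a, b)

    def add(self, gene_a: str, gene_b: str) -> None:
        if gene_a == gene_b:
            raise ValueError(f"self-pair for gene {gene_a}")
        self._pairs.add(frozenset((gene_a, gene_b)))

    def __contains__(self, pair) -> bool:
        if isinstance(pair, GenePair):
            return pair.key() in self._pairs
        a, b = pair
        return frozenset((a, b)) in self._pairs

    def __len__(self) -> int:
        return len(self._pairs)

    def __iter__(self) -> Iterator[tuple[str, str]]:
        for fs in self._pairs:
            a, b = sorted(fs)
            yield (a, b)

    def __eq__(self, other) -> bool:
        return isinstance(other, OrthologyMap) and self._pairs == other._pairs


def assign_order_indices(
    records: Iterable[GeneRecord],
) -> list[GeneRecord]:
    """Recompute 0-based per-chromosome order indices.

    Genes are ranked by start coordinate within each chromosome; equal
    starts are broken by lexicographic gene id so the ranking is
    deterministic.
    """
    by_chrom: dict[tuple[str, str], list[GeneRecord]] = {}
    for rec in records:
        by_chrom.setdefault((rec.genome_id, rec.chrom), []).append(rec)
    out: list[GeneRecord] = []
    for key in sorted(by_chrom):
        genes = sorted(by_chrom[key], key=lambda r: (r.start, r.gene_id))
        for idx, rec in enumerate(genes):
            out.append(replace(rec, order_index=idx))
    return out


def gene_index(records: Iterable[GeneRecord]) -> dict[str, GeneRecord]:
    """Map gene_id -> record, erroring on duplicates within the collection."""
    idx: dict[str, GeneRecord] = {}
    for rec in records:
        if rec.gene_id in idx:
            raise ValueError(f"duplicate gene_id {rec.gene_id!r}")
        idx[rec.gene_id] = rec
    return idx
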