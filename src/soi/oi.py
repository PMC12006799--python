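"""The Orthology Index (OI): per-block computation, filtering, summaries.

For a syntenic block with ``m`` gene pairs of which ``n`` are
pre-inferred as orthologs, OI = n/m.  Orthologous blocks (tracing to a
speciation) have OI near 1; out-paralogous blocks (tracing to a genome
duplication predating the speciation) have OI near 0.  Filtering at a
cutoff (default 0.6) retains orthologous synteny; the distribution of
OI over pairs is typically polarized, and the mass falling in the
intermediate band [0.3, 0.7) serves as a noise statistic.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Iterable, Mapping, Optional, Sequence

import numpy as np

from .model import OrthologyMap, SyntenyBlock

NOISE_BAND = (0.3, 0.7)


@dataclass(frozen=True)
class OIAnnotation:
    """Stored truth for one block: m pairs, n pre-inferred orthologs."""

    block_id: str
    m: int
    n: int

    @property
    def oi(self) -> float:
        return self.n / self.m

    def __post_init__(self) -> None:
        if self.m < 1:
            raise ValueError(f"block {self.block_id}: m must be >= 1")
        if not 0 <= self.n <= self.m:
            raise ValueError(f"block {self.block_id}: need 0 <= n <= m")


@dataclass
class OIDistribution:
    bin_edges: np.ndarray
    pair_weighted_counts: np.ndarray
    block_counts: np.ndarray
    noise: float
    block_noise: float

    @property
    def total_pairs(self) -> int:
        return int(self.pair_weighted_counts.sum())


def compute_oi(block: SyntenyBlock, orthology: OrthologyMap) -> OIAnnotation:
    """OI = n/m for one block: the fraction of its pairs pre-inferred
    as orthologs."""
    m = block.n_pairs
    if m < 1:
        raise ValueError(f"block {block.block_id}: cannot compute OI of empty block")
    n = sum(1 for p in block.pairs if p in orthology)
    return OIAnnotation(block_id=block.block_id, m=m, n=n)


def annotate_blocks(
    blocks: Iterable[SyntenyBlock],
    orthology: OrthologyMap,
    ks_map: Optional[Mapping[frozenset, float]] = None,
) -> list[SyntenyBlock]:
    """Return copies of ``blocks`` with oi, per-pair is_ortholog flags and
    median_ks filled in.  Missing Ks values are not an error."""
    out = []
    for block in blocks:
        b = block.copy()
        for p in b.pairs:
            p.is_ortholog = p in orthology
            if ks_map is not None and p.ks is None:
                ks = ks_map.get(p.key())
                if ks is not None:
                    p.ks = ks
        ann = compute_oi(b, orthology)
        b.oi = ann.oi
        b.median_ks = b.compute_median_ks()
        out.append(b)
    return out


def filter_blocks(
    blocks: Sequence[SyntenyBlock],
    oi_cutoff: float = 0.6,
    min_pairs: int = 1,
) -> list[SyntenyBlock]:
    """Retain blocks with oi >= oi_cutoff and n_pairs >= min_pairs.

    Boundary semantics: a block exactly at the cutoff is retained (only
    blocks *below* the threshold are discarded).  Input order is
    preserved and the input is not modified.
    """
    if not 0 <= oi_cutoff <= 1:
        raise ValueError(f"oi_cutoff {oi_cutoff} outside [0, 1]")
    for b in blocks:
        if b.oi is None:
            raise ValueError(f"block {b.block_id} not annotated; run annotate_blocks")
    return [b for b in blocks if b.oi >= oi_cutoff and b.n_pairs >= min_pairs]


def oi_distribution(
    blocks: Sequence[SyntenyBlock], bin_width: float = 0.05
) -> OIDistribution:
    """Pair-weighted OI histogram plus the intermediate-band noise statistic.

    Bins are half-open [lo, hi) with the last bin closed.  ``noise`` is
    the fraction of syntenic gene pairs whose block OI falls in
    [0.3, 0.7); ``block_noise`` is the block-weighted variant.
    """
    if not blocks:
        raise ValueError("oi_distribution of zero blocks")
    ois = np.array([b.oi for b in blocks], dtype=float)
    if np.any(np.isnan(ois)):
        raise ValueError("unannotated block passed to oi_distribution")
    weights = np.array([b.n_pairs for b in blocks], dtype=float)
    nbins = int(round(1.0 / bin_width))
    edges = np.linspace(0.0, 1.0, nbins + 1)
    pair_counts, _ = np.histogram(ois, bins=edges, weights=weights)
    block_counts, _ = np.histogram(ois, bins=edges)
    lo, hi = NOISE_BAND
    in_band = (ois >= lo) & (ois < hi)
    noise = float(weights[in_band].sum() / weights.sum())
    block_noise = float(in_band.sum() / len(ois))
    return OIDistribution(
        bin_edges=edges,
        pair_weighted_counts=pair_counts.astype(int),
        block_counts=block_counts.astype(int),
        noise=noise,
        block_noise=block_noise,
    )


def extract_syntenic_orthologs(
    retained_blocks: Iterable[SyntenyBlock],
) -> set[frozenset]:
    """Union of all pairs of the retained (OI-filtered) blocks.

    Every pair of a retained block is emitted, including pairs that were
    not pre-inferred as orthologs: within an orthologous block such
    pairs are presumed orthologs the upstream inference missed (the
    rescue effect of syntenic context).  Duplicates across blocks are
    collapsed.
    """
    out: set[frozenset] = set()
    for block in retained_blocks:
        for p in block.pairs:
            out.add(p.key())
    return out


def syntenic_ortholog_table(
    retained_blocks: Iterable[SyntenyBlock],
) -> list[tuple[str, str, float, Optional[float]]]:
    """Per-pair rows (geneA, geneB, oi, ks); a pair appearing in several
    retained blocks is reported once with the maximum block OI."""
    best: dict[frozenset, tuple[str, str, float, Optional[float]]] = {}
    for block in retained_blocks:
        for p in block.pairs:
            key = p.key()
            row = (p.gene_a, p.gene_b, float(block.oi or 0.0), p.ks)
            if key not in best or row[2] > best[key][2]:
                best[key] = row
    return sorted(best.values())
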