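"""Orthologous synteny depth in gene-rank windows and relative ploidy.

The reference genome's chromosomes are tiled with windows of a fixed
number of genes (default 50, the last window may be short); a window's
depth is the number of syntenic blocks whose reference-side gene-rank
interval overlaps it.  After OI filtering, the modal depth over covered
windows estimates relative ploidy p: p = 1 means one orthologous region
per reference window (no polyploidy since the divergence from the other
genome), p = 2 suggests tetraploidy, p = 3 hexaploidy.  Comparing the
depth ratio in the two directions (e.g. 2:2 before filtering vs 1:1
after) discriminates a shared WGD from lineage-specific WGDs.

Windows tile gene ranks, not base pairs, so intergenic length variation
cannot bias depth.  Depth counts overlapping blocks (not pair coverage)
by default, which is robust to internal gene loss; a pair-counting mode
is available.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from typing import Iterable, Mapping, Sequence

from .model import GeneRecord, SyntenyBlock


@dataclass
class DepthProfile:
    reference_genome: str
    window_size: int
    # (chrom, window_start_index, depth) with start index in gene ranks
    windows: list[tuple[str, int, int]]
    depth_histogram: dict[int, int]
    modal_depth: int
    warnings: list[str] = field(default_factory=list)


def _reference_side(block: SyntenyBlock, genome_id: str) -> int:
    if block.genome_pair[0] == genome_id:
        return 0
    if block.genome_pair[1] == genome_id:
        return 1
    raise ValueError(
        f"block {block.block_id} ({block.genome_pair}) does not involve "
        f"reference genome {genome_id!r}"
    )


def compute_depth(
    blocks: Iterable[SyntenyBlock],
    genes: Sequence[GeneRecord],
    window_size: int = 50,
    mode: str = "blocks",
) -> DepthProfile:
    """Window the reference genome by gene rank and count overlapping blocks.

    ``genes`` are the reference genome's records (their genome_id fixes
    which side of each block is the reference side).  In ``blocks`` mode
    each block overlapping a window contributes 1 regardless of overlap
    length; in ``pairs`` mode each syntenic pair contributes 1 to the
    window holding its reference gene.
    """
    if window_size < 1:
        raise ValueError("window_size must be >= 1")
    if mode not in ("blocks", "pairs"):
        raise ValueError(f"unknown depth mode {mode!r}")
    genes = list(genes)
    if not genes:
        raise ValueError("empty reference gene table")
    reference_genome = genes[0].genome_id
    rank: dict[str, tuple[str, int]] = {}
    chrom_sizes: dict[str, int] = {}
    for g in genes:
        rank[g.gene_id] = (g.chrom, g.order_index)
        chrom_sizes[g.chrom] = max(chrom_sizes.get(g.chrom, 0), g.order_index + 1)

    n_windows = {
        chrom: (size + window_size - 1) // window_size
        for chrom, size in chrom_sizes.items()
    }
    depth = {
        chrom: [0] * n for chrom, n in n_windows.items()
    }

    for block in blocks:
        side = _reference_side(block, reference_genome)
        ranks = []
        for p in block.pairs:
            gid = p.gene_a if side == 0 else p.gene_b
            if gid not in rank:
                raise ValueError(
                    f"block {block.block_id} references unknown gene {gid!r}"
                )
            ranks.append(rank[gid])
        chroms = {c for c, _ in ranks}
        if len(chroms) != 1:
            raise ValueError(
                f"block {block.block_id}: reference side spans chromosomes {chroms}"
            )
        chrom = chroms.pop()
        if mode == "pairs":
            for _, r in ranks:
                depth[chrom][r // window_size] += 1
        else:
            lo = min(r for _, r in ranks) // window_size
            hi = max(r for _, r in ranks) // window_size
            for w in range(lo, hi + 1):
                depth[chrom][w] += 1

    windows = [
        (chrom, w * window_size, depth[chrom][w])
        for chrom in sorted(depth)
        for w in range(len(depth[chrom]))
    ]
    histogram: dict[int, int] = {}
    for _, _, d in windows:
        histogram[d] = histogram.get(d, 0) + 1
    modal = _modal_nonzero_depth(histogram)
    return DepthProfile(
        reference_genome=reference_genome,
        window_size=window_size,
        windows=windows,
        depth_histogram=histogram,
        modal_depth=modal,
    )


def _modal_nonzero_depth(histogram: Mapping[int, int]) -> int:
    """Argmax of the window-depth histogram over depths >= 1; ties go to
    the smaller depth."""
    nonzero = {d: c for d, c in histogram.items() if d >= 1}
    if not nonzero:
        return 0
    best = max(nonzero.values())
    tied = sorted(d for d, c in nonzero.items() if c == best)
    return tied[0]


def estimate_relative_ploidy(
    profile: DepthProfile, min_covered_fraction: float = 0.5
) -> int:
    """Relative ploidy p = modal depth among covered (depth >= 1) windows.

    p = 0 only when no window is covered.  A warning is attached to the
    profile (and emitted) when coverage is sparse or the mode is tied.
    """
    total = len(profile.windows)
    covered = sum(1 for _, _, d in profile.windows if d >= 1)
    if total == 0 or covered == 0:
        msg = f"{profile.reference_genome}: no covered windows; p = 0"
        profile.warnings.append(msg)
        warnings.warn(msg, stacklevel=2)
        return 0
    if covered / total < min_covered_fraction:
        msg = (
            f"{profile.reference_genome}: only {covered}/{total} windows covered "
            f"(< {min_covered_fraction:.0%}); ploidy estimate may be unreliable"
        )
        profile.warnings.append(msg)
        warnings.warn(msg, stacklevel=2)
    nonzero = {d: c for d, c in profile.depth_histogram.items() if d >= 1}
    best = max(nonzero.values())
    tied = sorted(d for d, c in nonzero.items() if c == best)
    if len(tied) > 1:
        msg = (
            f"{profile.reference_genome}: modal depth tie {tied}; "
            f"reporting the smaller depth"
        )
        profile.warnings.append(msg)
        warnings.warn(msg, stacklevel=2)
    return tied[0]


def depth_ratio(
    profile_ab: DepthProfile, profile_ba: DepthProfile
) -> tuple[int, int]:
    """(p relative to A, p relative to B) for the same block set profiled
    with the reference on each genome in turn.  (1, 1) after OI filtering
    with (2, 2) before indicates a shared WGD; (2, 2) after filtering
    indicates lineage-specific WGDs."""
    return (
        estimate_relative_ploidy(profile_ab),
        estimate_relative_ploidy(profile_ba),
    )


def write_depth_profile(profile: DepthProfile, path) -> None:
    """TSV: chrom, window_start_gene, window_end_gene, depth."""
    with open(path, "w") as fh:
        fh.write("chrom\twindow_start_gene\twindow_end_gene\tdepth\n")
        for chrom, start, d in profile.windows:
            fh.write(f"{chrom}\t{start}\t{start + profile.window_size - 1}\t{d}\n")


def write_depth_histogram(profile: DepthProfile, path) -> None:
    with open(path, "w") as fh:
        fh.write("depth\tn_windows\n")
        for d in sorted(profile.depth_histogram):
            fh.write(f"{d}\t{profile.depth_histogram[d]}\n")
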