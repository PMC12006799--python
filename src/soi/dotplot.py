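"""Four-panel synteny diagnostics: homolog dot plot colored by OI or Ks,
the matching color-value histogram, and per-genome synteny-depth panels.

Coordinates are cumulative gene ranks (per-chromosome ranks offset by
the sizes of preceding chromosomes), matching the gene-order semantics
of synteny; chromosomes are ordered by descending gene count unless an
explicit order is given.  Rendering is deterministic: identical input
produces byte-identical SVG.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Optional, Sequence

import matplotlib

matplotlib.use("Agg")

import matplotlib.pyplot as plt
import numpy as np

from .depth import DepthProfile
from .model import GeneRecord, SyntenyBlock
from .oi import OIDistribution

#: color map contract: low values cool, high values warm
_CMAP = "viridis"


@dataclass
class DotData:
    # (x, y, color_value or nan, retained)
    points: list
    offsets_x: dict  # chrom -> cumulative start rank
    offsets_y: dict
    size_x: int
    size_y: int
    color_mode: str
    genome_x: str
    genome_y: str


def _chrom_layout(
    genes: Sequence[GeneRecord], order: Optional[Sequence[str]] = None
) -> tuple[dict, dict, int]:
    sizes: dict[str, int] = {}
    for g in genes:
        sizes[g.chrom] = max(sizes.get(g.chrom, 0), g.order_index + 1)
    if order is None:
        order = sorted(sizes, key=lambda c: (-sizes[c], c))
    offsets, cum = {}, 0
    for chrom in order:
        offsets[chrom] = cum
        cum += sizes[chrom]
    return offsets, sizes, cum


def assemble_dot_data(
    blocks: Sequence[SyntenyBlock],
    genes_x: Sequence[GeneRecord],
    genes_y: Sequence[GeneRecord],
    color_mode: str = "oi",
    oi_cutoff: float = 0.6,
    chrom_order_x: Optional[Sequence[str]] = None,
    chrom_order_y: Optional[Sequence[str]] = None,
) -> DotData:
    """One point per block pair at cumulative gene-rank coordinates.

    In ``oi`` mode every pair of a block is colored by the block OI; in
    ``ks`` mode by the pair Ks (NaN when absent).  ``retained`` flags
    pairs of blocks at or above ``oi_cutoff``.
    """
    if color_mode not in ("oi", "ks"):
        raise ValueError(f"unknown color_mode {color_mode!r}")
    genes_x, genes_y = list(genes_x), list(genes_y)
    off_x, _, size_x = _chrom_layout(genes_x, chrom_order_x)
    off_y, _, size_y = _chrom_layout(genes_y, chrom_order_y)
    lookup_x = {g.gene_id: g for g in genes_x}
    lookup_y = {g.gene_id: g for g in genes_y}
    genome_x = genes_x[0].genome_id if genes_x else "X"
    genome_y = genes_y[0].genome_id if genes_y else "Y"

    points = []
    for block in blocks:
        retained = block.oi is not None and block.oi >= oi_cutoff
        for p in block.pairs:
            if p.gene_a in lookup_x and p.gene_b in lookup_y:
                ga, gb = lookup_x[p.gene_a], lookup_y[p.gene_b]
            elif p.gene_b in lookup_x and p.gene_a in lookup_y:
                ga, gb = lookup_x[p.gene_b], lookup_y[p.gene_a]
            else:
                missing = p.gene_a if p.gene_a not in lookup_x else p.gene_b
                raise ValueError(f"pair references unknown gene {missing!r}")
            x = off_x[ga.chrom] + ga.order_index
            y = off_y[gb.chrom] + gb.order_index
            if color_mode == "oi":
                color = float(block.oi) if block.oi is not None else float("nan")
            else:
                color = float(p.ks) if p.ks is not None else float("nan")
            points.append((x, y, color, retained))
    return DotData(
        points=points,
        offsets_x=off_x,
        offsets_y=off_y,
        size_x=size_x,
        size_y=size_y,
        color_mode=color_mode,
        genome_x=genome_x,
        genome_y=genome_y,
    )


def render(
    dotdata: DotData,
    depth_x: Optional[DepthProfile],
    depth_y: Optional[DepthProfile],
    histogram: Optional[OIDistribution],
    path,
    format: str = "svg",
    retained_only: bool = False,
    ks_clip: float = 3.0,
) -> None:
    """Write the 4-panel figure: dots, color histogram, two depth panels.

    ``ks_clip`` caps the Ks color scale so the old-duplication tail does
    not flatten it.  SVG output carries no timestamps and uses a fixed
    hash salt, so identical input gives byte-identical files.
    """
    if format not in ("png", "svg", "pdf"):
        raise ValueError(f"unknown format {format!r}")
    with matplotlib.rc_context({"svg.hashsalt": "soi"}):
        fig = plt.figure(figsize=(11, 7))
        gs = fig.add_gridspec(3, 2, width_ratios=[2.2, 1.0])
        ax_dots = fig.add_subplot(gs[:, 0])
        ax_hist = fig.add_subplot(gs[0, 1])
        ax_dx = fig.add_subplot(gs[1, 1])
        ax_dy = fig.add_subplot(gs[2, 1])

        pts = [p for p in dotdata.points if p[3]] if retained_only else dotdata.points
        if pts:
            xs = np.array([p[0] for p in pts])
            ys = np.array([p[1] for p in pts])
            cs = np.array([p[2] for p in pts])
            vmax = 1.0 if dotdata.color_mode == "oi" else ks_clip
            missing = np.isnan(cs)
            if missing.any():
                ax_dots.scatter(
                    xs[missing], ys[missing], s=2, c="0.7", linewidths=0
                )
            sc = ax_dots.scatter(
                xs[~missing], ys[~missing], s=2, c=np.clip(cs[~missing], 0, vmax),
                cmap=_CMAP, vmin=0.0, vmax=vmax, linewidths=0,
            )
            fig.colorbar(sc, ax=ax_dots, label=dotdata.color_mode.upper(),
                         fraction=0.04)
        for off in sorted(dotdata.offsets_x.values()):
            ax_dots.axvline(off, color="0.85", lw=0.5, zorder=0)
        for off in sorted(dotdata.offsets_y.values()):
            ax_dots.axhline(off, color="0.85", lw=0.5, zorder=0)
        ax_dots.set_xlim(0, dotdata.size_x)
        ax_dots.set_ylim(0, dotdata.size_y)
        ax_dots.set_xlabel(f"{dotdata.genome_x} (cumulative gene rank)")
        ax_dots.set_ylabel(f"{dotdata.genome_y} (cumulative gene rank)")

        if histogram is not None:
            centers = 0.5 * (histogram.bin_edges[:-1] + histogram.bin_edges[1:])
            width = histogram.bin_edges[1] - histogram.bin_edges[0]
            colors = plt.get_cmap(_CMAP)(
                np.clip(centers, 0, 1) if dotdata.color_mode == "oi"
                else np.clip(centers / max(ks_clip, 1e-9), 0, 1)
            )
            ax_hist.bar(centers, histogram.pair_weighted_counts, width=width * 0.95,
                        color=colors)
            ax_hist.set_xlabel(dotdata.color_mode.upper())
            ax_hist.set_ylabel("gene pairs")

        for ax, prof, label in (
            (ax_dx, depth_x, dotdata.genome_x),
            (ax_dy, depth_y, dotdata.genome_y),
        ):
            if prof is None:
                ax.set_visible(False)
                continue
            depths = sorted(prof.depth_histogram)
            ax.bar(depths, [prof.depth_histogram[d] for d in depths],
                   color="0.4", width=0.8)
            ax.set_xlabel(f"synteny depth on {label}")
            ax.set_ylabel(f"{prof.window_size}-gene windows")

        fig.tight_layout()
        fig.savefig(path, format=format, metadata=_clean_metadata(format))
        plt.close(fig)


def _clean_metadata(format: str) -> Optional[dict]:
    if format == "svg":
        return {"Date": None}
    if format == "pdf":
        return {"CreationDate": None}
    return None
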