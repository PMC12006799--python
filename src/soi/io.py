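"""Readers and writers for the on-disk artifacts the toolkit consumes.

Supported syntenic-block dialects
---------------------------------
``canonical``
    This toolkit's own round-trippable format::

        #block <id> <genomeA> <genomeB> <chromA> <chromB> <orientation> <n_pairs> <oi|.> <median_ks|.>
        geneA<TAB>geneB<TAB><ks|.><TAB><is_ortholog 0/1|.>

``mcscanx``
    MCScanX collinearity: ``## Alignment`` headers followed by numbered
    pair lines.
``anchors``
    JCVI/MCscan anchors: blocks separated by ``###`` lines, 2-3 columns
    per pair (third column score, ignored).
``wgdi``
    WGDI-style block-info CSV with header; required columns ``id``,
    ``chr1``, ``chr2``, ``block1``, ``block2`` where block1/block2 are
    ``_``-joined gene-id lists; optional ``ks`` (``_``-joined floats) and
    ``ks_median`` columns.

Ortholog-pair dialects: ``pairs`` (two-column TSV) and ``orthofinder``
(per-row many-to-many lists; columns 2 and 3 hold comma-separated gene
ids and are expanded to their Cartesian product).

Floats are written with 4 decimals and no timestamps are emitted, so
output is bit-stable for fixed input.
"""

from __future__ import annotations

import csv
import io as _io
import warnings
from pathlib import Path
from typing import Iterable, Mapping, Optional, Sequence, Union

from .model import (
    GenePair,
    GeneRecord,
    OrthologyMap,
    SyntenyBlock,
    assign_order_indices,
)

PathLike = Union[str, Path]

_MISSING = "."


# ---------------------------------------------------------------------------
# gene tables


def read_gene_table(path: PathLike, genome_id: str) -> list[GeneRecord]:
    """Read a TSV gene-position table: chrom, start, end, gene_id, [strand].

    Coordinates are interpreted as 1-based inclusive.  Order indices are
    recomputed from start coordinates per chromosome (ties broken by
    gene id).  Lines starting with ``#`` are ignored.
    """
    records: list[GeneRecord] = []
    seen: set[str] = set()
    with open(path) as fh:
        for lineno, line in enumerate(fh, 1):
            line = line.rstrip("\n")
            if not line or line.startswith("#"):
                continue
            fields = line.split("\t")
            if len(fields) < 4:
                raise ValueError(
                    f"{path}:{lineno}: expected >=4 tab-separated columns, "
                    f"got {len(fields)}"
                )
            chrom, start_s, end_s, gene_id = fields[:4]
            strand = fields[4] if len(fields) > 4 and fields[4] in "+-" else "?"
            try:
                start, end = int(start_s), int(end_s)
            except ValueError:
                raise ValueError(
                    f"{path}:{lineno}: non-numeric coordinate "
                    f"({start_s!r}, {end_s!r})"
                ) from None
            if gene_id in seen:
                raise ValueError(f"{path}: duplicate gene_id {gene_id!r}")
            seen.add(gene_id)
            records.append(
                GeneRecord(
                    genome_id=genome_id,
                    chrom=chrom,
                    start=start,
                    end=end,
                    strand=strand,
                    gene_id=gene_id,
                    order_index=0,
                )
            )
    return assign_order_indices(records)


def write_gene_table(records: Sequence[GeneRecord], path: PathLike) -> None:
    with open(path, "w") as fh:
        for rec in sorted(records, key=lambda r: (r.chrom, r.order_index)):
            strand = rec.strand if rec.strand in "+-" else "?"
            fh.write(
                f"{rec.chrom}\t{rec.start}\t{rec.end}\t{rec.gene_id}\t{strand}\n"
            )


# ---------------------------------------------------------------------------
# syntenic blocks


def _fmt(value: Optional[float]) -> str:
    return _MISSING if value is None else f"{value:.4f}"


def _parse_opt_float(tok: str) -> Optional[float]:
    return None if tok == _MISSING or tok == "" else float(tok)


def _finalize_block(block: SyntenyBlock, genes: Optional[Mapping[str, GeneRecord]]):
    """Validate monotonicity and infer orientation when positions are known.

    Blocks that violate within-block monotonicity are kept with a
    warning (real detector outputs contain minor order noise and the
    Orthology Index does not depend on within-block order); orientation
    is then inferred from the majority direction of the second genome's
    rank steps.
    """
    if genes is None:
        return block
    try:
        xa = [genes[p.gene_a].order_index for p in block.pairs]
        xb = [genes[p.gene_b].order_index for p in block.pairs]
    except KeyError:
        return block  # positions unavailable for some genes; skip validation
    if len(xa) > 1:
        da = [j - i for i, j in zip(xa, xa[1:])]
        db = [j - i for i, j in zip(xb, xb[1:])]
        up_b = sum(1 for d in db if d > 0)
        down_b = sum(1 for d in db if d < 0)
        orientation = "same" if up_b >= down_b else "inverted"
        monotone_a = all(d > 0 for d in da)
        monotone_b = all(d > 0 for d in db) or all(d < 0 for d in db)
        if not (monotone_a and monotone_b):
            warnings.warn(
                f"block {block.block_id}: gene order not monotone; kept with "
                f"majority orientation {orientation!r}",
                stacklevel=3,
            )
        block.orientation = orientation
    return block


def read_synteny_blocks(
    path: PathLike,
    dialect: str = "canonical",
    genome_pair: tuple[str, str] = ("A", "B"),
    genes: Optional[Mapping[str, GeneRecord]] = None,
) -> list[SyntenyBlock]:
    """Parse syntenic blocks from one of the supported dialects.

    ``genes`` (gene_id -> GeneRecord over both genomes) is optional; when
    given, block monotonicity is validated and orientation inferred from
    gene ranks.
    """
    readers = {
        "canonical": _read_canonical,
        "mcscanx": _read_mcscanx,
        "anchors": _read_anchors,
        "wgdi": _read_wgdi,
    }
    if dialect not in readers:
        raise ValueError(
            f"unknown dialect {dialect!r}; expected one of {sorted(readers)}"
        )
    blocks = readers[dialect](Path(path), genome_pair)
    return [_finalize_block(b, genes) for b in blocks]


def _read_canonical(path: Path, genome_pair) -> list[SyntenyBlock]:
    blocks: list[SyntenyBlock] = []
    header = None
    pairs: list[GenePair] = []

    def flush():
        nonlocal header, pairs
        if header is None:
            return
        bid, ga, gb, ca, cb, orient, _n, oi, mks = header
        blocks.append(
            SyntenyBlock(
                block_id=bid,
                genome_pair=(ga, gb),
                chrom_pair=(ca, cb),
                pairs=pairs,
                orientation=orient,
                oi=oi,
                median_ks=mks,
            )
        )
        header, pairs = None, []

    with open(path) as fh:
        for lineno, line in enumerate(fh, 1):
            line = line.rstrip("\n")
            if not line:
                continue
            if line.startswith("#block"):
                flush()
                toks = line.split()
                if len(toks) < 8:
                    raise ValueError(f"{path}:{lineno}: malformed #block header")
                oi = _parse_opt_float(toks[8]) if len(toks) > 8 else None
                mks = _parse_opt_float(toks[9]) if len(toks) > 9 else None
                header = (
                    toks[1], toks[2], toks[3], toks[4], toks[5], toks[6],
                    int(toks[7]), oi, mks,
                )
            elif line.startswith("#"):
                continue
            else:
                if header is None:
                    raise ValueError(
                        f"{path}:{lineno}: pair line before any #block header"
                    )
                toks = line.split("\t")
                if len(toks) < 2:
                    raise ValueError(f"{path}:{lineno}: malformed pair line")
                ks = _parse_opt_float(toks[2]) if len(toks) > 2 else None
                is_orth = None
                if len(toks) > 3 and toks[3] != _MISSING:
                    is_orth = bool(int(toks[3]))
                pairs.append(
                    GenePair(
                        gene_a=toks[0],
                        gene_b=toks[1],
                        genome_a=header[1],
                        genome_b=header[2],
                        ks=ks,
                        is_ortholog=is_orth,
                    )
                )
    flush()
    return blocks


def _read_mcscanx(path: Path, genome_pair) -> list[SyntenyBlock]:
    ga, gb = genome_pair
    blocks: list[SyntenyBlock] = []
    header = None
    pairs: list[GenePair] = []

    def flush():
        nonlocal header, pairs
        if header is None:
            return
        bid, ca, cb, orient = header
        if pairs:
            blocks.append(
                SyntenyBlock(
                    block_id=bid,
                    genome_pair=(ga, gb),
                    chrom_pair=(ca, cb),
                    pairs=pairs,
                    orientation=orient,
                )
            )
        header, pairs = None, []

    with open(path) as fh:
        for line in fh:
            line = line.rstrip("\n")
            if line.startswith("## Alignment"):
                flush()
                toks = line.split()
                # "## Alignment 0: score=500 e_value=0 N=80 at1&bt1 plus"
                bid = toks[2].rstrip(":")
                chrom_tok = next((t for t in toks if "&" in t), "NA&NA")
                ca, _, cb = chrom_tok.partition("&")
                orient = "inverted" if toks[-1] == "minus" else "same"
                header = (bid, ca, cb, orient)
            elif line.startswith("#") or not line.strip():
                continue
            elif header is not None:
                body = line.split(":", 1)[1] if ":" in line else line
                toks = body.split()
                if len(toks) < 2:
                    continue
                pairs.append(
                    GenePair(gene_a=toks[0], gene_b=toks[1], genome_a=ga, genome_b=gb)
                )
    flush()
    return blocks


def _read_anchors(path: Path, genome_pair) -> list[SyntenyBlock]:
    ga, gb = genome_pair
    blocks: list[SyntenyBlock] = []
    pairs: list[GenePair] = []

    def flush():
        nonlocal pairs
        if pairs:
            blocks.append(
                SyntenyBlock(
                    block_id=str(len(blocks)),
                    genome_pair=(ga, gb),
                    chrom_pair=("NA", "NA"),
                    pairs=pairs,
                )
            )
        pairs = []

    with open(path) as fh:
        for lineno, line in enumerate(fh, 1):
            line = line.rstrip("\n")
            if line.startswith("###"):
                flush()
            elif line.startswith("#") or not line.strip():
                continue
            else:
                toks = line.split("\t") if "\t" in line else line.split()
                if len(toks) < 2:
                    raise ValueError(f"{path}:{lineno}: malformed anchors line")
                pairs.append(
                    GenePair(gene_a=toks[0], gene_b=toks[1], genome_a=ga, genome_b=gb)
                )
    flush()
    return blocks


def _read_wgdi(path: Path, genome_pair) -> list[SyntenyBlock]:
    ga, gb = genome_pair
    blocks: list[SyntenyBlock] = []
    with open(path, newline="") as fh:
        reader = csv.DictReader(fh)
        required = {"id", "chr1", "chr2", "block1", "block2"}
        if reader.fieldnames is None or not required.issubset(reader.fieldnames):
            raise ValueError(
                f"{path}: wgdi dialect requires CSV header with columns {sorted(required)}"
            )
        for row in reader:
            genes1 = row["block1"].split("_")
            genes2 = row["block2"].split("_")
            if len(genes1) != len(genes2):
                raise ValueError(
                    f"{path}: block {row['id']}: block1/block2 length mismatch"
                )
            ks_list: list[Optional[float]] = [None] * len(genes1)
            if row.get("ks"):
                ks_list = [
                    None if t in ("", _MISSING) else float(t)
                    for t in row["ks"].split("_")
                ]
            pairs = [
                GenePair(gene_a=a, gene_b=b, genome_a=ga, genome_b=gb, ks=k)
                for a, b, k in zip(genes1, genes2, ks_list)
            ]
            mks = None
            if row.get("ks_median"):
                mks = float(row["ks_median"])
            blocks.append(
                SyntenyBlock(
                    block_id=row["id"],
                    genome_pair=(ga, gb),
                    chrom_pair=(row["chr1"], row["chr2"]),
                    pairs=pairs,
                    median_ks=mks,
                )
            )
    return blocks


def write_blocks(
    blocks: Iterable[SyntenyBlock], path: PathLike, dialect: str = "canonical"
) -> None:
    """Write blocks; the canonical dialect round-trips through
    :func:`read_synteny_blocks` to an equal in-memory structure."""
    writers = {
        "canonical": _write_canonical,
        "mcscanx": _write_mcscanx,
        "anchors": _write_anchors,
    }
    if dialect not in writers:
        raise ValueError(f"unknown writer dialect {dialect!r}")
    buf = _io.StringIO()
    writers[dialect](list(blocks), buf)
    with open(path, "w") as fh:
        fh.write(buf.getvalue())


def _write_canonical(blocks: list[SyntenyBlock], fh) -> None:
    fh.write("#soi canonical block file v1\n")
    for b in blocks:
        fh.write(
            f"#block {b.block_id} {b.genome_pair[0]} {b.genome_pair[1]} "
            f"{b.chrom_pair[0]} {b.chrom_pair[1]} {b.orientation} "
            f"{b.n_pairs} {_fmt(b.oi)} {_fmt(b.median_ks)}\n"
        )
        for p in b.pairs:
            flag = _MISSING if p.is_ortholog is None else str(int(p.is_ortholog))
            fh.write(f"{p.gene_a}\t{p.gene_b}\t{_fmt(p.ks)}\t{flag}\n")


def _write_mcscanx(blocks: list[SyntenyBlock], fh) -> None:
    for b in blocks:
        strand = "minus" if b.orientation == "inverted" else "plus"
        fh.write(
            f"## Alignment {b.block_id}: score=0 e_value=0 N={b.n_pairs} "
            f"{b.chrom_pair[0]}&{b.chrom_pair[1]} {strand}\n"
        )
        for i, p in enumerate(b.pairs):
            fh.write(f"{b.block_id}-{i}:\t{p.gene_a}\t{p.gene_b}\t0\n")


def _write_anchors(blocks: list[SyntenyBlock], fh) -> None:
    for b in blocks:
        fh.write("###\n")
        for p in b.pairs:
            fh.write(f"{p.gene_a}\t{p.gene_b}\t0\n")


# ---------------------------------------------------------------------------
# ortholog pairs


def read_ortholog_pairs(path: PathLike, dialect: str = "pairs") -> OrthologyMap:
    """Read pre-inferred ortholog pairs.

    ``pairs``: two-column TSV of gene ids.  ``orthofinder``: rows with an
    orthogroup column then two comma-separated gene lists, expanded to the
    Cartesian product of the two lists (the toolkit's documented handling
    of many-to-many co-ortholog rows).
    """
    if dialect not in ("pairs", "orthofinder"):
        raise ValueError(f"unknown ortholog dialect {dialect!r}")
    omap = OrthologyMap(source=dialect)
    with open(path) as fh:
        for lineno, line in enumerate(fh, 1):
            line = line.rstrip("\n")
            if not line or line.startswith("#"):
                continue
            toks = line.split("\t")
            if dialect == "pairs":
                if len(toks) < 2:
                    raise ValueError(
                        f"{path}:{lineno}: expected 2 columns, got {len(toks)}"
                    )
                omap.add(toks[0], toks[1])
            else:
                if lineno == 1 and toks[0].lower() == "orthogroup":
                    continue  # header row
                if len(toks) < 3:
                    raise ValueError(
                        f"{path}:{lineno}: expected >=3 columns, got {len(toks)}"
                    )
                list_a = [g.strip() for g in toks[1].split(",") if g.strip()]
                list_b = [g.strip() for g in toks[2].split(",") if g.strip()]
                for a in list_a:
                    for b in list_b:
                        omap.add(a, b)
    return omap


def write_ortholog_pairs(omap: OrthologyMap, path: PathLike) -> None:
    with open(path, "w") as fh:
        for a, b in sorted(omap):
            fh.write(f"{a}\t{b}\n")


# ---------------------------------------------------------------------------
# Ks tables


def read_ks_table(
    path: PathLike, column: Optional[Union[int, str]] = None
) -> dict[frozenset, float]:
    """Read a per-pair Ks TSV into a symmetric lookup.

    The file has two gene-id columns followed by one or more numeric
    columns; ``column`` selects which (name from a header line, or
    0-based column index); by default the last numeric column is used.
    A header line is detected by non-numeric tokens past column 2.
    """
    lookup: dict[frozenset, float] = {}
    header: Optional[list[str]] = None
    col_idx: Optional[int] = None
    with open(path) as fh:
        for lineno, line in enumerate(fh, 1):
            line = line.rstrip("\n")
            if not line or line.startswith("#"):
                continue
            toks = line.split("\t")
            if len(toks) < 3:
                raise ValueError(
                    f"{path}:{lineno}: expected >=3 columns, got {len(toks)}"
                )
            if header is None and col_idx is None:
                numeric = []
                for i, t in enumerate(toks[2:], start=2):
                    try:
                        float(t)
                        numeric.append(i)
                    except ValueError:
                        pass
                if not numeric:  # header line
                    header = toks
                    continue
            if col_idx is None:
                if isinstance(column, str):
                    if header is None or column not in header:
                        raise ValueError(
                            f"{path}: Ks column {column!r} not found in header"
                        )
                    col_idx = header.index(column)
                elif isinstance(column, int):
                    col_idx = column
                else:
                    col_idx = len(toks) - 1
            try:
                ks = float(toks[col_idx])
            except (ValueError, IndexError):
                raise ValueError(
                    f"{path}:{lineno}: non-numeric Ks in column {col_idx}"
                ) from None
            if ks != ks:  # NaN: treat as missing
                continue
            if ks < 0:
                raise ValueError(f"{path}:{lineno}: negative Ks {ks}")
            lookup[frozenset((toks[0], toks[1]))] = ks
    return lookup


# ---------------------------------------------------------------------------
# SOG tables


def write_sogs(sogs, path: PathLike) -> None:
    """Write syntenic orthogroups as TSV: sog_id, genome_id, gene_id."""
    with open(path, "w") as fh:
        fh.write("sog_id\tgenome_id\tgene_id\n")
        for sog in sogs:
            for genome_id in sorted(sog.members):
                for gene_id in sorted(sog.members[genome_id]):
                    fh.write(f"{sog.sog_id}\t{genome_id}\t{gene_id}\n")


def read_sog_table(path: PathLike) -> dict[str, dict[str, list[str]]]:
    """Read a SOG TSV back into {sog_id: {genome_id: [gene_ids]}}."""
    out: dict[str, dict[str, list[str]]] = {}
    with open(path) as fh:
        for lineno, line in enumerate(fh, 1):
            line = line.rstrip("\n")
            if not line or line.startswith("#"):
                continue
            toks = line.split("\t")
            if toks[:3] == ["sog_id", "genome_id", "gene_id"]:
                continue
            if len(toks) < 3:
                raise ValueError(f"{path}:{lineno}: expected 3 columns")
            out.setdefault(toks[0], {}).setdefault(toks[1], []).append(toks[2])
    return out
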