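"""Readers and writers for the plain-text formats the pipeline exchanges.

BED and bedGraph are tab-separated, 0-based half-open.  Tables (gene
annotation, differential regions, DEGs, candidate reports) are TSV with
headers and go through pandas.
"""

from __future__ import annotations

import os
from typing import Iterable

import numpy as np
import pandas as pd

from .intervals import CoverageTrack, GenomeTable, GeneModel, Region, RegionSet

__all__ = [
    "read_bed",
    "write_bed",
    "read_chrom_sizes",
    "write_chrom_sizes",
    "read_bedgraph",
    "write_bedgraph",
    "read_gene_annotation",
    "write_gene_annotation",
    "read_marker_list",
    "write_marker_list",
]


def read_bed(path: str | os.PathLike, label: str = "") -> RegionSet:
    """Read BED3+ (optional 4th column kept as the region name)."""
    regions = []
    with open(path) as fh:
        for ln, line in enumerate(fh, 1):
            line = line.rstrip("\n")
            if not line or line.startswith(("#", "track", "browser")):
                continue
            parts = line.split("\t")
            if len(parts) < 3:
                raise ValueError(f"{path}:{ln}: fewer than 3 BED columns")
            name = parts[3] if len(parts) > 3 and parts[3] != "." else None
            regions.append(Region(parts[0], int(parts[1]), int(parts[2]), name))
    return RegionSet(regions, label=label or str(path))


def write_bed(regions: RegionSet, path: str | os.PathLike) -> None:
    with open(path, "w") as fh:
        for r in regions:
            if r.name is not None:
                fh.write(f"{r.chrom}\t{r.start}\t{r.end}\t{r.name}\n")
            else:
                fh.write(f"{r.chrom}\t{r.start}\t{r.end}\n")


def read_chrom_sizes(path: str | os.PathLike) -> GenomeTable:
    chroms, lengths = [], []
    with open(path) as fh:
        for line in fh:
            if not line.strip():
                continue
            c, l = line.split("\t")[:2]
            chroms.append(c)
            lengths.append(int(l))
    return GenomeTable(tuple(chroms), tuple(lengths))


def write_chrom_sizes(genome: GenomeTable, path: str | os.PathLike) -> None:
    with open(path, "w") as fh:
        for c, l in zip(genome.chroms, genome.lengths):
            fh.write(f"{c}\t{l}\n")


def read_bedgraph(path: str | os.PathLike, name: str = "") -> CoverageTrack:
    per_chrom: dict[str, tuple[list, list, list]] = {}
    with open(path) as fh:
        for line in fh:
            line = line.rstrip("\n")
            if not line or line.startswith(("#", "track")):
                continue
            c, s, e, v = line.split("\t")[:4]
            acc = per_chrom.setdefault(c, ([], [], []))
            acc[0].append(int(s))
            acc[1].append(int(e))
            acc[2].append(float(v))
    return CoverageTrack(
        name or str(path),
        {c: (np.array(s), np.array(e), np.array(v)) for c, (s, e, v) in per_chrom.items()},
    )


def write_bedgraph(track: CoverageTrack, path: str | os.PathLike) -> None:
    with open(path, "w") as fh:
        for chrom in sorted(track.intervals):
            starts, ends, values = track.intervals[chrom]
            for s, e, v in zip(starts.tolist(), ends.tolist(), values.tolist()):
                fh.write(f"{chrom}\t{s}\t{e}\t{v:g}\n")


def read_gene_annotation(path: str | os.PathLike) -> list[GeneModel]:
    """TSV with header: symbol, chrom, strand, tss [, exon_starts, exon_ends].

    Exon columns are comma-separated 0-based half-open coordinates.
    """
    df = pd.read_csv(path, sep="\t", dtype=str)
    required = {"symbol", "chrom", "strand", "tss"}
    missing = required - set(df.columns)
    if missing:
        raise ValueError(f"gene annotation missing columns: {sorted(missing)}")
    genes: list[GeneModel] = []
    has_exons = {"exon_starts", "exon_ends"} <= set(df.columns)
    for row in df.itertuples(index=False):
        exons = None
        if has_exons and isinstance(row.exon_starts, str) and row.exon_starts:
            ss = [int(x) for x in row.exon_starts.rstrip(",").split(",")]
            ee = [int(x) for x in row.exon_ends.rstrip(",").split(",")]
            exons = tuple(Region(row.chrom, s, e) for s, e in zip(ss, ee))
        genes.append(
            GeneModel(row.symbol, row.chrom, row.strand, int(row.tss), exons)
        )
    return genes


def write_gene_annotation(genes: Iterable[GeneModel], path: str | os.PathLike) -> None:
    rows = []
    for g in genes:
        if g.exons:
            es = ",".join(str(e.start) for e in g.exons)
            ee = ",".join(str(e.end) for e in g.exons)
        else:
            es = ee = ""
        rows.append((g.symbol, g.chrom, g.strand, g.tss, es, ee))
    pd.DataFrame(
        rows, columns=["symbol", "chrom", "strand", "tss", "exon_starts", "exon_ends"]
    ).to_csv(path, sep="\t", index=False)


def read_marker_list(path: str | os.PathLike, label: str = "") -> "MarkerList":
    from .discovery import MarkerList

    with open(path) as fh:
        symbols = [ln.strip() for ln in fh if ln.strip()]
    return MarkerList(frozenset(symbols), label=label or str(path))


def write_marker_list(markers, path: str | os.PathLike) -> None:
    with open(path, "w") as fh:
        for s in sorted(markers.symbols):
            fh.write(s + "\n")
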