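"""Integration stage: consensus DARs, consensus DEGs, marker-gene mapping,
score attachment and candidate-report summaries.

A differentially accessible region (DAR) is trusted only when the primary
caller's region overlaps a region from an independent confirming caller
with the same direction of change.  DARs opened in the later condition are
mapped to their nearest gene; those whose nearest gene belongs to a marker
list become candidate regulatory elements, which are then given ensemble
enhancer scores and summarised.
"""

from __future__ import annotations

import importlib.resources
import os
from dataclasses import dataclass, replace
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd

from .intervals import (
    GeneModel,
    Region,
    RegionSet,
    annotate_nearest_tss,
    parse_region_id,
)

__all__ = [
    "SignedRegion",
    "DEGRecord",
    "MarkerList",
    "CandidateRE",
    "MotifHitTable",
    "consensus_dars",
    "select_opened",
    "consensus_degs",
    "map_to_markers",
    "attach_scores",
    "summarize_candidates",
    "motif_copresence",
    "read_differential_table",
    "write_differential_table",
    "read_deg_table",
    "candidates_to_frame",
    "write_candidate_table",
    "read_candidate_table",
    "load_table2_candidates",
    "load_table3_scores",
]

DIRECTIONS = ("up", "down")
NOT_EXPRESSED = "not expressed"


@dataclass(frozen=True)
class SignedRegion:
    """A differential-accessibility row: region, direction and statistics."""

    region: Region
    direction: str
    logfc: float
    p: float
    fdr: float

    def __post_init__(self) -> None:
        if self.direction not in DIRECTIONS:
            raise ValueError(f"direction must be one of {DIRECTIONS}")
        if self.logfc != 0 and (self.logfc > 0) != (self.direction == "up"):
            raise ValueError(
                f"direction {self.direction!r} inconsistent with logFC {self.logfc}"
            )
        if not (0 <= self.p <= 1 and 0 <= self.fdr <= 1):
            raise ValueError("p and FDR must lie in [0, 1]")


@dataclass(frozen=True)
class DEGRecord:
    gene: str
    log2fc: float
    significant: bool


@dataclass(frozen=True)
class MarkerList:
    """Marker genes of one cluster (symbols unique by construction)."""

    symbols: frozenset[str]
    label: str = ""

    @classmethod
    def from_iterable(cls, symbols: Iterable[str], label: str = "") -> "MarkerList":
        return cls(frozenset(s.strip() for s in symbols if s.strip()), label)

    def __contains__(self, symbol: str) -> bool:
        return symbol in self.symbols

    def __len__(self) -> int:
        return len(self.symbols)


@dataclass(frozen=True)
class CandidateRE:
    """One candidate regulatory element (one row of the candidate report)."""

    region: Region
    location: str
    distance_to_tss: int
    gene: str
    gene_log2fc: float | None  # None renders as "not expressed"
    logfc_atac: float = float("nan")
    p: float = float("nan")
    fdr: float = float("nan")
    score: float | None = None
    literature_ref: str = ""

    def __post_init__(self) -> None:
        if self.score is not None and not 0.0 <= self.score <= 1.0:
            raise ValueError(f"score {self.score} outside [0, 1]")


class MotifHitTable:
    """Per-region sets of motif-family labels, over a declared vocabulary."""

    def __init__(
        self,
        hits: Mapping[str, Iterable[str]],
        vocabulary: Iterable[str] | None = None,
    ) -> None:
        self.hits = {rid: frozenset(fams) for rid, fams in hits.items()}
        seen = set().union(*self.hits.values()) if self.hits else set()
        self.vocabulary = frozenset(vocabulary) if vocabulary is not None else frozenset(seen)
        unknown = seen - self.vocabulary
        if unknown:
            raise ValueError(f"motif labels outside vocabulary: {sorted(unknown)}")

    def __len__(self) -> int:
        return len(self.hits)


def consensus_dars(
    primary: Sequence[SignedRegion], confirming: Sequence[SignedRegion]
) -> list[SignedRegion]:
    """Primary rows confirmed by an overlapping same-direction row.

    Coordinates come from the primary caller; a row survives iff at least
    one confirming region overlaps it with the same direction.
    """
    by_dir = {
        d: RegionSet([c.region for c in confirming if c.direction == d])
        for d in DIRECTIONS
    }
    return [s for s in primary if by_dir[s.direction].any_overlap(s.region)]


def select_opened(
    dars: Sequence[SignedRegion], direction: str = "up"
) -> list[SignedRegion]:
    """Rows changed in the requested direction only."""
    if direction not in DIRECTIONS:
        raise ValueError(f"unknown direction {direction!r}")
    return [d for d in dars if d.direction == direction]


def consensus_degs(
    a: Sequence[DEGRecord], b: Sequence[DEGRecord]
) -> set[str]:
    """Genes significant in both tables with the same log2FC sign."""
    b_by_gene = {r.gene: r for r in b if r.significant}
    out = set()
    for r in a:
        if not r.significant:
            continue
        other = b_by_gene.get(r.gene)
        if other is not None and np.sign(r.log2fc) == np.sign(other.log2fc):
            out.add(r.gene)
    return out


def map_to_markers(
    opened_dars: Sequence[SignedRegion],
    genes: Sequence[GeneModel],
    markers: MarkerList,
    deg: Mapping[str, float] | Sequence[DEGRecord],
) -> list[CandidateRE]:
    """Candidate REs: opened DARs whose nearest gene is a marker gene.

    ``deg`` maps gene symbol -> log2FC (records or mapping); a candidate
    whose gene has no entry is reported as not expressed.  Output is in
    coordinate order (scores are attached later).
    """
    if not genes:
        raise ValueError("gene annotation is empty")
    if isinstance(deg, Mapping):
        log2fc_of = dict(deg)
    else:
        log2fc_of = {r.gene: r.log2fc for r in deg}
    out: list[CandidateRE] = []
    for dar in opened_dars:
        ann = annotate_nearest_tss(dar.region, genes)
        if ann.gene not in markers:
            continue
        out.append(
            CandidateRE(
                region=dar.region,
                location=ann.location,
                distance_to_tss=ann.distance_to_tss,
                gene=ann.gene,
                gene_log2fc=log2fc_of.get(ann.gene),
                logfc_atac=dar.logfc,
                p=dar.p,
                fdr=dar.fdr,
            )
        )
    out.sort(key=lambda c: (c.region.chrom, c.region.start, c.region.end))
    return out


def attach_scores(
    candidates: Sequence[CandidateRE], scores
) -> list[CandidateRE]:
    """Join ensemble mean scores and sort by score descending.

    ``scores`` is an :class:`~ecre.model.EnsembleScore` or any mapping
    region-id -> score.  A candidate with no score raises, naming the
    region.  Ties break on coordinates.
    """
    if isinstance(scores, Mapping):
        lookup = scores.__getitem__
    else:
        lookup = scores.score_of
    joined = []
    for c in candidates:
        try:
            s = float(lookup(c.region.id))
        except KeyError:
            raise KeyError(f"no ensemble score for region {c.region.id}") from None
        joined.append(replace(c, score=s))
    joined.sort(
        key=lambda c: (-c.score, c.region.chrom, c.region.start, c.region.end)
    )
    return joined


def summarize_candidates(
    candidates: Sequence[CandidateRE], tau: float = 0.5
) -> dict:
    """Headline counts: total, above threshold (strict), literature-backed.

    Percentages are rounded to the nearest integer.
    """
    if any(c.score is None for c in candidates):
        raise ValueError("summarize_candidates requires scores attached")
    n_total = len(candidates)
    above = [c for c in candidates if c.score > tau]
    n_above = len(above)
    n_ref = sum(1 for c in above if c.literature_ref)
    return {
        "n_total": n_total,
        "n_above": n_above,
        "n_above_with_ref": n_ref,
        "pct_above": round(100.0 * n_above / n_total) if n_total else 0,
        "pct_ref_of_above": round(100.0 * n_ref / n_above) if n_above else 0,
    }


def motif_copresence(
    hits: MotifHitTable, fam_a: str, fam_b: str
) -> tuple[int, float]:
    """Regions carrying at least one hit of each family: (count, fraction)."""
    if len(hits) == 0:
        raise ValueError("motif hit table is empty")
    count = sum(1 for fams in hits.hits.values() if fam_a in fams and fam_b in fams)
    return count, count / len(hits)


# ---------------------------------------------------------------------------
# Tables on disk
# ---------------------------------------------------------------------------

_DIFF_COLS = ["chrom", "start", "end", "logfc", "p_value", "fdr", "direction"]


def read_differential_table(path: str | os.PathLike) -> list[SignedRegion]:
    df = pd.read_csv(path, sep="\t")
    missing = set(_DIFF_COLS) - set(df.columns)
    if missing:
        raise ValueError(f"differential table missing columns: {sorted(missing)}")
    return [
        SignedRegion(
            Region(r.chrom, int(r.start), int(r.end)),
            r.direction,
            float(r.logfc),
            float(r.p_value),
            float(r.fdr),
        )
        for r in df.itertuples(index=False)
    ]


def write_differential_table(
    rows: Sequence[SignedRegion], path: str | os.PathLike
) -> None:
    pd.DataFrame(
        [
            (s.region.chrom, s.region.start, s.region.end, s.logfc, s.p, s.fdr, s.direction)
            for s in rows
        ],
        columns=_DIFF_COLS,
    ).to_csv(path, sep="\t", index=False)


def read_deg_table(path: str | os.PathLike) -> list[DEGRecord]:
    df = pd.read_csv(path, sep="\t")
    missing = {"gene", "log2fc", "significant"} - set(df.columns)
    if missing:
        raise ValueError(f"DEG table missing columns: {sorted(missing)}")
    return [
        DEGRecord(r.gene, float(r.log2fc), bool(r.significant))
        for r in df.itertuples(index=False)
    ]


_CANDIDATE_COLS = [
    "region_id",
    "logfc_atac",
    "p_value",
    "fdr",
    "location",
    "distance_to_tss",
    "gene",
    "gene_log2fc",
    "prediction_score",
    "literature_ref",
]


def candidates_to_frame(candidates: Sequence[CandidateRE]) -> pd.DataFrame:
    rows = []
    for c in candidates:
        rows.append(
            (
                c.region.id,
                c.logfc_atac,
                c.p,
                c.fdr,
                c.location,
                c.distance_to_tss,
                c.gene,
                NOT_EXPRESSED if c.gene_log2fc is None else c.gene_log2fc,
                c.score,
                c.literature_ref,
            )
        )
    return pd.DataFrame(rows, columns=_CANDIDATE_COLS)


def write_candidate_table(
    candidates: Sequence[CandidateRE], path: str | os.PathLike
) -> None:
    candidates_to_frame(candidates).to_csv(
        path, sep="\t", index=False, float_format="%.10g"
    )


def _frame_to_candidates(df: pd.DataFrame) -> list[CandidateRE]:
    out = []
    for r in df.itertuples(index=False):
        raw_fc = r.gene_log2fc
        if pd.isna(raw_fc) or str(raw_fc).strip() in ("", NOT_EXPRESSED):
            fc = None
        else:
            fc = float(raw_fc)
        ref = "" if pd.isna(r.literature_ref) else str(r.literature_ref)
        out.append(
            CandidateRE(
                region=parse_region_id(r.region_id),
                location=str(r.location),
                distance_to_tss=int(r.distance_to_tss),
                gene=str(r.gene),
                gene_log2fc=fc,
                logfc_atac=float(r.logfc_atac),
                p=float(r.p_value),
                fdr=float(r.fdr),
                score=None if pd.isna(r.prediction_score) else float(r.prediction_score),
                literature_ref=ref,
            )
        )
    return out


def read_candidate_table(path: str | os.PathLike) -> list[CandidateRE]:
    df = pd.read_csv(path, sep="\t", dtype={"literature_ref": str})
    missing = set(_CANDIDATE_COLS) - set(df.columns)
    if missing:
        raise ValueError(f"candidate table missing columns: {sorted(missing)}")
    return _frame_to_candidates(df)


def _data_path(name: str):
    return importlib.resources.files("ecre.data").joinpath(name)


def load_table2_candidates() -> list[CandidateRE]:
    """The published 101 candidate regulatory elements, with scores."""
    with importlib.resources.as_file(_data_path("table2_candidates.tsv")) as p:
        return read_candidate_table(p)


def load_table3_scores() -> pd.DataFrame:
    """Six manually curated REs of major endothelial genes, with scores."""
    with importlib.resources.as_file(_data_path("table3_candidates.tsv")) as p:
        return pd.read_csv(p, sep="\t")
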