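"""Genomic interval arithmetic on 0-based half-open coordinates.

Everything downstream — feature assembly, matched-negative sampling,
differential-region consensus, nearest-gene annotation — is built on the
primitives here.  Internally all coordinates are BED-style 0-based half-open;
the ``chrN-start-end`` id strings used in candidate reports are 1-based
inclusive display coordinates, bridged explicitly by
:func:`parse_region_id` / :meth:`Region.id` so the off-by-one lives in
exactly one place.
"""

from __future__ import annotations

import re
from bisect import bisect_right
from dataclasses import dataclass, field
from typing import Iterable, Iterator, Sequence

import numpy as np

__all__ = [
    "GenomeTable",
    "Region",
    "RegionSet",
    "GeneModel",
    "AnnotationResult",
    "CoverageTrack",
    "parse_region_id",
    "overlaps",
    "intersect",
    "filter_excluded",
    "consensus_peaks",
    "shuffle_match",
    "annotate_nearest_tss",
    "PROMOTER_WINDOW",
]

#: Half-width (bp) of the promoter window around a TSS.
PROMOTER_WINDOW = 1000

_REGION_ID = re.compile(r"^([A-Za-z0-9_.]+)-(\d+)-(\d+)$")


class RegionParseError(ValueError):
    """Raised when a region id string cannot be interpreted."""


@dataclass(frozen=True)
class GenomeTable:
    """Chromosome names and lengths (a chrom.sizes table)."""

    chroms: tuple[str, ...]
    lengths: tuple[int, ...]

    def __post_init__(self) -> None:
        if len(self.chroms) != len(set(self.chroms)):
            raise ValueError("duplicate chromosome labels")
        if any(l <= 0 for l in self.lengths):
            raise ValueError("chromosome lengths must be positive")
        if len(self.chroms) != len(self.lengths):
            raise ValueError("chroms and lengths differ in number")

    @classmethod
    def from_dict(cls, sizes: dict[str, int]) -> "GenomeTable":
        return cls(tuple(sizes), tuple(sizes.values()))

    def length_of(self, chrom: str) -> int:
        try:
            return self.lengths[self.chroms.index(chrom)]
        except ValueError:
            raise KeyError(f"unknown chromosome {chrom!r}") from None

    def __contains__(self, chrom: str) -> bool:
        return chrom in self.chroms

    @property
    def total_length(self) -> int:
        return int(sum(self.lengths))


@dataclass(frozen=True, order=True)
class Region:
    """A half-open genomic interval [start, end) on one chromosome."""

    chrom: str
    start: int
    end: int
    name: str | None = field(default=None, compare=False)

    def __post_init__(self) -> None:
        if self.start < 0:
            raise ValueError(f"negative start {self.start}")
        if self.start >= self.end:
            raise ValueError(
                f"empty interval {self.chrom}:{self.start}-{self.end}"
            )

    def __len__(self) -> int:
        return self.end - self.start

    @property
    def id(self) -> str:
        """1-based inclusive display id, e.g. ``chr11-55022942-55023482``."""
        return f"{self.chrom}-{self.start + 1}-{self.end}"

    @property
    def midpoint(self) -> int:
        return (self.start + self.end) // 2


def parse_region_id(text: str) -> Region:
    """Parse a ``<chrom>-<start>-<end>`` display id into a :class:`Region`.

    Display ids are 1-based inclusive, so the internal half-open start is
    ``start_display - 1``.  Formatting the result (:attr:`Region.id`)
    reproduces the input.
    """
    m = _REGION_ID.match(text.strip())
    if not m:
        raise RegionParseError(f"malformed region id {text!r}")
    chrom, start_s, end_s = m.groups()
    if int(start_s) >= int(end_s):
        raise RegionParseError(
            f"degenerate interval in region id {text!r} ({start_s} >= {end_s})"
        )
    return Region(chrom, int(start_s) - 1, int(end_s))


def overlaps(a: Region, b: Region) -> bool:
    """True iff the two regions share at least one base."""
    return a.chrom == b.chrom and max(a.start, b.start) < min(a.end, b.end)


class RegionSet:
    """An ordered collection of regions, kept sorted by (chrom, start, end)."""

    def __init__(self, regions: Iterable[Region] = (), label: str = "") -> None:
        self.regions: list[Region] = sorted(
            regions, key=lambda r: (r.chrom, r.start, r.end)
        )
        self.label = label
        self._index: dict[str, tuple[np.ndarray, np.ndarray, np.ndarray]] | None = None

    def __len__(self) -> int:
        return len(self.regions)

    def __iter__(self) -> Iterator[Region]:
        return iter(self.regions)

    def __getitem__(self, i: int) -> Region:
        return self.regions[i]

    def __eq__(self, other: object) -> bool:
        if not isinstance(other, RegionSet):
            return NotImplemented
        return self.regions == other.regions

    def __repr__(self) -> str:
        lab = f" {self.label!r}" if self.label else ""
        return f"<RegionSet{lab} n={len(self)}>"

    def lengths(self) -> list[int]:
        return [len(r) for r in self.regions]

    def by_chrom(self) -> dict[str, tuple[np.ndarray, np.ndarray]]:
        """Per-chromosome (starts, ends) arrays, sorted by start."""
        out: dict[str, tuple[list[int], list[int]]] = {}
        for r in self.regions:
            s, e = out.setdefault(r.chrom, ([], []))
            s.append(r.start)
            e.append(r.end)
        return {
            c: (np.asarray(s, dtype=np.int64), np.asarray(e, dtype=np.int64))
            for c, (s, e) in out.items()
        }

    def merged(self) -> "RegionSet":
        """Union of the base set: overlapping or bookended regions fused."""
        out: list[Region] = []
        for chrom, (starts, ends) in self.by_chrom().items():
            cur_s, cur_e = None, None
            for s, e in zip(starts.tolist(), ends.tolist()):
                if cur_s is None:
                    cur_s, cur_e = s, e
                elif s <= cur_e:  # touching counts: single base set
                    cur_e = max(cur_e, e)
                else:
                    out.append(Region(chrom, cur_s, cur_e))
                    cur_s, cur_e = s, e
            if cur_s is not None:
                out.append(Region(chrom, cur_s, cur_e))
        return RegionSet(out, label=self.label)

    def _overlap_index(self) -> dict[str, tuple[np.ndarray, np.ndarray, np.ndarray]]:
        """Cached (starts, ends, running-max-of-ends) per chromosome."""
        if self._index is None:
            self._index = {
                c: (s, e, np.maximum.accumulate(e))
                for c, (s, e) in self.by_chrom().items()
            }
        return self._index

    def any_overlap(self, region: Region) -> bool:
        """Does any member overlap ``region``?  O(log n)."""
        idx = self._overlap_index().get(region.chrom)
        if idx is None:
            return False
        starts, _, maxends = idx
        # members starting at or beyond region.end cannot overlap; among the
        # earlier ones the running max end decides
        k = int(np.searchsorted(starts, region.end, side="left"))
        return k > 0 and bool(maxends[k - 1] > region.start)


def intersect(a: RegionSet, b: RegionSet) -> RegionSet:
    """Overlap fragments of the two base sets, bookended fragments merged.

    Every returned base lies in some region of ``a`` and some region of
    ``b``.  Computed on the merged (union) form of each input, so the
    fragments are disjoint and maximal.
    """
    am, bm = a.merged().by_chrom(), b.merged().by_chrom()
    out: list[Region] = []
    for chrom in sorted(set(am) & set(bm)):
        sa, ea = am[chrom]
        sb, eb = bm[chrom]
        i = j = 0
        while i < len(sa) and j < len(sb):
            s = max(sa[i], sb[j])
            e = min(ea[i], eb[j])
            if s < e:
                out.append(Region(chrom, int(s), int(e)))
            if ea[i] < eb[j]:
                i += 1
            else:
                j += 1
    return RegionSet(out)


def filter_excluded(a: RegionSet, excl: RegionSet) -> RegionSet:
    """Members of ``a`` overlapping no region of ``excl`` (whole-region drop)."""
    if len(excl) == 0:
        return RegionSet(a.regions, label=a.label)
    exm = excl.merged()
    kept = [r for r in a if not exm.any_overlap(r)]
    return RegionSet(kept, label=a.label)


def consensus_peaks(
    rep1: RegionSet, rep2: RegionSet, mode: str = "fragments"
) -> RegionSet:
    """Peaks supported by both replicates.

    ``mode="fragments"`` (default) returns the overlap fragments of the two
    base sets; ``mode="rep1"`` keeps each full rep1 peak that overlaps at
    least one rep2 peak.
    """
    if mode == "fragments":
        return intersect(rep1, rep2)
    if mode == "rep1":
        kept = [r for r in rep1 if rep2.any_overlap(r)]
        return RegionSet(kept, label=rep1.label)
    raise ValueError(f"unknown consensus mode {mode!r}")


class PlacementError(RuntimeError):
    """Raised when a shuffled region cannot be placed."""


def shuffle_match(
    templates: RegionSet,
    genome: GenomeTable,
    excl: RegionSet,
    rng: np.random.Generator,
    max_attempts: int = 1000,
) -> RegionSet:
    """Random genome placement of length-matched regions avoiding ``excl``.

    Emulates a bedtools-shuffle style negative draw: for each template a
    chromosome is chosen with probability proportional to its length, a
    start uniform over the admissible range, and the placement is rejected
    (and redrawn, up to ``max_attempts`` times) while it overlaps any
    exclusion region or exceeds the chromosome bounds.  The output length
    multiset equals the template length multiset exactly.  Output regions
    may overlap one another; they avoid only ``excl``.
    """
    if len(templates) == 0:
        return RegionSet()
    chrom_lengths = np.asarray(genome.lengths, dtype=np.float64)
    probs = chrom_lengths / chrom_lengths.sum()
    exm = excl.merged()
    placed: list[Region] = []
    for t in templates:
        length = len(t)
        ok = False
        for _ in range(max_attempts):
            ci = int(rng.choice(len(genome.chroms), p=probs))
            chrom = genome.chroms[ci]
            span = genome.lengths[ci] - length
            if span < 0:
                continue
            start = int(rng.integers(0, span + 1))
            cand = Region(chrom, start, start + length)
            if exm.any_overlap(cand):
                continue
            placed.append(cand)
            ok = True
            break
        if not ok:
            raise PlacementError(
                f"could not place a region of length {length} bp "
                f"after {max_attempts} attempts"
            )
    return RegionSet(placed, label="shuffled")


@dataclass(frozen=True)
class GeneModel:
    """Minimal gene annotation: symbol, strand, TSS, optional exon structure."""

    symbol: str
    chrom: str
    strand: str
    tss: int
    exons: tuple[Region, ...] | None = None

    def __post_init__(self) -> None:
        if self.strand not in ("+", "-"):
            raise ValueError(f"strand must be + or -, got {self.strand!r}")
        if self.exons is not None:
            ex = sorted(self.exons, key=lambda r: r.start)
            for a, b in zip(ex, ex[1:]):
                if a.end > b.start:
                    raise ValueError(f"overlapping exons in {self.symbol}")
            object.__setattr__(self, "exons", tuple(ex))

    @property
    def body(self) -> Region | None:
        if not self.exons:
            return None
        return Region(
            self.chrom, self.exons[0].start, self.exons[-1].end, self.symbol
        )


@dataclass(frozen=True)
class AnnotationResult:
    """Nearest-gene call for one region."""

    gene: str
    distance_to_tss: int
    location: str


def _signed_tss_distance(region: Region, gene: GeneModel) -> int:
    """Signed bp from the TSS to the nearest region boundary.

    0 if the region contains the TSS; negative means the region lies
    upstream of the TSS on the gene's strand.
    """
    if region.start <= gene.tss < region.end:
        return 0
    if region.start > gene.tss:
        genomic = region.start - gene.tss
    else:
        genomic = (region.end - 1) - gene.tss  # last covered base
    return genomic if gene.strand == "+" else -genomic


def _structural_location(region: Region, gene: GeneModel) -> str:
    """Exon/Intron 'i of n' by region midpoint, or Distal Intergenic."""
    body = gene.body
    mid = region.midpoint
    if body is None or not (body.start <= mid < body.end):
        return "Distal Intergenic"
    exons = gene.exons
    assert exons is not None
    n_ex = len(exons)
    starts = [e.start for e in exons]
    k = bisect_right(starts, mid) - 1  # genomic exon index containing/preceding mid
    if mid < exons[k].end:  # inside exon k
        num = k + 1 if gene.strand == "+" else n_ex - k
        return f"exon {num} of {n_ex}"
    n_in = n_ex - 1
    num = k + 1 if gene.strand == "+" else n_in - k
    return f"intron {num} of {n_in}"


def annotate_nearest_tss(
    region: Region, genes: Sequence[GeneModel]
) -> AnnotationResult:
    """Nearest gene by |signed TSS distance|, with a location category.

    The winner is the gene minimising the absolute distance from its TSS to
    the nearest region boundary; ties break on smaller |distance| then
    lexicographic symbol.  The location is ``Promoter`` when the region
    overlaps the TSS +-1000 bp window, else exon/intron (midpoint rule,
    requires exon structure), else ``Distal Intergenic``.
    """
    if not genes:
        raise ValueError("gene list is empty")
    same_chrom = [g for g in genes if g.chrom == region.chrom]
    if not same_chrom:
        raise ValueError(
            f"no genes on chromosome {region.chrom!r} to annotate against"
        )
    best = min(
        same_chrom,
        key=lambda g: (abs(_signed_tss_distance(region, g)), g.symbol),
    )
    dist = _signed_tss_distance(region, best)
    win_lo = best.tss - PROMOTER_WINDOW
    win_hi = best.tss + PROMOTER_WINDOW + 1  # half-open, window inclusive
    if max(region.start, win_lo) < min(region.end, win_hi):
        location = "Promoter"
    else:
        location = _structural_location(region, best)
    return AnnotationResult(best.symbol, dist, location)


class CoverageTrack:
    """A piecewise-constant non-negative signal (bedGraph semantics).

    Stores per-chromosome sorted, non-overlapping (starts, ends, values)
    arrays; bases not covered by any interval have value 0.
    """

    def __init__(
        self,
        name: str,
        intervals: dict[str, tuple[np.ndarray, np.ndarray, np.ndarray]],
    ) -> None:
        self.name = name
        self.intervals = {}
        for chrom, (s, e, v) in intervals.items():
            s = np.asarray(s, dtype=np.int64)
            e = np.asarray(e, dtype=np.int64)
            v = np.asarray(v, dtype=np.float64)
            if np.any(v < 0):
                raise ValueError(f"negative coverage value in track {name!r}")
            order = np.argsort(s, kind="stable")
            self.intervals[chrom] = (s[order], e[order], v[order])

    def region_sum(self, region: Region) -> float:
        """Base-pair-weighted coverage sum over ``region``:
        sum of value x overlapped-bases for every intersecting interval."""
        arr = self.intervals.get(region.chrom)
        if arr is None:
            return 0.0
        starts, ends, values = arr
        lo = int(np.searchsorted(ends, region.start, side="right"))
        hi = int(np.searchsorted(starts, region.end, side="left"))
        if lo >= hi:
            return 0.0
        s = np.maximum(starts[lo:hi], region.start)
        e = np.minimum(ends[lo:hi], region.end)
        w = np.clip(e - s, 0, None)
        return float(np.dot(w, values[lo:hi]))
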