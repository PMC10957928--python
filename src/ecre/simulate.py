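"""Synthetic genomes, track libraries and differential tables with known truth.

Every generator is a pure function of a :class:`SimulationConfig`: the
random substream of each generator is derived by stable hashing of
(seed, generator name), so adding a generator never perturbs the output of
the others and reruns are byte-identical.

The simulation emulates the shape of the real inputs — planted enhancers
standing in for validated enhancer coordinates, peak tracks that cover a
planted enhancer with a stated foreground probability against a Poisson
background, coverage tracks with a mean gain over enhancers, paired
differential-region tables with a known same-sign consensus, and a gene
annotation in which each enhancer's nearest gene is known by construction.
It makes no attempt at sequence content, fragment-size structure or
read-level noise.
"""

from __future__ import annotations

import json
import zlib
from dataclasses import asdict, dataclass, field

import numpy as np

from .discovery import DEGRecord, MarkerList, SignedRegion
from .intervals import CoverageTrack, GenomeTable, GeneModel, Region, RegionSet

__all__ = [
    "SimulationConfig",
    "TrackGroundTruth",
    "make_genome",
    "simulate_enhancers",
    "simulate_tracks",
    "simulate_coverage",
    "simulate_dar_tables",
    "simulate_annotation",
]


@dataclass(frozen=True)
class SimulationConfig:
    """Study conditions of the synthetic benchmark.

    Defaults follow the parameter-recovery design: 500 planted enhancers
    on a 50 Mb two-chromosome genome, 20 informative peak tracks covering
    each enhancer with probability 0.9 against a 0.05/kb background, 20
    pure-noise tracks, and 2 coverage tracks with a five-fold mean gain
    over enhancers.
    """

    seed: int = 0
    n_chrom: int = 2
    chrom_length: int = 25_000_000
    n_pos: int = 500
    length_range: tuple[int, int] = (500, 2000)
    n_informative: int = 20
    n_noise: int = 20
    p_fg: float = 0.9
    p_bg: float = 0.05
    coverage_gain: float = 5.0
    n_coverage: int = 2
    n_genes: int = 1000
    marker_fraction: float = 0.25
    n_dar: int = 100
    dar_flip_fraction: float = 0.2
    dar_orphan_fraction: float = 0.2

    def __post_init__(self) -> None:
        if self.length_range[0] < 1 or self.length_range[0] > self.length_range[1]:
            raise ValueError("length_range must satisfy 1 <= min <= max")
        for name in ("n_chrom", "chrom_length", "n_pos", "n_informative",
                     "n_noise", "n_coverage", "n_genes", "n_dar"):
            if getattr(self, name) < 0:
                raise ValueError(f"{name} must be >= 0")
        if not 0 <= self.p_bg <= self.p_fg <= 1:
            raise ValueError("need 0 <= p_bg <= p_fg <= 1")
        if self.coverage_gain < 1:
            raise ValueError("coverage_gain must be >= 1")

    def rng(self, generator_name: str) -> np.random.Generator:
        """Substream for one generator: hash of (seed, name)."""
        key = zlib.crc32(generator_name.encode())
        return np.random.default_rng(np.random.SeedSequence([self.seed, key]))

    def to_json(self) -> str:
        return json.dumps(asdict(self), sort_keys=True)


@dataclass(frozen=True)
class TrackGroundTruth:
    """What a simulated track knows about itself."""

    name: str
    informative: bool
    p_fg: float
    p_bg: float

    def __post_init__(self) -> None:
        if not 0 <= self.p_bg <= self.p_fg <= 1:
            raise ValueError("need 0 <= p_bg <= p_fg <= 1")
        if not self.informative and self.p_fg != self.p_bg:
            raise ValueError("noise tracks must have p_fg == p_bg")


def make_genome(cfg: SimulationConfig) -> GenomeTable:
    """``n_chrom`` chromosomes of equal configured length."""
    if cfg.n_chrom < 1:
        raise ValueError("need at least one chromosome")
    return GenomeTable(
        tuple(f"chr{i + 1}" for i in range(cfg.n_chrom)),
        tuple([cfg.chrom_length] * cfg.n_chrom),
    )


def simulate_enhancers(cfg: SimulationConfig, genome: GenomeTable) -> RegionSet:
    """Plant ``n_pos`` non-overlapping enhancers, lengths uniform in range."""
    rng = cfg.rng("enhancers")
    lo, hi = cfg.length_range
    if cfg.n_pos == 0:
        return RegionSet(label="enhancers")
    if cfg.n_pos * hi > genome.total_length:
        raise ValueError("genome too small for the requested enhancers")
    lengths = rng.integers(lo, hi + 1, size=cfg.n_pos)
    probs = np.asarray(genome.lengths, dtype=float) / genome.total_length
    placed = RegionSet(label="enhancers")
    regions: list[Region] = []
    for k, length in enumerate(lengths.tolist()):
        for _ in range(10_000):
            ci = int(rng.choice(cfg.n_chrom, p=probs))
            span = genome.lengths[ci] - length
            start = int(rng.integers(0, span + 1))
            cand = Region(genome.chroms[ci], start, start + length, f"enh{k}")
            if not placed.any_overlap(cand):
                regions.append(cand)
                placed = RegionSet(regions, label="enhancers")
                break
        else:
            raise RuntimeError("could not place an enhancer without overlap")
    return placed


def _background_peaks(
    rng: np.random.Generator,
    genome: GenomeTable,
    enhancers: RegionSet,
    p_bg: float,
    peak_len: tuple[int, int] = (300, 800),
) -> list[Region]:
    """Poisson-like background: each 1 kb window away from any enhancer
    carries a peak with probability ``p_bg``."""
    out: list[Region] = []
    for chrom, clen in zip(genome.chroms, genome.lengths):
        n_win = clen // 1000
        hits = np.flatnonzero(rng.random(n_win) < p_bg)
        lens = rng.integers(peak_len[0], peak_len[1] + 1, size=len(hits))
        for w, L in zip(hits.tolist(), lens.tolist()):
            start = w * 1000
            end = min(start + int(L), clen)
            if end <= start:
                continue
            cand = Region(chrom, start, end)
            if not enhancers.any_overlap(cand):
                out.append(cand)
    return out


def simulate_tracks(
    cfg: SimulationConfig, genome: GenomeTable, enhancers: RegionSet
) -> tuple[dict[str, RegionSet], list[TrackGroundTruth]]:
    """Peak-track library with known per-track informativeness.

    Informative tracks cover each enhancer with probability ``p_fg``
    (a peak centred on the enhancer with +-200 bp jitter); noise tracks
    do so at the background rate ``p_bg``.  Both carry background peaks
    in enhancer-free 1 kb windows at ``p_bg`` per window, so an
    enhancer's overlap probability is exactly the track's foreground
    rate.
    """
    tracks: dict[str, RegionSet] = {}
    truths: list[TrackGroundTruth] = []
    specs = [(f"informative_{i:02d}", cfg.p_fg, True) for i in range(cfg.n_informative)]
    specs += [(f"noise_{i:02d}", cfg.p_bg, False) for i in range(cfg.n_noise)]
    for name, p_enh, informative in specs:
        rng = cfg.rng(f"track:{name}")
        peaks: list[Region] = []
        for enh in enhancers:
            if rng.random() >= p_enh:
                continue
            jitter = int(rng.integers(-200, 201))
            half = max(len(enh) // 2, 150)
            mid = enh.midpoint + jitter
            start = max(mid - half, 0)
            end = min(mid + half, genome.length_of(enh.chrom))
            cand = Region(enh.chrom, start, end)
            # jitter never exceeds half-width, so the peak still overlaps
            peaks.append(cand)
        peaks.extend(_background_peaks(rng, genome, enhancers, cfg.p_bg))
        tracks[name] = RegionSet(peaks, label=name)
        truths.append(TrackGroundTruth(name, informative, p_enh if informative else cfg.p_bg, cfg.p_bg))
    return tracks, truths


def simulate_coverage(
    cfg: SimulationConfig,
    genome: GenomeTable,
    enhancers: RegionSet,
    name: str = "coverage_00",
    bin_size: int = 200,
) -> CoverageTrack:
    """Piecewise-constant coverage, mean ``coverage_gain``-fold over enhancers.

    Background bins draw Gamma(4, 1/4) values (mean 1); bins overlapping a
    planted enhancer are scaled by the gain.
    """
    rng = cfg.rng(f"coverage:{name}")
    intervals = {}
    for chrom, clen in zip(genome.chroms, genome.lengths):
        n_bin = (clen + bin_size - 1) // bin_size
        starts = np.arange(n_bin, dtype=np.int64) * bin_size
        ends = np.minimum(starts + bin_size, clen)
        values = rng.gamma(4.0, 0.25, size=n_bin)
        idx = enhancers.by_chrom().get(chrom)
        if idx is not None:
            enh_starts, enh_ends = idx
            for s, e in zip(enh_starts.tolist(), enh_ends.tolist()):
                b0 = s // bin_size
                b1 = (e - 1) // bin_size + 1
                values[b0:b1] *= cfg.coverage_gain
        intervals[chrom] = (starts, ends, values)
    return CoverageTrack(name, intervals)


def simulate_dar_tables(
    cfg: SimulationConfig, genome: GenomeTable
) -> tuple[list[SignedRegion], list[SignedRegion], set[str]]:
    """Two differential-region tables with a planted consensus.

    Primary rows split into three planted classes: confirmed (a confirming
    row overlaps with the same sign), flipped (overlapping row of opposite
    sign) and orphan (no overlapping row).  Returns (primary, confirming,
    ids of the true consensus) where ids are display region ids.
    """
    rng = cfg.rng("dars")
    n = cfg.n_dar
    n_flip = int(round(n * cfg.dar_flip_fraction))
    n_orphan = int(round(n * cfg.dar_orphan_fraction))
    n_ok = n - n_flip - n_orphan
    if n_ok < 0:
        raise ValueError("flip and orphan fractions exceed 1")
    # lay DARs on a fixed grid so rows never collide with each other
    spacing = genome.lengths[0] // max(n, 1)
    if spacing < 3000:
        raise ValueError("genome too small for the requested DAR count")
    chrom = genome.chroms[0]
    primary: list[SignedRegion] = []
    confirming: list[SignedRegion] = []
    truth: set[str] = set()
    classes = ["ok"] * n_ok + ["flip"] * n_flip + ["orphan"] * n_orphan
    rng.shuffle(classes)
    for i, cls in enumerate(classes):
        start = i * spacing + 500
        length = int(rng.integers(400, 1200))
        region = Region(chrom, start, start + length)
        direction = "up" if rng.random() < 0.5 else "down"
        sign = 1.0 if direction == "up" else -1.0
        logfc = sign * float(rng.uniform(0.5, 5.0))
        p = float(rng.uniform(1e-8, 1e-3))
        row = SignedRegion(region, direction, logfc, p, min(p * 5, 1.0))
        primary.append(row)
        if cls == "orphan":
            continue
        flip = cls == "flip"
        c_dir = ("down" if direction == "up" else "up") if flip else direction
        c_sign = 1.0 if c_dir == "up" else -1.0
        shift = int(rng.integers(-200, 201))
        c_start = max(start + shift, 0)
        c_region = Region(chrom, c_start, c_start + int(rng.integers(400, 1200)))
        cp = float(rng.uniform(1e-8, 1e-3))
        confirming.append(
            SignedRegion(c_region, c_dir, c_sign * float(rng.uniform(0.5, 5.0)), cp, min(cp * 5, 1.0))
        )
        if not flip:
            truth.add(region.id)
    return primary, confirming, truth


@dataclass(frozen=True)
class AnnotationTruth:
    """Ground truth of the simulated annotation."""

    genes: tuple[GeneModel, ...]
    markers: MarkerList
    degs: tuple[DEGRecord, ...]
    nearest_gene_of: dict[str, str] = field(hash=False, default_factory=dict)


def simulate_annotation(
    cfg: SimulationConfig, genome: GenomeTable, enhancers: RegionSet
) -> AnnotationTruth:
    """Genes placed so each enhancer's nearest gene is known by construction.

    One gene is anchored 2–20 kb from each of the first ``n_pos`` enhancers
    (TSS offset from the enhancer edge); remaining genes land uniformly at
    random, and the per-enhancer nearest gene is recorded by a brute-force
    scan over the realised TSS layout.  ``marker_fraction`` of genes
    are flagged as cluster markers; the DEG table draws marker log2FC from
    N(3, 1) (all significant) and non-marker log2FC from N(0, 1) with 10%
    significance.
    """
    if cfg.n_genes < 1:
        raise ValueError("need n_genes >= 1")
    rng = cfg.rng("annotation")
    genes: list[GeneModel] = []
    for k, enh in enumerate(enhancers):
        if k >= cfg.n_genes:
            break
        offset = int(rng.integers(2000, 20_001))
        strand = "+" if rng.random() < 0.5 else "-"
        clen = genome.length_of(enh.chrom)
        tss = min(enh.end + offset, clen - 1)
        genes.append(GeneModel(f"Gene{k:04d}", enh.chrom, strand, tss))
    # filler genes at uniform random positions; the nearest-gene truth below
    # is recomputed from the realised TSS layout, so no clearance is needed
    for k in range(len(genes), cfg.n_genes):
        ci = int(rng.integers(0, len(genome.chroms)))
        chrom = genome.chroms[ci]
        tss = int(rng.integers(0, genome.length_of(chrom)))
        strand = "+" if rng.random() < 0.5 else "-"
        genes.append(GeneModel(f"Gene{k:04d}", chrom, strand, tss))
    # truth-nearest gene per enhancer: plain brute-force scan over the
    # known TSS positions (independent of annotate_nearest_tss)
    nearest: dict[str, str] = {}
    for enh in enhancers:
        best_sym, best_abs = None, None
        for g in genes:
            if g.chrom != enh.chrom:
                continue
            if enh.start <= g.tss < enh.end:
                d = 0
            elif enh.start > g.tss:
                d = enh.start - g.tss
            else:
                d = g.tss - (enh.end - 1)
            if best_abs is None or (d, g.symbol) < (best_abs, best_sym):
                best_sym, best_abs = g.symbol, d
        nearest[enh.id] = best_sym
    n_markers = int(round(cfg.marker_fraction * cfg.n_genes))
    marker_idx = rng.choice(cfg.n_genes, size=n_markers, replace=False)
    marker_syms = {genes[i].symbol for i in marker_idx.tolist()}
    degs: list[DEGRecord] = []
    for g in genes:
        if g.symbol in marker_syms:
            degs.append(DEGRecord(g.symbol, float(rng.normal(3.0, 1.0)), True))
        else:
            degs.append(
                DEGRecord(g.symbol, float(rng.normal(0.0, 1.0)), bool(rng.random() < 0.1))
            )
    return AnnotationTruth(
        genes=tuple(genes),
        markers=MarkerList(frozenset(marker_syms), label="simulated-cluster"),
        degs=tuple(degs),
        nearest_gene_of=nearest,
    )
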