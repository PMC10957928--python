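import numpy as np
import pytest
from hypothesis import settings

from ecre.intervals import GenomeTable, Region, RegionSet

settings.register_profile("ci", deadline=None, derandomize=True, max_examples=50)
settings.load_profile("ci")


@pytest.fixture
def rng():
    return np.random.default_rng(20240321)


@pytest.fixture
def toy_genome():
    """A 10 kb single-chromosome genome for base-level oracle tests."""
    return GenomeTable(("chr1",), (10_000,))


def random_region_set(rng, n, genome_len=10_000, max_len=300, chrom="chr1"):
    starts = rng.integers(0, genome_len - max_len, size=n)
    lengths = rng.integers(1, max_len, size=n)
    return RegionSet(
        [Region(chrom, int(s), int(s + l)) for s, l in zip(starts, lengths)]
    )


def base_mask(regions, genome_len=10_000, chrom="chr1"):
    """Per-base boolean occupancy — the brute-force interval oracle."""
    mask = np.zeros(genome_len, dtype=bool)
    for r in regions:
        if r.chrom == chrom:
            mask[r.start : r.end] = True
    return mask


def mask_to_regions(mask, chrom="chr1"):
    """Maximal runs of True bases as a RegionSet."""
    padded = np.concatenate([[False], mask, [False]])
    diff = np.diff(padded.astype(int))
    starts = np.flatnonzero(diff == 1)
    ends = np.flatnonzero(diff == -1)
    return RegionSet([Region(chrom, int(s), int(e)) for s, e in zip(starts, ends)])
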