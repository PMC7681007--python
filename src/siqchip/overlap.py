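"""Hypergeometric overlap statistics for binned genomic coverage sets.

Two coverage sets (e.g. peaks called from two antibodies) are compared on
a common grid of fixed-width bins. With a universe of N bins of which the
first set covers |A| and the second |B|, the number of co-covered bins
under the null of independent placement follows the hypergeometric
distribution (drawing |B| bins from N with |A| marked), so both a
fold-enrichment over expectation (observed / (|A||B|/N)) and an
upper-tail p-value are exact. Binning makes the urn model literal, at the
resolution the tracks themselves use.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Iterable, Mapping, Optional

import numpy as np
from scipy.stats import hypergeom

__all__ = ["CoverageSet", "OverlapResult", "overlap_stats", "read_chrom_sizes"]


@dataclass(frozen=True)
class CoverageSet:
    """A set of covered bins on a binned genome.

    ``bins`` holds (chrom, bin-index) pairs; ``universe`` is the total
    number of bins in the genome the set lives on. Construction from
    intervals marks every bin an interval touches, so self-overlapping
    interval lists collapse to the same set.
    """

    bins: frozenset
    universe: int
    bin_width: int

    def __post_init__(self) -> None:
        if self.universe <= 0:
            raise ValueError("universe must hold at least one bin")
        if len(self.bins) > self.universe:
            raise ValueError("coverage exceeds the universe")

    def __len__(self) -> int:
        return len(self.bins)

    @classmethod
    def from_intervals(cls, intervals: Iterable[tuple], bin_width: int,
                       chrom_sizes: Mapping[str, int]) -> "CoverageSet":
        """Bin 0-based half-open intervals on a genome of known sizes."""
        if bin_width <= 0:
            raise ValueError("bin_width must be positive")
        n_bins = {c: -(-size // bin_width) for c, size in chrom_sizes.items()}
        universe = sum(n_bins.values())
        bins = set()
        for chrom, start, end in intervals:
            if chrom not in n_bins:
                raise ValueError(f"interval on unknown chromosome {chrom!r}")
            if not (0 <= start < end):
                raise ValueError(f"bad interval {chrom}:{start}-{end}")
            last = min(-(-end // bin_width), n_bins[chrom])
            for b in range(start // bin_width, last):
                bins.add((chrom, b))
        return cls(bins=frozenset(bins), universe=universe, bin_width=bin_width)

    @classmethod
    def from_bed(cls, path, bin_width: int,
                 chrom_sizes: Mapping[str, int]) -> "CoverageSet":
        intervals = []
        with open(path) as fh:
            for line in fh:
                line = line.strip()
                if not line or line.startswith(("#", "track", "browser")):
                    continue
                fields = line.split("\t") if "\t" in line else line.split()
                intervals.append((fields[0], int(fields[1]), int(fields[2])))
        return cls.from_intervals(intervals, bin_width, chrom_sizes)


@dataclass
class OverlapResult:
    observed: int
    expected: float
    fold: float
    p_value: float


def overlap_stats(a: CoverageSet, b: CoverageSet) -> OverlapResult:
    """Fold enrichment and hypergeometric significance of bin co-coverage.

    observed = |A intersect B|; expected = |A||B|/N; p is the upper tail
    P(X >= observed) for X ~ Hypergeometric(N, |A|, |B|). Symmetric in the
    two sets. An empty set leaves the fold undefined (NaN) with p = 1.
    """
    if a.universe != b.universe or a.bin_width != b.bin_width:
        raise ValueError("coverage sets live on different binned universes")
    n = a.universe
    observed = len(a.bins & b.bins)
    if len(a) == 0 or len(b) == 0:
        return OverlapResult(observed=0, expected=0.0, fold=float("nan"),
                             p_value=1.0)
    expected = len(a) * len(b) / n
    p = float(hypergeom.sf(observed - 1, n, len(a), len(b)))
    return OverlapResult(observed=observed, expected=expected,
                         fold=observed / expected, p_value=min(p, 1.0))


def read_chrom_sizes(path) -> dict:
    """Read a two-column chrom<TAB>size file (UCSC chrom.sizes layout)."""
    sizes = {}
    with open(path) as fh:
        for line in fh:
            line = line.strip()
            if not line:
                continue
            chrom, size = line.split()[:2]
            sizes[chrom] = int(size)
    return sizes
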