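"""Shared fixtures: per-base boolean-array oracle and small toy inputs.

The oracle materializes every chromosome as a boolean base mask, so
cardinalities and intersections are literal base counts — an independent
check on the sweep-line interval algebra, usable for genomes up to a few
hundred kilobases.
"""

from __future__ import annotations

import math

import numpy as np
import pytest

from coloc import Genome, GenomicInterval, IntervalSet


class BitmapOracle:
    """Per-base truth for interval sets on a small genome."""

    def __init__(self, genome: Genome):
        self.genome = genome
        self.masks: dict[str, np.ndarray] = {}

    @staticmethod
    def mask_of(s: IntervalSet, genome: Genome) -> dict[str, np.ndarray]:
        masks = {c: np.zeros(n, dtype=bool) for c, n in genome.sizes.items()}
        for iv in s.intervals:
            masks[iv.chrom][iv.start : iv.end] = True
        return masks

    def cardinality(self, s: IntervalSet) -> int:
        return int(sum(m.sum() for m in self.mask_of(s, self.genome).values()))

    def intersection_cardinality(self, a: IntervalSet, b: IntervalSet) -> int:
        ma = self.mask_of(a, self.genome)
        mb = self.mask_of(b, self.genome)
        return int(sum((ma[c] & mb[c]).sum() for c in self.genome.sizes))

    def counts(self, a: IntervalSet, b: IntervalSet) -> tuple[int, int, int, int]:
        return (
            self.cardinality(a),
            self.cardinality(b),
            self.intersection_cardinality(a, b),
            self.genome.total,
        )

    def metrics(self, a: IntervalSet, b: IntervalSet) -> dict[str, float]:
        """Six scores recomputed from literal base counts (plain arithmetic,
        no shared code with the library's metric functions)."""
        na, nb, nab, g = self.counts(a, b)
        out: dict[str, float] = {}
        if na == 0 or nb == 0:
            out.update(c=0.0, j=0.0, sd=0.0, ss=0.0, pmi=math.nan, npmi=math.nan)
            return out
        out["c"] = nab / math.sqrt(na * nb)
        out["j"] = nab / (na + nb - nab)
        out["sd"] = 2 * nab / (na + nb)
        out["ss"] = nab / min(na, nb)
        if nab == 0:
            out["pmi"] = -math.inf
            out["npmi"] = -1.0
        elif nab == g:
            out["pmi"] = 0.0
            out["npmi"] = 1.0
        else:
            out["pmi"] = math.log((nab / g) / ((na / g) * (nb / g)))
            out["npmi"] = math.log((na / g) * (nb / g)) / math.log(nab / g) - 1.0
        return out


def random_raw_set(
    rng: np.random.Generator, genome: Genome, n_max: int = 40, name: str = "S"
) -> IntervalSet:
    """Random, possibly overlapping raw intervals (exercises merging)."""
    n = int(rng.integers(0, n_max + 1))
    intervals = []
    chroms = list(genome.sizes)
    for _ in range(n):
        chrom = chroms[int(rng.integers(0, len(chroms)))]
        length = genome.sizes[chrom]
        start = int(rng.integers(0, length))
        width = int(rng.integers(1, max(2, length // 8)))
        intervals.append(GenomicInterval(chrom, start, min(start + width, length)))
    return IntervalSet(name, tuple(intervals), canonical=False)


@pytest.fixture
def toy_genome() -> Genome:
    return Genome({"chr1": 1000})


@pytest.fixture
def two_chrom_genome() -> Genome:
    return Genome({"chr1": 700, "chr2": 300})


@pytest.fixture
def oracle(two_chrom_genome) -> BitmapOracle:
    return BitmapOracle(two_chrom_genome)
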