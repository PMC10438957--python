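"""Synthetic BED / chrom.sizes fixtures with controlled overlap structure.

Three generators cover the study designs the statistics are tested on:

* :func:`generate_pair` — two interval sets where a *planted* fraction of
  set A's bases is re-used by set B (the rest of B is placed in space not
  covered by A), so the realized shared fraction is exact by construction.
* :func:`generate_independent_pair` — a deterministic layout achieving
  |A∩B| = |A|·|B| / G *exactly*, the base-coverage analogue of statistical
  independence, so PMI = 0 and NPMI = 0 to machine precision.
* :func:`generate_biased_database` — a query-plus-database scenario with
  one truly collocated target (few peaks, large shared base fraction) and
  many independent targets whose peak counts span two orders of magnitude;
  the coverage-heavy independent targets win a 1-nt threshold-and-count
  ranking while the planted target wins the combined-Z scan, reproducing
  the known peak-count bias of the threshold-and-count approach.

All placement is deterministic per seed.  Intervals within one generated
set never overlap or abut (gaps of at least one base are enforced), so the
canonical interval count equals the requested count.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from pathlib import Path
from typing import Sequence

import numpy as np

from .intervals import (
    Genome,
    GenomicInterval,
    IntervalSet,
    cardinality,
    intersect,
    merge,
    write_bed,
)

__all__ = [
    "LengthSampler",
    "FixtureSpec",
    "GeneratedPair",
    "BiasedDatabase",
    "random_interval_set",
    "generate_pair",
    "generate_independent_pair",
    "generate_biased_database",
    "demo_scan_scenario",
]


@dataclass(frozen=True)
class LengthSampler:
    """Interval-length distribution: 'fixed', 'uniform' (lo..hi inclusive)
    or 'geometric' (mean length, minimum 1 base)."""

    kind: str = "fixed"
    length: int = 1000
    low: int = 500
    high: int = 2000
    mean: float = 1000.0

    def sample(self, rng: np.random.Generator, n: int) -> np.ndarray:
        if self.kind == "fixed":
            return np.full(n, self.length, dtype=np.int64)
        if self.kind == "uniform":
            return rng.integers(self.low, self.high + 1, size=n, dtype=np.int64)
        if self.kind == "geometric":
            return rng.geometric(1.0 / self.mean, size=n).astype(np.int64)
        raise ValueError(f"unknown length sampler kind {self.kind!r}")


@dataclass(frozen=True)
class FixtureSpec:
    """Recipe for a pair of interval sets with a planted shared fraction."""

    genome: Genome
    n_intervals_a: int
    n_intervals_b: int
    length_sampler: LengthSampler = LengthSampler()
    planted_shared_fraction: float = 0.0
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_intervals_a < 1 or self.n_intervals_b < 1:
            raise ValueError("interval counts must be >= 1")
        if not 0.0 <= self.planted_shared_fraction <= 1.0:
            raise ValueError("planted_shared_fraction must be in [0, 1]")


@dataclass(frozen=True)
class GeneratedPair:
    a: IntervalSet
    b: IntervalSet
    genome: Genome
    realized_shared_fraction: float


# ---------------------------------------------------------------------------
# placement machinery

_Region = tuple[str, int, int]  # chrom, start, end (half-open)


def _genome_regions(g: Genome) -> list[_Region]:
    return [(chrom, 0, length) for chrom, length in sorted(g.sizes.items())]


def _complement(g: Genome, occupied: IntervalSet, pad: int = 1) -> list[_Region]:
    """Free regions of the genome, shrunk by ``pad`` bases around occupied
    blocks so newly placed intervals cannot abut existing ones."""
    blocks: dict[str, list[tuple[int, int]]] = {c: [] for c in g.sizes}
    for iv in merge(occupied).intervals:
        blocks[iv.chrom].append((iv.start, iv.end))
    regions: list[_Region] = []
    for chrom, length in sorted(g.sizes.items()):
        cursor = 0
        for s, e in blocks[chrom]:
            if s - pad > cursor:
                regions.append((chrom, cursor, s - pad))
            cursor = max(cursor, e + pad)
        if cursor < length:
            regions.append((chrom, cursor, length))
    return regions


def _place_lengths(
    rng: np.random.Generator, regions: list[_Region], lengths: Sequence[int]
) -> list[GenomicInterval]:
    """Place intervals of the given lengths into the free regions, without
    overlap and with >= 1-base gaps; a region holding an interval is split
    around it.  Regions are chosen with probability proportional to the
    number of admissible start positions.  Raises on infeasible packing.
    """
    free = list(regions)
    placed: list[GenomicInterval] = []
    for n_left, L in enumerate(sorted(lengths, reverse=True)):
        L = int(L)
        room = np.array([e - s - L + 1 for _, s, e in free], dtype=np.int64)
        ok = room > 0
        if not ok.any():
            raise ValueError(
                f"infeasible packing: no free region can hold a {L}-base "
                f"interval ({len(lengths) - n_left} interval(s) unplaced)"
            )
        weights = np.where(ok, room, 0).astype(float)
        ridx = int(rng.choice(len(free), p=weights / weights.sum()))
        chrom, rs, re_ = free.pop(ridx)
        start = int(rng.integers(rs, re_ - L + 1))
        placed.append(GenomicInterval(chrom, start, start + L))
        if start - 1 > rs:
            free.append((chrom, rs, start - 1))
        if start + L + 1 < re_:
            free.append((chrom, start + L + 1, re_))
    placed.sort()
    return placed


def random_interval_set(
    genome: Genome,
    n: int,
    length_sampler: LengthSampler,
    seed: int,
    name: str = "random",
) -> IntervalSet:
    """Uniformly place ``n`` non-overlapping, non-abutting intervals."""
    rng = np.random.default_rng(seed)
    lengths = length_sampler.sample(rng, n)
    placed = _place_lengths(rng, _genome_regions(genome), lengths)
    return IntervalSet(name=name, intervals=tuple(placed), canonical=True)


# ---------------------------------------------------------------------------
# generators


def generate_pair(spec: FixtureSpec) -> GeneratedPair:
    """Generate sets A and B where ``planted_shared_fraction`` of A's bases
    is also covered by B (exactly, by copying/trimming A intervals), and
    B's remaining intervals sit in space not covered by A."""
    rng = np.random.default_rng(spec.seed)
    lengths_a = spec.length_sampler.sample(rng, spec.n_intervals_a)
    a_intervals = _place_lengths(rng, _genome_regions(spec.genome), lengths_a)
    a = IntervalSet("A", tuple(a_intervals), canonical=True)
    card_a = cardinality(a)

    target_shared = int(round(spec.planted_shared_fraction * card_a))
    b_intervals: list[GenomicInterval] = []
    shared = 0
    if target_shared > 0:
        for idx in rng.permutation(len(a_intervals)):
            if shared >= target_shared or len(b_intervals) >= spec.n_intervals_b:
                break
            iv = a_intervals[int(idx)]
            take = min(len(iv), target_shared - shared)
            b_intervals.append(GenomicInterval(iv.chrom, iv.start, iv.start + take))
            shared += take

    n_rest = spec.n_intervals_b - len(b_intervals)
    if n_rest > 0:
        lengths_b = spec.length_sampler.sample(rng, n_rest)
        free = _complement(spec.genome, a)
        b_intervals.extend(_place_lengths(rng, free, lengths_b))
    b_intervals.sort()
    b = IntervalSet("B", tuple(b_intervals), canonical=True)
    realized = shared / card_a if card_a else 0.0
    return GeneratedPair(a=a, b=b, genome=spec.genome, realized_shared_fraction=realized)


def _linear_to_intervals(
    segments: Sequence[tuple[int, int]], genome: Genome
) -> list[GenomicInterval]:
    """Map half-open segments on the concatenated-genome line [0, G)
    (wrapping allowed) back to per-chromosome intervals."""
    total = genome.total
    chrom_bounds: list[tuple[str, int, int]] = []
    cursor = 0
    for chrom, length in sorted(genome.sizes.items()):
        chrom_bounds.append((chrom, cursor, cursor + length))
        cursor += length

    flat: list[tuple[int, int]] = []
    for s, e in segments:
        if e <= s:
            continue
        s_mod, e_mod = s % total, s % total + (e - s)
        if e_mod <= total:
            flat.append((s_mod, e_mod))
        else:  # wraps past the end of the line
            flat.append((s_mod, total))
            flat.append((0, e_mod - total))

    out: list[GenomicInterval] = []
    for s, e in flat:
        for chrom, cs, ce in chrom_bounds:
            lo, hi = max(s, cs), min(e, ce)
            if lo < hi:
                out.append(GenomicInterval(chrom, lo - cs, hi - cs))
    out.sort()
    return out


def generate_independent_pair(
    genome: Genome, card_a: int, card_b: int, seed: int = 0
) -> tuple[IntervalSet, IntervalSet]:
    """Deterministic pair with exactly |A∩B| = |A|·|B| / G shared bases,
    the base-coverage analogue of independence (PMI = NPMI = 0).

    Requires ``card_a * card_b`` to be divisible by the genome total, so
    the expected intersection is an integer; otherwise raises with the
    nearest feasible cardinalities suggested.  The layout is a contiguous
    block for A and a two-piece block for B, rotated along the
    concatenated genome by a seed-chosen offset.
    """
    g = genome.total
    if not 0 < card_a <= g or not 0 < card_b <= g:
        raise ValueError("cardinalities must be in (0, genome total]")
    if (card_a * card_b) % g != 0:
        step = g // math.gcd(card_a, g)
        lo = (card_b // step) * step
        suggestions = sorted({max(step, lo), min(g, lo + step)})
        raise ValueError(
            f"card_a*card_b = {card_a * card_b} is not divisible by G = {g}; "
            f"nearest feasible card_b for card_a={card_a}: {suggestions}"
        )
    k = (card_a * card_b) // g
    rng = np.random.default_rng(seed)
    off = int(rng.integers(0, g))
    a_segments = [(off, off + card_a)]
    b_segments = [(off, off + k), (off + card_a, off + card_a + (card_b - k))]
    a = merge(IntervalSet("A", tuple(_linear_to_intervals(a_segments, genome))))
    b = merge(IntervalSet("B", tuple(_linear_to_intervals(b_segments, genome))))
    assert cardinality(a) == card_a and cardinality(b) == card_b
    assert cardinality(intersect(a, b)) == k
    return a, b


@dataclass(frozen=True)
class BiasedDatabase:
    """Handle to an emitted query-vs-database scenario on disk."""

    manifest_path: Path
    collocated_label: str
    labels: tuple[str, ...]
    peak_counts: dict[str, int]


def generate_biased_database(
    genome: Genome,
    n_targets: int,
    query: IntervalSet,
    seed: int,
    outdir: str | Path,
    *,
    collocated_fraction: float = 0.4,
    min_peaks: int = 20,
    max_peaks: int = 5000,
    peak_length: int = 1000,
) -> BiasedDatabase:
    """Emit one truly collocated target plus independent targets with peak
    counts log-spaced across two orders of magnitude; write BEDs and a
    two-column manifest TSV.

    The collocated target copies ``collocated_fraction`` of the query's
    peaks verbatim (few peaks, deep overlap).  Independent targets are
    placed uniformly, ignoring the query; the largest ones blanket enough
    of the genome that nearly every query peak touches them by >= 1 nt.
    """
    if n_targets < 1:
        raise ValueError("n_targets must be >= 1")
    if len(query) == 0:
        raise ValueError("query set is empty")
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    rng = np.random.default_rng(seed)

    labels: list[str] = []
    counts: dict[str, int] = {}

    colloc_label = "planted_collocated"
    n_copy = max(1, int(round(collocated_fraction * len(query))))
    copy_idx = np.sort(rng.choice(len(query), size=n_copy, replace=False))
    colloc = IntervalSet(
        colloc_label,
        tuple(query.intervals[int(i)] for i in copy_idx),
        canonical=query.canonical,
    )
    write_bed(colloc, outdir / f"{colloc_label}.bed")
    labels.append(colloc_label)
    counts[colloc_label] = n_copy

    if n_targets > 1:
        n_ind = n_targets - 1
        if n_ind == 1:
            peak_ns = np.array([max_peaks])
        else:
            peak_ns = np.unique(
                np.geomspace(min_peaks, max_peaks, n_ind).round().astype(int)
            )
            while len(peak_ns) < n_ind:  # pad collisions from rounding
                peak_ns = np.append(peak_ns, peak_ns[-1] + 1)
        for i, n_peaks in enumerate(sorted(int(x) for x in peak_ns)):
            label = f"independent_{i:02d}_n{n_peaks}"
            t = random_interval_set(
                genome,
                n_peaks,
                LengthSampler("fixed", length=peak_length),
                seed=int(rng.integers(0, 2**31)),
                name=label,
            )
            write_bed(t, outdir / f"{label}.bed")
            labels.append(label)
            counts[label] = n_peaks

    manifest = outdir / "manifest.tsv"
    with open(manifest, "wt") as fh:
        for label in labels:
            fh.write(f"{label}\t{label}.bed\n")
    return BiasedDatabase(
        manifest_path=manifest,
        collocated_label=colloc_label,
        labels=tuple(labels),
        peak_counts=counts,
    )


def demo_scan_scenario(
    outdir: str | Path, seed: int
) -> tuple[Genome, IntervalSet, BiasedDatabase]:
    """The canonical peak-count-bias scenario at its default study size.

    A 10 Mb single-chromosome genome; a query of 500 non-overlapping 1 kb
    peaks; a 20-target database from :func:`generate_biased_database`
    (one planted collocated target copying 40% of the query's peaks, and
    19 independent targets whose 1 kb peak counts are log-spaced from 20
    to 5,000, the largest blanketing roughly half the genome).  Sized so
    the coverage-heavy target reliably tops a 1-nt threshold-and-count
    ranking while the planted target tops the combined-Z scan.
    """
    rng = np.random.default_rng(seed)
    genome = Genome({"chr1": 10_000_000})
    query = random_interval_set(
        genome, 500, LengthSampler("fixed", length=1000),
        seed=int(rng.integers(0, 2**31)), name="query",
    )
    db = generate_biased_database(
        genome, 20, query, seed=int(rng.integers(0, 2**31)), outdir=outdir
    )
    return genome, query, db
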