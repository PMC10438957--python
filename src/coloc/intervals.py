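"""Genomic interval sets, base-exact algebra, and BED / chrom.sizes I/O.

Coordinates follow the BED convention throughout: 0-based, half-open
``[start, end)``.  All cardinalities are counts of distinct genomic bases
after merging redundant coverage ("non-redundant bases"), which is the
quantity every collocation statistic is defined on.  Strand is ignored;
chromosome names are matched as exact strings (``chr1`` != ``1``).
"""

from __future__ import annotations

import gzip
import io
import logging
from dataclasses import dataclass
from pathlib import Path
from typing import Iterator, Mapping

import numpy as np

logger = logging.getLogger(__name__)

__all__ = [
    "GenomicInterval",
    "IntervalSet",
    "Genome",
    "OverlapSummary",
    "BedParseError",
    "read_bed",
    "read_chrom_sizes",
    "write_bed",
    "merge",
    "cardinality",
    "intersect",
    "summarize_overlap",
    "subsample",
]


class BedParseError(ValueError):
    """Raised for malformed BED or chrom.sizes input, naming the line."""


@dataclass(frozen=True, order=True)
class GenomicInterval:
    """A half-open genomic interval ``[start, end)`` on one chromosome."""

    chrom: str
    start: int
    end: int

    def __post_init__(self) -> None:
        if self.start < 0:
            raise ValueError(f"negative start: {self.chrom}:{self.start}-{self.end}")
        if self.end <= self.start:
            raise ValueError(
                f"zero- or negative-length interval: {self.chrom}:{self.start}-{self.end}"
            )

    def __len__(self) -> int:
        return self.end - self.start


@dataclass(frozen=True)
class Genome:
    """Chromosome-name -> length map; ``total`` is the background size G."""

    sizes: Mapping[str, int]

    def __post_init__(self) -> None:
        for chrom, length in self.sizes.items():
            if length <= 0:
                raise ValueError(f"non-positive length for {chrom}: {length}")
        object.__setattr__(self, "sizes", dict(self.sizes))

    @property
    def total(self) -> int:
        return sum(self.sizes.values())

    def __contains__(self, chrom: str) -> bool:
        return chrom in self.sizes

    def __getitem__(self, chrom: str) -> int:
        return self.sizes[chrom]


@dataclass(frozen=True)
class IntervalSet:
    """A named collection of genomic intervals.

    ``canonical`` is True once the set has been sorted and merged so that
    no two intervals on one chromosome overlap or abut; only canonical
    sets have interval counts that equal their block counts, but base
    cardinality is well defined either way (merging happens on demand).
    """

    name: str
    intervals: tuple[GenomicInterval, ...]
    canonical: bool = False

    def __post_init__(self) -> None:
        object.__setattr__(self, "intervals", tuple(self.intervals))

    def __len__(self) -> int:
        return len(self.intervals)

    def __iter__(self) -> Iterator[GenomicInterval]:
        return iter(self.intervals)

    @property
    def chroms(self) -> list[str]:
        return sorted({iv.chrom for iv in self.intervals})

    # convenience method aliases for the module-level operations
    def merge(self) -> "IntervalSet":
        return merge(self)

    def cardinality(self) -> int:
        return cardinality(self)

    def subsample(self, fraction: float, seed: int) -> "IntervalSet":
        return subsample(self, fraction, seed)


@dataclass(frozen=True)
class OverlapSummary:
    """The base-count quadruple (|A|, |B|, |A∩B|, G) every metric derives from."""

    card_a: int
    card_b: int
    card_ab: int
    genome_size: int
    name_a: str = "A"
    name_b: str = "B"

    def __post_init__(self) -> None:
        if min(self.card_a, self.card_b, self.card_ab, self.genome_size) < 0:
            raise ValueError("negative base count")
        if self.card_ab > min(self.card_a, self.card_b):
            raise ValueError(
                f"|A∩B|={self.card_ab} exceeds min(|A|,|B|)="
                f"{min(self.card_a, self.card_b)}"
            )
        if max(self.card_a, self.card_b) > self.genome_size:
            raise ValueError("set cardinality exceeds genome size")

    @property
    def card_union(self) -> int:
        return self.card_a + self.card_b - self.card_ab


# ---------------------------------------------------------------------------
# parsing


def _open_text(path: str | Path) -> io.TextIOBase:
    path = Path(path)
    if path.suffix == ".gz":
        return io.TextIOWrapper(gzip.open(path, "rb"))
    return open(path, "rt")


_SKIP_PREFIXES = ("#", "track", "browser")


def read_bed(path: str | Path, name: str | None = None) -> IntervalSet:
    """Parse a BED3+ file (optionally gzip-compressed) into an IntervalSet.

    Only the first three columns (chrom, start, end) are used; extra
    columns are discarded.  Comment/track/browser lines are skipped.
    Input order is preserved and the returned set is *not* canonical.
    """
    path = Path(path)
    if name is None:
        name = path.name
        for suffix in (".gz", ".bed"):
            if name.endswith(suffix):
                name = name[: -len(suffix)]
    intervals: list[GenomicInterval] = []
    with _open_text(path) as fh:
        for lineno, line in enumerate(fh, start=1):
            line = line.strip()
            if not line or line.startswith(_SKIP_PREFIXES):
                continue
            fields = line.split()
            if len(fields) < 3:
                raise BedParseError(f"{path}:{lineno}: expected >=3 columns")
            chrom, start_s, end_s = fields[0], fields[1], fields[2]
            try:
                start, end = int(start_s), int(end_s)
            except ValueError as exc:
                raise BedParseError(f"{path}:{lineno}: non-integer coordinate") from exc
            try:
                intervals.append(GenomicInterval(chrom, start, end))
            except ValueError as exc:
                raise BedParseError(f"{path}:{lineno}: {exc}") from exc
    return IntervalSet(name=name, intervals=tuple(intervals), canonical=False)


def read_chrom_sizes(path: str | Path) -> Genome:
    """Parse a UCSC chrom.sizes file (two-column TSV: name, length)."""
    path = Path(path)
    sizes: dict[str, int] = {}
    with _open_text(path) as fh:
        for lineno, line in enumerate(fh, start=1):
            line = line.strip()
            if not line or line.startswith("#"):
                continue
            fields = line.split()
            if len(fields) < 2:
                raise BedParseError(f"{path}:{lineno}: expected 2 columns")
            chrom, length_s = fields[0], fields[1]
            try:
                length = int(length_s)
            except ValueError as exc:
                raise BedParseError(f"{path}:{lineno}: non-integer length") from exc
            if length <= 0:
                raise BedParseError(f"{path}:{lineno}: non-positive length for {chrom}")
            if chrom in sizes:
                raise BedParseError(f"{path}:{lineno}: duplicate chromosome {chrom}")
            sizes[chrom] = length
    return Genome(sizes=sizes)


def write_bed(s: IntervalSet, path: str | Path) -> None:
    """Write an interval set as BED3 (uncompressed, tab-separated)."""
    with open(path, "wt") as fh:
        for iv in s.intervals:
            fh.write(f"{iv.chrom}\t{iv.start}\t{iv.end}\n")


# ---------------------------------------------------------------------------
# algebra (numpy sweep-line on per-chromosome start/end arrays)


def _by_chrom(s: IntervalSet) -> dict[str, tuple[np.ndarray, np.ndarray]]:
    out: dict[str, tuple[list[int], list[int]]] = {}
    for iv in s.intervals:
        starts, ends = out.setdefault(iv.chrom, ([], []))
        starts.append(iv.start)
        ends.append(iv.end)
    return {
        chrom: (np.asarray(starts, dtype=np.int64), np.asarray(ends, dtype=np.int64))
        for chrom, (starts, ends) in out.items()
    }


def _merge_arrays(starts: np.ndarray, ends: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    """Merge overlapping or abutting intervals; arrays need not be sorted."""
    order = np.argsort(starts, kind="stable")
    s, e = starts[order], ends[order]
    running_max = np.maximum.accumulate(e)
    # a new block starts strictly beyond everything seen so far (abutting merges)
    new_block = np.empty(len(s), dtype=bool)
    new_block[0] = True
    new_block[1:] = s[1:] > running_max[:-1]
    block_idx = np.flatnonzero(new_block)
    block_starts = s[block_idx]
    block_last = np.append(block_idx[1:] - 1, len(s) - 1)
    block_ends = running_max[block_last]
    return block_starts, block_ends


def merge(s: IntervalSet) -> IntervalSet:
    """Return the canonical (sorted, merged) form covering the same bases."""
    if s.canonical:
        return s
    merged: list[GenomicInterval] = []
    for chrom in sorted({iv.chrom for iv in s.intervals}):
        starts, ends = _by_chrom(s)[chrom]
        ms, me = _merge_arrays(starts, ends)
        merged.extend(
            GenomicInterval(chrom, int(a), int(b)) for a, b in zip(ms, me)
        )
    return IntervalSet(name=s.name, intervals=tuple(merged), canonical=True)


def cardinality(s: IntervalSet) -> int:
    """Total distinct bases covered by *s* (merges internally if needed)."""
    m = merge(s)
    return sum(iv.end - iv.start for iv in m.intervals)


def _intersect_arrays(
    sa: np.ndarray, ea: np.ndarray, sb: np.ndarray, eb: np.ndarray
) -> tuple[np.ndarray, np.ndarray]:
    """Intersection of two *canonical* interval arrays on one chromosome."""
    out_s: list[int] = []
    out_e: list[int] = []
    i = j = 0
    while i < len(sa) and j < len(sb):
        lo = max(sa[i], sb[j])
        hi = min(ea[i], eb[j])
        if lo < hi:
            out_s.append(int(lo))
            out_e.append(int(hi))
        if ea[i] < eb[j]:
            i += 1
        else:
            j += 1
    return np.asarray(out_s, dtype=np.int64), np.asarray(out_e, dtype=np.int64)


def intersect(a: IntervalSet, b: IntervalSet) -> IntervalSet:
    """Canonical set of bases covered by both *a* and *b*."""
    ma, mb = merge(a), merge(b)
    da, db = _by_chrom(ma), _by_chrom(mb)
    out: list[GenomicInterval] = []
    for chrom in sorted(set(da) & set(db)):
        sa, ea = da[chrom]
        sb, eb = db[chrom]
        cs, ce = _intersect_arrays(sa, ea, sb, eb)
        out.extend(GenomicInterval(chrom, int(x), int(y)) for x, y in zip(cs, ce))
    return IntervalSet(
        name=f"{a.name}&{b.name}", intervals=tuple(out), canonical=True
    )


def _check_bounds(s: IntervalSet, g: Genome, clip: bool) -> IntervalSet:
    """Validate chromosomes and coordinates against the genome.

    Out-of-bounds intervals are an error unless ``clip`` is set, in which
    case they are truncated to ``[0, length)`` with a logged warning —
    silent clipping would hide genome-version mismatches.
    """
    fixed: list[GenomicInterval] = []
    n_clipped = 0
    for iv in s.intervals:
        if iv.chrom not in g:
            raise ValueError(
                f"chromosome {iv.chrom!r} of set {s.name!r} not in genome"
            )
        length = g[iv.chrom]
        if iv.end > length:
            if not clip:
                raise ValueError(
                    f"interval {iv.chrom}:{iv.start}-{iv.end} of set {s.name!r} "
                    f"extends past chromosome length {length}"
                )
            n_clipped += 1
            if iv.start >= length:
                continue
            iv = GenomicInterval(iv.chrom, iv.start, length)
        fixed.append(iv)
    if n_clipped:
        logger.warning("clipped %d interval(s) of set %r to chromosome bounds",
                       n_clipped, s.name)
        return IntervalSet(name=s.name, intervals=tuple(fixed), canonical=False)
    return s


def summarize_overlap(
    a: IntervalSet, b: IntervalSet, g: Genome, *, clip: bool = False
) -> OverlapSummary:
    """Assemble the (|A|, |B|, |A∩B|, G) quadruple for a pair of sets.

    Every input interval participates in base counting regardless of
    whether it overlaps the other set.
    """
    a = _check_bounds(a, g, clip)
    b = _check_bounds(b, g, clip)
    card_a = cardinality(a)
    card_b = cardinality(b)
    card_ab = cardinality(intersect(a, b))
    return OverlapSummary(
        card_a=card_a,
        card_b=card_b,
        card_ab=card_ab,
        genome_size=g.total,
        name_a=a.name,
        name_b=b.name,
    )


def subsample(s: IntervalSet, fraction: float, seed: int) -> IntervalSet:
    """Uniformly draw ``max(1, floor(fraction * n))`` raw intervals, without
    replacement; deterministic for a fixed seed."""
    if not 0 < fraction <= 1:
        raise ValueError(f"fraction must be in (0, 1], got {fraction}")
    n = len(s.intervals)
    if n == 0:
        raise ValueError(f"cannot subsample empty set {s.name!r}")
    k = max(1, int(np.floor(fraction * n)))
    rng = np.random.default_rng(seed)
    idx = rng.choice(n, size=k, replace=False)
    idx.sort()
    return IntervalSet(
        name=s.name,
        intervals=tuple(s.intervals[int(i)] for i in idx),
        canonical=False,
    )


def per_interval_overlap(query: IntervalSet, target: IntervalSet) -> np.ndarray:
    """Total overlap, in bases, of each *raw* query interval with the merged
    target; multi-fragment overlaps of one interval are summed."""
    mt = _by_chrom(merge(target))
    out = np.zeros(len(query.intervals), dtype=np.int64)
    for i, iv in enumerate(query.intervals):
        if iv.chrom not in mt:
            continue
        ts, te = mt[iv.chrom]
        lo = np.searchsorted(te, iv.start, side="right")
        hi = np.searchsorted(ts, iv.end, side="left")
        if hi > lo:
            overlap = np.minimum(te[lo:hi], iv.end) - np.maximum(ts[lo:hi], iv.start)
            out[i] = int(overlap.sum())
    return out
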