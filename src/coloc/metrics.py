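"""The six collocation statistics computed from base-count summaries.

Four intersection-based coefficients normalize |A∩B| by a mean of the two
set sizes — geometric (collocation coefficient C), union (Jaccard J),
arithmetic (Sørensen–Dice SD), minimum (Szymkiewicz–Simpson SS) — and are
bounded in [0, 1].  Two information-theoretic measures compare the observed
joint coverage probability with the product of marginals: pointwise mutual
information PMI = ln(p(A∩B) / (p(A)·p(B))) in (−∞, min(−ln p(A), −ln p(B))],
and its normalization NPMI = ln(p(A)·p(B)) / ln(p(A∩B)) − 1 in [−1, 1].
Probabilities are base fractions of the genome, p(·) = card / G; logs are
natural.

Boundary conventions: the intersection-based coefficients are defined as 0
when either set is empty; PMI/NPMI are undefined there (returned as NaN —
p(A) = 0 makes the expression meaningless, and NaN is honest where 0 would
assert independence).  An empty intersection gives PMI = −inf and NPMI = −1
(the limit value); the degenerate p(A∩B) = 1 gives NPMI = 1 (the A = B
upper-bound case).
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import pandas as pd

from .intervals import Genome, IntervalSet, OverlapSummary, summarize_overlap

__all__ = [
    "MetricVector",
    "METRIC_NAMES",
    "collocation_coefficient",
    "jaccard",
    "sorensen_dice",
    "simpson",
    "pmi",
    "npmi",
    "compute_all",
    "metric_range",
    "pairwise_report",
]

METRIC_NAMES = ("c", "j", "sd", "ss", "pmi", "npmi")

_RANGES = {
    "c": (0.0, 1.0),
    "j": (0.0, 1.0),
    "sd": (0.0, 1.0),
    "ss": (0.0, 1.0),
    "pmi": (-math.inf, math.inf),
    "npmi": (-1.0, 1.0),
}


def metric_range(name: str) -> tuple[float, float]:
    """Theoretical (lower, upper) range of a metric, by short name."""
    return _RANGES[name]


@dataclass(frozen=True)
class MetricVector:
    """The six collocation scores for one pair of interval sets."""

    c: float
    j: float
    sd: float
    ss: float
    pmi: float
    npmi: float

    def as_dict(self) -> dict[str, float]:
        return {name: getattr(self, name) for name in METRIC_NAMES}

    def __getitem__(self, name: str) -> float:
        if name not in METRIC_NAMES:
            raise KeyError(name)
        return getattr(self, name)


def collocation_coefficient(o: OverlapSummary) -> float:
    """C = |A∩B| / sqrt(|A|·|B|); 0 when either set is empty."""
    if o.card_a == 0 or o.card_b == 0:
        return 0.0
    return o.card_ab / math.sqrt(o.card_a * o.card_b)


def jaccard(o: OverlapSummary) -> float:
    """J = |A∩B| / |A∪B|; 0 when either set is empty."""
    if o.card_a == 0 or o.card_b == 0:
        return 0.0
    return o.card_ab / o.card_union


def sorensen_dice(o: OverlapSummary) -> float:
    """SD = 2·|A∩B| / (|A| + |B|); 0 when either set is empty."""
    if o.card_a == 0 or o.card_b == 0:
        return 0.0
    return 2 * o.card_ab / (o.card_a + o.card_b)


def simpson(o: OverlapSummary) -> float:
    """SS = |A∩B| / min(|A|, |B|); 0 when either set is empty."""
    if o.card_a == 0 or o.card_b == 0:
        return 0.0
    return o.card_ab / min(o.card_a, o.card_b)


def pmi(o: OverlapSummary) -> float:
    """PMI = ln(p(A∩B) / (p(A)·p(B))), natural log.

    Returns −inf for an empty intersection and NaN when either set is
    empty (undefined, reported as NA rather than 0).
    """
    if o.genome_size <= 0:
        raise ValueError("genome size must be positive")
    if o.card_a == 0 or o.card_b == 0:
        return math.nan
    if o.card_ab == 0:
        return -math.inf
    g = o.genome_size
    return math.log(o.card_ab * g / (o.card_a * o.card_b))


def npmi(o: OverlapSummary) -> float:
    """NPMI = ln(p(A)·p(B)) / ln(p(A∩B)) − 1, bounded in [−1, 1].

    Returns −1 for an empty intersection, 1 when p(A∩B) = 1 (both sets
    cover the whole genome), and NaN when either set is empty.
    """
    if o.genome_size <= 0:
        raise ValueError("genome size must be positive")
    if o.card_a == 0 or o.card_b == 0:
        return math.nan
    if o.card_ab == 0:
        return -1.0
    if o.card_ab == o.genome_size:
        return 1.0
    g = o.genome_size
    p_a = o.card_a / g
    p_b = o.card_b / g
    p_ab = o.card_ab / g
    return math.log(p_a * p_b) / math.log(p_ab) - 1.0


_FUNCS = {
    "c": collocation_coefficient,
    "j": jaccard,
    "sd": sorensen_dice,
    "ss": simpson,
    "pmi": pmi,
    "npmi": npmi,
}


def metric_function(name: str):
    """Look up a metric by short name (c, j, sd, ss, pmi, npmi)."""
    if name not in _FUNCS:
        raise KeyError(f"unknown metric {name!r}; choose from {METRIC_NAMES}")
    return _FUNCS[name]


def metrics_from_summary(o: OverlapSummary) -> MetricVector:
    """All six scores from one base-count summary."""
    return MetricVector(**{name: _FUNCS[name](o) for name in METRIC_NAMES})


def compute_all(
    a: IntervalSet, b: IntervalSet, g: Genome, *, clip: bool = False
) -> MetricVector:
    """All six collocation scores for a pair of interval sets."""
    return metrics_from_summary(summarize_overlap(a, b, g, clip=clip))


def pairwise_report(
    a: IntervalSet, b: IntervalSet, g: Genome, *, clip: bool = False
) -> pd.DataFrame:
    """One-row report with base counts and all six scores.

    Columns: name_a, name_b, card_a, card_b, card_ab, card_union,
    genome_size, c, j, sd, ss, pmi, npmi.
    """
    o = summarize_overlap(a, b, g, clip=clip)
    m = metrics_from_summary(o)
    row = {
        "name_a": o.name_a,
        "name_b": o.name_b,
        "card_a": o.card_a,
        "card_b": o.card_b,
        "card_ab": o.card_ab,
        "card_union": o.card_union,
        "genome_size": o.genome_size,
        **m.as_dict(),
    }
    return pd.DataFrame([row])
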