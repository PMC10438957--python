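"""One-query-vs-many-database scans, combined Z-scores, and the
threshold-and-count baseline.

The scan computes all six collocation scores between one query interval set
and every set in a database, standardizes each metric across the database
to Z_i = (x − μ)/σ, combines the per-metric Z-scores into a single ranking
statistic, and flags putative cofactors/master regulators as records whose
combined Z lies more than 3 standard deviations from the scan mean.

The combined score is Σ Z_i / √k over the k metrics with defined values
(√k keeps the combination variance-stabilized, the convention of the gene
set variation analysis literature); Σ Z_i / k is available via
``denominator="k"``.  Ranking and outlier calls are identical under both,
since they differ by a positive scale factor only.

The baseline is the conventional approach the threshold-free scores are
designed to replace: label each query peak overlapped/non-overlapped at a
cutoff (1 nucleotide, or 10/30/50/80/100% of the peak's length) and rank
targets by the proportion of overlapped query peaks.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass, replace
from pathlib import Path
from typing import Iterable, Sequence

import numpy as np
import pandas as pd

from .intervals import (
    Genome,
    IntervalSet,
    per_interval_overlap,
    read_bed,
    summarize_overlap,
)
from .metrics import METRIC_NAMES, MetricVector, metrics_from_summary

logger = logging.getLogger(__name__)

__all__ = [
    "ScanRecord",
    "ThresholdSpec",
    "ThresholdCountResult",
    "DEFAULT_THRESHOLDS",
    "scan",
    "combine_z",
    "flag_outliers",
    "scan_table",
    "threshold_and_count",
    "rank_by_proportion",
    "baseline_table",
    "load_database",
]


@dataclass(frozen=True)
class ScanRecord:
    """One database entry's scores within a scan."""

    target_name: str
    metrics: MetricVector
    z_per_metric: dict[str, float]
    combined_z: float
    rank: int = 0
    outlier: bool = False


def combine_z(
    z_scores: Sequence[float] | dict[str, float], denominator: str = "sqrt"
) -> float:
    """Combine per-metric Z-scores into one statistic.

    NA (NaN) entries are dropped; the sum is renormalized over the k
    remaining metrics: Σ Z_i / √k (default) or Σ Z_i / k.  Returns NaN
    when no metric is defined.
    """
    if isinstance(z_scores, dict):
        values = list(z_scores.values())
    else:
        values = list(z_scores)
    finite = [z for z in values if not math.isnan(z)]
    k = len(finite)
    if k == 0:
        return math.nan
    denom = math.sqrt(k) if denominator == "sqrt" else float(k)
    return sum(finite) / denom


def _z_columns(rows: list[MetricVector]) -> dict[str, np.ndarray]:
    """Standardize each metric across the scan to mean 0, sample SD 1.

    −inf scores (PMI with an empty intersection) and NaN scores are
    treated as NA for that column; a column with σ = 0 (or fewer than two
    defined values) is set to 0 everywhere it is defined, with a warning.
    """
    out: dict[str, np.ndarray] = {}
    for name in METRIC_NAMES:
        col = np.array([row[name] for row in rows], dtype=float)
        col[~np.isfinite(col)] = np.nan
        defined = ~np.isnan(col)
        z = np.full(len(col), np.nan)
        n_def = int(defined.sum())
        if n_def >= 2:
            mu = col[defined].mean()
            sigma = col[defined].std(ddof=1)
            if sigma > 0:
                z[defined] = (col[defined] - mu) / sigma
            else:
                logger.warning("metric %s has zero variance across the scan; "
                               "its Z-scores are set to 0", name)
                z[defined] = 0.0
        elif n_def > 0:
            logger.warning("metric %s is defined for <2 targets; "
                           "its Z-scores are set to 0", name)
            z[defined] = 0.0
        out[name] = z
    return out


def flag_outliers(records: Sequence[ScanRecord]) -> list[ScanRecord]:
    """Set ``outlier`` = True on records whose combined Z is more than
    3 sample standard deviations from the mean combined Z of the scan."""
    if len(records) < 3:
        raise ValueError("need >= 3 records to call outliers")
    values = np.array([r.combined_z for r in records], dtype=float)
    finite = values[np.isfinite(values)]
    if len(finite) < 2:
        return [replace(r, outlier=False) for r in records]
    mu = finite.mean()
    sigma = finite.std(ddof=1)
    out = []
    for r, v in zip(records, values):
        is_out = bool(np.isfinite(v) and sigma > 0 and abs(v - mu) > 3 * sigma)
        out.append(replace(r, outlier=is_out))
    return out


def scan(
    query: IntervalSet,
    database: Iterable[IntervalSet],
    g: Genome,
    *,
    exclude: str | None = None,
    denominator: str = "sqrt",
) -> list[ScanRecord]:
    """Score the query against every database set; standardize, combine,
    rank (descending combined Z, name-lexicographic ties) and flag outliers.

    ``exclude`` removes a self-match label from the database before
    standardization (a query scanned against a database that contains it
    would otherwise standardize against itself).
    """
    targets = [t for t in database if t.name != exclude]
    if len(targets) < 3:
        raise ValueError(
            f"need >= 3 usable database targets, got {len(targets)}"
        )
    rows = []
    for t in targets:
        logger.info("scanning target %s", t.name)
        rows.append(metrics_from_summary(summarize_overlap(query, t, g)))
    zcols = _z_columns(rows)
    records = []
    for i, (t, m) in enumerate(zip(targets, rows)):
        z = {name: float(zcols[name][i]) for name in METRIC_NAMES}
        records.append(
            ScanRecord(
                target_name=t.name,
                metrics=m,
                z_per_metric=z,
                combined_z=combine_z(z, denominator=denominator),
            )
        )
    records.sort(key=lambda r: (-r.combined_z if not math.isnan(r.combined_z)
                                else math.inf, r.target_name))
    records = [replace(r, rank=i + 1) for i, r in enumerate(records)]
    return flag_outliers(records)


def scan_table(records: Sequence[ScanRecord], query_name: str = "query"
               ) -> pd.DataFrame:
    """Tabular scan report (one row per target, ordered by rank)."""
    rows = []
    for r in records:
        row: dict = {"target": r.target_name}
        row.update({k: v for k, v in r.metrics.as_dict().items()})
        row.update({f"z_{k}": v for k, v in r.z_per_metric.items()})
        row["combined_z"] = r.combined_z
        row["rank"] = r.rank
        row["outlier"] = r.outlier
        rows.append(row)
    return pd.DataFrame(rows)


# ---------------------------------------------------------------------------
# threshold-and-count baseline


@dataclass(frozen=True)
class ThresholdSpec:
    """Overlap cutoff for labeling one query peak as 'overlapped'.

    ``kind='nt'`` requires at least ``value`` overlapping bases (1 nt is
    the most relaxed cutoff); ``kind='pct'`` requires the peak's total
    overlap with the merged target to reach ``value`` percent of the
    peak's own length (100% — full coverage — is the most stringent).
    """

    kind: str  # "nt" | "pct"
    value: float

    def __post_init__(self) -> None:
        if self.kind not in ("nt", "pct"):
            raise ValueError(f"unknown threshold kind {self.kind!r}")
        if self.value <= 0:
            raise ValueError("threshold value must be positive")
        if self.kind == "pct" and self.value > 100:
            raise ValueError("percentage threshold cannot exceed 100")

    @classmethod
    def parse(cls, text: str) -> "ThresholdSpec":
        """Parse '1nt', '10', '10%', '50' ... into a spec."""
        text = text.strip().lower().rstrip("%")
        if text.endswith("nt"):
            return cls("nt", float(text[:-2]))
        return cls("pct", float(text))

    def label(self) -> str:
        if self.kind == "nt":
            return f"{self.value:g}nt"
        return f"{self.value:g}%"


DEFAULT_THRESHOLDS: tuple[ThresholdSpec, ...] = (
    ThresholdSpec("nt", 1),
    ThresholdSpec("pct", 10),
    ThresholdSpec("pct", 30),
    ThresholdSpec("pct", 50),
    ThresholdSpec("pct", 80),
    ThresholdSpec("pct", 100),
)


@dataclass(frozen=True)
class ThresholdCountResult:
    target_name: str
    threshold: ThresholdSpec
    n_query_peaks: int
    n_overlapped: int

    @property
    def proportion(self) -> float:
        return self.n_overlapped / self.n_query_peaks


def threshold_and_count(
    query: IntervalSet, target: IntervalSet, threshold: ThresholdSpec
) -> ThresholdCountResult:
    """Label each raw query peak overlapped/non-overlapped at the cutoff
    and count; a peak's overlap with multiple target fragments is summed."""
    if len(query) == 0:
        raise ValueError("query set is empty")
    overlaps = per_interval_overlap(query, target)
    lengths = np.array([len(iv) for iv in query.intervals], dtype=np.int64)
    if threshold.kind == "nt":
        hit = overlaps >= threshold.value
    else:
        hit = overlaps >= (threshold.value / 100.0) * lengths
    return ThresholdCountResult(
        target_name=target.name,
        threshold=threshold,
        n_query_peaks=len(query),
        n_overlapped=int(hit.sum()),
    )


def rank_by_proportion(
    results: Sequence[ThresholdCountResult],
) -> pd.DataFrame:
    """Rank targets by overlapped proportion, descending; ties broken by
    target name (stable, lexicographic)."""
    if len(results) == 0:
        raise ValueError("no results to rank")
    df = pd.DataFrame(
        {
            "target": [r.target_name for r in results],
            "threshold": [r.threshold.label() for r in results],
            "n_query_peaks": [r.n_query_peaks for r in results],
            "n_overlapped": [r.n_overlapped for r in results],
            "proportion": [r.proportion for r in results],
        }
    )
    df = df.sort_values(
        ["proportion", "target"], ascending=[False, True], kind="stable"
    ).reset_index(drop=True)
    df["rank"] = np.arange(1, len(df) + 1)
    return df


def baseline_table(
    query: IntervalSet,
    database: Iterable[IntervalSet],
    thresholds: Sequence[ThresholdSpec] = DEFAULT_THRESHOLDS,
    *,
    exclude: str | None = None,
) -> pd.DataFrame:
    """Threshold-and-count at each cutoff for every target; one ranked
    block per threshold, concatenated."""
    targets = [t for t in database if t.name != exclude]
    blocks = []
    for spec in thresholds:
        results = [threshold_and_count(query, t, spec) for t in targets]
        blocks.append(rank_by_proportion(results))
    return pd.concat(blocks, ignore_index=True)


# ---------------------------------------------------------------------------
# database loading


def load_database(path: str | Path) -> list[IntervalSet]:
    """Load a database of interval sets.

    ``path`` is either a directory of ``*.bed`` / ``*.bed.gz`` files (the
    label is the basename without extension) or a two-column TSV manifest
    of label and BED path (relative paths resolved against the manifest's
    directory).
    """
    path = Path(path)
    sets: list[IntervalSet] = []
    if path.is_dir():
        files = sorted(
            p for p in path.iterdir()
            if p.name.endswith(".bed") or p.name.endswith(".bed.gz")
        )
        if not files:
            raise ValueError(f"no BED files found in directory {path}")
        for p in files:
            sets.append(read_bed(p))
    else:
        with open(path) as fh:
            for lineno, line in enumerate(fh, start=1):
                line = line.strip()
                if not line or line.startswith("#"):
                    continue
                fields = line.split("\t")
                if len(fields) < 2:
                    raise ValueError(
                        f"{path}:{lineno}: manifest needs label<TAB>path"
                    )
                label, bed = fields[0], Path(fields[1])
                if not bed.is_absolute():
                    bed = path.parent / bed
                sets.append(read_bed(bed, name=label))
    names = [s.name for s in sets]
    if len(set(names)) != len(names):
        raise ValueError("duplicate labels in database")
    return sets
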