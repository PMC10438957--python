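"""Scan pipeline: Z-standardization, combined score, outlier calling, and
the threshold-and-count baseline."""

import math

import numpy as np
import pytest

from coloc import (
    Genome,
    GenomicInterval,
    IntervalSet,
    ScanRecord,
    ThresholdSpec,
    baseline_table,
    combine_z,
    flag_outliers,
    load_database,
    rank_by_proportion,
    scan,
    scan_table,
    threshold_and_count,
    write_bed,
)
from coloc.metrics import METRIC_NAMES, MetricVector
from coloc.scan import DEFAULT_THRESHOLDS


def block_set(name, spans):
    return IntervalSet(name, tuple(GenomicInterval("chr1", s, e) for s, e in spans))


@pytest.fixture
def small_db(toy_genome):
    """Query plus three targets with strictly ordered overlap depth."""
    query = block_set("Q", [(0, 100), (200, 300), (400, 500)])
    t1 = block_set("T1", [(0, 100), (200, 300)])       # 200 shared bases
    t2 = block_set("T2", [(0, 100)])                   # 100 shared
    t3 = block_set("T3", [(0, 50), (700, 750)])        # 50 shared
    return query, [t1, t2, t3]


class TestCombineZ:
    def test_zeros(self):
        assert combine_z([0.0] * 6) == 0.0

    def test_sqrt_k_normalization(self):
        assert combine_z([1.0] * 6) == pytest.approx(6 / math.sqrt(6))
        assert combine_z([1.0] * 6, denominator="k") == pytest.approx(1.0)

    def test_na_dropped_with_renormalization(self):
        zs = [1.0, 1.0, 1.0, 1.0, math.nan, math.nan]
        assert combine_z(zs) == pytest.approx(4 / math.sqrt(4))

    def test_all_na_gives_na(self):
        assert math.isnan(combine_z([math.nan] * 6))

    def test_monotone(self):
        assert combine_z([2.0] * 6) > combine_z([1.0] * 6)


class TestScan:
    def test_dominant_target_ranks_first(self, toy_genome, small_db):
        query, db = small_db
        records = scan(query, db, toy_genome)
        assert records[0].target_name == "T1" and records[0].rank == 1
        assert [r.rank for r in records] == [1, 2, 3]

    def test_hand_computed_z_scores(self, toy_genome, small_db):
        """Per-metric Z on a 3-row table equals (x − mean)/sample-SD."""
        query, db = small_db
        records = scan(query, db, toy_genome)
        by_name = {r.target_name: r for r in records}
        for name in METRIC_NAMES:
            col = np.array([by_name[t].metrics[name] for t in ("T1", "T2", "T3")])
            z_expected = (col - col.mean()) / col.std(ddof=1)
            for t, ze in zip(("T1", "T2", "T3"), z_expected):
                assert by_name[t].z_per_metric[name] == pytest.approx(ze)

    def test_z_columns_standardized(self, toy_genome, small_db):
        query, db = small_db
        records = scan(query, db, toy_genome)
        for name in METRIC_NAMES:
            col = np.array([r.z_per_metric[name] for r in records])
            assert abs(col.mean()) < 1e-9
            assert abs(col.std(ddof=1) - 1) < 1e-9

    def test_identical_targets_sigma_zero_path(self, toy_genome):
        query = block_set("Q", [(0, 100)])
        db = [block_set(f"T{i}", [(50, 150)]) for i in range(4)]
        records = scan(query, db, toy_genome)
        assert all(r.combined_z == 0.0 for r in records)
        assert not any(r.outlier for r in records)

    def test_exclude_removes_self_match(self, toy_genome, small_db):
        query, db = small_db
        self_copy = IntervalSet("Q", query.intervals)
        records = scan(query, db + [self_copy], toy_genome, exclude="Q")
        assert "Q" not in {r.target_name for r in records}
        assert len(records) == 3

    def test_too_few_targets_error(self, toy_genome, small_db):
        query, db = small_db
        with pytest.raises(ValueError, match=">= 3"):
            scan(query, db[:2], toy_genome)

    def test_ranking_invariant_to_denominator(self, toy_genome, small_db):
        """sum/sqrt(k) and sum/k are monotone transforms of each other."""
        query, db = small_db
        r_sqrt = scan(query, db, toy_genome, denominator="sqrt")
        r_k = scan(query, db, toy_genome, denominator="k")
        assert [r.target_name for r in r_sqrt] == [r.target_name for r in r_k]
        assert [r.outlier for r in r_sqrt] == [r.outlier for r in r_k]

    def test_scan_table_shape(self, toy_genome, small_db):
        query, db = small_db
        df = scan_table(scan(query, db, toy_genome))
        assert list(df["rank"]) == [1, 2, 3]
        assert {"combined_z", "outlier", "z_pmi", "npmi"} <= set(df.columns)


def _record(name, z):
    return ScanRecord(target_name=name,
                      metrics=MetricVector(0, 0, 0, 0, 0, 0),
                      z_per_metric={}, combined_z=z)


class TestFlagOutliers:
    def test_single_extreme_among_many(self):
        records = [_record(f"t{i}", 0.0) for i in range(100)]
        records.append(_record("hot", 10.0))
        values = np.array([r.combined_z for r in records])
        # brute-force check of the rule itself
        assert abs(10.0 - values.mean()) > 3 * values.std(ddof=1)
        flagged = [r.target_name for r in flag_outliers(records) if r.outlier]
        assert flagged == ["hot"]

    def test_all_equal_no_outliers(self):
        records = [_record(f"t{i}", 1.5) for i in range(5)]
        assert not any(r.outlier for r in flag_outliers(records))

    def test_symmetric_extremes_inflate_sd(self):
        """Two opposite extremes widen the SD so neither exceeds 3·SD."""
        zs = [-5.0, 0.0, 0.0, 0.0, 5.0]
        values = np.array(zs)
        assert all(abs(v - values.mean()) <= 3 * values.std(ddof=1) for v in zs)
        records = [_record(f"t{i}", z) for i, z in enumerate(zs)]
        assert not any(r.outlier for r in flag_outliers(records))

    def test_too_few_records(self):
        with pytest.raises(ValueError):
            flag_outliers([_record("a", 0.0)])


class TestThresholdAndCount:
    def test_percentage_thresholds_per_peak(self):
        query = block_set("Q", [(0, 100)])
        target = block_set("T", [(90, 200)])  # 10 of 100 bases
        at = lambda spec: threshold_and_count(query, target, spec).n_overlapped
        assert at(ThresholdSpec("pct", 10)) == 1
        assert at(ThresholdSpec("pct", 50)) == 0
        assert at(ThresholdSpec("nt", 1)) == 1

    def test_full_coverage_needed_at_100pct(self):
        query = block_set("Q", [(0, 100), (200, 300)])
        target = block_set("T", [(0, 100), (200, 299)])
        r = threshold_and_count(query, target, ThresholdSpec("pct", 100))
        assert r.n_overlapped == 1 and r.proportion == 0.5

    def test_multi_fragment_overlap_summed(self):
        query = block_set("Q", [(0, 100)])
        target = block_set("T", [(0, 30), (60, 90)])  # 30 + 30 = 60 bases
        assert threshold_and_count(
            query, target, ThresholdSpec("pct", 50)).n_overlapped == 1

    def test_monotone_across_default_thresholds(self, toy_genome):
        rng = np.random.default_rng(3)
        query = block_set("Q", [(i * 50, i * 50 + 30) for i in range(15)])
        target = block_set(
            "T", [(int(s), int(s) + 25)
                  for s in sorted(rng.choice(970, size=12, replace=False))])
        props = [threshold_and_count(query, target, t).proportion
                 for t in DEFAULT_THRESHOLDS]
        assert all(x >= y for x, y in zip(props, props[1:]))

    def test_empty_query_errors(self):
        with pytest.raises(ValueError):
            threshold_and_count(IntervalSet("Q", ()), block_set("T", [(0, 5)]),
                                ThresholdSpec("nt", 1))

    def test_threshold_spec_parsing(self):
        assert ThresholdSpec.parse("1nt") == ThresholdSpec("nt", 1)
        assert ThresholdSpec.parse("30%") == ThresholdSpec("pct", 30)
        assert ThresholdSpec.parse("80") == ThresholdSpec("pct", 80)
        with pytest.raises(ValueError):
            ThresholdSpec.parse("120")


class TestRanking:
    def test_descending_by_proportion(self):
        query = block_set("Q", [(0, 10), (20, 30), (40, 50), (60, 70),
                                (80, 90), (100, 110), (120, 130), (140, 150),
                                (160, 170), (180, 190)])
        spec = ThresholdSpec("nt", 1)
        targets = [
            block_set("deep", [(0, 10), (20, 30), (40, 50), (60, 70),
                               (80, 90), (100, 110), (120, 130), (140, 150),
                               (160, 170)]),                        # 9/10
            block_set("mid", [(0, 10), (20, 30), (40, 50), (60, 70),
                              (80, 90)]),                           # 5/10
            block_set("shallow", [(0, 10)]),                        # 1/10
        ]
        results = [threshold_and_count(query, t, spec) for t in targets]
        df = rank_by_proportion(results)
        assert list(df["target"]) == ["deep", "mid", "shallow"]
        assert list(df["rank"]) == [1, 2, 3]

    def test_tie_broken_lexicographically(self):
        query = block_set("Q", [(0, 10), (20, 30)])
        spec = ThresholdSpec("nt", 1)
        tb = block_set("beta", [(0, 10)])
        ta = block_set("alpha", [(20, 30)])
        df = rank_by_proportion(
            [threshold_and_count(query, t, spec) for t in (tb, ta)])
        assert list(df["target"]) == ["alpha", "beta"]


class TestLoadDatabase:
    def test_directory_and_manifest(self, tmp_path):
        for name in ("tf_b", "tf_a"):
            write_bed(block_set(name, [(0, 10)]), tmp_path / f"{name}.bed")
        sets = load_database(tmp_path)
        assert [s.name for s in sets] == ["tf_a", "tf_b"]

        manifest = tmp_path / "manifest.tsv"
        manifest.write_text("labelX\ttf_a.bed\nlabelY\ttf_b.bed\n")
        sets = load_database(manifest)
        assert [s.name for s in sets] == ["labelX", "labelY"]

    def test_duplicate_labels_rejected(self, tmp_path):
        write_bed(block_set("x", [(0, 10)]), tmp_path / "x.bed")
        manifest = tmp_path / "m.tsv"
        manifest.write_text("same\tx.bed\nsame\tx.bed\n")
        with pytest.raises(ValueError, match="duplicate"):
            load_database(manifest)
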