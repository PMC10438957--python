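"""Rank database targets by collocation with a query, and show where the
conventional threshold-and-count ranking goes wrong.

Builds the canonical biased scenario: a 500-peak query on a 10 Mb genome,
one planted target that copies 40% of the query's peaks, and 19
independent targets whose peak counts span 20 to 5,000.  The combined-Z
scan puts the planted target first and flags it as the only 3-SD outlier;
the 1-nt threshold-and-count baseline instead rewards the target with the
most peaks, which overlaps almost every query peak by sheer coverage.
"""

import tempfile

from coloc import (
    ThresholdSpec,
    demo_scan_scenario,
    load_database,
    rank_by_proportion,
    scan,
    threshold_and_count,
)

with tempfile.TemporaryDirectory() as tmp:
    genome, query, db = demo_scan_scenario(tmp, seed=424_242)
    targets = load_database(db.manifest_path)

    records = scan(query, targets, genome)
    print("combined-Z scan (top 3):")
    for r in records[:3]:
        flag = "  <-- outlier" if r.outlier else ""
        print(f"  rank {r.rank}: {r.target_name:22s} Z={r.combined_z:6.2f}{flag}")

    ranked = rank_by_proportion(
        [threshold_and_count(query, t, ThresholdSpec("nt", 1)) for t in targets]
    )
    print("\n1-nt threshold-and-count baseline (top 3):")
    for _, row in ranked.head(3).iterrows():
        print(f"  rank {row['rank']}: {row['target']:22s} "
              f"proportion={row['proportion']:.3f}")

    colloc = ranked.loc[ranked["target"] == db.collocated_label]
    print(f"\nplanted target under the baseline: rank "
          f"{int(colloc['rank'].iloc[0])} "
          f"(proportion {float(colloc['proportion'].iloc[0]):.3f})")
    print("The baseline rewards peak count; the combined Z-score rewards")
    print("genuinely shared bases.")
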