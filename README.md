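# coloc — threshold-free collocation statistics for genomic intervals

Deciding whether two sets of genomic intervals — ChIP-seq peaks,
ATAC-seq open-chromatin regions, enhancer calls — "overlap" is usually
done by picking an arbitrary cutoff, labeling each region overlapped or
not, and counting. That binary call discards the magnitude of the
overlap and systematically favors whichever set simply has the most (or
the widest) peaks. `coloc` instead quantifies collocation on the level
of shared genomic *bases*, for analysts ranking candidate cofactors or
master regulators against a query region set.

## The statistics

Let |A| and |B| be the non-redundant base counts covered by interval
sets A and B, |A∩B| the bases covered by both, and G the genome size.
With p(A) = |A|/G, p(B) = |B|/G, p(A∩B) = |A∩B|/G:

| statistic | definition | range |
|---|---|---|
| collocation coefficient | C = \|A∩B\| / √(\|A\|·\|B\|) | [0, 1] |
| Jaccard | J = \|A∩B\| / \|A∪B\| | [0, 1] |
| Sørensen–Dice | SD = 2\|A∩B\| / (\|A\|+\|B\|) | [0, 1] |
| Szymkiewicz–Simpson | SS = \|A∩B\| / min(\|A\|,\|B\|) | [0, 1] |
| pointwise mutual information | PMI = ln p(A∩B) − ln p(A) − ln p(B) | (−∞, min(−ln p(A), −ln p(B))] |
| normalized PMI | NPMI = ln(p(A)·p(B)) / ln p(A∩B) − 1 | [−1, 1] |

The four intersection-based coefficients differ only in how they
normalize the intersection (geometric mean, union, arithmetic mean,
minimum). PMI compares the observed joint coverage with the
independence expectation: PMI = 0 means A and B share exactly
|A|·|B|/G bases, positive means more than chance, negative less.

On top of the pairwise scores the package provides:

- **bootstrap confidence intervals** — 20 replicates, each subsampling
  75% of both sets' intervals without replacement (both defaults
  configurable);
- **one-vs-many scans** — score a query against a database of interval
  sets, standardize each metric to Z-scores across the database,
  combine them (Σ Zᵢ/√k), rank, and flag targets more than 3 SD from
  the mean as putative cofactors / master regulators;
- **the threshold-and-count baseline** — the conventional approach
  (cutoffs: 1 nt, 10/30/50/80/100% of each query peak), for comparison;
- **synthetic fixture generators** — interval sets with a planted
  shared-base fraction, exactly-independent pairs, and a biased
  query-vs-database scenario that reproduces the peak-count bias of
  threshold-and-count rankings.

## Worked example

```python
from coloc import Genome, GenomicInterval, IntervalSet, pairwise_report

genome = Genome({"chr1": 1000})
a = IntervalSet("setA", (GenomicInterval("chr1", 0, 200),))
b = IntervalSet("setB", (GenomicInterval("chr1", 190, 240),))
print(pairwise_report(a, b, genome).to_string(index=False))
```

```
name_a name_b  card_a  card_b  card_ab  card_union  genome_size   c         j   sd  ss  pmi  npmi
  setA   setB     200      50       10         240         1000 0.1 0.0416667 0.08 0.2  0.0   0.0
```

A covers 200 bases, B covers 50, they share 10. C = 10/√(200·50) = 0.1;
J = 10/240; SD = 20/250; SS = 10/50. The shared count happens to equal
the independence expectation 200·50/1000 = 10, so PMI = NPMI = 0: the
overlap is no more than chance, even though the intersection-based
coefficients are positive.

The same computation from the shell:

```sh
coloc stat A.bed B.bed -g genome.chrom.sizes --bootstrap
coloc scan query.bed --db database_dir/ -g genome.chrom.sizes -o scan.tsv
coloc baseline query.bed --db database_dir/ -o baseline.tsv
coloc simulate --shared-fraction 0.5 -o fixtures/
```

The scripts in `examples/` are narrative versions of each capability:
`pairwise_scores.py`, `bootstrap_intervals.py`, `scan_vs_baseline.py`
(the scan recovering a planted target that the threshold-and-count
baseline misranks), and `independence_construction.py`.

## Conventions that matter

- BED coordinates, 0-based half-open; every cardinality is a merged
  ("non-redundant") base count.
- Every input interval participates in base counting whether or not it
  overlaps the other set.
- Intersection-based coefficients are 0 when either set is empty;
  PMI/NPMI are reported as NA there. An empty intersection gives
  PMI = −inf and NPMI = −1.
- Logs are natural; NPMI is base-invariant.

See `docs/methods.md` for the full model description, parameter
defaults, and numerical edge-case policy.
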