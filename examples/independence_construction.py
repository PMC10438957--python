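"""Construct a pair of interval sets that are exactly independent.

Base-coverage independence means the shared base count equals
|A| x |B| / G, the product-of-marginals expectation.  The generator lays
the sets out so this holds exactly, which pins PMI and NPMI to 0 — the
reference point separating higher-than-expected from lower-than-expected
overlap.
"""

from coloc import Genome, cardinality, compute_all, generate_independent_pair, intersect

genome = Genome({"chr1": 1000})
a, b = generate_independent_pair(genome, card_a=500, card_b=200, seed=3)

shared = cardinality(intersect(a, b))
m = compute_all(a, b, genome)
print(f"|A| = {cardinality(a)}, |B| = {cardinality(b)}, G = {genome.total}")
print(f"|A∩B| = {shared}  (expected under independence: 500*200/1000 = 100)")
print(f"PMI  = {m.pmi:.3g}   NPMI = {m.npmi:.3g}")
print()
print("PMI > 0 would mean more overlap than chance; PMI < 0 less; here the")
print("overlap equals the chance expectation exactly, so both scores are 0.")
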