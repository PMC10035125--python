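"""Generate a seeded synthetic labeled corpus.

Each location has its own nucleotide-composition bias and a planted
trinucleotide motif; the generator stands in for a curated localization
corpus when exercising the pipeline.
"""
from collections import Counter

import subloc as sl

cfg = sl.five_location_config(seed=42, n_per_location=50)
corpus = sl.generate_synthetic_corpus(cfg)

counts = Counter(label for _, label in corpus.records)
print(f"{len(corpus)} sequences across {len(corpus.locations)} locations:")
for loc in corpus.locations:
    seqs = [s for s, lab in corpus.records if lab == loc]
    a_frac = sum(s.seq.count("A") / s.length for s in seqs) / len(seqs)
    motif, rate = cfg.motif[loc]
    carriers = sum(motif in s.seq for s in seqs) / len(seqs)
    print(f"  {loc:>13}: n={counts[loc]}, mean A fraction {a_frac:.3f}, "
          f"motif {motif} in {100 * carriers:.0f}% of sequences")
print("The A fraction tracks each location's composition bias; motif")
print("carrier rates exceed the planted 80% because short motifs also")
print("occur by chance.")
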