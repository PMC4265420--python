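"""Discover an overrepresented motif in one peak dataset.

A known word is planted into half of 200 peaks on a random genome; the
DREME-style finder recovers it against an order-3 Markov negative set.
"""
import numpy as np

from crmine import Dataset, DiscoveryConfig, find_motifs
from crmine.genome import Genome
from crmine.intervals import GenomicInterval

rng = np.random.default_rng(5)
word = "TGACGTCA"
peak_len, n_peaks = 300, 200
seq = list("".join("ACGT"[c] for c in rng.integers(0, 4, n_peaks * (peak_len + 10))))
intervals = []
for i in range(n_peaks):
    start = i * (peak_len + 10)
    intervals.append(GenomicInterval("chr1", start, start + peak_len))
    if rng.random() < 0.5:
        off = start + int(rng.integers(20, peak_len - 30))
        seq[off : off + len(word)] = list(word)
genome = Genome({"chr1": "".join(seq)})
dataset = Dataset.from_intervals("demo", "TF_demo", intervals)

motifs = find_motifs(dataset, genome, DiscoveryConfig(seed=1, max_motifs=3))
print(f"planted word: {word}")
for m in motifs:
    print(f"{m.motif_id}: pattern={m.consensus} consensus={m.pswm.consensus()} "
          f"support={m.support} E={m.evalue:.2e}")

# The first motif's consensus should match the planted word (possibly as
# its reverse complement); support counts the distinct peaks carrying at
# least one site, and E is the Fisher-test E-value over all candidate
# words examined.
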