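"""Motif discovery: Markov negatives, the finder, QC, scanning."""
from collections import Counter

import numpy as np
import pytest

from crmine.discovery import (
    DiscoveryConfig,
    apply_dataset_qc,
    find_motifs,
    markov_negative_set,
    attach_scan_support,
    scan_sites,
)
from crmine.genome import Genome, reverse_complement
from crmine.intervals import GenomicInterval
from crmine.peaks import Dataset
from crmine.pswm import PSWM


def hamming(a, b):
    return sum(x != y for x, y in zip(a, b))


class TestMarkovNegativeSet:
    def test_count_and_length_conservation(self, rng):
        seqs = ["".join("ACGT"[c] for c in rng.integers(0, 4, 500)) for _ in range(20)]
        neg = markov_negative_set(seqs, order=3, seed=1)
        assert len(neg) == 20
        assert [len(s) for s in neg] == [len(s) for s in seqs]

    def test_determinism(self, rng):
        seqs = ["".join("ACGT"[c] for c in rng.integers(0, 4, 300)) for _ in range(5)]
        assert markov_negative_set(seqs, 3, 42) == markov_negative_set(seqs, 3, 42)
        assert markov_negative_set(seqs, 3, 42) != markov_negative_set(seqs, 3, 43)

    def test_4mer_profile_matches_within_tv(self, rng):
        # brute-force 4-mer counting on both sets, total variation <= 0.05
        base = np.array([0.35, 0.15, 0.15, 0.35])
        seqs = ["".join(rng.choice(list("ACGT"), p=base, size=2000)) for _ in range(50)]
        neg = markov_negative_set(seqs, order=3, seed=9)

        def profile(ss):
            c = Counter()
            for s in ss:
                for i in range(len(s) - 3):
                    c[s[i : i + 4]] += 1
            total = sum(c.values())
            return {k: v / total for k, v in c.items()}

        p, q = profile(seqs), profile(neg)
        tv = 0.5 * sum(abs(p.get(k, 0) - q.get(k, 0)) for k in set(p) | set(q))
        assert tv <= 0.05

    def test_short_sequence_copied(self):
        out = markov_negative_set(["ACG", "ACGTACGTACGT"], order=3, seed=0)
        assert out[0] == "ACG"


def planted_dataset(n_peaks=200, peak_len=300, frac=0.5, word="TGACGTCA", seed=5):
    """Peaks on a random genome; a fraction carry the planted word."""
    rng = np.random.default_rng(seed)
    glen = n_peaks * (peak_len + 10)
    seq = list("".join("ACGT"[c] for c in rng.integers(0, 4, glen)))
    intervals = []
    planted_at = []
    for i in range(n_peaks):
        start = i * (peak_len + 10)
        intervals.append(GenomicInterval("chr1", start, start + peak_len))
        if rng.random() < frac:
            off = int(rng.integers(20, peak_len - 20 - len(word)))
            seq[start + off : start + off + len(word)] = list(word)
            planted_at.append((i, start + off))
    genome = Genome({"chr1": "".join(seq)})
    return Dataset.from_intervals("dtest", "TF", intervals), genome, planted_at


class TestFindMotifs:
    def test_planted_word_recovered_with_sites(self):
        ds, genome, planted_at = planted_dataset()
        motifs = find_motifs(ds, genome, DiscoveryConfig(seed=3, max_motifs=3))
        assert motifs, "no motif found on strongly planted data"
        top = motifs[0]
        cons = top.pswm.consensus()
        d = min(hamming(cons, "TGACGTCA"), hamming(cons, reverse_complement("TGACGTCA")))
        assert top.pswm.width >= 8
        # allow the finder to catch a wider superstring of the plant
        assert d <= 1 or "TGACGTCA" in cons or "TGACGTCA" in reverse_complement(cons)
        # site coordinates match the planting record
        planted_pos = {pos for _, pos in planted_at}
        hits = sum(1 for s in top.sites if any(abs(s.interval.start - p) <= 4 for p in planted_pos))
        assert hits / len(top.sites) > 0.9

    def test_pure_noise_rarely_yields_motifs(self):
        found = []
        for seed in range(10):
            rng = np.random.default_rng(1000 + seed)
            glen = 100 * 310
            genome = Genome({"chr1": "".join("ACGT"[c] for c in rng.integers(0, 4, glen))})
            ivs = [GenomicInterval("chr1", i * 310, i * 310 + 300) for i in range(100)]
            ds = Dataset.from_intervals(f"noise{seed}", "TF", ivs)
            motifs = find_motifs(ds, genome, DiscoveryConfig(seed=seed, max_motifs=5))
            found.append(len(motifs))
        assert sum(1 for n in found if n <= 2) >= 9

    def test_identical_sequences_maximal_support(self, rng):
        # 30 peaks of one identical random sequence: maximal enrichment
        unit = "".join("ACGT"[c] for c in rng.integers(0, 4, 200))
        genome = Genome({"chr1": unit * 30})
        ivs = [GenomicInterval("chr1", i * 200, (i + 1) * 200) for i in range(30)]
        ds = Dataset.from_intervals("dup", "TF", ivs)
        motifs = find_motifs(ds, genome, DiscoveryConfig(seed=0, max_motifs=1))
        assert motifs and motifs[0].support == 30

    def test_empty_dataset(self, small_genome):
        assert find_motifs(Dataset("e", "TF", []), small_genome, DiscoveryConfig()) == []

    def test_determinism(self):
        ds, genome, _ = planted_dataset(n_peaks=80)
        cfg = DiscoveryConfig(seed=11, max_motifs=2)
        a = find_motifs(ds, genome, cfg)
        b = find_motifs(ds, genome, cfg)
        assert [m.consensus for m in a] == [m.consensus for m in b]
        assert [[s.interval for s in m.sites] for m in a] == \
               [[s.interval for s in m.sites] for m in b]

    def test_no_duplicate_site_intervals_within_dataset(self):
        ds, genome, _ = planted_dataset()
        motifs = find_motifs(ds, genome, DiscoveryConfig(seed=3, max_motifs=4))
        seen = set()
        for m in motifs:
            for s in m.sites:
                key = (s.interval.start, s.interval.end)
                assert key not in seen
                seen.add(key)

    def test_sites_within_extended_peaks(self):
        ds, genome, _ = planted_dataset()
        peak_lookup = {p.peak_id: p for p in ds.peaks}
        for m in find_motifs(ds, genome, DiscoveryConfig(seed=3, max_motifs=3)):
            for s in m.sites:
                assert peak_lookup[s.peak_id].extended.contains(s.interval)
                # site sequence matches the genome at its interval/strand
                assert genome.fetch(s.interval) == s.seq


class TestQc:
    def test_thresholds(self):
        m = object()
        out = apply_dataset_qc({"d0": [], "d1": [m], "d2": [m, m]})
        assert list(out) == ["d2"]


class TestScanSites:
    def test_exact_match_both_strands(self):
        pswm = PSWM.from_sites(["ACGT"] * 50, pseudocount=0.0001)
        hits = scan_sites(pswm, ["TTACGTTT"], score_fraction=1.0)
        assert len(hits) == 1
        assert (hits[0].offset, hits[0].strand) == (2, "+")
        # strand handling: a non-palindromic motif found on the minus strand
        pswm2 = PSWM.from_sites(["AACC"] * 50, pseudocount=0.0001)
        hits2 = scan_sites(pswm2, ["TTGGTTTT"], 1.0)
        assert len(hits2) == 1
        assert hits2[0].strand == "-"
        assert hits2[0].seq == "AACC"

    def test_absent_consensus_empty(self):
        pswm = PSWM.from_sites(["ACGTAC"] * 10, pseudocount=0.0001)
        assert scan_sites(pswm, ["GGGGGGGGGG"], 1.0) == []

    def test_uniform_pswm_tie_resolved_leftmost(self):
        pswm = PSWM.from_freqs(np.full((4, 4), 0.25))
        hits = scan_sites(pswm, ["ACGTACGTACGT"], score_fraction=1.0)
        # every window ties at score 0 -> greedy keeps non-overlapping
        # leftmost windows: offsets 0, 4, 8
        assert [h.offset for h in hits] == [0, 4, 8]

    def test_smoothed_scan_tolerates_one_substitution(self):
        sites = ["TGACGTCA"] * 100
        pswm = PSWM.from_sites(sites).smoothed(0.04)
        seqs = ["AATGACGTCAAA", "AATGACGGCAAA", "AATGAAGGCAAA"]  # 0, 1, 2 subs
        got = [len(scan_sites(pswm, [s], 0.5)) for s in seqs]
        assert got == [1, 1, 0]


class TestAttachScanSupport:
    def test_support_from_scan_sites_keeps_site_list(self):
        ds, genome, _ = planted_dataset(n_peaks=100, frac=0.6)
        motifs = find_motifs(ds, genome, DiscoveryConfig(seed=3, max_motifs=1))
        refined = attach_scan_support(motifs[0], ds, genome)
        assert refined.support > 0
        # scan support is a superset of exact-pattern support: the scan
        # tolerates substitutions the pattern match does not
        exact_support = frozenset(s.peak_id for s in motifs[0].sites)
        assert len(refined.peak_ids) >= len(exact_support & refined.peak_ids)
        # the projectable site list is unchanged
        assert refined.sites == motifs[0].sites
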