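"""Discriminative motif discovery against a Markov-shuffled negative set.

The finder follows the DREME recipe: enumerate exact words over a range of
widths on both strands, score peak-level presence in positives versus
negatives with a one-sided Fisher exact test, generalize the best seeds by
one degenerate IUPAC position, accept the best candidate when its E-value
(p times the number of candidates tested) clears the threshold, collect and
mask its sites, and repeat. Counting is vectorized over integer-encoded
k-mers, so whole datasets are rescanned cheaply after masking.
"""
from __future__ import annotations

import logging
from dataclasses import dataclass, field
from typing import Optional, Sequence

import numpy as np
from scipy.special import gammaln

from .genome import Genome, reverse_complement
from .intervals import GenomicInterval
from .peaks import Dataset
from .pswm import BASES, PSWM

log = logging.getLogger(__name__)

_ENC = np.full(256, 4, dtype=np.uint8)
for _i, _b in enumerate("ACGT"):
    _ENC[ord(_b)] = _i
    _ENC[ord(_b.lower())] = _i

_IUPAC = {
    frozenset("A"): "A", frozenset("C"): "C", frozenset("G"): "G", frozenset("T"): "T",
    frozenset("AC"): "M", frozenset("AG"): "R", frozenset("AT"): "W",
    frozenset("CG"): "S", frozenset("CT"): "Y", frozenset("GT"): "K",
    frozenset("ACG"): "V", frozenset("ACT"): "H", frozenset("AGT"): "D",
    frozenset("CGT"): "B", frozenset("ACGT"): "N",
}


def encode(seq: str) -> np.ndarray:
    return _ENC[np.frombuffer(seq.encode("ascii"), dtype=np.uint8)]


def decode(codes: np.ndarray) -> str:
    return "".join("ACGTN"[c] for c in codes)


@dataclass(frozen=True)
class Site:
    peak_id: str
    interval: GenomicInterval
    strand: str
    seq: str


@dataclass
class Motif:
    """A discovered motif: PSWM plus its genomic sites within one dataset.

    ``support_peak_ids``, when set, restricts the supporting-peak notion to
    peaks whose *original* (unpadded) interval contains a site; co-occurrence
    statistics then reflect binding evidence rather than padded context.
    """

    motif_id: str
    dataset_id: str
    pswm: PSWM
    sites: list[Site]
    consensus: str = ""
    evalue: float = float("nan")
    support_peak_ids: Optional[frozenset] = None
    # substitution-tolerant scan hits (binding evidence); used for overlap
    # assessment where the exact pattern sites would miss mutated instances
    evidence_sites: Optional[list[Site]] = None

    @property
    def support(self) -> int:
        """Number of distinct supporting peaks."""
        return len(self.peak_ids)

    @property
    def peak_ids(self) -> frozenset:
        if self.support_peak_ids is not None:
            return self.support_peak_ids
        return frozenset(s.peak_id for s in self.sites)


@dataclass(frozen=True)
class DiscoveryConfig:
    # minimum core width 8: on kilobase-scale extended peaks the peak-level
    # presence of words shorter than ~8 bp saturates, which breaks the
    # Fisher enrichment test (every peak contains every short word)
    widths: tuple = tuple(range(8, 13))
    evalue_threshold: float = 0.05
    max_motifs: int = 100
    markov_order: int = 3
    seed: int = 0
    pseudocount: float = 0.25
    n_seeds_per_width: int = 2  # exact words taken forward to generalization
    # specificity guard: candidates present in more than this fraction of the
    # *negative* set match background too promiscuously to be TF sites
    max_negative_presence: float = 1 / 3

    def __post_init__(self) -> None:
        if min(self.widths) < 4:
            raise ValueError("word widths must be >= 4")
        if self.evalue_threshold <= 0:
            raise ValueError("E-value threshold must be > 0")


# ---------------------------------------------------------------------------
# Markov negative set
# ---------------------------------------------------------------------------
def markov_negative_set(seqs: Sequence[str], order: int, seed: int) -> list[str]:
    """One Markov-generated negative per positive, same lengths.

    Transition probabilities of the given order are estimated from the
    positive set with +1 smoothing; lower-order models seed the first
    characters. Sequences shorter than order+1 are copied verbatim.
    """
    if not seqs:
        raise ValueError("empty sequence list")
    if order < 0:
        raise ValueError("order must be >= 0")
    rng = np.random.default_rng(seed)

    # transition counts for orders 0..order, contexts as base-4 codes
    counts = [np.ones((4**k, 4)) for k in range(order + 1)]
    for seq in seqs:
        codes = encode(seq)
        n = len(codes)
        for k in range(order + 1):
            if n < k + 1:
                continue
            # valid windows: no N in context+next
            win_ok = np.ones(n - k, dtype=bool)
            for j in range(k + 1):
                win_ok &= codes[j : n - k + j] < 4
            if not win_ok.any():
                continue
            ctx = np.zeros(n - k, dtype=np.int64)
            for j in range(k):
                ctx = ctx * 4 + codes[j : n - k + j]
            nxt = codes[k:n]
            np.add.at(counts[k], (ctx[win_ok], nxt[win_ok]), 1)

    # plain nested lists + manual threshold comparison: the per-character
    # work is sequential, so scalar numpy calls would dominate the runtime
    cum = [
        (c / c.sum(axis=1, keepdims=True)).cumsum(axis=1)[:, :3].tolist()
        for c in counts
    ]
    mod = 4**order if order > 0 else 1
    out: list[str] = []
    for seq in seqs:
        n = len(seq)
        if n < order + 1:
            log.warning("sequence of length %d shorter than order+1; copied verbatim", n)
            out.append(seq)
            continue
        draws = rng.random(n).tolist()
        gen: list[int] = []
        table = cum[order]
        ctx = 0
        for i in range(n):
            if i < order:
                k = i
                ctx_i = 0
                for j in range(k):
                    ctx_i = ctx_i * 4 + gen[i - k + j]
                row = cum[k][ctx_i]
            else:
                row = table[ctx]
            u = draws[i]
            if u < row[0]:
                b = 0
            elif u < row[1]:
                b = 1
            elif u < row[2]:
                b = 2
            else:
                b = 3
            gen.append(b)
            if order > 0:
                ctx = (ctx * 4 + b) % mod
        out.append("".join("ACGT"[b] for b in gen))
    return out


# ---------------------------------------------------------------------------
# vectorized word counting
# ---------------------------------------------------------------------------
def _unique_sorted(arr: np.ndarray) -> np.ndarray:
    """Sorted distinct values (sort-based; avoids hashing overhead)."""
    if len(arr) == 0:
        return arr
    s = np.sort(arr)
    keep = np.empty(len(s), dtype=bool)
    keep[0] = True
    np.not_equal(s[1:], s[:-1], out=keep[1:])
    return s[keep]


def _counts_by_code(pairs: np.ndarray, n_seqs: int) -> tuple[np.ndarray, np.ndarray]:
    """Given sorted unique (code*n_seqs+seq) pairs, per-code presence counts."""
    if len(pairs) == 0:
        z = np.zeros(0, dtype=np.int64)
        return z, z
    codes = pairs // n_seqs
    boundary = np.flatnonzero(np.concatenate([[True], codes[1:] != codes[:-1]]))
    counts = np.diff(np.concatenate([boundary, [len(codes)]]))
    return codes[boundary], counts


class _SeqBank:
    """Integer-encoded concatenation of one sequence set with bookkeeping."""

    def __init__(self, seqs: Sequence[str]):
        self.n_seqs = len(seqs)
        self.lengths = np.array([len(s) for s in seqs], dtype=np.int64)
        parts = []
        for s in seqs:
            parts.append(encode(s))
            parts.append(np.array([4], dtype=np.uint8))  # separator
        self.codes = np.concatenate(parts) if parts else np.zeros(0, np.uint8)
        self.starts = np.concatenate(
            [[0], np.cumsum(self.lengths + 1)[:-1]]
        ).astype(np.int64) if self.n_seqs else np.zeros(0, np.int64)
        self.seq_of_pos = np.repeat(np.arange(self.n_seqs), self.lengths + 1)

    def word_presence(self, w: int) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
        """Either-strand peak-presence of all width-w words.

        Returns (codes, pos_counts, pairs_by_code) where ``codes`` are the
        distinct word codes present in >= 1 sequence, ``pos_counts`` the
        number of sequences containing each (on either strand), and
        ``pairs_by_code`` the sorted array of code * n_seqs + seq for
        presence lookups of individual words.
        """
        pairs = self._pairs(w)
        codes, counts = _counts_by_code(pairs, self.n_seqs)
        return codes, counts, pairs

    def _pairs(self, w: int, region: Optional[tuple[int, int]] = None) -> np.ndarray:
        """Sorted unique code*n_seqs+seq presence pairs for width w, over
        the whole concatenation or a [start, end) slice of it."""
        lo, hi = (0, len(self.codes)) if region is None else region
        n = hi - lo - w + 1
        if n <= 0:
            return np.zeros(0, dtype=np.int64)
        s = self.codes[lo:hi].astype(np.int64)
        fcode = np.zeros(n, dtype=np.int64)
        rcode = np.zeros(n, dtype=np.int64)
        valid = np.ones(n, dtype=bool)
        pw = 1
        for j in range(w):
            col = s[j : j + n]
            fcode = fcode * 4 + col
            rcode = rcode + (3 - col) * pw
            pw *= 4
            valid &= col < 4
        fcode = fcode[valid]
        rcode = rcode[valid]
        seqs = self.seq_of_pos[lo : lo + n][valid]
        pairs = np.concatenate([fcode * self.n_seqs + seqs, rcode * self.n_seqs + seqs])
        return _unique_sorted(pairs)

    def pairs_for_seqs(self, w: int, seq_ids: Sequence[int]) -> np.ndarray:
        """Presence pairs restricted to the given sequences (one pass)."""
        if len(seq_ids) == 0:
            return np.zeros(0, dtype=np.int64)
        code_chunks = []
        seq_chunks = []
        for sid in seq_ids:
            lo = int(self.starts[sid])
            hi = lo + int(self.lengths[sid]) + 1  # include trailing separator
            code_chunks.append(self.codes[lo:hi])
            seq_chunks.append(self.seq_of_pos[lo:hi])
        codes = np.concatenate(code_chunks).astype(np.int64)
        seqs_map = np.concatenate(seq_chunks)
        n = len(codes) - w + 1
        if n <= 0:
            return np.zeros(0, dtype=np.int64)
        fcode = np.zeros(n, dtype=np.int64)
        rcode = np.zeros(n, dtype=np.int64)
        valid = np.ones(n, dtype=bool)
        pw = 1
        for j in range(w):
            col = codes[j : j + n]
            fcode = fcode * 4 + col
            rcode = rcode + (3 - col) * pw
            pw *= 4
            valid &= col < 4
        # windows spanning two sequences are killed by the separators
        fcode = fcode[valid]
        rcode = rcode[valid]
        seqs = seqs_map[:n][valid]
        pairs = np.concatenate([fcode * self.n_seqs + seqs, rcode * self.n_seqs + seqs])
        return _unique_sorted(pairs)

    def peaks_with_word(self, pairs_by_code: np.ndarray, code: int) -> np.ndarray:
        lo = np.searchsorted(pairs_by_code, code * self.n_seqs)
        hi = np.searchsorted(pairs_by_code, (code + 1) * self.n_seqs)
        return pairs_by_code[lo:hi] % self.n_seqs

    def match_pattern(self, allowed: np.ndarray) -> np.ndarray:
        """Start positions (in the concatenation) matching a (w, 5) pattern."""
        w = allowed.shape[0]
        L = len(self.codes)
        n = L - w + 1
        if n <= 0:
            return np.zeros(0, dtype=np.int64)
        acc = allowed[0][self.codes[:n]]
        for j in range(1, w):
            acc &= allowed[j][self.codes[j : j + n]]
        return np.nonzero(acc)[0]


@dataclass
class _Pattern:
    """An IUPAC word: per-position allowed bases as a (w, 5) boolean table."""

    allowed: np.ndarray  # (w, 5), column 4 (N in sequence) always False

    @classmethod
    def from_code(cls, code: int, w: int) -> "_Pattern":
        allowed = np.zeros((w, 5), dtype=bool)
        for j in range(w - 1, -1, -1):
            allowed[j, code % 4] = True
            code //= 4
        return cls(allowed)

    def generalized(self, pos: int, bases: Sequence[int]) -> "_Pattern":
        allowed = self.allowed.copy()
        allowed[pos, :4] = False
        for b in bases:
            allowed[pos, b] = True
        return _Pattern(allowed)

    def reverse_complement(self) -> "_Pattern":
        allowed = np.zeros_like(self.allowed)
        w = self.allowed.shape[0]
        for j in range(w):
            for b in range(4):
                allowed[j, b] = self.allowed[w - 1 - j, 3 - b]
        return _Pattern(allowed)

    def iupac(self) -> str:
        out = []
        for j in range(self.allowed.shape[0]):
            letters = frozenset(BASES[b] for b in range(4) if self.allowed[j, b])
            out.append(_IUPAC[letters])
        return "".join(out)

    def variant_codes(self) -> list[int]:
        """All exact word codes matching the pattern (product over positions)."""
        codes = [0]
        for j in range(self.allowed.shape[0]):
            opts = [b for b in range(4) if self.allowed[j, b]]
            codes = [c * 4 + b for c in codes for b in opts]
        return codes


def _fisher_logp(
    pos_k: np.ndarray, neg_k: np.ndarray, n_pos: int, n_neg: int, max_terms: int = 128
) -> np.ndarray:
    """One-sided Fisher exact (enrichment) natural-log p, vectorized.

    P(X >= k) for X hypergeometric(N, K, n) is summed directly from the
    log-pmf with a multiplicative term recursion. The sum is truncated at
    ``max_terms`` with a geometric-series bound added for the remainder;
    for enriched candidates (the only ones whose exact value matters) the
    pmf decays fast and the truncation is far below float precision.
    """
    k = np.asarray(pos_k, dtype=np.int64)
    K = k + np.asarray(neg_k, dtype=np.int64)
    N = n_pos + n_neg
    n = n_pos
    upper = np.minimum(K, n)

    def logpmf(j: np.ndarray) -> np.ndarray:
        j = np.asarray(j, dtype=np.float64)
        return (
            gammaln(K + 1) - gammaln(j + 1) - gammaln(K - j + 1)
            + gammaln(N - K + 1) - gammaln(n - j + 1) - gammaln(N - K - n + j + 1)
            - (gammaln(N + 1) - gammaln(n + 1) - gammaln(N - n + 1))
        )

    total = np.where(k <= 0, 0.0, -np.inf)  # P = 1 when k <= 0
    cur = np.where((k > 0) & (k <= upper), logpmf(np.maximum(k, 0)), -np.inf)
    j = k.astype(np.float64)
    last_ratio = np.zeros_like(cur)
    for _ in range(max_terms):
        total = np.logaddexp(total, cur)
        with np.errstate(divide="ignore", invalid="ignore"):
            ratio = ((K - j) * (n - j)) / ((j + 1) * (N - K - n + j + 1))
        active = (j < upper) & np.isfinite(cur)
        ratio = np.where(active & (ratio > 0), ratio, 0.0)
        last_ratio = ratio
        with np.errstate(divide="ignore"):
            cur = np.where(ratio > 0, cur + np.log(ratio), -np.inf)
        j = j + 1
        if not np.any(np.isfinite(cur)):
            break
    else:
        # geometric remainder bound for still-active elements
        r = np.clip(last_ratio, 0.0, 0.999999)
        with np.errstate(divide="ignore", invalid="ignore"):
            rem = np.where(
                np.isfinite(cur) & (r > 0), cur + np.log(r / (1.0 - r)), -np.inf
            )
        total = np.logaddexp(total, rem)
    return np.minimum(total, 0.0)


def find_motifs(
    dataset: Dataset,
    genome: Genome,
    cfg: DiscoveryConfig = DiscoveryConfig(),
    negatives: Optional[Sequence[str]] = None,
) -> list[Motif]:
    """Greedy discriminative discovery of motifs in one extended dataset.

    Returns motifs in discovery order (rank 1 first). Deterministic given
    (dataset, seed, config).
    """
    if not dataset.peaks:
        return []
    pos_seqs = [genome.fetch(p.extended) for p in dataset.peaks]
    if negatives is None:
        negatives = markov_negative_set(pos_seqs, cfg.markov_order, cfg.seed)
    neg_bank = _SeqBank(negatives)
    pos_bank = _SeqBank(pos_seqs)
    n_pos, n_neg = pos_bank.n_seqs, neg_bank.n_seqs

    neg_cache = {w: neg_bank.word_presence(w) for w in cfg.widths}

    def presence(bank_pairs: np.ndarray, nseq: int, pat: _Pattern) -> int:
        codes = pat.variant_codes()
        bounds = np.empty(2 * len(codes), dtype=np.int64)
        for i, code in enumerate(codes):
            bounds[2 * i] = code * nseq
            bounds[2 * i + 1] = (code + 1) * nseq
        pos = np.searchsorted(bank_pairs, bounds)
        peaks = [bank_pairs[pos[2 * i] : pos[2 * i + 1]] % nseq for i in range(len(codes))]
        return len(_unique_sorted(np.concatenate(peaks))) if peaks else 0

    # incrementally maintained positive presence index per width
    pos_pairs: dict[int, np.ndarray] = {w: pos_bank._pairs(w) for w in cfg.widths}

    def update_pos_pairs(changed: Sequence[int]) -> None:
        if not changed:
            return
        ch = sorted(set(changed))
        flag = np.zeros(n_pos, dtype=bool)
        flag[ch] = True
        for w in cfg.widths:
            old = pos_pairs[w]
            keep = ~flag[old % n_pos]
            fresh = pos_bank.pairs_for_seqs(w, ch)
            merged = np.concatenate([old[keep], fresh])
            merged.sort()
            pos_pairs[w] = merged

    motifs: list[Motif] = []
    while len(motifs) < cfg.max_motifs:
        best = None  # (logp, iupac, width, _Pattern)
        n_candidates = 0
        seeds: list[tuple[float, int, int]] = []  # (logp, width, code)
        pos_cache = {}
        for w in cfg.widths:
            p_pairs = pos_pairs[w]
            p_codes, p_cnt = _counts_by_code(p_pairs, n_pos)
            pos_cache[w] = p_pairs
            if len(p_codes) == 0:
                continue
            ncodes, ncnt_all, _ = neg_cache[w]
            if len(ncodes):
                idx = np.searchsorted(ncodes, p_codes).clip(0, len(ncodes) - 1)
                ncnt = np.where(ncodes[idx] == p_codes, ncnt_all[idx], 0)
            else:
                ncnt = np.zeros(len(p_codes), dtype=np.int64)
            # cheap enrichment prefilter, then exact Fisher on the shortlist
            crude = p_cnt * n_neg - ncnt * n_pos
            n_short = min(2000, len(p_codes))
            short = np.argpartition(-crude, n_short - 1)[:n_short]
            specific = ncnt[short] <= cfg.max_negative_presence * n_neg
            short = short[specific]
            if len(short) == 0:
                continue
            # E-value corrects for every enumerated word; the prefilter only
            # skips exact scoring of words that cannot win
            n_candidates += len(p_codes)
            logp = _fisher_logp(p_cnt[short], ncnt[short], n_pos, n_neg)
            k = min(cfg.n_seeds_per_width, len(logp))
            for si in np.lexsort((p_codes[short], logp))[:k]:
                code = int(p_codes[short][si])
                seeds.append((float(logp[si]), w, code))
                pat = _Pattern.from_code(code, w)
                cand = (float(logp[si]), pat.iupac(), w, pat)
                if best is None or (cand[0], cand[1]) < (best[0], best[1]):
                    best = cand
        if best is None:
            break

        # single-position IUPAC generalizations of each width's best seeds,
        # scored in one batched Fisher call
        gen_pats: list[tuple[int, _Pattern]] = []
        gen_pk: list[int] = []
        gen_nk: list[int] = []
        for seed_logp, w, code in seeds:
            base_pat = _Pattern.from_code(code, w)
            p_pairs = pos_cache[w]
            n_pairs = neg_cache[w][2]
            for pos in range(w):
                orig = int(np.nonzero(base_pat.allowed[pos, :4])[0][0])
                others = [b for b in range(4) if b != orig]
                subsets = (
                    [[orig, b] for b in others]
                    + [[orig, others[0], others[1]], [orig, others[0], others[2]],
                       [orig, others[1], others[2]]]
                    + [[0, 1, 2, 3]]
                )
                for bases in subsets:
                    pat = base_pat.generalized(pos, bases)
                    nk = presence(n_pairs, n_neg, pat)
                    if nk > cfg.max_negative_presence * n_neg:
                        continue  # specificity guard
                    gen_pats.append((w, pat))
                    gen_pk.append(presence(p_pairs, n_pos, pat))
                    gen_nk.append(nk)
        if gen_pats:
            n_candidates += len(gen_pats)
            gen_logp = _fisher_logp(np.array(gen_pk), np.array(gen_nk), n_pos, n_neg)
            for (w, pat), lp in zip(gen_pats, gen_logp):
                if (float(lp), pat.iupac()) < (best[0], best[1]):
                    best = (float(lp), pat.iupac(), w, pat)

        log_e = best[0] + np.log(n_candidates)
        if log_e >= np.log(cfg.evalue_threshold):
            break

        # collect sites of the accepted pattern in positives
        pat = best[3]
        w = best[2]
        fwd = pos_bank.match_pattern(pat.allowed)
        rev = pos_bank.match_pattern(pat.reverse_complement().allowed)
        taken = set(fwd.tolist())
        hits = [(int(p), "+") for p in fwd] + [
            (int(p), "-") for p in rev if int(p) not in taken
        ]
        if not hits:  # numerically impossible, but stay safe
            break
        hits.sort()
        # extract all site sequences before masking any of them
        extracted = []
        for posn, strand in hits:
            seq_idx = int(pos_bank.seq_of_pos[posn])
            off = posn - int(pos_bank.starts[seq_idx])
            raw = decode(pos_bank.codes[posn : posn + w])
            extracted.append((posn, strand, seq_idx, off, raw))
        sites: list[Site] = []
        site_seqs: list[str] = []
        for posn, strand, seq_idx, off, raw in extracted:
            peak = dataset.peaks[seq_idx]
            ext = peak.extended
            if ext.strand == "-":
                # fetched sequence was reverse-complemented: map back
                g_start = ext.end - off - w
                g_strand = "-" if strand == "+" else "+"
            else:
                g_start = ext.start + off
                g_strand = strand
            iv = GenomicInterval(ext.chrom, g_start, g_start + w, g_strand)
            sseq = raw if strand == "+" else reverse_complement(raw)
            sites.append(Site(peak.peak_id, iv, g_strand, sseq))
            site_seqs.append(sseq)
            pos_bank.codes[posn : posn + w] = 4  # mask
        update_pos_pairs([seq_idx for _, _, seq_idx, _, _ in extracted])

        rank = len(motifs) + 1
        pswm = PSWM.from_sites(site_seqs, pseudocount=cfg.pseudocount,
                               name=f"{dataset.dataset_id}.m{rank}")
        motifs.append(
            Motif(
                motif_id=f"{dataset.dataset_id}.m{rank}",
                dataset_id=dataset.dataset_id,
                pswm=pswm,
                sites=sites,
                consensus=best[1],
                evalue=float(np.exp(min(log_e, 700.0))),
            )
        )
    return motifs


def apply_dataset_qc(motifs_per_dataset: dict) -> dict:
    """Drop datasets yielding fewer than 2 motifs (they cannot form a pair)."""
    kept = {k: v for k, v in motifs_per_dataset.items() if len(v) >= 2}
    dropped = sorted(set(motifs_per_dataset) - set(kept))
    if dropped:
        log.info("QC dropped %d datasets with <2 motifs: %s", len(dropped), dropped)
    return kept


@dataclass(frozen=True)
class ScanHit:
    seq_index: int
    offset: int
    strand: str
    score: float
    seq: str


def scan_sites(
    pswm: PSWM, seqs: Sequence[str], score_fraction: float
) -> list[ScanHit]:
    """Scan both strands with the PSWM log-odds against the scanned set's
    base composition; report windows scoring >= score_fraction * max score.

    Overlapping hits are resolved to the higher-scoring one (ties: leftmost,
    then '+' strand). Windows containing N are skipped.
    """
    if not (0 < score_fraction <= 1):
        raise ValueError("score_fraction must be in (0, 1]")
    bank = _SeqBank(seqs)
    counts = np.bincount(bank.codes, minlength=5)[:4].astype(float)
    if counts.sum() == 0:
        return []
    bg = (counts + 1.0) / (counts.sum() + 4.0)  # add-one smoothed background
    bg = 0.5 * (bg + bg[::-1])  # strand-symmetric (A~T, C~G)
    w = pswm.width
    lo_f = np.vstack([pswm.log_odds(bg), np.full((1, w), -np.inf)])  # row 4 = N
    lo_r = np.vstack([pswm.reverse_complement().log_odds(bg), np.full((1, w), -np.inf)])
    max_score = lo_f[:4].max(axis=0).sum()
    thr = score_fraction * max_score - 1e-9  # tolerate float accumulation order

    L = len(bank.codes)
    n = L - w + 1
    if n <= 0:
        return []
    score_f = np.zeros(n)
    score_r = np.zeros(n)
    for j in range(w):
        col = bank.codes[j : j + n]
        score_f += lo_f[col, j]
        score_r += lo_r[col, j]
    cand = np.nonzero((score_f >= thr) | (score_r >= thr))[0]
    raw_hits: list[ScanHit] = []
    for posn in cand:
        sf, sr = score_f[posn], score_r[posn]
        strand, score = ("+", sf) if sf >= sr else ("-", sr)
        if score < thr:
            continue
        seq_idx = int(bank.seq_of_pos[posn])
        off = int(posn - bank.starts[seq_idx])
        raw = decode(bank.codes[posn : posn + w])
        raw_hits.append(ScanHit(seq_idx, off, strand, float(score),
                                raw if strand == "+" else reverse_complement(raw)))
    # resolve overlapping hits within the same sequence: best score, leftmost
    raw_hits.sort(key=lambda h: (-h.score, h.seq_index, h.offset, h.strand))
    chosen: list[ScanHit] = []
    occupied: dict[int, list[tuple[int, int]]] = {}
    for h in raw_hits:
        spans = occupied.setdefault(h.seq_index, [])
        if any(h.offset < e and s < h.offset + w for s, e in spans):
            continue
        spans.append((h.offset, h.offset + w))
        chosen.append(h)
    chosen.sort(key=lambda h: (h.seq_index, h.offset))
    return chosen


def attach_scan_support(
    motif: Motif,
    dataset: Dataset,
    genome: Genome,
    score_fraction: float = 0.5,
    rel_pseudocount: float = 0.04,
) -> Motif:
    """Attach substitution-tolerant supporting-peak evidence to a motif.

    The discovery pattern match is exact by construction and misses true
    sites carrying substitutions, which deflates peak-level co-occurrence
    statistics; scanning with a smoothed log-odds matrix at half the maximum
    score admits roughly one substitution in a sharp, information-rich motif
    while rejecting doubly-mutated windows. A peak supports the motif when a
    scan hit overlaps its *original* (unpadded) interval — binding evidence,
    not padded context. The motif's site list (used for genome projection)
    and its PSWM are left unchanged.
    """
    seqs = [genome.fetch(p.extended) for p in dataset.peaks]
    scan_pswm = motif.pswm.smoothed(rel_pseudocount)
    hits = scan_sites(scan_pswm, seqs, score_fraction)
    support: set[str] = set()
    evidence: list[Site] = []
    w = motif.pswm.width
    for h in hits:
        peak = dataset.peaks[h.seq_index]
        g_start = peak.extended.start + h.offset
        iv = GenomicInterval(peak.extended.chrom, g_start, g_start + w, h.strand)
        evidence.append(Site(peak.peak_id, iv, h.strand, h.seq))
        if iv.overlaps(peak.original):
            support.add(peak.peak_id)
    return Motif(
        motif_id=motif.motif_id,
        dataset_id=motif.dataset_id,
        pswm=motif.pswm,
        sites=motif.sites,
        consensus=motif.consensus,
        evalue=motif.evalue,
        support_peak_ids=frozenset(support),
        evidence_sites=evidence,
    )
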