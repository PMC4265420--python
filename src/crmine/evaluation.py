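"""Evaluation: known-CRM recovery, circular random baseline, conservation.

A known CRM counts as recovered when a single predicted CRM covers at
least half of its length. The random baseline concatenates the peak-covered
genome into a circle and drops same-length arcs uniformly at random, which
preserves both the number and the lengths of the predictions while
destroying their positions.
"""
from __future__ import annotations

import logging
from dataclasses import dataclass, field
from typing import Optional, Sequence, Union

import numpy as np
from scipy.stats import ks_2samp

from .assembly import CRM
from .intervals import AnnotationSet, ConservationTrack, GenomicInterval

log = logging.getLogger(__name__)

Footprint = list[GenomicInterval]  # one prediction, possibly split into pieces


@dataclass
class RecoveryReport:
    n_known: int
    n_recovered: int
    rate: float
    overlap_fractions: list[float]
    baseline_mean: Optional[float] = None
    baseline_sd: Optional[float] = None


def _footprints(predicted: Sequence[Union[CRM, GenomicInterval, Footprint]]) -> list[Footprint]:
    out: list[Footprint] = []
    for p in predicted:
        if isinstance(p, CRM):
            out.append([p.span])
        elif isinstance(p, GenomicInterval):
            out.append([p])
        else:
            out.append(list(p))
    return out


def recovery_rate(
    known: AnnotationSet,
    predicted: Sequence[Union[CRM, GenomicInterval, Footprint]],
    min_fraction: float = 0.5,
) -> RecoveryReport:
    """Half-length recovery: the best *single* prediction must cover at
    least ``min_fraction`` of the known CRM (max over predictions, never
    summed across them). Raises on an empty known set."""
    if len(known) == 0:
        raise ValueError("empty known-CRM set")
    preds = _footprints(predicted)
    # index prediction pieces per chromosome as sorted arrays for fast sweep
    by_chrom: dict[str, tuple[np.ndarray, np.ndarray, np.ndarray, int]] = {}
    tmp: dict[str, list[tuple[int, int, int]]] = {}
    n_pred = len(preds)
    for pi, fp in enumerate(preds):
        for iv in fp:
            tmp.setdefault(iv.chrom, []).append((iv.start, iv.end, pi))
    for chrom, pieces in tmp.items():
        pieces.sort()
        starts = np.array([p[0] for p in pieces], dtype=np.int64)
        ends = np.array([p[1] for p in pieces], dtype=np.int64)
        pis = np.array([p[2] for p in pieces], dtype=np.int64)
        max_len = int((ends - starts).max()) if len(starts) else 0
        by_chrom[chrom] = (starts, ends, pis, max_len)

    fractions: list[float] = []
    n_rec = 0
    for kiv in known:
        entry = by_chrom.get(kiv.chrom)
        best = 0
        if entry is not None:
            starts, ends, pis, max_len = entry
            lo = int(np.searchsorted(starts, kiv.start - max_len))
            hi = int(np.searchsorted(starts, kiv.end))
            if hi > lo:
                s = starts[lo:hi]
                e = ends[lo:hi]
                ov = np.minimum(e, kiv.end) - np.maximum(s, kiv.start)
                sel = ov > 0
                if sel.any():
                    per_pred = np.bincount(pis[lo:hi][sel], weights=ov[sel], minlength=n_pred)
                    best = int(per_pred.max())
        frac = best / kiv.length
        fractions.append(frac)
        if best >= min_fraction * kiv.length:
            n_rec += 1
    return RecoveryReport(
        n_known=len(known),
        n_recovered=n_rec,
        rate=n_rec / len(known),
        overlap_fractions=fractions,
    )


# ---------------------------------------------------------------------------
# circular random baseline
# ---------------------------------------------------------------------------
def circular_random_baseline(
    predicted: Sequence[Union[CRM, GenomicInterval, Footprint]],
    covered: AnnotationSet,
    known: AnnotationSet,
    n_reps: int = 50,
    seed: int = 0,
    min_fraction: float = 0.5,
) -> tuple[float, float, list[float]]:
    """Recovery rate of same-length random arcs on the circularized covered
    sequence; returns (mean, sd, per-repetition rates)."""
    segments = covered.merged().intervals
    seg_lens = np.array([iv.length for iv in segments], dtype=np.int64)
    if len(seg_lens) == 0:
        raise ValueError("covered region set is empty")
    circle = int(seg_lens.sum())
    lengths = [sum(iv.length for iv in fp) for fp in _footprints(predicted)]
    if not lengths:
        raise ValueError("no predictions")
    if max(lengths) > circle:
        raise ValueError("covered sequence shorter than the longest prediction")
    bounds = np.concatenate([[0], np.cumsum(seg_lens)])
    rng = np.random.default_rng(seed)
    rates: list[float] = []
    for _ in range(n_reps):
        starts = rng.integers(0, circle, size=len(lengths))
        arcs: list[Footprint] = []
        for s, ln in zip(starts, lengths):
            pieces: Footprint = []
            remaining = ln
            pos = int(s)
            while remaining > 0:
                pos %= circle
                seg_i = int(np.searchsorted(bounds, pos, side="right") - 1)
                seg = segments[seg_i]
                off = pos - int(bounds[seg_i])
                take = min(remaining, seg.length - off)
                pieces.append(
                    GenomicInterval(seg.chrom, seg.start + off, seg.start + off + take)
                )
                remaining -= take
                pos += take
            arcs.append(pieces)
        rates.append(recovery_rate(known, arcs, min_fraction).rate)
    return float(np.mean(rates)), float(np.std(rates, ddof=1) if n_reps > 1 else 0.0), rates


# ---------------------------------------------------------------------------
# conservation comparison
# ---------------------------------------------------------------------------
@dataclass
class ConservationReport:
    region_means: list[float]
    random_means: list[float]
    n_excluded: int
    ks_statistic: float
    ks_pvalue: float
    n_highly_conserved: int  # mean >= 0.98
    n_non_conserved: int  # mean <= 0.02


def sample_matched_regions(
    lengths: Sequence[int],
    pool: AnnotationSet,
    rng: np.random.Generator,
) -> list[GenomicInterval]:
    """Random regions with the given lengths drawn from the pool, each lying
    fully inside one pool segment; segments are chosen with probability
    proportional to the number of valid start positions."""
    segments = pool.merged().intervals
    out = []
    for ln in lengths:
        slots = np.array([max(0, iv.length - ln + 1) for iv in segments], dtype=float)
        total = slots.sum()
        if total == 0:
            raise ValueError(f"no pool segment can hold a region of length {ln}")
        seg = segments[int(rng.choice(len(segments), p=slots / total))]
        start = int(rng.integers(0, seg.length - ln + 1))
        out.append(GenomicInterval(seg.chrom, seg.start + start, seg.start + start + ln))
    return out


def conservation_compare(
    regions: Sequence[GenomicInterval],
    track: ConservationTrack,
    pool: AnnotationSet,
    n_reps: int = 1,
    seed: int = 0,
    conserved_threshold: float = 0.98,
    nonconserved_threshold: float = 0.02,
) -> ConservationReport:
    """Compare mean conservation of the regions with same-number,
    same-length random selections from ``pool``.

    Regions fully uncovered by the track are excluded (counted). The two
    mean-score samples are compared with a two-sample KS test."""
    rng = np.random.default_rng(seed)
    region_means: list[float] = []
    n_excluded = 0
    kept_lengths: list[int] = []
    for iv in regions:
        m = track.mean(iv)
        if m is None:
            n_excluded += 1
            continue
        region_means.append(m)
        kept_lengths.append(iv.length)
    if n_excluded:
        log.info("conservation_compare: %d regions fully uncovered, excluded", n_excluded)
    random_means: list[float] = []
    for _ in range(max(1, n_reps)):
        for riv in sample_matched_regions(kept_lengths, pool, rng):
            m = track.mean(riv)
            if m is not None:
                random_means.append(m)
    if region_means and random_means:
        ks = ks_2samp(region_means, random_means)
        stat, pval = float(ks.statistic), float(ks.pvalue)
    else:
        stat, pval = float("nan"), float("nan")
    arr = np.asarray(region_means)
    return ConservationReport(
        region_means=region_means,
        random_means=random_means,
        n_excluded=n_excluded,
        ks_statistic=stat,
        ks_pvalue=pval,
        n_highly_conserved=int((arr >= conserved_threshold).sum()) if len(arr) else 0,
        n_non_conserved=int((arr <= nonconserved_threshold).sum()) if len(arr) else 0,
    )
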