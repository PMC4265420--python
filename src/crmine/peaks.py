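"""Per-dataset binding-peak filtering, extension and overlap scoring.

Peaks shorter than the extension target are padded equally on both ends so
that motif search sees the likely CRM context around each summit region;
padding on a side stops at the distal edge of the first exon it reaches and
at chromosome ends. Over-long peaks are discarded outright.
"""
from __future__ import annotations

import logging
from dataclasses import dataclass, replace
from typing import Optional, Sequence

from .genome import Genome
from .intervals import AnnotationSet, GenomicInterval

log = logging.getLogger(__name__)


@dataclass(frozen=True)
class Peak:
    """One binding peak: the original call and its extended interval."""

    peak_id: str
    dataset_id: str
    original: GenomicInterval
    extended: GenomicInterval
    is_signal: Optional[bool] = None  # ground-truth label for synthetic data

    def __post_init__(self) -> None:
        if not self.extended.contains(self.original):
            raise ValueError(f"peak {self.peak_id}: original not within extended")


@dataclass
class Dataset:
    """All peaks of one ChIP dataset for one TF."""

    dataset_id: str
    tf_name: str
    peaks: list[Peak]
    provenance: str = ""

    def __post_init__(self) -> None:
        ids = [p.peak_id for p in self.peaks]
        if len(ids) != len(set(ids)):
            raise ValueError(f"dataset {self.dataset_id}: duplicate peak ids")

    def __len__(self) -> int:
        return len(self.peaks)

    @classmethod
    def from_intervals(
        cls,
        dataset_id: str,
        tf_name: str,
        intervals: Sequence[GenomicInterval],
        labels: Optional[Sequence[bool]] = None,
    ) -> "Dataset":
        peaks = [
            Peak(
                peak_id=f"{dataset_id}:{i}",
                dataset_id=dataset_id,
                original=iv,
                extended=iv,
                is_signal=None if labels is None else labels[i],
            )
            for i, iv in enumerate(intervals)
        ]
        return cls(dataset_id, tf_name, peaks)


@dataclass(frozen=True)
class PrepConfig:
    extend_target: int = 3000
    max_peak_len: int = 5000

    def __post_init__(self) -> None:
        if not (0 < self.extend_target <= self.max_peak_len):
            raise ValueError("require 0 < extend_target <= max_peak_len")


@dataclass
class PrepReport:
    dataset_id: str
    n_input: int = 0
    n_hot_removed: int = 0
    n_too_long: int = 0
    n_kept: int = 0


def filter_hot(dataset: Dataset, hot: AnnotationSet, report: Optional[PrepReport] = None) -> Dataset:
    """Drop peaks with >= 1 bp overlap with any high-occupancy-target region."""
    kept = [p for p in dataset.peaks if not hot.any_overlap(p.original)]
    n_removed = len(dataset.peaks) - len(kept)
    if n_removed:
        log.info("dataset %s: removed %d HOT-overlapping peaks", dataset.dataset_id, n_removed)
    if report is not None:
        report.n_hot_removed += n_removed
    return Dataset(dataset.dataset_id, dataset.tf_name, kept, dataset.provenance)


def extend_peaks(
    dataset: Dataset,
    genome: Genome,
    exons: AnnotationSet,
    cfg: PrepConfig = PrepConfig(),
    report: Optional[PrepReport] = None,
) -> Dataset:
    """Apply the length filter and the equal-padding extension rule.

    Peaks longer than ``max_peak_len`` are dropped (strictly longer; peaks
    of exactly that length are kept). Shorter-than-target peaks are padded
    equally on both ends up to ``extend_target``; a side's padding is
    truncated at the distal edge of the first exon it reaches and at
    chromosome ends, with no compensation on the opposite side.
    """
    out: list[Peak] = []
    n_too_long = 0
    for p in dataset.peaks:
        iv = p.original
        if iv.length > cfg.max_peak_len:
            n_too_long += 1
            continue
        if iv.length >= cfg.extend_target:
            out.append(replace(p, extended=iv))
            continue
        total_pad = cfg.extend_target - iv.length
        pad_left = total_pad // 2
        pad_right = total_pad - pad_left
        chrom_len = genome.chrom_length(iv.chrom)

        # left side
        lo = max(0, iv.start - pad_left)
        if iv.start > lo:
            hits = exons.overlapping(GenomicInterval(iv.chrom, lo, iv.start))
            if hits:
                # first exon reached going left = the one with the largest end
                first = max(hits, key=lambda h: (h.end, h.start))
                lo = max(lo, min(first.start, iv.start))
        # right side
        hi = min(chrom_len, iv.end + pad_right)
        if hi > iv.end:
            hits = exons.overlapping(GenomicInterval(iv.chrom, iv.end, hi))
            if hits:
                # first exon reached going right = the one with the smallest start
                first = min(hits, key=lambda h: (h.start, h.end))
                hi = min(hi, max(first.end, iv.end))
        out.append(replace(p, extended=GenomicInterval(iv.chrom, lo, hi, iv.strand)))
    if report is not None:
        report.n_too_long += n_too_long
        report.n_kept = len(out)
    if n_too_long:
        log.info("dataset %s: dropped %d peaks longer than %d bp",
                 dataset.dataset_id, n_too_long, cfg.max_peak_len)
    return Dataset(dataset.dataset_id, dataset.tf_name, out, dataset.provenance)


def overlap_score_matrix(datasets: Sequence[Dataset]):
    """Pairwise S_o matrix over extended datasets as a DataFrame, for
    export (e.g. hierarchical clustering of TFs by binding overlap)."""
    import pandas as pd

    ids = [d.dataset_id for d in datasets]
    n = len(datasets)
    mat = [[1.0] * n for _ in range(n)]
    for i in range(n):
        for j in range(i + 1, n):
            s = dataset_overlap_score(datasets[i], datasets[j])
            mat[i][j] = mat[j][i] = float("nan") if s is None else s
    return pd.DataFrame(mat, index=ids, columns=ids)


def dataset_overlap_score(a: Dataset, b: Dataset) -> Optional[float]:
    """Overlap score S_o between two extended datasets.

    S_o = o / min(|a|, |b|) where o is the number of peaks of the smaller
    dataset with >= 1 bp (extended) overlap with any peak of the other.
    Returns None for an empty dataset.
    """
    if not a.peaks or not b.peaks:
        return None
    small, big = (a, b) if len(a) <= len(b) else (b, a)
    big_set = AnnotationSet([p.extended for p in big.peaks], kind="peaks")
    o = sum(1 for p in small.peaks if big_set.any_overlap(p.extended))
    return o / len(small)
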