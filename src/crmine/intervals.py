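"""Core coordinate types: intervals, annotation sets and conservation tracks.

All coordinates are 0-based half-open internally; 1-based inclusive spans
appear only in human-readable reports.
"""
from __future__ import annotations

from dataclasses import dataclass
from typing import Iterable, Iterator, Optional, Sequence

import numpy as np
from intervaltree import IntervalTree


@dataclass(frozen=True, order=True)
class GenomicInterval:
    """A half-open genomic interval ``[start, end)`` on ``chrom``."""

    chrom: str
    start: int
    end: int
    strand: str = "."

    def __post_init__(self) -> None:
        if not (0 <= self.start < self.end):
            raise ValueError(
                f"invalid interval {self.chrom}:{self.start}-{self.end}: "
                "require 0 <= start < end"
            )
        if self.strand not in ("+", "-", "."):
            raise ValueError(f"invalid strand {self.strand!r}")

    @property
    def length(self) -> int:
        return self.end - self.start

    def overlaps(self, other: "GenomicInterval") -> bool:
        return (
            self.chrom == other.chrom
            and self.start < other.end
            and other.start < self.end
        )

    def overlap_bp(self, other: "GenomicInterval") -> int:
        if self.chrom != other.chrom:
            return 0
        return max(0, min(self.end, other.end) - max(self.start, other.start))

    def contains(self, other: "GenomicInterval") -> bool:
        return (
            self.chrom == other.chrom
            and self.start <= other.start
            and other.end <= self.end
        )

    def pretty(self) -> str:
        """1-based inclusive span for reports."""
        return f"{self.chrom}:{self.start + 1}..{self.end}"


@dataclass(frozen=True)
class Gene:
    gene_id: str
    chrom: str
    tss: int
    strand: str


class AnnotationSet:
    """A sorted, queryable collection of intervals of one region kind.

    ``kind`` labels what the set is (``"exon"``, ``"hot"``, ``"known_crm"``
    ...); ``genes`` carries (gene id, TSS, strand) records when the set was
    parsed from a gene annotation.
    """

    def __init__(
        self,
        intervals: Iterable[GenomicInterval],
        kind: str = "region",
        genes: Optional[Sequence[Gene]] = None,
        names: Optional[Sequence[str]] = None,
        scores: Optional[Sequence[float]] = None,
    ):
        ivs = list(intervals)
        idx = sorted(range(len(ivs)), key=lambda i: (ivs[i].chrom, ivs[i].start, ivs[i].end))
        self.intervals: list[GenomicInterval] = [ivs[i] for i in idx]
        self.names: Optional[list[str]] = [names[i] for i in idx] if names else None
        self.scores: Optional[list[float]] = [list(scores)[i] for i in idx] if scores is not None else None
        self.kind = kind
        self.genes: list[Gene] = list(genes) if genes else []
        self._trees: dict[str, IntervalTree] = {}
        for i, iv in enumerate(self.intervals):
            self._trees.setdefault(iv.chrom, IntervalTree()).addi(iv.start, iv.end, i)

    def __len__(self) -> int:
        return len(self.intervals)

    def __iter__(self) -> Iterator[GenomicInterval]:
        return iter(self.intervals)

    def overlapping(self, iv: GenomicInterval) -> list[GenomicInterval]:
        """All member intervals intersecting ``iv`` (>= 1 bp)."""
        tree = self._trees.get(iv.chrom)
        if tree is None:
            return []
        hits = sorted(tree.overlap(iv.start, iv.end), key=lambda h: (h.begin, h.end))
        return [self.intervals[h.data] for h in hits]

    def any_overlap(self, iv: GenomicInterval) -> bool:
        tree = self._trees.get(iv.chrom)
        return tree is not None and bool(tree.overlap(iv.start, iv.end))

    def total_bp(self) -> int:
        return sum(iv.length for iv in self.intervals)

    def merged(self) -> "AnnotationSet":
        """Union of the members: overlapping intervals collapsed."""
        out: list[GenomicInterval] = []
        for iv in self.intervals:
            if out and out[-1].chrom == iv.chrom and iv.start < out[-1].end:
                if iv.end > out[-1].end:
                    out[-1] = GenomicInterval(iv.chrom, out[-1].start, iv.end)
            else:
                out.append(GenomicInterval(iv.chrom, iv.start, iv.end))
        return AnnotationSet(out, kind=self.kind)


class ConservationTrack:
    """Per-base conservation scores in [0, 1]; uncovered bases are absent.

    Stored densely per chromosome with NaN marking uncovered positions,
    which is adequate for the genome sizes this package targets.
    """

    def __init__(self) -> None:
        self._chrom: dict[str, np.ndarray] = {}

    def set_scores(self, chrom: str, start: int, values: np.ndarray) -> None:
        values = np.asarray(values, dtype=float)
        if values.size and (np.nanmin(values) < 0 or np.nanmax(values) > 1):
            raise ValueError("conservation scores must lie in [0, 1]")
        end = start + len(values)
        arr = self._chrom.get(chrom)
        if arr is None or len(arr) < end:
            new = np.full(max(end, 2 * len(arr) if arr is not None else end), np.nan)
            if arr is not None:
                new[: len(arr)] = arr
            self._chrom[chrom] = arr = new
        arr[start:end] = values

    def covered_bp(self) -> int:
        return int(sum(np.count_nonzero(~np.isnan(a)) for a in self._chrom.values()))

    def mean(self, iv: GenomicInterval) -> Optional[float]:
        """Mean score over covered bases of ``iv``; None if none covered."""
        arr = self._chrom.get(iv.chrom)
        if arr is None:
            return None
        sl = arr[iv.start : min(iv.end, len(arr))]
        n = np.count_nonzero(~np.isnan(sl))
        if n == 0:
            return None
        return float(np.nansum(sl) / n)

    def values(self, iv: GenomicInterval) -> np.ndarray:
        arr = self._chrom.get(iv.chrom)
        if arr is None:
            return np.full(iv.length, np.nan)
        out = np.full(iv.length, np.nan)
        hi = min(iv.end, len(arr))
        if hi > iv.start:
            out[: hi - iv.start] = arr[iv.start : hi]
        return out


def merge_labelled_intervals(
    items: Sequence[tuple[GenomicInterval, frozenset]],
) -> list[tuple[GenomicInterval, frozenset]]:
    """Collapse overlapping labelled intervals into non-overlapping ones.

    Labels of contributing intervals are unioned. Half-open adjacency
    (gap 0) is *not* merged.
    """
    ordered = sorted(items, key=lambda t: (t[0].chrom, t[0].start, t[0].end))
    out: list[tuple[GenomicInterval, frozenset]] = []
    for iv, lab in ordered:
        if out:
            prev, plab = out[-1]
            if prev.chrom == iv.chrom and iv.start < prev.end:
                out[-1] = (
                    GenomicInterval(prev.chrom, prev.start, max(prev.end, iv.end)),
                    plab | lab,
                )
                continue
        out.append((iv, frozenset(lab)))
    return out
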