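"""Pairwise PSWM similarity.

The default metric aligns the two frequency matrices at every ungapped
offset (both orientations), scores each aligned column as one minus half
the L1 distance, and normalizes the best alignment's column-score sum by
the larger width, so identical motifs score exactly 1 and partial overlap
is penalized. The metric sits behind a name so alternatives can be added.
"""
from __future__ import annotations

from dataclasses import dataclass
from typing import Optional, Sequence

import numpy as np

from .pswm import PSWM


@dataclass(frozen=True)
class SimilarityConfig:
    """``column-l1-corrected`` (default) subtracts each pair's chance floor
    (the expected column score under random column pairing) and rescales so
    that ~0 means unrelated and 1 means identical; ``column-l1`` is the raw
    best-alignment column score. Identical motifs score exactly 1 in both.
    """

    metric: str = "column-l1-corrected"
    min_overlap: int = 4
    reverse_complement: bool = True

    def __post_init__(self) -> None:
        if self.min_overlap < 1:
            raise ValueError("min_overlap must be >= 1")


def _alignment_score(fm: np.ndarray, fn: np.ndarray, min_overlap: int) -> float:
    wm, wn = fm.shape[1], fn.shape[1]
    norm = max(wm, wn)
    best = 0.0
    for offset in range(-(wn - min_overlap), wm - min_overlap + 1):
        lo_m = max(0, offset)
        hi_m = min(wm, offset + wn)
        if hi_m - lo_m < min_overlap:
            continue
        a = fm[:, lo_m:hi_m]
        b = fn[:, lo_m - offset : hi_m - offset]
        col = 1.0 - 0.5 * np.abs(a - b).sum(axis=0)
        score = col.sum() / norm
        if score > best:
            best = score
    return best


def _shift_null(fm: np.ndarray, fn: np.ndarray, min_overlap: int) -> float:
    """Chance level of the raw best-alignment score for this pair.

    Cyclic column shifts preserve each motif's column composition while
    destroying the alignment, so the mean best-alignment score against the
    shifted decoys estimates what an unrelated motif of identical makeup
    would score — including the maximization-over-offsets bias that a
    per-column expectation misses.
    """
    scores = []
    wn = fn.shape[1]
    for c in range(1, wn):
        decoy = np.roll(fn, c, axis=1)
        scores.append(_alignment_score(fm, decoy, min_overlap))
    wm = fm.shape[1]
    for c in range(1, wm):
        decoy = np.roll(fm, c, axis=1)
        scores.append(_alignment_score(fn, decoy, min_overlap))
    return float(np.mean(scores)) if scores else 0.0


def motif_similarity(
    m: PSWM, n: PSWM, cfg: SimilarityConfig = SimilarityConfig()
) -> Optional[float]:
    """Similarity in [0, 1]; symmetric; 1 exactly for identical motifs.

    Returns None when either motif is narrower than the minimum overlap.
    """
    if cfg.metric not in ("column-l1", "column-l1-corrected"):
        raise ValueError(f"unknown similarity metric {cfg.metric!r}")
    if m.width < cfg.min_overlap or n.width < cfg.min_overlap:
        return None
    best = _alignment_score(m.freqs, n.freqs, cfg.min_overlap)
    if cfg.reverse_complement:
        best = max(best, _alignment_score(m.freqs, n.reverse_complement().freqs, cfg.min_overlap))
    best = float(min(best, 1.0))
    if cfg.metric == "column-l1":
        return best
    floor = _shift_null(m.freqs, n.freqs, cfg.min_overlap)
    if cfg.reverse_complement:
        floor = max(floor, _shift_null(m.freqs, n.reverse_complement().freqs, cfg.min_overlap))
    if floor >= 0.99:  # degenerate (e.g. homopolymer columns): raw scale
        return best
    return float(np.clip((best - floor) / (1.0 - floor), 0.0, 1.0))


def similarity_matrix(
    pswms: Sequence[PSWM], cfg: SimilarityConfig = SimilarityConfig()
):
    """Symmetric pairwise similarity matrix as a DataFrame (TSV-ready)."""
    import pandas as pd

    names = [p.name or f"motif_{i}" for i, p in enumerate(pswms)]
    n = len(pswms)
    mat = np.ones((n, n))
    for i in range(n):
        for j in range(i + 1, n):
            s = motif_similarity(pswms[i], pswms[j], cfg)
            mat[i, j] = mat[j, i] = np.nan if s is None else s
    return pd.DataFrame(mat, index=names, columns=names)


def rank_against_library(
    m: PSWM, library: Sequence[PSWM], cfg: SimilarityConfig = SimilarityConfig()
) -> list[tuple[int, float]]:
    """Rank library motifs by similarity to ``m``, descending; ties keep
    library order. Motifs with undefined similarity are excluded."""
    if not library:
        raise ValueError("empty library")
    scored = []
    for i, cand in enumerate(library):
        s = motif_similarity(m, cand, cfg)
        if s is not None:
            scored.append((i, s))
    scored.sort(key=lambda t: (-t[1], t[0]))
    return scored
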