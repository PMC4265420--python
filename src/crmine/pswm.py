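"""Position-specific weight matrices (PSWMs).

Rows are ordered A, C, G, T. Information content uses log base 2, so a
point-mass column carries 2 bits.
"""
from __future__ import annotations

from typing import Optional, Sequence

import numpy as np

BASES = "ACGT"
BASE_INDEX = {b: i for i, b in enumerate(BASES)}


class PSWM:
    """A motif model: 4 x w count and frequency matrices.

    ``counts`` may be fractional (e.g. after merging); ``freqs`` columns sum
    to 1. A pseudocount is applied when building from counts.
    """

    def __init__(
        self,
        counts: np.ndarray,
        pseudocount: float = 0.25,
        name: Optional[str] = None,
    ):
        counts = np.asarray(counts, dtype=float)
        if counts.ndim != 2 or counts.shape[0] != 4:
            raise ValueError("counts must be a 4 x w matrix")
        if counts.shape[1] == 0:
            raise ValueError("zero-width PSWM")
        if np.any(counts < 0):
            raise ValueError("negative counts")
        self.counts = counts
        self.pseudocount = float(pseudocount)
        padded = counts + pseudocount
        self.freqs = padded / padded.sum(axis=0, keepdims=True)
        self.name = name

    # -- constructors -------------------------------------------------------
    @classmethod
    def from_sites(
        cls, sites: Sequence[str], pseudocount: float = 0.25, name: Optional[str] = None
    ) -> "PSWM":
        if not sites:
            raise ValueError("no sites")
        w = len(sites[0])
        counts = np.zeros((4, w))
        for s in sites:
            if len(s) != w:
                raise ValueError("sites of unequal width")
            for j, b in enumerate(s.upper()):
                if b in BASE_INDEX:
                    counts[BASE_INDEX[b], j] += 1
        return cls(counts, pseudocount=pseudocount, name=name)

    @classmethod
    def from_freqs(
        cls, freqs: np.ndarray, name: Optional[str] = None, tol: float = 1e-3
    ) -> "PSWM":
        """Build from a frequency matrix; columns must sum to 1 within ``tol``
        and are renormalized exactly."""
        freqs = np.asarray(freqs, dtype=float)
        if freqs.ndim != 2 or freqs.shape[0] != 4 or freqs.shape[1] == 0:
            raise ValueError("freqs must be a 4 x w matrix with w >= 1")
        sums = freqs.sum(axis=0)
        if np.any(np.abs(sums - 1.0) > tol):
            raise ValueError(f"frequency columns must sum to 1 within {tol}")
        obj = cls.__new__(cls)
        obj.counts = freqs / sums
        obj.pseudocount = 0.0
        obj.freqs = freqs / sums
        obj.name = name
        return obj

    # -- properties ---------------------------------------------------------
    @property
    def width(self) -> int:
        return self.freqs.shape[1]

    @property
    def n_sites(self) -> float:
        return float(self.counts.sum(axis=0).max())

    def information_content(self) -> np.ndarray:
        """Per-column IC in bits: 2 + sum_b f log2 f."""
        f = self.freqs
        with np.errstate(divide="ignore", invalid="ignore"):
            term = np.where(f > 0, f * np.log2(f), 0.0)
        return 2.0 + term.sum(axis=0)

    def consensus(self) -> str:
        return "".join(BASES[i] for i in np.argmax(self.freqs, axis=0))

    def reverse_complement(self) -> "PSWM":
        obj = PSWM.__new__(PSWM)
        obj.counts = self.counts[::-1, ::-1].copy()
        obj.pseudocount = self.pseudocount
        obj.freqs = self.freqs[::-1, ::-1].copy()
        obj.name = self.name
        return obj

    def smoothed(self, rel_pseudocount: float) -> "PSWM":
        """Add a pseudocount proportional to the site count per base.

        Used to build scanning matrices whose mismatch penalty reflects an
        assumed per-base substitution scale rather than the sampling depth.
        """
        n = max(self.n_sites, 1.0)
        return PSWM(self.counts, pseudocount=rel_pseudocount * n, name=self.name)

    def log_odds(self, background: Optional[np.ndarray] = None) -> np.ndarray:
        bg = np.full(4, 0.25) if background is None else np.asarray(background, float)
        bg = bg / bg.sum()
        return np.log2(self.freqs / bg[:, None])

    def __repr__(self) -> str:  # pragma: no cover
        return f"PSWM({self.name or 'unnamed'}, w={self.width})"
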