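"""Sequence context of methylation sites: ±10 windows, motifs, enrichment.

Methylation sites are examined in a window of ten residues on either side of
the modified K/R (21-mer, clipped at protein termini).  Named local motifs —
the methylarginine RGG/RGX/RXG and GXXR contexts, the WXXXR context, and the
MK methyllysine context — are matched by exact position-specific letters
(X = any residue).  Position-specific amino-acid enrichment against the
proteome-average residue frequency is assessed with a one-sided exact
binomial tail (default) or an R ``prop.test``-style continuity-corrected
normal approximation, with Bonferroni correction.
"""

from __future__ import annotations

import sys
from dataclasses import dataclass
from typing import Iterable, Mapping, Sequence

import numpy as np
from scipy import stats

from .massdigest import ProteinRecord, STANDARD_RESIDUES

__all__ = [
    "FLANK",
    "MotifWindow",
    "Motif",
    "MOTIFS",
    "EnrichmentResult",
    "extract_window",
    "window_from_string",
    "match_motif",
    "positional_enrichment",
    "proteome_background",
]

FLANK = 10


@dataclass(frozen=True)
class MotifWindow:
    """Up-to-21-residue context around a site; offset 0 is the modified residue."""

    accession: str
    position: int
    residue: str
    window: str
    start_offset: int  # offset of window[0], in [-FLANK, 0]

    def __post_init__(self):
        center_idx = -self.start_offset
        if not (0 <= center_idx < len(self.window)):
            raise ValueError("window does not contain its center")
        if self.window[center_idx] != self.residue:
            raise ValueError(
                f"{self.accession}:{self.position} window center "
                f"{self.window[center_idx]!r} != site residue {self.residue!r}"
            )

    @property
    def offsets(self) -> range:
        return range(self.start_offset, self.start_offset + len(self.window))

    def letter_at(self, offset: int) -> str | None:
        """Residue at a signed offset from the site, None beyond the termini."""
        idx = offset - self.start_offset
        if 0 <= idx < len(self.window):
            return self.window[idx]
        return None


@dataclass(frozen=True)
class Motif:
    """Position-specific letters anchored on the modified residue.

    ``letters`` maps signed offsets to required residue letters; the center
    (offset 0) must be one of ``center``.
    """

    name: str
    center: frozenset
    letters: Mapping

    def __post_init__(self):
        object.__setattr__(self, "center", frozenset(self.center))
        object.__setattr__(self, "letters", dict(self.letters))
        for off in self.letters:
            if off == 0 or abs(off) > FLANK:
                raise ValueError(f"motif offset {off} outside the ±{FLANK} window")

    @classmethod
    def from_pattern(cls, name: str, pattern: str) -> "Motif":
        """Build from a linear pattern with the center bracketed, e.g. ``GXX[R]XG``.

        ``X`` matches any residue.
        """
        lo = pattern.index("[")
        hi = pattern.index("]")
        center = pattern[lo + 1 : hi]
        left = pattern[:lo]
        right = pattern[hi + 1 :]
        letters = {}
        for i, aa in enumerate(left):
            if aa != "X":
                letters[i - len(left)] = aa
        for i, aa in enumerate(right):
            if aa != "X":
                letters[i + 1] = aa
        return cls(name, frozenset(center), letters)


MOTIFS = {
    m.name: m
    for m in [
        Motif.from_pattern("MK", "M[K]"),
        Motif.from_pattern("RGX", "[R]G"),
        Motif.from_pattern("RXG", "[R]XG"),
        Motif.from_pattern("GXXR", "GXX[R]"),
        Motif.from_pattern("GXXRXG", "GXX[R]XG"),
        Motif.from_pattern("WXXXR", "WXXX[R]"),
    ]
}


@dataclass(frozen=True)
class EnrichmentResult:
    offset: int
    residue: str
    observed: int
    n_windows: int  # windows covering this offset
    background: float
    raw_p: float
    corrected_p: float
    degenerate: bool = False


def extract_window(
    protein: ProteinRecord, position: int, residue: str | None = None
) -> MotifWindow:
    """Clipped 21-mer around a site; errors on center-residue mismatch."""
    if not (1 <= position <= len(protein.sequence)):
        raise ValueError(f"position {position} outside {protein.accession}")
    actual = protein.residue_at(position)
    if residue is not None and actual != residue:
        raise ValueError(
            f"{protein.accession}:{position} is {actual}, site table says {residue}"
        )
    lo = max(1, position - FLANK)
    hi = min(len(protein.sequence), position + FLANK)
    return MotifWindow(
        accession=protein.accession,
        position=position,
        residue=actual,
        window=protein.sequence[lo - 1 : hi],
        start_offset=lo - position,
    )


def window_from_string(
    accession: str, position: int, residue: str, window: str, start_offset: int = None
) -> MotifWindow:
    """Window from a pre-extracted string (e.g. a published 21-mer)."""
    if start_offset is None:
        # full windows are 21-mers centered on the site
        if len(window) != 2 * FLANK + 1:
            raise ValueError(
                "start_offset required for clipped windows "
                f"({accession}:{position}, length {len(window)})"
            )
        start_offset = -FLANK
    return MotifWindow(accession, position, residue, window, start_offset)


def match_motif(window: MotifWindow, motif: Motif) -> bool:
    """True iff the center and all specified offsets exist and match."""
    if window.residue not in motif.center:
        return False
    for off, aa in motif.letters.items():
        if window.letter_at(off) != aa:
            return False
    return True


def proteome_background(proteins: Sequence) -> dict:
    """Residue frequencies over all residues of the analysed protein set."""
    counts = {aa: 0 for aa in STANDARD_RESIDUES}
    total = 0
    for p in proteins:
        for aa in p.sequence:
            counts[aa] += 1
            total += 1
    if total == 0:
        raise ValueError("empty protein set")
    return {aa: c / total for aa, c in counts.items()}


def positional_enrichment(
    windows: Sequence,
    background: Mapping,
    n_tests: int | None = None,
    method: str = "binom",
    offsets: Iterable | None = None,
) -> list:
    """One-sided enrichment of each residue at each offset vs background.

    For each (offset, letter) the observed count is compared with a binomial
    null at the background proportion over the windows that actually cover
    that offset (clipping-aware denominator).  ``method="binom"`` uses the
    exact upper binomial tail; ``method="prop"`` uses the continuity-
    corrected one-sided normal approximation of R's ``prop.test``.
    Bonferroni correction multiplies by ``n_tests`` (default 20 letters x
    21 offsets = 420).
    """
    if n_tests is None:
        n_tests = 20 * (2 * FLANK + 1)
    if offsets is None:
        offsets = [o for o in range(-FLANK, FLANK + 1) if o != 0]
    results = []
    letters = sorted(STANDARD_RESIDUES)
    for off in offsets:
        present = [w.letter_at(off) for w in windows]
        present = [aa for aa in present if aa is not None]
        n = len(present)
        if n == 0:
            continue
        for aa in letters:
            k = sum(1 for x in present if x == aa)
            p0 = float(background.get(aa, 0.0))
            degenerate = False
            if p0 <= 0.0:
                if k > 0:
                    raw = sys.float_info.min
                    degenerate = True
                else:
                    raw = 1.0
            elif method == "binom":
                raw = float(stats.binom.sf(k - 1, n, p0))
            elif method == "prop":
                mu = n * p0
                sd = np.sqrt(n * p0 * (1 - p0))
                if sd == 0:
                    raw = 1.0 if k <= mu else sys.float_info.min
                else:
                    cc = min(0.5, abs(k - mu))
                    z = (k - mu - cc) / sd if k > mu else (k - mu + cc) / sd
                    raw = float(stats.norm.sf(z))
            else:
                raise ValueError(f"unknown method {method!r}")
            raw = min(max(raw, sys.float_info.min), 1.0)
            results.append(
                EnrichmentResult(
                    offset=off,
                    residue=aa,
                    observed=k,
                    n_windows=n,
                    background=p0,
                    raw_p=raw,
                    corrected_p=min(1.0, raw * n_tests),
                    degenerate=degenerate,
                )
            )
    return results
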