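"""Peptide-mass matching, tailor-made tolerances, and ambiguity classes.

Each replicate spectrum of an identified protein is a list of singly
protonated monoisotopic peptide masses.  Because the protein identity is
known, a spectrum-specific ("tailor-made") mass tolerance can be estimated
from the deviations between its peaks and the theoretical masses of the
protein's unmodified tryptic peptides; spectra whose tolerance exceeds
0.1 Da are excluded from site discovery.  Experimental masses are then
matched against unmodified peptides and against single-modification variants
(mass + modification delta), and each query mass is classified unambiguous
(exactly one peptide+modification explanation) or ambiguous.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, replace
from statistics import median
from typing import Iterable, Sequence

import numpy as np

from .massdigest import (
    ModificationSpec,
    ModifiedCandidate,
    TheoreticalPeptide,
    apply_modification,
)

__all__ = [
    "SpectrumRecord",
    "ToleranceEstimate",
    "PeptideMatch",
    "PORCINE_TRYPSIN_AUTOLYSIS",
    "preprocess_spectrum",
    "estimate_tolerance",
    "match_unmodified",
    "match_modified",
    "classify_ambiguity",
]

# Commonly excluded porcine-trypsin autolysis products, monoisotopic [M+H]+.
PORCINE_TRYPSIN_AUTOLYSIS = (842.5099, 1045.5642, 2211.1046, 2283.1807)

MIN_PEAK_MASS = 500.0


@dataclass(frozen=True)
class SpectrumRecord:
    """One replicate identification: protein accession + sorted [M+H]+ peaks."""

    spectrum_id: str
    accession: str
    peaks: tuple

    def __post_init__(self):
        object.__setattr__(self, "peaks", tuple(sorted(float(p) for p in self.peaks)))


@dataclass(frozen=True)
class ToleranceEstimate:
    spectrum_id: str
    tolerance: float
    n_support: int
    excluded: bool
    fallback: bool = False


@dataclass(frozen=True)
class PeptideMatch:
    """A (query mass, peptide, modification) assignment.

    ``modification`` is None for unmodified matches, in which case
    ``candidate_positions`` is empty.  ``candidate_positions`` holds the
    1-based parent-protein coordinates that could carry the modification.
    """

    spectrum_id: str
    query_mass: float
    peptide: TheoreticalPeptide
    modification: ModificationSpec | None
    candidate_positions: tuple
    mass_error: float
    ambiguous: bool = False

    @property
    def identity(self) -> tuple:
        """Peptide+modification identity; oxidation variants collapse."""
        mod = self.modification.name if self.modification else None
        return (self.peptide.parent, self.peptide.start, self.peptide.end, mod)


def preprocess_spectrum(
    spectrum_id: str,
    accession: str,
    raw_peaks: Sequence,
    autolysis_masses: Sequence = PORCINE_TRYPSIN_AUTOLYSIS,
    autolysis_tolerance: float = 0.1,
    min_mass: float = MIN_PEAK_MASS,
) -> SpectrumRecord | None:
    """Remove sub-500 Da peaks and porcine-trypsin autolysis peaks.

    Peaks matching the protein's own unmodified peptides are *retained* here:
    filter 1 of the site pipeline needs them to discard query masses that are
    explained by unmodified peptides.  Returns None (with a warning) when no
    peak survives.
    """
    autolysis = np.asarray(sorted(autolysis_masses), dtype=float)
    kept = []
    for p in raw_peaks:
        p = float(p)
        if p <= 0:
            raise ValueError(f"{spectrum_id}: non-positive peak mass {p}")
        if p < min_mass:
            continue
        if autolysis.size and np.min(np.abs(autolysis - p)) <= autolysis_tolerance:
            continue
        kept.append(p)
    if not kept:
        warnings.warn(f"{spectrum_id}: no peaks left after preprocessing; dropped")
        return None
    return SpectrumRecord(spectrum_id, accession, tuple(kept))


def estimate_tolerance(
    spectrum: SpectrumRecord,
    unmodified_peptides: Sequence,
    coarse_window: float = 0.15,
    min_support: int = 3,
    fallback: float = 0.04,
    floor: float = 0.001,
    exclusion_threshold: float = 0.1,
) -> ToleranceEstimate:
    """Tailor-made tolerance: median |empirical - theoretical| over unmodified matches.

    Each peak is paired with its nearest theoretical unmodified mass
    (oxidation variants included) found within ``coarse_window``.  With fewer
    than ``min_support`` pairings the estimate falls back to the global
    default (0.04 Da, the dataset-wide average and median).  The estimate is
    floored at ``floor`` so noise-free inputs still yield a usable tolerance,
    and spectra above ``exclusion_threshold`` are flagged for exclusion from
    site discovery.
    """
    theory = np.array(sorted(p.mh_mass for p in unmodified_peptides), dtype=float)
    errors = []
    for peak in spectrum.peaks:
        if theory.size == 0:
            break
        err = float(np.min(np.abs(theory - peak)))
        if err <= coarse_window:
            errors.append(err)
    if len(errors) < min_support:
        tol = fallback
        used_fallback = True
        n = len(errors)
    else:
        tol = float(median(errors))
        used_fallback = False
        n = len(errors)
    tol = max(tol, floor)
    return ToleranceEstimate(
        spectrum_id=spectrum.spectrum_id,
        tolerance=tol,
        n_support=n,
        excluded=tol > exclusion_threshold,
        fallback=used_fallback,
    )


def match_unmodified(
    spectrum: SpectrumRecord,
    peptides: Sequence,
    tolerance: float,
) -> list:
    """All (peak, peptide-with-oxidation-variant) pairs within tolerance."""
    if tolerance <= 0:
        raise ValueError("tolerance must be positive")
    masses = np.array([p.mh_mass for p in peptides], dtype=float)
    order = np.argsort(masses)
    sorted_masses = masses[order]
    out = []
    for peak in spectrum.peaks:
        lo = np.searchsorted(sorted_masses, peak - tolerance, side="left")
        hi = np.searchsorted(sorted_masses, peak + tolerance, side="right")
        for idx in order[lo:hi]:
            pep = peptides[idx]
            out.append(
                PeptideMatch(
                    spectrum_id=spectrum.spectrum_id,
                    query_mass=peak,
                    peptide=pep,
                    modification=None,
                    candidate_positions=(),
                    mass_error=peak - pep.mh_mass,
                )
            )
    return out


def match_modified(
    spectrum: SpectrumRecord,
    peptides: Sequence,
    modifications: Sequence,
    tolerance: float,
    discard_trimethyl_lysine: bool = True,
) -> list:
    """All (peak, peptide, modification) assignments within tolerance.

    One modification instance per peptide.  Tri-methyl-lysine candidates are
    discarded (near-isobaric with acetyl-lysine); tri-methyl matches survive
    only through arginine candidate positions.
    """
    if not modifications:
        raise ValueError("empty modification table")
    if tolerance <= 0:
        raise ValueError("tolerance must be positive")
    candidates: list[ModifiedCandidate] = []
    for pep in peptides:
        for mod in modifications:
            cand = apply_modification(pep, mod)
            if cand is None:
                continue
            positions = cand.candidate_positions
            if discard_trimethyl_lysine and mod.name == "trimethyl":
                positions = tuple(
                    pos
                    for pos in positions
                    if pep.sequence[pos - pep.start] != "K"
                )
                if not positions:
                    continue
                cand = replace(cand, candidate_positions=positions)
            candidates.append(cand)
    masses = np.array([c.mh_mass for c in candidates], dtype=float)
    order = np.argsort(masses) if masses.size else np.array([], dtype=int)
    sorted_masses = masses[order] if masses.size else masses
    out = []
    for peak in spectrum.peaks:
        lo = np.searchsorted(sorted_masses, peak - tolerance, side="left")
        hi = np.searchsorted(sorted_masses, peak + tolerance, side="right")
        for idx in order[lo:hi]:
            cand = candidates[idx]
            out.append(
                PeptideMatch(
                    spectrum_id=spectrum.spectrum_id,
                    query_mass=peak,
                    peptide=cand.peptide,
                    modification=cand.modification,
                    candidate_positions=cand.candidate_positions,
                    mass_error=peak - cand.mh_mass,
                )
            )
    return out


def classify_ambiguity(matches: Iterable) -> list:
    """Set the ambiguous flag per (spectrum, query mass) group.

    A query mass is unambiguous iff exactly one distinct
    (peptide sequence span, modification) identity explains it; oxidation
    variants of the same peptide+modification collapse to one identity.
    Candidate-position multiplicity within one peptide does not by itself
    create ambiguity (localization is the site-consensus filter's job).
    """
    matches = list(matches)
    groups: dict = {}
    for m in matches:
        groups.setdefault((m.spectrum_id, round(m.query_mass, 6)), set()).add(
            m.identity
        )
    return [
        replace(
            m,
            ambiguous=len(groups[(m.spectrum_id, round(m.query_mass, 6))]) > 1,
        )
        for m in matches
    ]
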