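"""In-silico tryptic digestion and monoisotopic peptide mass arithmetic.

Peptide mass fingerprinting characterizes a (mostly pure) protein by the
monoisotopic [M+H]+ masses of its tryptic peptides.  This module provides the
substrate for everything downstream: a validated protein record, exhaustive
tryptic digestion with at most one missed cleavage, monoisotopic mass
computation for unmodified and Met/Trp-oxidised peptides, and the application
of a single post-translational modification (e.g. mono- or di-methylation of
K/R, +14.01565 / +28.03130 Da) to a peptide.

The residue mass table is generated at import time from residue elemental
compositions and atomic monoisotopic masses rather than hand-typed, so that
independent composition-summing oracles agree to numerical precision.
"""

from __future__ import annotations

from dataclasses import dataclass, replace

__all__ = [
    "ProteinRecord",
    "TheoreticalPeptide",
    "ModificationSpec",
    "ModifiedCandidate",
    "MONO_ELEMENT",
    "RESIDUE_MASS",
    "WATER",
    "PROTON",
    "OXYGEN",
    "CH2",
    "STANDARD_RESIDUES",
    "mh_mass",
    "digest",
    "oxidation_variants",
    "digest_with_oxidation",
    "apply_modification",
    "default_modifications",
    "methylation_modifications",
]

# Monoisotopic atomic masses (IUPAC, most abundant isotope), Da.
MONO_ELEMENT = {
    "H": 1.00782503207,
    "C": 12.0,
    "N": 14.0030740048,
    "O": 15.99491461956,
    "S": 31.97207100,
}

PROTON = 1.00727646677  # mass of H+, Da

# Elemental composition of each amino-acid *residue* (i.e. minus one water).
_RESIDUE_FORMULA = {
    "G": dict(C=2, H=3, N=1, O=1),
    "A": dict(C=3, H=5, N=1, O=1),
    "S": dict(C=3, H=5, N=1, O=2),
    "P": dict(C=5, H=7, N=1, O=1),
    "V": dict(C=5, H=9, N=1, O=1),
    "T": dict(C=4, H=7, N=1, O=2),
    "C": dict(C=3, H=5, N=1, O=1, S=1),
    "L": dict(C=6, H=11, N=1, O=1),
    "I": dict(C=6, H=11, N=1, O=1),
    "N": dict(C=4, H=6, N=2, O=2),
    "D": dict(C=4, H=5, N=1, O=3),
    "Q": dict(C=5, H=8, N=2, O=2),
    "K": dict(C=6, H=12, N=2, O=1),
    "E": dict(C=5, H=7, N=1, O=3),
    "M": dict(C=5, H=9, N=1, O=1, S=1),
    "H": dict(C=6, H=7, N=3, O=1),
    "F": dict(C=9, H=9, N=1, O=1),
    "R": dict(C=6, H=12, N=4, O=1),
    "Y": dict(C=9, H=9, N=1, O=2),
    "W": dict(C=11, H=10, N=2, O=1),
}

STANDARD_RESIDUES = frozenset(_RESIDUE_FORMULA)


def _formula_mass(formula: dict) -> float:
    return sum(MONO_ELEMENT[el] * n for el, n in formula.items())


RESIDUE_MASS = {aa: _formula_mass(f) for aa, f in _RESIDUE_FORMULA.items()}
WATER = _formula_mass(dict(H=2, O=1))
OXYGEN = MONO_ELEMENT["O"]
CH2 = _formula_mass(dict(C=1, H=2))  # one methyl-group increment, 14.01565 Da
ACETYL = _formula_mass(dict(C=2, H=2, O=1))  # 42.010565 Da


@dataclass(frozen=True)
class ProteinRecord:
    """A protein sequence with identifiers and mature-chain coordinates.

    ``mature_start``/``mature_end`` are 1-based inclusive coordinates of the
    analysed chain (signal peptides and propeptides removed where annotated);
    they default to the whole sequence.
    """

    accession: str
    sequence: str
    gene_names: tuple = ()
    mature_start: int = 1
    mature_end: int = 0  # 0 => full length, resolved in __post_init__

    def __post_init__(self):
        if not self.sequence:
            raise ValueError(f"{self.accession}: empty sequence")
        bad = set(self.sequence) - STANDARD_RESIDUES
        if bad:
            raise ValueError(
                f"{self.accession}: non-standard residue letters {sorted(bad)}"
            )
        if self.mature_end == 0:
            object.__setattr__(self, "mature_end", len(self.sequence))
        if not (1 <= self.mature_start <= self.mature_end <= len(self.sequence)):
            raise ValueError(
                f"{self.accession}: invalid mature chain "
                f"[{self.mature_start}, {self.mature_end}]"
            )
        object.__setattr__(self, "gene_names", tuple(self.gene_names))

    @property
    def mature_sequence(self) -> str:
        return self.sequence[self.mature_start - 1 : self.mature_end]

    def residue_at(self, position: int) -> str:
        """Residue letter at a 1-based position."""
        return self.sequence[position - 1]


@dataclass(frozen=True)
class TheoreticalPeptide:
    """A tryptic fragment with 1-based inclusive parent coordinates."""

    parent: str
    start: int
    end: int
    sequence: str
    missed_cleavages: int
    oxidation_count: int = 0
    mh_mass: float = 0.0

    def __post_init__(self):
        if self.missed_cleavages not in (0, 1):
            raise ValueError("missed_cleavages must be 0 or 1")
        n_ox_sites = sum(self.sequence.count(a) for a in "MW")
        if self.oxidation_count > n_ox_sites:
            raise ValueError("oxidation_count exceeds M+W residues")
        if self.mh_mass == 0.0:
            object.__setattr__(
                self, "mh_mass", mh_mass(self.sequence, self.oxidation_count)
            )
        if self.mh_mass <= 0:
            raise ValueError("mh_mass must be positive")

    @property
    def span(self) -> tuple:
        return (self.start, self.end)

    def overlaps(self, other: "TheoreticalPeptide") -> bool:
        return self.parent == other.parent and not (
            self.end < other.start or other.end < self.start
        )


@dataclass(frozen=True)
class ModificationSpec:
    """A post-translational modification: name, target residues, mass delta.

    ``degree`` is the number of added methyl groups for methylation specs
    (1 = mono, 2 = di); 0 for non-methyl modifications.
    """

    name: str
    target_residues: frozenset
    delta: float
    degree: int = 0

    def __post_init__(self):
        object.__setattr__(self, "target_residues", frozenset(self.target_residues))


@dataclass(frozen=True)
class ModifiedCandidate:
    """Result of applying one modification instance to a peptide."""

    peptide: TheoreticalPeptide
    modification: ModificationSpec
    mh_mass: float
    candidate_positions: tuple  # 1-based parent-protein coordinates


def mh_mass(sequence: str, oxidation_count: int = 0) -> float:
    """Monoisotopic [M+H]+ mass of a peptide, with optional M/W oxidations.

    Sum of residue monoisotopic masses + water + one proton +
    ``oxidation_count`` oxygen atoms.
    """
    try:
        total = sum(RESIDUE_MASS[aa] for aa in sequence)
    except KeyError as exc:
        raise ValueError(f"invalid residue letter {exc.args[0]!r}") from None
    n_ox_sites = sum(sequence.count(a) for a in "MW")
    if oxidation_count < 0 or oxidation_count > n_ox_sites:
        raise ValueError("oxidation_count exceeds M+W residues")
    return total + WATER + PROTON + oxidation_count * OXYGEN


def cleavage_positions(
    sequence: str, suppress_before_proline: bool = True
) -> list:
    """0-based indices i such that trypsin cleaves between i and i+1."""
    sites = []
    for i, aa in enumerate(sequence[:-1]):
        if aa in "KR":
            if suppress_before_proline and sequence[i + 1] == "P":
                continue
            sites.append(i)
    return sites


def digest(
    protein: ProteinRecord,
    max_missed: int = 1,
    suppress_before_proline: bool = True,
) -> list:
    """All tryptic fragments of the mature chain with 0..max_missed missed cleavages.

    Cleaves C-terminal to K/R (optionally not before P).  Every 1-missed-
    cleavage peptide is the concatenation of two adjacent fully cleaved
    peptides.  No mass filtering is applied here.
    """
    if max_missed not in (0, 1):
        raise ValueError("max_missed must be 0 or 1")
    chain = protein.mature_sequence
    if not chain:
        raise ValueError(f"{protein.accession}: empty mature chain")
    offset = protein.mature_start  # parent coordinate of chain position 0
    sites = cleavage_positions(chain, suppress_before_proline)
    bounds = [0] + [i + 1 for i in sites] + [len(chain)]
    zero_mc = []
    for a, b in zip(bounds[:-1], bounds[1:]):
        zero_mc.append(
            TheoreticalPeptide(
                parent=protein.accession,
                start=offset + a,
                end=offset + b - 1,
                sequence=chain[a:b],
                missed_cleavages=0,
            )
        )
    peptides = list(zero_mc)
    if max_missed == 1:
        for p, q in zip(zero_mc[:-1], zero_mc[1:]):
            peptides.append(
                TheoreticalPeptide(
                    parent=protein.accession,
                    start=p.start,
                    end=q.end,
                    sequence=p.sequence + q.sequence,
                    missed_cleavages=1,
                )
            )
    return peptides


def oxidation_variants(
    peptide: TheoreticalPeptide, max_oxidation: int = 2
) -> list:
    """Peptide variants with 0..min(max_oxidation, #M+#W) oxidations."""
    n_ox_sites = sum(peptide.sequence.count(a) for a in "MW")
    top = min(max_oxidation, n_ox_sites)
    return [
        replace(peptide, oxidation_count=k, mh_mass=0.0) for k in range(top + 1)
    ]


def digest_with_oxidation(
    protein: ProteinRecord,
    max_missed: int = 1,
    suppress_before_proline: bool = True,
    max_oxidation: int = 2,
) -> list:
    """Digestion expanded over oxidation states; order-stable."""
    out = []
    for pep in digest(protein, max_missed, suppress_before_proline):
        out.extend(oxidation_variants(pep, max_oxidation))
    return out


def apply_modification(
    peptide: TheoreticalPeptide, mod: ModificationSpec
) -> ModifiedCandidate | None:
    """Apply exactly one instance of ``mod`` to ``peptide``.

    Returns the shifted [M+H]+ mass together with the parent-protein
    coordinates of every residue that could carry the modification, or
    ``None`` when the peptide contains no target residue (non-candidacy).
    Multi-site modified peptides are out of scope: one instance per peptide.
    """
    positions = tuple(
        peptide.start + i
        for i, aa in enumerate(peptide.sequence)
        if aa in mod.target_residues
    )
    if not positions:
        return None
    return ModifiedCandidate(
        peptide=peptide,
        modification=mod,
        mh_mass=peptide.mh_mass + mod.delta,
        candidate_positions=positions,
    )


def methylation_modifications() -> list:
    """Mono- and di-methylation of K/R, plus tri-methylation.

    Tri-methyl-lysine is near-isobaric with acetyl-lysine and is discarded at
    match time by the matching engine.
    """
    return [
        ModificationSpec("monomethyl", frozenset("KR"), CH2, degree=1),
        ModificationSpec("dimethyl", frozenset("KR"), 2 * CH2, degree=2),
        ModificationSpec("trimethyl", frozenset("KR"), 3 * CH2, degree=3),
    ]


def default_modifications() -> list:
    """Minimal modification screen: methylations, acetylation, oxidation.

    The full modification table used in large screens is user-supplied as a
    TSV (see :mod:`methylsieve.io`); this default exercises the matching and
    ambiguity machinery.
    """
    return methylation_modifications() + [
        ModificationSpec("acetyl", frozenset("K"), ACETYL, degree=0),
        ModificationSpec("oxidation", frozenset("MW"), OXYGEN, degree=0),
    ]
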