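"""The five sequential confidence filters and the end-to-end site pipeline.

Putatively methylated peptide matches are winnowed by five filters:

1. the query mass must not also match an unmodified peptide;
2. the peptide must contain no Asp/Glu (partial methyl-esterification of
   D/E side chains produces artifactual +14 Da shifts);
3. the modification must be seen in two or more *overlapping* peptides that
   share a candidate residue — exploiting the reduced efficiency of tryptic
   cleavage at methylated K/R, which yields both the cleaved (0 missed
   cleavage, site at the C-terminus) and read-through (1 missed cleavage)
   peptide forms;
4. at least one peptide in the overlapping group must be an unambiguous
   match;
5. two or more peptides passing 1-4 must overlap and agree on the *same*
   modified residue, which is then emitted as a high-confidence site.

Mono- and di-methylation evidence never merge: a residue carrying both is
reported as two distinct sites (degree-strict consensus).
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from typing import Iterable, Sequence

from .massdigest import (
    ModificationSpec,
    ProteinRecord,
    default_modifications,
    digest_with_oxidation,
)
from .pmf_engine import (
    PeptideMatch,
    SpectrumRecord,
    classify_ambiguity,
    estimate_tolerance,
    match_modified,
    match_unmodified,
    preprocess_spectrum,
)

__all__ = [
    "MethylationSite",
    "SiteGroup",
    "PipelineConfig",
    "PipelineResult",
    "filter1_not_unmodified",
    "filter2_no_DE",
    "filter3_overlap",
    "filter4_unambiguous_anchor",
    "filter5_site_consensus",
    "run_pipeline",
]


@dataclass(frozen=True)
class MethylationSite:
    """A high-confidence (protein, position, residue, degree) call."""

    accession: str
    position: int
    residue: str
    degree: int
    supporting_matches: tuple
    n_unambiguous: int

    def __post_init__(self):
        object.__setattr__(
            self, "supporting_matches", tuple(self.supporting_matches)
        )
        if len(self.supporting_matches) < 2:
            raise ValueError("a site needs >= 2 supporting matches")
        if self.n_unambiguous < 1:
            raise ValueError("a site needs >= 1 unambiguous supporter")
        if self.residue not in ("K", "R"):
            raise ValueError(f"unexpected residue {self.residue!r}")

    @property
    def token(self) -> str:
        return f"{'md'[self.degree - 1]}{self.residue}{self.position}"


@dataclass(frozen=True)
class SiteGroup:
    """Overlapping same-modification matches sharing one candidate residue."""

    accession: str
    position: int
    modification: ModificationSpec
    matches: tuple

    def __post_init__(self):
        object.__setattr__(self, "matches", tuple(self.matches))

    @property
    def n_distinct_peptides(self) -> int:
        return len({(m.peptide.start, m.peptide.end) for m in self.matches})

    @property
    def n_unambiguous(self) -> int:
        return sum(1 for m in self.matches if not m.ambiguous)


@dataclass
class PipelineConfig:
    """Knobs of the discovery pipeline; defaults mirror the reference protocol."""

    max_missed: int = 1
    suppress_before_proline: bool = True
    max_oxidation: int = 2
    coarse_window: float = 0.15
    tolerance_fallback: float = 0.04
    tolerance_floor: float = 0.001
    tolerance_exclusion: float = 0.1
    min_peak_mass: float = 500.0
    autolysis_tolerance: float = 0.1
    require_distinct_peptides: bool = True
    modifications: list = field(default_factory=default_modifications)

    def __post_init__(self):
        if self.max_missed == 0:
            # overlap evidence (filter 3) is unreachable without read-through
            raise ValueError(
                "max_missed=0 leaves the overlapping-peptide filter unreachable"
            )


@dataclass
class PipelineResult:
    sites: list
    audit: dict
    tolerances: list
    matches: list  # matches surviving filters 1-4, ambiguity-flagged


def filter1_not_unmodified(
    modified_matches: Iterable, unmodified_matches: Iterable
) -> list:
    """Drop modified matches whose query mass also matches an unmodified peptide."""
    explained = {
        (m.spectrum_id, round(m.query_mass, 6)) for m in unmodified_matches
    }
    return [
        m
        for m in modified_matches
        if (m.spectrum_id, round(m.query_mass, 6)) not in explained
    ]


def filter2_no_DE(matches: Iterable) -> list:
    """Drop matches whose peptide contains Asp or Glu."""
    return [
        m
        for m in matches
        if "D" not in m.peptide.sequence and "E" not in m.peptide.sequence
    ]


def _mod_key(mod: ModificationSpec) -> tuple:
    return (mod.name, mod.degree)


def _build_groups(matches: Sequence, require_distinct_peptides: bool) -> list:
    """Per (protein, modification, candidate position) overlap groups.

    Matches sharing a candidate position necessarily overlap in coordinates;
    a group is viable when it contains >= 2 distinct peptide sequences (or
    match instances, when ``require_distinct_peptides`` is off).
    """
    by_pos: dict = {}
    for m in matches:
        for pos in m.candidate_positions:
            key = (m.peptide.parent, _mod_key(m.modification), pos)
            by_pos.setdefault(key, []).append(m)
    groups = []
    for (acc, _mk, pos), members in sorted(
        by_pos.items(), key=lambda kv: (kv[0][0], kv[0][2], kv[0][1])
    ):
        size = (
            len({(m.peptide.start, m.peptide.end) for m in members})
            if require_distinct_peptides
            else len(members)
        )
        if size >= 2:
            groups.append(
                SiteGroup(
                    accession=acc,
                    position=pos,
                    modification=members[0].modification,
                    matches=tuple(members),
                )
            )
    return groups


def filter3_overlap(
    matches: Iterable, require_distinct_peptides: bool = True
) -> tuple:
    """Keep matches backed by >= 2 overlapping peptides sharing a candidate residue.

    Returns ``(surviving_matches, groups)``; all overlap topologies
    (0+1 MC, 1+1 MC, 0 MC + two 1 MC) are admitted since sharing a candidate
    position implies coordinate overlap.
    """
    matches = list(matches)
    groups = _build_groups(matches, require_distinct_peptides)
    keep = set()
    for g in groups:
        keep.update(id(m) for m in g.matches)
    return [m for m in matches if id(m) in keep], groups


def filter4_unambiguous_anchor(groups: Iterable) -> list:
    """Drop groups in which every member is an ambiguous match."""
    return [g for g in groups if g.n_unambiguous >= 1]


def filter5_site_consensus(
    groups: Iterable,
    proteins: dict,
    require_distinct_peptides: bool = True,
) -> list:
    """Emit a high-confidence site per surviving (protein, mod, position) group.

    Groups are already per-candidate-position intersections of overlapping
    same-degree matches; each viable group becomes one
    :class:`MethylationSite`.  ``proteins`` maps accession to
    :class:`ProteinRecord` for residue verification.
    """
    sites = []
    for g in groups:
        size = (
            g.n_distinct_peptides
            if require_distinct_peptides
            else len(g.matches)
        )
        if size < 2 or g.n_unambiguous < 1:
            continue
        if g.modification.degree not in (1, 2):
            continue  # only mono/di-methylation is reported as a site
        residue = proteins[g.accession].residue_at(g.position)
        if residue not in g.modification.target_residues:
            raise AssertionError(
                f"{g.accession}:{g.position} residue {residue} cannot carry "
                f"{g.modification.name}"
            )
        sites.append(
            MethylationSite(
                accession=g.accession,
                position=g.position,
                residue=residue,
                degree=g.modification.degree,
                supporting_matches=g.matches,
                n_unambiguous=g.n_unambiguous,
            )
        )
    sites.sort(key=lambda s: (s.accession, s.position, s.degree))
    return sites


def run_pipeline(
    spectra: Sequence,
    proteins: Sequence,
    config: PipelineConfig | None = None,
) -> PipelineResult:
    """Preprocess, estimate tolerances, match, and apply filters 1-5.

    Matches are pooled across a protein's replicate spectra before the
    overlap filters: the cleaved and read-through forms of a methylated
    peptide typically surface in different replicates.  Spectra whose
    tailor-made tolerance exceeds the exclusion threshold are left out of
    site discovery.  The audit dict mirrors the filtering funnel at
    peptide-match granularity.
    """
    if config is None:
        config = PipelineConfig()
    prot_index = {p.accession: p for p in proteins}
    digests: dict = {}
    for p in proteins:
        digests[p.accession] = digest_with_oxidation(
            p,
            max_missed=config.max_missed,
            suppress_before_proline=config.suppress_before_proline,
            max_oxidation=config.max_oxidation,
        )

    tolerances = []
    modified_all: list = []
    unmodified_all: list = []
    n_queries = 0
    for spec in spectra:
        if spec.accession not in prot_index:
            warnings.warn(f"{spec.spectrum_id}: unknown accession {spec.accession}")
            continue
        peptides = digests[spec.accession]
        est = estimate_tolerance(
            spec,
            peptides,
            coarse_window=config.coarse_window,
            fallback=config.tolerance_fallback,
            floor=config.tolerance_floor,
            exclusion_threshold=config.tolerance_exclusion,
        )
        tolerances.append(est)
        if est.excluded:
            continue
        n_queries += len(spec.peaks)
        unmodified_all.extend(match_unmodified(spec, peptides, est.tolerance))
        modified_all.extend(
            match_modified(spec, peptides, config.modifications, est.tolerance)
        )

    modified_all = classify_ambiguity(modified_all)
    audit = {
        "queries": n_queries,
        "modified_matches": len(modified_all),
    }
    f1 = filter1_not_unmodified(modified_all, unmodified_all)
    audit["after_filter1"] = len(f1)
    f2 = filter2_no_DE(f1)
    audit["after_filter2"] = len(f2)
    f3, groups = filter3_overlap(f2, config.require_distinct_peptides)
    audit["after_filter3"] = len(f3)
    groups4 = filter4_unambiguous_anchor(groups)
    keep = set()
    for g in groups4:
        keep.update(id(m) for m in g.matches)
    f4 = [m for m in f3 if id(m) in keep]
    audit["after_filter4"] = len(f4)
    audit["unambiguous_matches"] = len({id(m) for m in f4 if not m.ambiguous})
    audit["ambiguous_matches"] = len({id(m) for m in f4 if m.ambiguous})
    sites = filter5_site_consensus(
        groups4, prot_index, config.require_distinct_peptides
    )
    audit["sites"] = len(sites)

    stages = [
        audit["modified_matches"],
        audit["after_filter1"],
        audit["after_filter2"],
        audit["after_filter3"],
        audit["after_filter4"],
    ]
    assert all(a >= b for a, b in zip(stages[:-1], stages[1:])), (
        "filter funnel must be non-increasing"
    )
    return PipelineResult(sites=sites, audit=audit, tolerances=tolerances, matches=f4)
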