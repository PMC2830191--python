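"""In-silico benchmarking of the delta-matching engine.

Builds test sets of methylated peptide masses with known ground truth —
either a user-supplied table of literature-annotated sites or an "artificial"
set sampled from the proteome — and measures, per methylation class, the
true-positive rate of mass matching.  Following the field convention for
this kind of screen, the true-positive rate is a precision over matches:

    tp_rate = 100 * TP / (TP + FP)

where a match counts as TP only when residue, sequence position and
methylation type are all correct.  Recall (fraction of planted sites with at
least one correct match) is reported separately.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass
from typing import Sequence

import numpy as np
import pandas as pd

from .massdigest import (
    CH2,
    ModificationSpec,
    ProteinRecord,
    apply_modification,
    digest_with_oxidation,
    methylation_modifications,
)

__all__ = [
    "BenchmarkSite",
    "BenchmarkQuery",
    "BenchmarkResult",
    "CLASSES",
    "build_artificial_set",
    "build_known_set",
    "evaluate_tp_rate",
    "results_table",
]

# (class name, residue, degree)
CLASSES = (
    ("monomethyl-K", "K", 1),
    ("dimethyl-K", "K", 2),
    ("monomethyl-R", "R", 1),
    ("dimethyl-R", "R", 2),
)

MIN_TEST_CASES = 10  # below this a class's rate is flagged N.D.


@dataclass(frozen=True)
class BenchmarkSite:
    accession: str
    position: int
    residue: str
    degree: int
    provenance: str  # "known" | "artificial"

    def __post_init__(self):
        if self.residue not in ("K", "R"):
            raise ValueError("benchmark residue must be K or R")
        if self.degree not in (1, 2):
            raise ValueError("trimethylation is excluded from benchmarking")

    @property
    def klass(self) -> str:
        return f"{'monomethyl' if self.degree == 1 else 'dimethyl'}-{self.residue}"


@dataclass(frozen=True)
class BenchmarkQuery:
    """One methylated theoretical peptide mass with its ground truth."""

    site: BenchmarkSite
    peptide_start: int
    peptide_end: int
    oxidation_count: int
    mass: float


@dataclass
class BenchmarkResult:
    klass: str
    n_true_positive: int
    n_false_positive: int
    n_sites_tested: int
    n_peptides_tested: int
    n_sites_recovered: int

    @property
    def tp_rate(self) -> float | None:
        total = self.n_true_positive + self.n_false_positive
        if total == 0:
            return None
        return 100.0 * self.n_true_positive / total

    @property
    def recall(self) -> float | None:
        if self.n_sites_tested == 0:
            return None
        return 100.0 * self.n_sites_recovered / self.n_sites_tested

    @property
    def nd(self) -> bool:
        return self.n_sites_tested < MIN_TEST_CASES


def _queries_for_site(
    site: BenchmarkSite,
    digests: dict,
    mass_range: tuple,
) -> list:
    delta = site.degree * CH2
    lo, hi = mass_range
    out = []
    for pep in digests[site.accession]:
        if not (pep.start <= site.position <= pep.end):
            continue
        if pep.sequence[site.position - pep.start] != site.residue:
            continue
        m = pep.mh_mass + delta
        if lo <= m <= hi:
            out.append(
                BenchmarkQuery(
                    site=site,
                    peptide_start=pep.start,
                    peptide_end=pep.end,
                    oxidation_count=pep.oxidation_count,
                    mass=m,
                )
            )
    return out


def build_artificial_set(
    proteins: Sequence,
    sample_fraction: float = 0.06,
    seed: int | None = None,
    rng: np.random.Generator | None = None,
    mass_range: tuple = (500.0, 3000.0),
    max_oxidation: int = 2,
    suppress_before_proline: bool = True,
) -> tuple:
    """Sample K/R residues per class and emit modified peptide masses.

    Roughly ``sample_fraction`` of the eligible residues is drawn
    independently for each of the four classes (monomethyl-K, dimethyl-K,
    monomethyl-R, dimethyl-R).  Peptides keep at most one missed cleavage,
    include oxidation variants, and are windowed to ``mass_range``.
    Reproducible bit-for-bit under a fixed seed.
    """
    if not 0 < sample_fraction <= 1:
        raise ValueError("sample_fraction must be in (0, 1]")
    if rng is None:
        rng = np.random.default_rng(seed)
    digests = {
        p.accession: digest_with_oxidation(
            p, 1, suppress_before_proline, max_oxidation
        )
        for p in proteins
    }
    eligible = {"K": [], "R": []}
    for p in proteins:
        for i in range(p.mature_start, p.mature_end + 1):
            aa = p.residue_at(i)
            if aa in eligible:
                eligible[aa].append((p.accession, i))
    if not eligible["K"] and not eligible["R"]:
        raise ValueError("proteome contains no K or R residues")
    sites, queries = [], []
    for klass, residue, degree in CLASSES:
        pool = eligible[residue]
        draws = rng.random(len(pool)) < sample_fraction
        for (acc, pos), take in zip(pool, draws):
            if not take:
                continue
            site = BenchmarkSite(acc, pos, residue, degree, "artificial")
            qs = _queries_for_site(site, digests, mass_range)
            if qs:
                sites.append(site)
                queries.extend(qs)
    return sites, queries


def build_known_set(
    table: pd.DataFrame,
    proteins: Sequence,
    mass_range: tuple = (500.0, 3000.0),
    max_oxidation: int = 2,
    suppress_before_proline: bool = True,
) -> tuple:
    """Benchmark set from a user table with columns accession/position/residue/degree."""
    prot = {p.accession: p for p in proteins}
    digests = {
        p.accession: digest_with_oxidation(
            p, 1, suppress_before_proline, max_oxidation
        )
        for p in proteins
    }
    sites, queries = [], []
    for row in table.itertuples(index=False):
        if row.accession not in prot:
            warnings.warn(f"known site on unknown protein {row.accession}; skipped")
            continue
        if prot[row.accession].residue_at(int(row.position)) != row.residue:
            raise ValueError(
                f"known-site table disagrees with sequence at "
                f"{row.accession}:{row.position}"
            )
        site = BenchmarkSite(
            row.accession, int(row.position), row.residue, int(row.degree), "known"
        )
        qs = _queries_for_site(site, digests, mass_range)
        if qs:
            sites.append(site)
            queries.extend(qs)
    return sites, queries


def evaluate_tp_rate(
    sites: Sequence,
    queries: Sequence,
    proteins: Sequence,
    tolerance: float = 0.04,
    modifications: Sequence | None = None,
    max_oxidation: int = 2,
    suppress_before_proline: bool = True,
) -> dict:
    """Match each benchmark mass against its protein and score TP/FP per class.

    Every (peptide variant, modification) pair within tolerance is one match;
    it is TP iff the methylation type is correct and the planted position is
    among the match's candidate residues (localization among a single
    peptide's candidates is the consensus filter's job, not the matcher's),
    FP otherwise.  The D/E filter is not applied (no artifactual
    esterification exists in silico).  Tri-methyl-lysine candidates are
    discarded as in the production matcher.
    """
    if modifications is None:
        modifications = methylation_modifications()
    digests = {
        p.accession: digest_with_oxidation(
            p, 1, suppress_before_proline, max_oxidation
        )
        for p in proteins
    }
    # Pre-assemble candidate (mass, mod, positions) matches per protein.
    assignments: dict = {}
    for acc, peps in digests.items():
        rows = []
        for pep in peps:
            for mod in modifications:
                cand = apply_modification(pep, mod)
                if cand is None:
                    continue
                positions = cand.candidate_positions
                if mod.name == "trimethyl":
                    positions = tuple(
                        pos
                        for pos in positions
                        if pep.sequence[pos - pep.start] != "K"
                    )
                    if not positions:
                        continue
                rows.append((cand.mh_mass, mod, positions))
        rows.sort(key=lambda r: r[0])
        assignments[acc] = (
            np.array([r[0] for r in rows], dtype=float),
            rows,
        )

    results = {
        klass: BenchmarkResult(klass, 0, 0, 0, 0, 0) for klass, _r, _d in CLASSES
    }
    recovered: dict = {klass: set() for klass, _r, _d in CLASSES}
    site_counts: dict = {klass: set() for klass, _r, _d in CLASSES}
    peptide_counts: dict = {klass: 0 for klass, _r, _d in CLASSES}
    for s in sites:
        site_counts[s.klass].add((s.accession, s.position, s.degree))
    for q in queries:
        klass = q.site.klass
        peptide_counts[klass] += 1
        masses, rows = assignments[q.site.accession]
        lo = np.searchsorted(masses, q.mass - tolerance, side="left")
        hi = np.searchsorted(masses, q.mass + tolerance, side="right")
        res = results[klass]
        for _m, mod, positions in rows[lo:hi]:
            correct_type = (
                mod.degree == q.site.degree
                and q.site.residue in mod.target_residues
            )
            if correct_type and q.site.position in positions:
                res.n_true_positive += 1
                recovered[klass].add(
                    (q.site.accession, q.site.position, q.site.degree)
                )
            else:
                res.n_false_positive += 1
    for klass, _r, _d in CLASSES:
        res = results[klass]
        res.n_sites_tested = len(site_counts[klass])
        res.n_peptides_tested = peptide_counts[klass]
        res.n_sites_recovered = len(recovered[klass])
        if res.n_true_positive == 0 and res.n_false_positive == 0:
            warnings.warn(f"{klass}: no matches at all; tp_rate undefined")
    return results


def results_table(results: dict) -> pd.DataFrame:
    rows = []
    for klass, res in results.items():
        rows.append(
            {
                "class": klass,
                "tp_rate_pct": None if res.nd else res.tp_rate,
                "nd": res.nd,
                "n_true_positive": res.n_true_positive,
                "n_false_positive": res.n_false_positive,
                "n_sites_tested": res.n_sites_tested,
                "n_peptides_tested": res.n_peptides_tested,
                "recall_pct": res.recall,
            }
        )
    return pd.DataFrame(rows)
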