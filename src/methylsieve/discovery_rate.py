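"""Peptide/residue discovery rates and their comparative statistics.

The discovery rate of a peptide is the fraction of a protein's replicate
identifications (spectra) in which the peptide's mass is observed; sub-
stoichiometric methylated peptides therefore show low rates.  Identification
counts of proteins with identical mature sequences (duplicated genes) are
pooled, since peptide mass fingerprinting cannot distinguish them.  A wide
matching tolerance (1.5 Da) is used here — independent of the site-discovery
tolerance — to maximise the sample size.

The residue-level rate is the sum of the rates of all distinct peptides
covering the residue (same construction for methylated residues over
methylated peptide forms, kept separate per methylation degree).
"""

from __future__ import annotations

import warnings
from typing import Iterable, Sequence

import numpy as np
import pandas as pd
from scipy import stats

from .massdigest import TheoreticalPeptide, digest

__all__ = [
    "WIDE_TOLERANCE",
    "group_paralogs",
    "peptide_discovery_rate",
    "residue_discovery_rate",
    "compare_rates",
    "site_rate_table",
    "peptide_rate_samples",
]

WIDE_TOLERANCE = 1.5  # Da


def group_paralogs(proteins: Sequence) -> dict:
    """Map accession -> group id; identical mature sequences share a group."""
    by_seq: dict = {}
    for p in proteins:
        by_seq.setdefault(p.mature_sequence, []).append(p.accession)
    groups = {}
    for accs in by_seq.values():
        gid = "+".join(sorted(accs))
        for a in accs:
            groups[a] = gid
    return groups


def peptide_discovery_rate(
    target_mass: float,
    spectra: Sequence,
    wide_tolerance: float = WIDE_TOLERANCE,
) -> float | None:
    """Fraction of pooled group spectra containing a peak within tolerance.

    ``spectra`` must already be the pooled replicate spectra of the paralog
    group.  Returns None (with a warning) when the group has no spectra.
    """
    n = len(spectra)
    if n == 0:
        warnings.warn("no identifications for group; discovery rate undefined")
        return None
    seen = 0
    for spec in spectra:
        peaks = np.asarray(spec.peaks, dtype=float)
        if peaks.size and np.min(np.abs(peaks - target_mass)) <= wide_tolerance:
            seen += 1
    return seen / n


def residue_discovery_rate(
    position: int, peptide_rates: Iterable
) -> float:
    """Sum of rates over distinct peptides covering ``position``.

    ``peptide_rates`` yields ``(TheoreticalPeptide, rate)`` pairs; duplicate
    peptide spans are counted once.
    """
    total = 0.0
    seen = set()
    for pep, rate in peptide_rates:
        if rate is None:
            continue
        if (pep.start, pep.end) in seen:
            continue
        if pep.start <= position <= pep.end:
            seen.add((pep.start, pep.end))
            total += rate
    return total


def compare_rates(
    methylated_rates: Sequence,
    unmodified_rates: Sequence,
    pairs: Sequence | None = None,
) -> dict:
    """Rank-sum comparison of the two rate samples, plus paired correlation.

    ``pairs`` is an optional sequence of (methylated rate, unmodified rate)
    tuples for residues observed in both forms; Kendall's tau is computed on
    it when at least 3 pairs are available.
    """
    a = np.asarray(methylated_rates, dtype=float)
    b = np.asarray(unmodified_rates, dtype=float)
    if a.size == 0 or b.size == 0:
        raise ValueError("both rate samples must be non-empty")
    if np.array_equal(a, b):
        u, p = np.nan, 1.0  # identical samples: no evidence of a shift
    else:
        u, p = stats.mannwhitneyu(a, b, alternative="two-sided")
    out = {
        "median_methylated": float(np.median(a)),
        "median_unmodified": float(np.median(b)),
        "mannwhitney_u": float(u) if not np.isnan(u) else None,
        "mannwhitney_p": float(p),
        "kendall_tau": None,
        "kendall_p": None,
        "n_pairs": 0,
    }
    if pairs is not None:
        pairs = [(float(x), float(y)) for x, y in pairs]
        out["n_pairs"] = len(pairs)
        if len(pairs) < 3:
            warnings.warn("fewer than 3 paired residues; correlation skipped")
        else:
            xs, ys = zip(*pairs)
            tau, tp = stats.kendalltau(xs, ys)
            out["kendall_tau"] = float(tau)
            out["kendall_p"] = float(tp)
    return out


def peptide_rate_samples(
    proteins: Sequence,
    spectra: Sequence,
    sites: Sequence,
    modification_deltas: dict,
    max_missed: int = 1,
    suppress_before_proline: bool = True,
    wide_tolerance: float = WIDE_TOLERANCE,
    mass_range: tuple = (500.0, 3000.0),
) -> tuple:
    """Peptide-level rate samples: methylated site peptides vs all unmodified.

    Mirrors the group comparison of methylated against unmodified peptide
    discovery rates: the methylated sample holds the rates of each site's
    covering peptide forms at their methylated mass, the unmodified sample
    the rates of every fully cleaved peptide of the site proteins at its
    unmodified mass (detectable mass window applied to both).
    """
    groups = group_paralogs(proteins)
    spectra_by_group: dict = {}
    for s in spectra:
        gid = groups.get(s.accession)
        if gid is not None:
            spectra_by_group.setdefault(gid, []).append(s)
    lo, hi = mass_range
    site_accessions = {s.accession for s in sites}
    methylated, unmodified = [], []
    for p in proteins:
        if p.accession not in site_accessions:
            continue
        pool = spectra_by_group.get(groups[p.accession], [])
        if not pool:
            continue
        peptides = digest(p, max_missed, suppress_before_proline)
        for pep in peptides:
            if pep.missed_cleavages == 0 and lo <= pep.mh_mass <= hi:
                unmodified.append(
                    peptide_discovery_rate(pep.mh_mass, pool, wide_tolerance)
                )
        for site in (s for s in sites if s.accession == p.accession):
            delta = modification_deltas[site.degree]
            for pep in peptides:
                if not (pep.start <= site.position <= pep.end):
                    continue
                m = pep.mh_mass + delta
                if lo <= m <= hi:
                    methylated.append(
                        peptide_discovery_rate(m, pool, wide_tolerance)
                    )
    return methylated, unmodified


def site_rate_table(
    proteins: Sequence,
    spectra: Sequence,
    sites: Sequence,
    modification_deltas: dict,
    max_missed: int = 1,
    suppress_before_proline: bool = True,
    wide_tolerance: float = WIDE_TOLERANCE,
) -> pd.DataFrame:
    """Per-site methylated vs unmodified residue discovery rates.

    For each high-confidence site, the methylated residue rate sums the rates
    of the site's covering peptides shifted by the site's methyl delta
    (``modification_deltas`` maps degree -> Da), and the unmodified residue
    rate sums the rates of the same covering peptides at their unmodified
    masses.  Rates are computed over the pooled spectra of the site protein's
    paralog group.
    """
    groups = group_paralogs(proteins)
    spectra_by_group: dict = {}
    for s in spectra:
        gid = groups.get(s.accession)
        if gid is not None:
            spectra_by_group.setdefault(gid, []).append(s)
    digests = {
        p.accession: digest(p, max_missed, suppress_before_proline)
        for p in proteins
    }
    rows = []
    for site in sites:
        gid = groups[site.accession]
        pool = spectra_by_group.get(gid, [])
        covering = [
            pep
            for pep in digests[site.accession]
            if pep.start <= site.position <= pep.end
        ]
        delta = modification_deltas[site.degree]
        meth_rates = [
            (pep, peptide_discovery_rate(pep.mh_mass + delta, pool, wide_tolerance))
            for pep in covering
        ]
        unmod_rates = [
            (pep, peptide_discovery_rate(pep.mh_mass, pool, wide_tolerance))
            for pep in covering
        ]
        rows.append(
            {
                "accession": site.accession,
                "group": gid,
                "position": site.position,
                "residue": site.residue,
                "degree": site.degree,
                "n_spectra": len(pool),
                "methylated_rate": residue_discovery_rate(site.position, meth_rates),
                "unmodified_rate": residue_discovery_rate(site.position, unmod_rates),
            }
        )
    return pd.DataFrame(
        rows,
        columns=[
            "accession",
            "group",
            "position",
            "residue",
            "degree",
            "n_spectra",
            "methylated_rate",
            "unmodified_rate",
        ],
    )
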