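"""Functional co-analysis of methylated proteins.

GO-slim term enrichment of the methylated protein set against the annotated
universe (one-sided Fisher's exact test, Bonferroni-corrected per ontology
branch), non-parametric comparisons of numeric annotations such as abundance
(copies/cell) and half-life (minutes) between methylated and non-methylated
proteins (Mann-Whitney), and the overlap proportion between methylation and
a binary per-protein or per-site flag (e.g. known phosphorylation, predicted
ubiquitination).
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd
from scipy import stats

__all__ = [
    "ContingencyTable",
    "go_enrichment",
    "group_compare",
    "interplay_proportion",
    "round_half_up",
]


@dataclass(frozen=True)
class ContingencyTable:
    """2x2 table: methylated/non-methylated x with/without a term."""

    n11: int
    n12: int
    n21: int
    n22: int

    def __post_init__(self):
        if min(self.n11, self.n12, self.n21, self.n22) < 0:
            raise ValueError("contingency counts must be non-negative")

    def fisher_greater(self) -> float:
        """One-sided (enrichment) Fisher exact p."""
        _odds, p = stats.fisher_exact(
            [[self.n11, self.n12], [self.n21, self.n22]], alternative="greater"
        )
        return float(p)


def go_enrichment(
    methylated: Iterable,
    annotations: Mapping,
    universe: Iterable,
    terms: Sequence | None = None,
) -> pd.DataFrame:
    """Per-term contingency tables with raw and Bonferroni-corrected Fisher p.

    ``annotations`` maps accession -> set of terms (possibly empty); every
    universe protein must appear in it.  The correction factor is the number
    of terms actually tested in this call — callers testing the three GO
    branches should call once per branch.  Terms absent from the universe are
    skipped with a warning.
    """
    universe = set(universe)
    methylated = set(methylated) & universe
    missing = universe - set(annotations)
    if missing:
        raise ValueError(
            f"{len(missing)} universe proteins lack annotation entries"
        )
    if terms is None:
        terms = sorted({t for acc in universe for t in annotations[acc]})
    tested = []
    for term in terms:
        with_term = {acc for acc in universe if term in annotations[acc]}
        if not with_term:
            warnings.warn(f"term {term!r} absent from universe; skipped")
            continue
        n11 = len(methylated & with_term)
        n12 = len(methylated - with_term)
        n21 = len(with_term - methylated)
        n22 = len(universe) - n11 - n12 - n21
        tested.append((term, ContingencyTable(n11, n12, n21, n22)))
    n_tests = len(tested)
    rows = []
    for term, tab in tested:
        raw = tab.fisher_greater()
        rows.append(
            {
                "term": term,
                "n11": tab.n11,
                "n12": tab.n12,
                "n21": tab.n21,
                "n22": tab.n22,
                "raw_p": raw,
                "corrected_p": min(1.0, raw * n_tests),
            }
        )
    df = pd.DataFrame(
        rows,
        columns=["term", "n11", "n12", "n21", "n22", "raw_p", "corrected_p"],
    )
    return df.sort_values("raw_p", kind="stable").reset_index(drop=True)


def group_compare(
    methylated_values: Sequence, other_values: Sequence
) -> dict:
    """Group medians and two-sided Mann-Whitney p; missing values dropped."""
    a = pd.Series(list(methylated_values), dtype=float).dropna().to_numpy()
    b = pd.Series(list(other_values), dtype=float).dropna().to_numpy()
    if a.size == 0 or b.size == 0:
        raise ValueError("a group is empty after dropping missing values")
    if np.array_equal(np.sort(a), np.sort(b)):
        u, p = None, 1.0
    else:
        u, p = stats.mannwhitneyu(a, b, alternative="two-sided")
        u, p = float(u), float(p)
    return {
        "median_methylated": float(np.median(a)),
        "median_other": float(np.median(b)),
        "n_methylated": int(a.size),
        "n_other": int(b.size),
        "mannwhitney_u": u,
        "mannwhitney_p": p,
    }


def round_half_up(x: float) -> int:
    """Round to nearest integer, halves away from zero (report convention)."""
    return int(math.floor(x + 0.5))


def interplay_proportion(
    methylated: Iterable, flags: Mapping
) -> dict:
    """Fraction of the methylated set carrying a binary annotation.

    Returns flagged count, total, exact percentage and the half-up-rounded
    integer percentage used for reporting.
    """
    members = list(methylated)
    if not members:
        raise ValueError("empty methylated set")
    flagged = sum(1 for acc in members if flags.get(acc, False))
    pct = 100.0 * flagged / len(members)
    return {
        "flagged": flagged,
        "total": len(members),
        "percent": pct,
        "percent_rounded": round_half_up(pct),
    }
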