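"""Packaged reference tables of the published yeast methylation screen.

Three small TSVs transcribed from the printed results ship with the package
so downstream bookkeeping (site tallies, motif-class counts, GO enrichment
bounds) runs with no network access:

* ``table1_sites.tsv`` — the high-confidence methylated proteins and their
  site tokens (``mK121`` = monomethyl-lysine 121, ``dR35`` = dimethyl-
  arginine 35);
* ``table5_motifs.tsv`` — methylation-motif windows (21-mers centred on the
  modified residue) with a FindMod-vs-literature provenance flag;
* ``table4_go.tsv`` — GO-slim enrichment contingency rows.

Self-consistency checks (site-token grammar, window-centre agreement) run at
load time.
"""

from __future__ import annotations

import re
from dataclasses import dataclass
from importlib import resources

import pandas as pd

from .motif_analysis import MOTIFS, match_motif, window_from_string

__all__ = [
    "SiteToken",
    "parse_site_token",
    "load_table1",
    "load_table5",
    "load_table4",
    "table1_counts",
    "table5_motif_counts",
]

_TOKEN_RE = re.compile(r"^(m|d)(K|R)(\d+)$")


@dataclass(frozen=True)
class SiteToken:
    degree: int  # 1 = mono, 2 = di
    residue: str
    position: int


def parse_site_token(token: str) -> SiteToken:
    """Parse a site token like ``mK121`` or ``dR35``."""
    m = _TOKEN_RE.match(token.strip())
    if not m:
        raise ValueError(f"malformed site token {token!r}")
    return SiteToken(
        degree=1 if m.group(1) == "m" else 2,
        residue=m.group(2),
        position=int(m.group(3)),
    )


def _read(name: str) -> pd.DataFrame:
    with resources.files("methylsieve.data").joinpath(name).open() as fh:
        return pd.read_csv(fh, sep="\t")


def load_table1() -> pd.DataFrame:
    """Methylated-protein rows; validates every site token at load time."""
    df = _read("table1_sites.tsv")
    for row in df.itertuples():
        for tok in str(row.sites).split(","):
            try:
                parse_site_token(tok)
            except ValueError as exc:
                raise ValueError(f"table1 row {row.gene}: {exc}") from None
    return df


def load_table5() -> pd.DataFrame:
    """Motif windows; validates token grammar and window-centre agreement."""
    df = _read("table5_motifs.tsv")
    for row in df.itertuples():
        tok = parse_site_token(str(row.site))
        window = str(row.window)
        if len(window) != 21:
            raise ValueError(f"table5 row {row.gene} {row.site}: window not 21-mer")
        if window[10] != tok.residue:
            raise ValueError(
                f"table5 row {row.gene} {row.site}: centre {window[10]!r} "
                f"does not match residue {tok.residue!r}"
            )
    return df


def load_table4() -> pd.DataFrame:
    return _read("table4_go.tsv")


def table1_counts(df: pd.DataFrame | None = None) -> dict:
    """Site tallies from the packaged site table, computed by counting tokens."""
    if df is None:
        df = load_table1()
    tokens = []
    per_protein_residues = []
    for row in df.itertuples():
        toks = [parse_site_token(t) for t in str(row.sites).split(",")]
        tokens.extend(toks)
        per_protein_residues.append({t.residue for t in toks})
    counts = {
        "lysine_sites": sum(1 for t in tokens if t.residue == "K"),
        "arginine_sites": sum(1 for t in tokens if t.residue == "R"),
        "monomethyl_lysine": sum(
            1 for t in tokens if t.residue == "K" and t.degree == 1
        ),
        "dimethyl_lysine": sum(
            1 for t in tokens if t.residue == "K" and t.degree == 2
        ),
        "monomethyl_arginine": sum(
            1 for t in tokens if t.residue == "R" and t.degree == 1
        ),
        "dimethyl_arginine": sum(
            1 for t in tokens if t.residue == "R" and t.degree == 2
        ),
        "total_sites": len(tokens),
        "protein_rows": len(per_protein_residues),
        "lysine_proteins": sum(1 for s in per_protein_residues if "K" in s),
        "arginine_proteins": sum(1 for s in per_protein_residues if "R" in s),
        "dual_methylated_proteins": sum(
            1 for s in per_protein_residues if s == {"K", "R"}
        ),
    }
    return counts


def _table5_windows(df: pd.DataFrame):
    for row in df.itertuples():
        tok = parse_site_token(str(row.site))
        yield row, tok, window_from_string(
            accession=str(row.accession),
            position=tok.position,
            residue=tok.residue,
            window=str(row.window),
        )


def table5_motif_counts(df: pd.DataFrame | None = None) -> dict:
    """Motif-class counts over the packaged windows, via the motif matcher.

    Counts are distinct (accession, position) pairs — a residue methylated at
    both degrees counts once, matching the published counting convention.
    """
    if df is None:
        df = load_table5()
    hits = {name: set() for name in ("RGX_or_RXG", "GXXRXG", "WXXXR", "MK")}
    mk_findmod = set()
    for row, tok, window in _table5_windows(df):
        key = (str(row.accession), tok.position)
        if match_motif(window, MOTIFS["RGX"]) or match_motif(window, MOTIFS["RXG"]):
            hits["RGX_or_RXG"].add(key)
        if match_motif(window, MOTIFS["GXXRXG"]):
            hits["GXXRXG"].add(key)
        if match_motif(window, MOTIFS["WXXXR"]):
            hits["WXXXR"].add(key)
        if match_motif(window, MOTIFS["MK"]):
            hits["MK"].add(key)
            if str(row.provenance) == "findmod":
                mk_findmod.add(key)
    out = {name: len(s) for name, s in hits.items()}
    out["MK_findmod"] = len(mk_findmod)
    return out
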