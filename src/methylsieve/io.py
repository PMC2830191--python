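"""Format round-tripping: FASTA, peak lists, minimal MGF, TSV tables."""

from __future__ import annotations

import re
from pathlib import Path
from typing import Sequence

import pandas as pd
from Bio import SeqIO

from .massdigest import ModificationSpec, ProteinRecord

__all__ = [
    "read_fasta",
    "read_peak_list",
    "write_peak_list",
    "read_mgf_peaks",
    "read_modification_table",
    "write_modification_table",
    "sites_to_frame",
    "write_tsv",
]

_GN_RE = re.compile(r"GN=(\S+)")


def _parse_accession(record_id: str) -> str:
    # UniProt-style "sp|P00359|G3P3_YEAST" headers carry the accession second
    parts = record_id.split("|")
    if len(parts) >= 3 and parts[0] in ("sp", "tr"):
        return parts[1]
    return record_id


def read_fasta(path) -> list:
    """ProteinRecords from FASTA; gene names from an optional GN= tag."""
    proteins = []
    for rec in SeqIO.parse(str(path), "fasta"):
        genes = tuple(_GN_RE.findall(rec.description))
        proteins.append(
            ProteinRecord(
                accession=_parse_accession(rec.id),
                sequence=str(rec.seq).upper(),
                gene_names=genes,
            )
        )
    if not proteins:
        raise ValueError(f"{path}: no FASTA records")
    return proteins


def read_peak_list(path) -> list:
    """Plain-text peak list: one [M+H]+ mass per line; # comments allowed."""
    peaks = []
    for line in Path(path).read_text().splitlines():
        line = line.strip()
        if not line or line.startswith("#"):
            continue
        peaks.append(float(line.split()[0]))
    return peaks


def write_peak_list(path, peaks: Sequence) -> None:
    with open(path, "w") as fh:
        for p in peaks:
            fh.write(f"{float(p):.6f}\n")


def read_mgf_peaks(path) -> list:
    """Minimal MGF subset: PEPMASS of each BEGIN/END IONS block, as [M+H]+."""
    peaks = []
    in_block = False
    for line in Path(path).read_text().splitlines():
        line = line.strip()
        if line == "BEGIN IONS":
            in_block = True
        elif line == "END IONS":
            in_block = False
        elif in_block and line.startswith("PEPMASS="):
            peaks.append(float(line.split("=", 1)[1].split()[0]))
    return peaks


def read_modification_table(path) -> list:
    """TSV with columns name, targets, delta, degree."""
    df = pd.read_csv(path, sep="\t")
    required = {"name", "targets", "delta", "degree"}
    if not required <= set(df.columns):
        raise ValueError(f"{path}: modification table needs columns {sorted(required)}")
    mods = []
    for row in df.itertuples(index=False):
        mods.append(
            ModificationSpec(
                name=str(row.name),
                target_residues=frozenset(str(row.targets)),
                delta=float(row.delta),
                degree=int(row.degree),
            )
        )
    if not mods:
        raise ValueError(f"{path}: empty modification table")
    return mods


def write_modification_table(path, mods: Sequence) -> None:
    pd.DataFrame(
        {
            "name": [m.name for m in mods],
            "targets": ["".join(sorted(m.target_residues)) for m in mods],
            "delta": [m.delta for m in mods],
            "degree": [m.degree for m in mods],
        }
    ).to_csv(path, sep="\t", index=False)


def sites_to_frame(sites: Sequence, proteins: dict | None = None) -> pd.DataFrame:
    rows = []
    for s in sites:
        gene = ""
        if proteins and s.accession in proteins:
            names = proteins[s.accession].gene_names
            gene = names[0] if names else ""
        rows.append(
            {
                "accession": s.accession,
                "gene": gene,
                "position": s.position,
                "residue": s.residue,
                "degree": s.degree,
                "site": s.token,
                "n_support": len(s.supporting_matches),
                "n_unambiguous": s.n_unambiguous,
                "spectra": ";".join(
                    sorted({m.spectrum_id for m in s.supporting_matches})
                ),
            }
        )
    return pd.DataFrame(
        rows,
        columns=[
            "accession",
            "gene",
            "position",
            "residue",
            "degree",
            "site",
            "n_support",
            "n_unambiguous",
            "spectra",
        ],
    )


def write_tsv(path, df: pd.DataFrame) -> None:
    df.to_csv(path, sep="\t", index=False)
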