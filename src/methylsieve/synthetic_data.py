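"""Synthetic proteomes, planted methylation sites, and replicate peak lists.

Emulates the statistical structure of a MALDI-ToF peptide-mass-
fingerprinting compendium with many replicate spectra per protein:

* i.i.d. protein sequences with yeast-like residue composition and
  lognormal lengths;
* planted mono/di-methylation sites on K/R with a given stoichiometry,
  "filter-compatible" by default (on cleavable residues, hosted by D/E-free
  peptides) so the overlap/consensus filters are exercisable, or
  deliberately incompatible in adversarial mode to test rejection;
* replicate spectra (mean 11, minimum 3 per protein): unmodified tryptic
  peptides detected per replicate with a Bernoulli detection probability,
  methylated peptides with probability stoichiometry x detection; partial
  tryptic cleavage at methylated residues makes both the cleaved (0 missed
  cleavage, site at the peptide C-terminus) and read-through (1 missed
  cleavage) forms appear across replicates; Gaussian mass error
  (sigma 0.02 Da by default), uniform contaminant peaks, and a 500 Da
  low-mass cutoff.

Everything is deterministic under the mandatory seed.
"""

from __future__ import annotations

import json
from dataclasses import asdict, dataclass, field
from pathlib import Path
from typing import Sequence

import numpy as np

from .massdigest import (
    CH2,
    ProteinRecord,
    TheoreticalPeptide,
    digest,
    mh_mass,
)
from .pmf_engine import SpectrumRecord

__all__ = [
    "YEAST_AA_FREQ",
    "SimulationConfig",
    "PlantedSite",
    "generate_proteome",
    "plant_sites",
    "simulate_spectra",
    "simulate_dataset",
    "write_dataset",
]

# Approximate residue frequencies of the S. cerevisiae proteome.
YEAST_AA_FREQ = {
    "A": 0.055, "C": 0.013, "D": 0.058, "E": 0.065, "F": 0.045,
    "G": 0.050, "H": 0.022, "I": 0.066, "K": 0.073, "L": 0.096,
    "M": 0.021, "N": 0.061, "P": 0.044, "Q": 0.039, "R": 0.044,
    "S": 0.089, "T": 0.059, "V": 0.056, "W": 0.010, "Y": 0.034,
}


@dataclass
class SimulationConfig:
    """Study conditions for the synthetic compendium.

    Defaults mirror the reference data set this generator emulates: an
    average of 11 replicate spectra per protein with a minimum of 3, an
    average mass error of 0.02 Da, and strongly sub-stoichiometric
    methylation.
    """

    seed: int  # mandatory; every random draw flows from it
    n_proteins: int = 30
    length_log_mean: float = 5.9  # lognormal, median ~365 aa
    length_log_sigma: float = 0.35
    min_length: int = 120
    max_length: int = 1500
    composition: dict = field(default_factory=lambda: dict(YEAST_AA_FREQ))
    site_stoichiometry: float = 0.3
    k_site_fraction: float = 0.05
    r_site_fraction: float = 0.05
    mono_fraction: float = 0.5
    mean_replicates: float = 11.0
    min_replicates: int = 3
    detection_probability: float = 0.7
    mass_error_sigma: float = 0.02
    contaminant_rate: float = 2.0
    partial_cleavage_probability: float = 0.5
    unmodified_missed_cleavage_rate: float = 0.05
    mass_range: tuple = (500.0, 3000.0)
    suppress_before_proline: bool = True
    filter_compatible: bool = True

    def __post_init__(self):
        if self.seed is None:
            raise ValueError("seed is mandatory")
        total = sum(self.composition.values())
        if abs(total - 1.0) > 1e-6:
            raise ValueError(f"composition sums to {total}, not 1")
        for name in (
            "site_stoichiometry",
            "k_site_fraction",
            "r_site_fraction",
            "mono_fraction",
            "detection_probability",
            "partial_cleavage_probability",
            "unmodified_missed_cleavage_rate",
        ):
            v = getattr(self, name)
            if not 0.0 <= v <= 1.0:
                raise ValueError(f"{name}={v} outside [0, 1]")
        if self.min_replicates < 3:
            raise ValueError("at least 3 replicate spectra per protein")

    def rng(self) -> np.random.Generator:
        return np.random.default_rng(self.seed)


@dataclass(frozen=True)
class PlantedSite:
    accession: str
    position: int
    residue: str
    degree: int
    stoichiometry: float


def generate_proteome(config: SimulationConfig) -> list:
    """i.i.d. sequences from the configured composition; seed-deterministic."""
    rng = np.random.default_rng(config.seed)
    letters = sorted(config.composition)
    probs = np.array([config.composition[a] for a in letters])
    probs = probs / probs.sum()
    proteins = []
    for i in range(config.n_proteins):
        length = int(
            np.clip(
                rng.lognormal(config.length_log_mean, config.length_log_sigma),
                config.min_length,
                config.max_length,
            )
        )
        seq = "".join(rng.choice(letters, size=length, p=probs))
        proteins.append(
            ProteinRecord(
                accession=f"SYN{i + 1:04d}",
                sequence=seq,
                gene_names=(f"syn{i + 1}",),
            )
        )
    return proteins


def _host_forms(protein: ProteinRecord, position: int, config: SimulationConfig):
    """The cleaved (0 MC ending at site) and read-through (1 MC) host peptides.

    Returns None unless the site sits at a tryptic cleavage position with
    both forms available.
    """
    zero_mc = [
        p
        for p in digest(protein, 0, config.suppress_before_proline)
        if p.missed_cleavages == 0
    ]
    cleaved = next((p for p in zero_mc if p.end == position), None)
    if cleaved is None:
        return None
    nxt = next((p for p in zero_mc if p.start == position + 1), None)
    if nxt is None:
        return None  # site is the chain C-terminus; no read-through exists
    readthrough = TheoreticalPeptide(
        parent=protein.accession,
        start=cleaved.start,
        end=nxt.end,
        sequence=cleaved.sequence + nxt.sequence,
        missed_cleavages=1,
    )
    return cleaved, readthrough


def _filter_compatible(cleaved, readthrough, delta, mass_range) -> bool:
    lo, hi = mass_range
    for pep in (cleaved, readthrough):
        if "D" in pep.sequence or "E" in pep.sequence:
            return False
        if not (lo <= pep.mh_mass + delta <= hi):
            return False
    # unique localization: the shared (cleaved) span must carry no second
    # K/R candidate (e.g. a proline-suppressed KP/RP inside the peptide)
    if sum(cleaved.sequence.count(aa) for aa in "KR") != 1:
        return False
    return True


def plant_sites(
    proteins: Sequence,
    config: SimulationConfig,
    rng: np.random.Generator | None = None,
) -> list:
    """Sample methylation sites per residue class at the configured fractions.

    Filter-compatible mode only accepts cleavable K/R whose host peptides
    (both forms) are D/E-free and inside the detectable mass window, and
    never plants two sites on overlapping host peptides (multi-modification
    peptides are not modelled).  Adversarial mode inverts the compatibility
    requirement to exercise the pipeline's rejection paths.
    """
    if rng is None:
        rng = np.random.default_rng(config.seed + 1)
    if not any(aa in p.sequence for p in proteins for aa in "KR"):
        raise ValueError("proteome contains no K or R residues")
    fractions = {"K": config.k_site_fraction, "R": config.r_site_fraction}
    truth = []
    for protein in proteins:
        occupied: set = set()  # positions covered by a planted site's hosts
        for pos in range(protein.mature_start, protein.mature_end + 1):
            aa = protein.residue_at(pos)
            if aa not in fractions or fractions[aa] == 0.0:
                continue
            if rng.random() >= fractions[aa]:
                continue
            degree = 1 if rng.random() < config.mono_fraction else 2
            forms = _host_forms(protein, pos, config)
            if config.filter_compatible:
                if forms is None:
                    continue
                cleaved, readthrough = forms
                if not _filter_compatible(
                    cleaved, readthrough, degree * CH2, config.mass_range
                ):
                    continue
                span = set(range(readthrough.start, readthrough.end + 1))
                if span & occupied:
                    continue
                occupied |= span
            else:
                # adversarial: keep only sites the filters must reject
                if forms is not None:
                    cleaved, readthrough = forms
                    if _filter_compatible(
                        cleaved, readthrough, degree * CH2, config.mass_range
                    ):
                        continue
            truth.append(
                PlantedSite(
                    accession=protein.accession,
                    position=pos,
                    residue=aa,
                    degree=degree,
                    stoichiometry=config.site_stoichiometry,
                )
            )
    return truth


def simulate_spectra(
    proteins: Sequence,
    truth: Sequence,
    config: SimulationConfig,
    rng: np.random.Generator | None = None,
) -> list:
    """Replicate peak lists with detection noise, mass error and contaminants."""
    if rng is None:
        rng = np.random.default_rng(config.seed + 2)
    lo, hi = config.mass_range
    truth_by_prot: dict = {}
    for site in truth:
        truth_by_prot.setdefault(site.accession, []).append(site)
    spectra = []
    for protein in proteins:
        zero_mc = digest(protein, 0, config.suppress_before_proline)
        one_mc = [
            p
            for p in digest(protein, 1, config.suppress_before_proline)
            if p.missed_cleavages == 1
        ]
        sites = truth_by_prot.get(protein.accession, [])
        site_forms = []
        for site in sites:
            forms = _host_forms(protein, site.position, config)
            if forms is not None:
                site_forms.append((site, forms))
        methylated_spans = {
            (f.start, f.end) for _s, pair in site_forms for f in pair
        }
        n_rep = max(config.min_replicates, int(rng.poisson(config.mean_replicates)))
        for rep in range(n_rep):
            peaks = []
            for pep in zero_mc:
                if not (lo <= pep.mh_mass <= hi):
                    continue
                p_detect = config.detection_probability
                hosted = [s for s in sites if pep.start <= s.position <= pep.end]
                if hosted:
                    # only the unmethylated fraction yields the cleaved peptide
                    p_detect *= 1.0 - max(s.stoichiometry for s in hosted)
                if rng.random() < p_detect:
                    peaks.append(pep.mh_mass)
            for pep in one_mc:
                if not (lo <= pep.mh_mass <= hi):
                    continue
                if (pep.start, pep.end) in methylated_spans:
                    continue  # read-through at a methylated site is modelled below
                if rng.random() < (
                    config.unmodified_missed_cleavage_rate
                    * config.detection_probability
                ):
                    peaks.append(pep.mh_mass)
            for site, (cleaved, readthrough) in site_forms:
                delta = site.degree * CH2
                p_emit = site.stoichiometry * config.detection_probability
                pc = config.partial_cleavage_probability
                if pc > 0.0 and rng.random() < p_emit:
                    m = cleaved.mh_mass + delta
                    if lo <= m <= hi:
                        peaks.append(m)
                if pc < 1.0 and rng.random() < p_emit:
                    m = readthrough.mh_mass + delta
                    if lo <= m <= hi:
                        peaks.append(m)
            if config.mass_error_sigma > 0 and peaks:
                peaks = list(
                    np.asarray(peaks)
                    + rng.normal(0.0, config.mass_error_sigma, size=len(peaks))
                )
            n_cont = rng.poisson(config.contaminant_rate)
            if n_cont:
                peaks.extend(rng.uniform(lo, hi, size=n_cont))
            peaks = [p for p in peaks if p >= 500.0]
            spectra.append(
                SpectrumRecord(
                    spectrum_id=f"{protein.accession}_r{rep + 1:02d}",
                    accession=protein.accession,
                    peaks=tuple(peaks),
                )
            )
    return spectra


def simulate_dataset(config: SimulationConfig) -> tuple:
    """Proteome, ground truth and spectra from one config; fully seeded."""
    proteins = generate_proteome(config)
    truth = plant_sites(proteins, config)
    spectra = simulate_spectra(proteins, truth, config)
    return proteins, truth, spectra


def write_dataset(
    out_dir, proteins, truth, spectra, config: SimulationConfig
) -> None:
    """FASTA + per-protein replicate peak lists + truth TSV + config manifest."""
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    with open(out / "proteome.fasta", "w") as fh:
        for p in proteins:
            gene = f" GN={p.gene_names[0]}" if p.gene_names else ""
            fh.write(f">{p.accession}{gene}\n")
            for i in range(0, len(p.sequence), 60):
                fh.write(p.sequence[i : i + 60] + "\n")
    with open(out / "ground_truth.tsv", "w") as fh:
        fh.write("accession\tposition\tresidue\tdegree\tstoichiometry\n")
        for s in truth:
            fh.write(
                f"{s.accession}\t{s.position}\t{s.residue}\t{s.degree}\t"
                f"{s.stoichiometry}\n"
            )
    peak_dir = out / "peaks"
    for spec in spectra:
        d = peak_dir / spec.accession
        d.mkdir(parents=True, exist_ok=True)
        with open(d / f"{spec.spectrum_id}.txt", "w") as fh:
            for p in spec.peaks:
                fh.write(f"{p:.6f}\n")
    cfg = asdict(config)
    cfg["mass_range"] = list(cfg["mass_range"])
    with open(out / "manifest.json", "w") as fh:
        json.dump(cfg, fh, indent=2, sort_keys=True)
        fh.write("\n")
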