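"""The synthetic-data generator: determinism, limits, degradation."""

import filecmp

import numpy as np
import pytest

from methylsieve.filter_pipeline import PipelineConfig, run_pipeline
from methylsieve.massdigest import CH2, digest
from methylsieve.synthetic_data import (
    SimulationConfig,
    generate_proteome,
    plant_sites,
    simulate_dataset,
    simulate_spectra,
    write_dataset,
)


class TestConfig:
    def test_composition_must_sum_to_one(self):
        with pytest.raises(ValueError):
            SimulationConfig(seed=1, composition={"A": 0.5, "K": 0.4})

    def test_probabilities_bounded(self):
        with pytest.raises(ValueError):
            SimulationConfig(seed=1, detection_probability=1.5)

    def test_minimum_replicates_enforced(self):
        with pytest.raises(ValueError):
            SimulationConfig(seed=1, min_replicates=2)


class TestProteome:
    def test_zero_proteins_empty(self):
        assert generate_proteome(SimulationConfig(seed=1, n_proteins=0)) == []

    def test_same_seed_identical_output(self, tmp_path):
        for d in ("a", "b"):
            config = SimulationConfig(seed=42, n_proteins=5)
            write_dataset(tmp_path / d, *simulate_dataset(config), config)
        assert filecmp.cmp(
            tmp_path / "a" / "proteome.fasta", tmp_path / "b" / "proteome.fasta",
            shallow=False,
        )
        assert filecmp.cmp(
            tmp_path / "a" / "ground_truth.tsv", tmp_path / "b" / "ground_truth.tsv",
            shallow=False,
        )

    def test_degenerate_composition_gives_single_residue_peptides(self):
        config = SimulationConfig(
            seed=1, n_proteins=1, composition={"K": 1.0}, min_length=5
        )
        protein = generate_proteome(config)[0]
        assert set(protein.sequence) == {"K"}
        assert all(len(p.sequence) == 1 for p in digest(protein, 0))


class TestPlanting:
    def test_zero_fraction_empty_truth(self):
        config = SimulationConfig(seed=3, k_site_fraction=0.0, r_site_fraction=0.0)
        proteins = generate_proteome(config)
        assert plant_sites(proteins, config) == []

    def test_planted_residues_match_sequence(self):
        config = SimulationConfig(seed=3)
        proteins = generate_proteome(config)
        prot = {p.accession: p for p in proteins}
        for site in plant_sites(proteins, config):
            assert prot[site.accession].residue_at(site.position) == site.residue

    def test_no_basic_residues_rejected(self):
        config = SimulationConfig(seed=3)
        from methylsieve.massdigest import ProteinRecord

        with pytest.raises(ValueError):
            plant_sites([ProteinRecord(accession="P1", sequence="AAGG")], config)

    def test_seeded_truth_reproducible(self):
        config = SimulationConfig(seed=5)
        proteins = generate_proteome(config)
        assert plant_sites(proteins, config) == plant_sites(proteins, config)


class TestSpectra:
    def test_noise_free_limit_reproduces_theory_exactly(self):
        config = SimulationConfig(
            seed=9,
            n_proteins=6,
            k_site_fraction=0.2,
            r_site_fraction=0.2,
            mass_error_sigma=0.0,
            contaminant_rate=0.0,
            site_stoichiometry=1.0,
            detection_probability=1.0,
            unmodified_missed_cleavage_rate=0.0,
        )
        proteins = generate_proteome(config)
        truth = plant_sites(proteins, config)
        spectra = simulate_spectra(proteins, truth, config)
        assert truth  # the check below is vacuous without planted sites
        lo, hi = config.mass_range
        for protein in proteins:
            expected = set()
            zero_mc = digest(protein, 0)
            hosts = {
                s.position: s for s in truth if s.accession == protein.accession
            }
            for pep in zero_mc:
                hosted = [
                    s for s in hosts.values() if pep.start <= s.position <= pep.end
                ]
                if not hosted and lo <= pep.mh_mass <= hi:
                    expected.add(round(pep.mh_mass, 9))
            for site in hosts.values():
                cleaved = next(p for p in zero_mc if p.end == site.position)
                nxt = next(p for p in zero_mc if p.start == site.position + 1)
                delta = site.degree * CH2
                from methylsieve.massdigest import mh_mass

                read_seq = cleaved.sequence + nxt.sequence
                for m in (cleaved.mh_mass + delta, mh_mass(read_seq) + delta):
                    if lo <= m <= hi:
                        expected.add(round(m, 9))
            for spec in (s for s in spectra if s.accession == protein.accession):
                assert {round(p, 9) for p in spec.peaks} == expected

    def test_zero_stoichiometry_emits_no_methylated_peaks(self):
        config = SimulationConfig(
            seed=9, n_proteins=6, site_stoichiometry=0.0, contaminant_rate=0.0,
            mass_error_sigma=0.0,
        )
        proteins = generate_proteome(config)
        truth = plant_sites(proteins, config)
        spectra = simulate_spectra(proteins, truth, config)
        prot = {p.accession: p for p in proteins}
        for site in truth:
            zero_mc = digest(prot[site.accession], 0)
            cleaved = next(p for p in zero_mc if p.end == site.position)
            target = cleaved.mh_mass + site.degree * CH2
            for spec in (s for s in spectra if s.accession == site.accession):
                assert all(abs(p - target) > 1e-6 for p in spec.peaks)

    def test_replicate_floor_respected(self, default_run):
        _config, proteins, _truth, spectra, _result = default_run
        per_protein: dict = {}
        for s in spectra:
            per_protein[s.accession] = per_protein.get(s.accession, 0) + 1
        assert min(per_protein.values()) >= 3
        assert len(per_protein) == len(proteins)

    def test_peaks_respect_low_mass_cutoff(self, default_run):
        _config, _proteins, _truth, spectra, _result = default_run
        for spec in spectra:
            assert all(p >= 500.0 for p in spec.peaks)

    def test_raising_noise_never_improves_recovery(self):
        recoveries = []
        for sigma in (0.0, 0.02, 0.08):
            config = SimulationConfig(seed=21, n_proteins=25, mass_error_sigma=sigma)
            proteins, truth, spectra = simulate_dataset(config)
            result = run_pipeline(spectra, proteins, PipelineConfig())
            truth_keys = {(s.accession, s.position, s.degree) for s in truth}
            found = {(s.accession, s.position, s.degree) for s in result.sites}
            recoveries.append(len(found & truth_keys) / len(truth_keys))
        assert recoveries[0] >= recoveries[1] >= recoveries[2] - 1e-9

    def test_adversarial_sites_are_rejected_by_the_pipeline(self):
        config = SimulationConfig(
            seed=33, n_proteins=25, filter_compatible=False,
            mass_error_sigma=0.0, contaminant_rate=0.0,
        )
        proteins, truth, spectra = simulate_dataset(config)
        assert truth  # adversarial planting found incompatible sites
        result = run_pipeline(spectra, proteins, PipelineConfig())
        truth_keys = {(s.accession, s.position, s.degree) for s in truth}
        found = {(s.accession, s.position, s.degree) for s in result.sites}
        assert not (found & truth_keys)
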