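"""The five confidence filters, individually and end to end."""

import pytest

from methylsieve.filter_pipeline import (
    PipelineConfig,
    filter1_not_unmodified,
    filter2_no_DE,
    filter3_overlap,
    filter4_unambiguous_anchor,
    filter5_site_consensus,
    run_pipeline,
)
from methylsieve.massdigest import (
    CH2,
    ModificationSpec,
    ProteinRecord,
    TheoreticalPeptide,
)
from methylsieve.pmf_engine import PeptideMatch

MONO = ModificationSpec("monomethyl", frozenset("KR"), CH2, degree=1)
DI = ModificationSpec("dimethyl", frozenset("KR"), 2 * CH2, degree=2)

# 30-mer with lysines at 17 and 25; D/E-free
SEQ = "AAAAGGGGVVVVLLLLKAAGGVVLLKGGVV"
PROTEINS = {"P1": ProteinRecord(accession="P1", sequence=SEQ)}


def pep(start, end, mc):
    return TheoreticalPeptide("P1", start, end, SEQ[start - 1 : end], mc)


def match(peptide, mod=MONO, positions=(17,), sid="s1", qmass=1000.0, ambiguous=False):
    return PeptideMatch(
        spectrum_id=sid,
        query_mass=qmass,
        peptide=peptide,
        modification=mod,
        candidate_positions=tuple(positions),
        mass_error=0.0,
        ambiguous=ambiguous,
    )


def unmod_match(sid, qmass):
    return PeptideMatch(
        spectrum_id=sid,
        query_mass=qmass,
        peptide=pep(1, 17, 0),
        modification=None,
        candidate_positions=(),
        mass_error=0.0,
    )


class TestFilter1:
    def test_query_mass_also_unmodified_removed(self):
        m = match(pep(1, 17, 0), qmass=900.0)
        assert filter1_not_unmodified([m], [unmod_match("s1", 900.0)]) == []

    def test_query_mass_only_modified_kept(self):
        m = match(pep(1, 17, 0), qmass=900.0)
        assert filter1_not_unmodified([m], [unmod_match("s1", 901.0)]) == [m]

    def test_unmodified_match_in_other_spectrum_does_not_remove(self):
        m = match(pep(1, 17, 0), qmass=900.0, sid="s1")
        assert filter1_not_unmodified([m], [unmod_match("s2", 900.0)]) == [m]

    def test_empty_input(self):
        assert filter1_not_unmodified([], [unmod_match("s1", 900.0)]) == []


class TestFilter2:
    @pytest.mark.parametrize(
        "seq,kept", [("GLDK", False), ("GLVK", True), ("EEEK", False)]
    )
    def test_aspartate_glutamate_peptides_removed(self, seq, kept):
        p = TheoreticalPeptide("P1", 1, 4, seq, 0)
        out = filter2_no_DE([match(p, positions=(4,))])
        assert (len(out) == 1) is kept


class TestFilter3:
    def test_cleaved_plus_readthrough_overlap_kept(self):
        a = match(pep(10, 17, 0), positions=(17,), sid="s1")
        b = match(pep(10, 26, 1), positions=(17, 26), sid="s2")
        survivors, groups = filter3_overlap([a, b])
        assert set(map(id, survivors)) == {id(a), id(b)}
        assert [(g.position, len(g.matches)) for g in groups] == [(17, 2)]

    def test_two_readthrough_peptides_sharing_site_kept(self):
        a = match(pep(5, 17, 1), positions=(17,))
        b = match(pep(10, 26, 1), positions=(17, 26))
        survivors, groups = filter3_overlap([a, b])
        assert len(survivors) == 2 and groups[0].position == 17

    def test_disjoint_peptides_removed(self):
        a = match(pep(10, 17, 0), positions=(17,))
        b = match(pep(18, 26, 0), positions=(26,))
        survivors, groups = filter3_overlap([a, b])
        assert survivors == [] and groups == []

    def test_same_peptide_twice_needs_distinct_sequences_by_default(self):
        a = match(pep(10, 17, 0), positions=(17,), sid="s1")
        b = match(pep(10, 17, 0), positions=(17,), sid="s2")
        assert filter3_overlap([a, b])[0] == []
        survivors, _ = filter3_overlap([a, b], require_distinct_peptides=False)
        assert len(survivors) == 2

    def test_degree_mismatch_does_not_group(self):
        a = match(pep(10, 17, 0), mod=MONO, positions=(17,))
        b = match(pep(10, 26, 1), mod=DI, positions=(17,))
        assert filter3_overlap([a, b])[0] == []


class TestFilters4And5:
    def group(self, amb_a=False, amb_b=False, pos_a=(17,), pos_b=(17, 26)):
        a = match(pep(10, 17, 0), positions=pos_a, sid="s1", ambiguous=amb_a)
        b = match(pep(10, 26, 1), positions=pos_b, sid="s2", ambiguous=amb_b)
        _, groups = filter3_overlap([a, b])
        return groups

    @pytest.mark.parametrize(
        "amb_a,amb_b,kept",
        [(False, True, True), (True, True, False), (False, False, True)],
    )
    def test_anchor_requires_one_unambiguous_member(self, amb_a, amb_b, kept):
        groups = self.group(amb_a, amb_b)
        assert (len(filter4_unambiguous_anchor(groups)) == 1) is kept

    def test_shared_candidate_becomes_site(self):
        sites = filter5_site_consensus(self.group(), PROTEINS)
        assert [(s.position, s.residue, s.degree) for s in sites] == [(17, "K", 1)]
        assert sites[0].n_unambiguous == 2

    def test_disjoint_candidate_sets_give_no_site(self):
        a = match(pep(10, 17, 0), positions=(17,))
        b = match(pep(10, 26, 1), positions=(26,))
        _, groups = filter3_overlap([a, b])
        assert filter5_site_consensus(groups, PROTEINS) == []

    def test_mono_and_di_evidence_never_merge(self):
        a = match(pep(10, 17, 0), mod=MONO, positions=(17,))
        b = match(pep(10, 26, 1), mod=DI, positions=(17,))
        _, groups = filter3_overlap([a, b])
        assert filter5_site_consensus(groups, PROTEINS) == []
        # but each still forms a site with a same-degree partner
        c = match(pep(5, 17, 1), mod=MONO, positions=(17,))
        _, groups = filter3_overlap([a, b, c])
        sites = filter5_site_consensus(groups, PROTEINS)
        assert [(s.position, s.degree) for s in sites] == [(17, 1)]


class TestEndToEnd:
    def test_max_missed_zero_is_inconsistent_with_overlap_filter(self):
        with pytest.raises(ValueError):
            PipelineConfig(max_missed=0)

    def test_empty_spectra_give_empty_site_table(self):
        result = run_pipeline([], list(PROTEINS.values()), PipelineConfig())
        assert result.sites == []
        assert result.audit["modified_matches"] == 0

    def test_noise_free_planted_site_recovered_exactly(self, noise_free_run):
        _config, _proteins, truth, _spectra, result = noise_free_run
        truth_keys = {(s.accession, s.position, s.degree) for s in truth}
        found = {(s.accession, s.position, s.degree) for s in result.sites}
        assert found <= truth_keys  # precision 100% without noise
        assert len(found) >= 1

    def test_funnel_counts_non_increasing(self, default_run):
        *_rest, result = default_run
        a = result.audit
        stages = [
            a["modified_matches"],
            a["after_filter1"],
            a["after_filter2"],
            a["after_filter3"],
            a["after_filter4"],
        ]
        assert stages == sorted(stages, reverse=True)
        assert a["sites"] <= a["after_filter4"]

    def test_emitted_sites_respect_invariants(self, default_run):
        _config, proteins, _truth, _spectra, result = default_run
        prot = {p.accession: p for p in proteins}
        for site in result.sites:
            assert len(site.supporting_matches) >= 2
            assert site.n_unambiguous >= 1
            assert prot[site.accession].residue_at(site.position) == site.residue
            for m in site.supporting_matches:
                assert "D" not in m.peptide.sequence
                assert "E" not in m.peptide.sequence
                assert m.peptide.start <= site.position <= m.peptide.end

    def test_single_peptide_evidence_is_rejected(self):
        # one spectrum containing only the cleaved methylated form
        from methylsieve.pmf_engine import SpectrumRecord
        from methylsieve.massdigest import digest

        protein = PROTEINS["P1"]
        cleaved = next(p for p in digest(protein, 0) if p.end == 17)
        spec = SpectrumRecord("s1", "P1", (cleaved.mh_mass + CH2,))
        result = run_pipeline([spec], [protein], PipelineConfig())
        assert result.sites == []
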