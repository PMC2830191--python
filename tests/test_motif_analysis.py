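"""Windows, motif matching and position-specific enrichment."""

import numpy as np
import pytest

from methylsieve.fixtures import load_table5, parse_site_token
from methylsieve.massdigest import ProteinRecord
from methylsieve.motif_analysis import (
    FLANK,
    MOTIFS,
    Motif,
    extract_window,
    match_motif,
    positional_enrichment,
    proteome_background,
    window_from_string,
)

# glyceraldehyde-3-phosphate dehydrogenase context: its published dimethyl-R11
# window spans residues 1-21, so a synthetic protein starting with that window
# re-derives it exactly (including the N-terminal clip at offset -10)
TDH3_WINDOW = "MVRVAINGFGRIGRLVMRIAL"


class TestWindows:
    def test_published_window_rederives_from_sequence(self):
        protein = ProteinRecord(accession="P00359", sequence=TDH3_WINDOW + "AAAA")
        w = extract_window(protein, 11, "R")
        assert w.window == TDH3_WINDOW
        assert w.start_offset == -10
        assert w.letter_at(0) == "R"

    def test_clipping_near_termini(self):
        protein = ProteinRecord(accession="P1", sequence="AAAAKAAAAAAA")  # 12 aa
        w = extract_window(protein, 5, "K")
        assert list(w.offsets) == list(range(-4, 8))
        first = ProteinRecord(accession="P1", sequence="KAAAA")
        w1 = extract_window(first, 1, "K")
        assert w1.start_offset == 0 and w1.letter_at(-1) is None

    def test_center_mismatch_is_an_error(self):
        protein = ProteinRecord(accession="P1", sequence="AAAAKAAAA")
        with pytest.raises(ValueError):
            extract_window(protein, 5, "R")
        with pytest.raises(ValueError):
            extract_window(protein, 99, "K")

    def test_every_fixture_window_centers_on_its_residue(self):
        for row in load_table5().itertuples():
            tok = parse_site_token(row.site)
            w = window_from_string(row.accession, tok.position, tok.residue, row.window)
            assert w.letter_at(0) == tok.residue


class TestMotifMatching:
    def test_gxxrxg_matches_published_examples(self):
        w = window_from_string("P00359", 11, "R", TDH3_WINDOW)
        assert match_motif(w, MOTIFS["GXXRXG"])
        assert match_motif(w, MOTIFS["RXG"])
        assert not match_motif(w, MOTIFS["RGX"])

    def test_wxxxr_matches_tryptophan_at_minus_four(self):
        w = window_from_string("P38737", 542, "R", "ARLFNIWGTVRTNRFDIIEES")
        assert match_motif(w, MOTIFS["WXXXR"])

    def test_wrong_center_never_matches(self):
        w = window_from_string("P1", 11, "K", "AAAAAAAAAAKAAAAAAAAAA")
        assert not match_motif(w, MOTIFS["WXXXR"])
        assert not match_motif(w, MOTIFS["MK"])  # no M at -1

    def test_mk_motif(self):
        w = window_from_string("P41814", 436, "K", "RGKLHPLMTMKGGGGYLMWCH")
        assert match_motif(w, MOTIFS["MK"])

    def test_offsets_beyond_window_disqualify(self):
        # clipped window lacking position -4 cannot match WXXXR
        protein = ProteinRecord(accession="P1", sequence="WARAAAA")
        w = extract_window(protein, 3, "R")  # offsets -2..+4 only
        assert not match_motif(w, MOTIFS["WXXXR"])

    def test_pattern_outside_flank_rejected(self):
        with pytest.raises(ValueError):
            Motif("bad", frozenset("R"), {-11: "W"})


class TestEnrichment:
    def windows(self, strings, residue="K"):
        return [
            window_from_string(f"P{i}", FLANK + 1, residue, s)
            for i, s in enumerate(strings)
        ]

    def test_exact_binomial_tail_matches_independent_oracle(self):
        # 5 of 7 windows with M at -1, background 0.021:
        # sum_{k=5..7} C(7,k) 0.021^k 0.979^(7-k) = 8.2791323093115e-08
        strings = ["A" * 9 + "MK" + "A" * 10] * 5 + ["A" * 10 + "K" + "A" * 10] * 2
        res = positional_enrichment(
            self.windows(strings), {"M": 0.021, "A": 0.9}, n_tests=1
        )
        hit = next(r for r in res if r.offset == -1 and r.residue == "M")
        assert hit.observed == 5 and hit.n_windows == 7
        assert hit.raw_p == pytest.approx(8.2791323093115e-08, rel=1e-9)

    def test_null_observation_is_not_significant(self):
        # observed proportion equal to background keeps the tail >= 0.5
        strings = ["A" * 9 + "MK" + "A" * 10] * 2 + ["A" * 10 + "K" + "A" * 10] * 8
        res = positional_enrichment(
            self.windows(strings), {"M": 0.2, "A": 0.8}, n_tests=1
        )
        hit = next(r for r in res if r.offset == -1 and r.residue == "M")
        assert hit.raw_p >= 0.5

    def test_bonferroni_multiplication_and_cap(self):
        strings = ["A" * 9 + "MK" + "A" * 10] * 5 + ["A" * 10 + "K" + "A" * 10] * 2
        res = positional_enrichment(
            self.windows(strings), {"M": 0.021, "A": 0.9}, n_tests=420
        )
        hit = next(r for r in res if r.offset == -1 and r.residue == "M")
        assert hit.corrected_p == pytest.approx(hit.raw_p * 420)
        assert all(r.corrected_p >= r.raw_p for r in res)
        assert all(r.corrected_p <= 1.0 for r in res)

    def test_clipping_aware_denominator(self):
        protein = ProteinRecord(accession="P1", sequence="KAAAA")
        clipped = extract_window(protein, 1, "K")  # covers offsets 0..+4 only
        full = self.windows(["A" * 10 + "K" + "A" * 10])
        res = positional_enrichment(full + [clipped], {"A": 1.0}, n_tests=1)
        minus_one = [r for r in res if r.offset == -1 and r.residue == "A"]
        assert minus_one[0].n_windows == 1

    def test_zero_background_with_observation_flagged(self):
        strings = ["A" * 9 + "MK" + "A" * 10]
        res = positional_enrichment(self.windows(strings), {"A": 1.0}, n_tests=1)
        hit = next(r for r in res if r.offset == -1 and r.residue == "M")
        assert hit.degenerate and hit.raw_p > 0

    def test_prop_test_variant_agrees_in_direction(self):
        strings = ["A" * 9 + "MK" + "A" * 10] * 5 + ["A" * 10 + "K" + "A" * 10] * 2
        binom = positional_enrichment(
            self.windows(strings), {"M": 0.021, "A": 0.9}, n_tests=1
        )
        prop = positional_enrichment(
            self.windows(strings), {"M": 0.021, "A": 0.9}, n_tests=1, method="prop"
        )
        b = next(r for r in binom if r.offset == -1 and r.residue == "M")
        p = next(r for r in prop if r.offset == -1 and r.residue == "M")
        assert b.raw_p < 1e-4 and p.raw_p < 1e-4

    def test_family_wise_error_rate_controlled_under_null(self):
        # windows drawn i.i.d. from the background: corrected p < 0.05
        # anywhere should occur in <= ~5% of replicates
        rng = np.random.default_rng(23)
        letters = sorted("ACDEFGHIKLMNPQRSTVWY")
        probs = np.full(20, 0.05)
        false_hits = 0
        n_reps = 60
        for _ in range(n_reps):
            strings = [
                "".join(rng.choice(letters, size=10, p=probs))
                + "K"
                + "".join(rng.choice(letters, size=10, p=probs))
                for _ in range(15)
            ]
            res = positional_enrichment(
                self.windows(strings), dict(zip(letters, probs))
            )
            if any(r.corrected_p < 0.05 for r in res):
                false_hits += 1
        assert false_hits / n_reps <= 0.10  # 5% nominal + sampling slack

    def test_background_from_proteome(self):
        proteins = [ProteinRecord(accession="P1", sequence="AAKK")]
        bg = proteome_background(proteins)
        assert bg["A"] == 0.5 and bg["K"] == 0.5 and bg["W"] == 0.0
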