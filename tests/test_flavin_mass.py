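import itertools

import numpy as np
import pytest
from hypothesis import given
from hypothesis import strategies as st

from rdhc_miner.flavin_mass import (
    FMN_ADDUCT_AVERAGE,
    FMN_ADDUCT_MONO,
    FMN_AVERAGE,
    FMN_MONO,
    PROTON,
    WATER_MONO,
    MassError,
    annotate_spectrum,
    apply_met_excision,
    diagnostic_ions,
    flavinylate,
    fragment_ions,
    make_proteoform,
    peptide_masses,
    protein_mass,
    variant_effect,
)

AA = "ACDEFGHIKLMNPQRSTVWY"


class TestProteinMass:
    def test_glycine_average_mass(self):
        assert protein_mass("G", "average") == pytest.approx(75.07, abs=0.005)

    def test_diglycine_average_mass(self):
        assert protein_mass("GG", "average") == pytest.approx(132.12, abs=0.005)

    @given(st.text(alphabet=AA, min_size=1, max_size=40),
           st.text(alphabet=AA, min_size=1, max_size=40),
           st.sampled_from(["average", "monoisotopic"]))
    def test_additivity_minus_one_water(self, s1, s2, mode):
        """Chain concatenation adds residue masses and releases one water."""
        water = protein_mass("G", mode) - (
            protein_mass("GG", mode) - protein_mass("G", mode)
        )
        combined = protein_mass(s1 + s2, mode)
        assert combined == pytest.approx(
            protein_mass(s1, mode) + protein_mass(s2, mode) - water, abs=1e-6
        )

    def test_empty_and_nonstandard_rejected(self):
        with pytest.raises(MassError):
            protein_mass("", "average")
        with pytest.raises(MassError):
            protein_mass("AXC", "average")
        with pytest.raises(MassError):
            protein_mass("AC", "bogus-mode")


class TestMetExcision:
    def test_small_second_residue_triggers_excision(self):
        assert apply_met_excision("MGQSV") == "GQSV"

    def test_bulky_second_residue_blocks_excision(self):
        assert apply_met_excision("MKQSV") == "MKQSV"

    def test_no_initiator_met_unchanged(self):
        assert apply_met_excision("GQSV") == "GQSV"

    def test_forced_rules(self):
        assert apply_met_excision("MKQ", rule="always") == "KQ"
        assert apply_met_excision("MGQ", rule="never") == "MGQ"


class TestFlavinylate:
    def test_fmn_average_mass_matches_formula(self):
        assert round(FMN_AVERAGE, 1) == 456.3

    def test_adduct_is_fmn_minus_water(self):
        assert FMN_ADDUCT_AVERAGE == pytest.approx(438.33, abs=0.005)
        assert FMN_ADDUCT_MONO == pytest.approx(438.0940, abs=0.0005)

    def test_zero_fmn_is_identity(self):
        assert flavinylate(1234.5, 0, "average") == 1234.5

    def test_negative_count_rejected(self):
        with pytest.raises(MassError):
            flavinylate(1000.0, -1)

    @given(st.floats(500, 50000), st.integers(0, 3),
           st.sampled_from(["average", "monoisotopic"]))
    def test_round_trip(self, mass, n, mode):
        adduct = FMN_ADDUCT_AVERAGE if mode == "average" else FMN_ADDUCT_MONO
        assert flavinylate(mass, n, mode) - n * adduct == pytest.approx(mass, abs=1e-6)

    def test_intact_chain_reproduces_printed_masses(self):
        """Met-cleaved mass + one FMN adduct gives the flavoprotein mass."""
        assert round(flavinylate(18774.1, 1, "average"), 1) == 19212.4


class TestPeptideMasses:
    def test_fixed_carbamidomethyl_applied(self):
        (pm,) = peptide_masses(["CK"], fixed_mods=["carbamidomethyl-C"])
        assert pm.mass == pytest.approx(protein_mass("CK", "monoisotopic") + 57.0215, abs=0.001)

    def test_single_threonine_two_proteoforms(self):
        forms = peptide_masses(
            ["GSTV"], fixed_mods=[], variable_mods=["fmn-T"], max_var=1
        )
        assert len(forms) == 2
        deltas = sorted(round(f.mass - protein_mass("GSTV", "monoisotopic"), 4) for f in forms)
        assert deltas[0] == 0.0
        assert deltas[1] == pytest.approx(round(FMN_ADDUCT_MONO, 4))

    def test_enumeration_matches_powerset_oracle(self):
        """Variable-mod enumeration equals a brute-force powerset filter."""
        seq = "TMTK"  # 2 threonines, 1 methionine
        forms = peptide_masses(
            [seq], fixed_mods=[], variable_mods=["fmn-T", "oxidation-M"], max_var=2
        )
        sites = [(1, "fmn-T"), (3, "fmn-T"), (2, "oxidation-M")]
        expected = [
            combo
            for k in range(3)
            for combo in itertools.combinations(sites, k)
        ]
        assert len(forms) == len(expected) == 7
        got = sorted(
            tuple(sorted((s, n) for s, n, _ in f.modifications)) for f in forms
        )
        want = sorted(tuple(sorted(c)) for c in expected)
        assert got == want

    def test_unknown_modification_rejected(self):
        with pytest.raises(MassError):
            peptide_masses(["AK"], fixed_mods=["nonsense"])


class TestDiagnosticIons:
    def test_default_table_values(self):
        table = dict(diagnostic_ions("monoisotopic"))
        assert table["FMN+H"] == pytest.approx(FMN_MONO + PROTON, abs=1e-6)
        assert table["FMN+H"] == pytest.approx(457.1119, abs=0.001)
        assert table["FMN+H-H2O"] == pytest.approx(457.1119 - 18.0106, abs=0.001)
        assert table["FMN+H-HPO3"] == pytest.approx(377.1456, abs=0.001)

    def test_custom_table_replaces_defaults(self):
        assert diagnostic_ions(custom=[]) == []


class TestAnnotateSpectrum:
    def _flavinylated_peptide(self):
        # GSTVSSHAK with FMN on the threonine
        return make_proteoform("GSTVSSHAK", [(3, "fmn-T")])

    def test_self_generated_spectrum_fully_matched(self):
        pf = self._flavinylated_peptide()
        ions = fragment_ions(pf) + diagnostic_ions(pf.mode)
        peaks = sorted((mz, 100.0) for _, mz in ions)
        result = annotate_spectrum(peaks, pf, parent_mz=pf.mass + PROTON, charge=1)
        assert len(result.matches) == len(peaks)
        assert result.parent_ok is True
        assert all(abs(m.error_da) <= 0.05 for m in result.matches)

    def test_displaced_peak_beyond_tolerance_unmatched(self):
        pf = self._flavinylated_peptide()
        mz = fragment_ions(pf)[0][1]
        result = annotate_spectrum([(mz + 0.06, 10.0)], pf, frag_tol_da=0.05)
        assert result.matches == ()

    def test_parent_over_ppm_tolerance_fails(self):
        pf = self._flavinylated_peptide()
        bad_parent = (pf.mass * (1 + 10.1e-6)) + PROTON
        result = annotate_spectrum([], pf, parent_mz=bad_parent, charge=1)
        assert result.parent_ok is False

    def test_unsorted_peaks_rejected(self):
        pf = self._flavinylated_peptide()
        with pytest.raises(MassError):
            annotate_spectrum([(500.0, 1.0), (400.0, 1.0)], pf)

    def test_nonpositive_tolerance_rejected(self):
        pf = self._flavinylated_peptide()
        with pytest.raises(MassError):
            annotate_spectrum([], pf, frag_tol_da=0.0)

    def test_noise_peaks_never_remove_true_matches(self, rng):
        pf = self._flavinylated_peptide()
        ions = fragment_ions(pf)
        true_peaks = [(mz, 100.0) for _, mz in ions]
        noise = [(float(mz), 1.0) for mz in rng.uniform(100, 2000, 200)]
        peaks = sorted(true_peaks + noise)
        result = annotate_spectrum(peaks, pf)
        matched_obs = {round(m.observed_mz, 6) for m in result.matches}
        for mz, _ in true_peaks:
            assert round(mz, 6) in matched_obs

    def test_fragment_series_carries_modification(self):
        pf = self._flavinylated_peptide()
        ions = dict(fragment_ions(pf))
        plain = dict(fragment_ions(make_proteoform("GSTVSSHAK")))
        # b2 precedes the modified T, b3 includes it; y-ions past the T carry it too
        assert ions["b2"] == pytest.approx(plain["b2"], abs=1e-9)
        assert ions["b3"] == pytest.approx(plain["b3"] + FMN_ADDUCT_MONO, abs=1e-6)
        assert ions["y7"] == pytest.approx(plain["y7"] + FMN_ADDUCT_MONO, abs=1e-6)
        assert ions["y6"] == pytest.approx(plain["y6"], abs=1e-9)


class TestVariantEffect:
    WT = "TVTGSTVSSHA"

    def test_acceptor_substitution_abolishes_flavinylation(self):
        report = variant_effect(self.WT, "T6V")
        assert report.variant_sequence == "TVTGSVVSSHA"
        assert report.hits_before == 1
        assert report.hits_after == 0
        assert report.flavinylatable is False

    def test_substitution_outside_motif_is_neutral(self):
        report = variant_effect(self.WT, "H10Q")
        assert report.flavinylatable is True
        assert report.hits_after == 1

    def test_wrong_original_residue_rejected(self):
        with pytest.raises(MassError, match="position 6"):
            variant_effect(self.WT, "S6V")

    def test_malformed_substitution_rejected(self):
        with pytest.raises(MassError):
            variant_effect(self.WT, "6V")
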