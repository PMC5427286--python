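"""Cross-linking MS arithmetic: digestion, masses, quartets, matching."""

import numpy as np
import pytest
from hypothesis import given, settings, strategies as hst

from oligoxl import xlms
from oligoxl.synthetic import make_msms_spectrum, make_peaklists

AA = "ACDEFGHIKLMNPQRSTVWY"
peptide_seqs = hst.text(alphabet=AA, min_size=1, max_size=25)


class TestDigest:
    def test_exhaustive_enumeration_oracle(self):
        # brute force for AKRA: fragments AK | R | A, all join windows
        peps = {p.sequence for p in xlms.digest("AKRA", max_missed=2)}
        assert peps == {"AK", "R", "A", "AKR", "RA", "AKRA"}

    def test_no_cleavage_before_proline(self):
        peps = xlms.digest("AAKPAA", max_missed=0)
        assert [p.sequence for p in peps] == ["AAKPAA"]

    def test_hsp21_n_terminal_peptide_span(self, hsp21_sequence):
        spans = {p.sequence: p.span for p in xlms.digest(hsp21_sequence)}
        assert spans["MQDQR"] == (1, 5)
        assert spans["APWDIKEEEHEIK"] == (84, 96)
        assert spans["KEDSDDSWSGR"] == (126, 136)
        assert spans["TKVER"] == (172, 176)

    def test_zero_missed_cleavage_peptides_tile_sequence(self, hsp21_sequence):
        zero = [p for p in xlms.digest(hsp21_sequence) if
                p.missed_cleavages == 0]
        zero.sort(key=lambda p: p.span)
        assert "".join(p.sequence for p in zero) == hsp21_sequence
        # spans are contiguous
        for a, b in zip(zero, zero[1:]):
            assert a.span[1] + 1 == b.span[0]

    def test_illegal_character_raises(self):
        with pytest.raises(xlms.SequenceError):
            xlms.digest("AKZ")


class TestMasses:
    def test_published_acd_peptide_mz(self):
        # MALDI [M+H]+ of the ACD reporter peptide and its 15N form
        assert xlms.peptide_mz("APWDIKEEEHEIK") == pytest.approx(1623.8,
                                                                 abs=0.1)
        p15 = xlms.Peptide("APWDIKEEEHEIK", label="15N")
        assert xlms.peptide_mz(p15) == pytest.approx(1641.8, abs=0.1)

    def test_glycine_hand_sum(self):
        # residue 57.02146 + water 18.01056 + proton 1.00728
        assert xlms.peptide_mz("G") == pytest.approx(76.0393, abs=1e-3)

    def test_nitrogen_counts(self):
        assert xlms.nitrogen_count("G") == 1
        assert xlms.nitrogen_count("R") == 4
        assert xlms.nitrogen_count("APWDIKEEEHEIK") == 18

    def test_charge_algebra(self):
        m1 = xlms.peptide_mz("APWDIKEEEHEIK", charge=1)
        m2 = xlms.peptide_mz("APWDIKEEEHEIK", charge=2)
        assert (m1 - xlms.PROTON) == pytest.approx(2 * m2 - 2 * xlms.PROTON,
                                                   abs=1e-6)

    def test_met_oxidation_modification(self):
        plain = xlms.peptide_mass(xlms.Peptide("MQDQR", (1, 5)))
        ox = xlms.peptide_mass(xlms.Peptide("MQDQR", (1, 5),
                                            modifications={1: 15.994915}))
        assert ox - plain == pytest.approx(15.994915, abs=1e-9)

    @settings(deadline=None, max_examples=100, derandomize=True)
    @given(peptide_seqs)
    def test_15n_shift_equals_nitrogen_count(self, seq):
        light = xlms.peptide_mass(xlms.Peptide(seq, label="14N"))
        heavy = xlms.peptide_mass(xlms.Peptide(seq, label="15N"))
        assert heavy - light == pytest.approx(
            xlms.nitrogen_count(seq) * 0.9970349, abs=1e-9)


class TestCrossLinkMass:
    def test_internal_linker_additivity(self):
        pa, pb = xlms.Peptide("MQDQR"), xlms.Peptide("GEQK")
        sp = xlms.CrossLinkSpecies(pa, pb, None, None, "BS3_internal")
        assert xlms.crosslink_mass(sp) - (
            xlms.peptide_mass(pa) + xlms.peptide_mass(pb)) == pytest.approx(
            138.06808, abs=1e-9)

    def test_symmetric_in_peptide_order(self):
        pa, pb = xlms.Peptide("MQDQR"), xlms.Peptide("GEQK")
        ab = xlms.CrossLinkSpecies(pa, pb, None, None, "BS3_internal")
        ba = xlms.CrossLinkSpecies(pb, pa, None, None, "BS3_internal")
        assert xlms.crosslink_mass(ab) == pytest.approx(
            xlms.crosslink_mass(ba), abs=1e-12)

    def test_deadend_on_protein_n_terminus(self):
        pep = xlms.Peptide("MQDQR", (1, 5))
        sp = xlms.CrossLinkSpecies(pep, None, 1, None, "BS3_deadend")
        assert xlms.crosslink_mass(sp) - xlms.peptide_mass(pep) == \
            pytest.approx(156.07864, abs=1e-9)

    def test_internal_without_partner_raises(self):
        with pytest.raises(xlms.SpeciesError):
            xlms.CrossLinkSpecies(xlms.Peptide("MQDQR"), None, 1, None,
                                  "BS3_internal")

    def test_non_lysine_site_raises(self):
        pep = xlms.Peptide("AGGA", (10, 13))
        with pytest.raises(xlms.SpeciesError, match="neither lysine"):
            xlms.CrossLinkSpecies(pep, None, 11, None, "BS3_deadend")


class TestQuartet:
    @staticmethod
    def species(seq_a, seq_b):
        return xlms.CrossLinkSpecies(xlms.Peptide(seq_a), xlms.Peptide(seq_b),
                                     None, None, "BS3_internal")

    def test_total_shift_closed_form(self):
        sp = self.species("ISVEDNVLVIKGEQK", "KEDSDDSWSGR")
        q = xlms.predict_quartet(sp)
        assert q.masses[3] - q.masses[0] == pytest.approx(
            (q.n_a + q.n_b) * 0.9970349, abs=1e-9)
        assert q.masses[1] - q.masses[0] == pytest.approx(
            min(q.n_a, q.n_b) * 0.9970349, abs=1e-9)
        # nitrogen counts from the two peptides' atomic compositions
        assert q.n_a == xlms.nitrogen_count("ISVEDNVLVIKGEQK")
        assert q.n_b == xlms.nitrogen_count("KEDSDDSWSGR")

    def test_equal_nitrogen_counts_collapse_middle_peaks(self):
        sp = self.species("GGK", "AGK")  # both 4 N
        q = xlms.predict_quartet(sp)
        assert q.n_a == q.n_b
        assert q.masses[1] == pytest.approx(q.masses[2], abs=1e-12)

    def test_masses_ascending(self):
        sp = self.species("MQDQR", "AELKNGVLFITIPK")
        q = xlms.predict_quartet(sp)
        assert q.masses[0] < q.masses[1] <= q.masses[2] < q.masses[3]

    def test_deadend_has_no_quartet(self):
        sp = xlms.CrossLinkSpecies(xlms.Peptide("MQDQR"), None, None, None,
                                   "BS3_deadend")
        with pytest.raises(xlms.SpeciesError):
            xlms.predict_quartet(sp)


class TestClassifyHybrid:
    @staticmethod
    def quartet():
        sp = TestQuartet.species("ISVEDNVLVIKGEQK", "KEDSDDSWSGR")
        return xlms.predict_quartet(sp)

    def test_all_four_peaks_is_hybrid(self):
        q = self.quartet()
        pl = xlms.PeakList(np.array(q.mz(1)), np.full(4, 1e4))
        assert xlms.classify_hybrid(pl, q) == "hybrid_signature"

    def test_outer_only_is_intra(self):
        q = self.quartet()
        mz = q.mz(1)
        pl = xlms.PeakList(np.array([mz[0], mz[3]]), np.full(2, 1e4))
        assert xlms.classify_hybrid(pl, q) == "intra_signature"

    def test_single_mixed_peak_is_not_detected(self):
        q = self.quartet()
        mz = q.mz(1)
        pl = xlms.PeakList(np.array([mz[0], mz[1], mz[3]]), np.full(3, 1e4))
        assert xlms.classify_hybrid(pl, q) == "not_detected"

    def test_empty_list_not_detected(self):
        q = self.quartet()
        pl = xlms.PeakList(np.array([100.0]), np.array([0.0]))
        assert xlms.classify_hybrid(
            xlms.PeakList(np.empty(0), np.empty(0)), q) == "not_detected"
        assert xlms.classify_hybrid(pl, q) == "not_detected"

    def test_no_false_hybrid_calls_under_decoys(self):
        # dense uniform decoys must not fake both mixed peaks at 10 ppm
        truth = [("ISVEDNVLVIKGEQK", "KEDSDDSWSGR")]
        false_calls = 0
        for seed in range(20):
            pl, _ = make_peaklists(
                [], truth, ppm_jitter=0.0, decoy_density=1.0, seed=seed,
                hybrid=False)
            sp = TestQuartet.species(*truth[0])
            q = xlms.predict_quartet(sp)
            if xlms.classify_hybrid(pl, q) == "hybrid_signature":
                false_calls += 1
        assert false_calls == 0


class TestMatchCandidates:
    def test_recovers_planted_crosslink(self, hsp21_sequence):
        pa = xlms.Peptide("MQDQR", (1, 5))
        pb = xlms.Peptide("ENSIDVVQQGQQKGNQGSSVEK", (6, 27))
        sp = xlms.CrossLinkSpecies(pa, pb, 1, 18, "BS3_internal")
        mz = xlms.crosslink_mass(sp) + xlms.PROTON
        pl = xlms.PeakList(np.array([mz]), np.array([1e5]))
        cands = xlms.match_candidates(pl, hsp21_sequence, ppm=10.0)
        pairs = {(c["species"].peptide_a.sequence,
                  c["species"].peptide_b.sequence if c["species"].peptide_b
                  else None) for c in cands}
        assert ("MQDQR", "ENSIDVVQQGQQKGNQGSSVEK") in pairs or \
               ("ENSIDVVQQGQQKGNQGSSVEK", "MQDQR") in pairs

    def test_empty_peaklist_empty_candidates(self, hsp21_sequence):
        pl = xlms.PeakList(np.empty(0), np.empty(0))
        assert xlms.match_candidates(pl, hsp21_sequence) == []

    def test_tolerance_boundary(self):
        seq = "AKGGR"
        pep = [p for p in xlms.digest(seq) if p.sequence == "AK"][0]
        sp = xlms.CrossLinkSpecies(pep, pep, 2, 2, "BS3_internal")
        mz = xlms.crosslink_mass(sp) + xlms.PROTON
        inside = xlms.PeakList(np.array([mz * (1 + 8e-6)]), np.array([1.0]))
        outside = xlms.PeakList(np.array([mz * (1 + 20e-6)]), np.array([1.0]))
        hits_in = [c for c in xlms.match_candidates(inside, seq)
                   if c["species"].linker == "BS3_internal"]
        hits_out = [c for c in xlms.match_candidates(outside, seq)
                    if c["species"].linker == "BS3_internal"]
        assert hits_in and not hits_out


class TestFragmentAcceptance:
    @staticmethod
    def species():
        pa = xlms.Peptide("APWDIKEEEHEIK", (84, 96))
        pb = xlms.Peptide("TKVER", (172, 176))
        return xlms.CrossLinkSpecies(pa, pb, 89, 173, "BS3_internal")

    def test_full_theoretical_spectrum_accepted(self):
        sp = self.species()
        spec = make_msms_spectrum(sp, 1.0, 1.0, seed=0)
        res = xlms.fragment_acceptance(sp, spec)
        assert res["coverage_a"] == pytest.approx(1.0)
        assert res["coverage_b"] == pytest.approx(1.0)
        assert res["accepted"]

    def test_ablated_partner_rejected(self):
        sp = self.species()
        spec = make_msms_spectrum(sp, 1.0, 0.0, seed=0)
        res = xlms.fragment_acceptance(sp, spec)
        assert res["coverage_b"] == 0.0
        assert not res["accepted"]

    def test_coverage_threshold_boundary(self):
        # exactly 30% of both ladders is accepted; just below is not
        sp = self.species()
        ions_a = xlms.fragment_ions(sp, "a")
        ions_b = xlms.fragment_ions(sp, "b")
        import math
        n_a = math.ceil(0.30 * len(ions_a))
        n_b = math.ceil(0.30 * len(ions_b))
        assert n_a / len(ions_a) >= 0.30 and n_b / len(ions_b) >= 0.30
        mz = np.concatenate([ions_a[:n_a], ions_b[:n_b]])
        prec = (xlms.crosslink_mass(sp) + 3 * xlms.PROTON) / 3
        spec = xlms.Spectrum(prec, 3, mz, np.full(len(mz), 1e3),
                             precursor_intensity=1e4)
        assert xlms.fragment_acceptance(sp, spec)["accepted"]
        mz_low = np.concatenate([ions_a[:n_a - 1], ions_b[:n_b]])
        spec_low = xlms.Spectrum(prec, 3, mz_low,
                                 np.full(len(mz_low), 1e3),
                                 precursor_intensity=1e4)
        assert not xlms.fragment_acceptance(sp, spec_low)["accepted"]

    def test_weak_precursor_rejected(self):
        sp = self.species()
        spec = make_msms_spectrum(sp, 1.0, 1.0, seed=0,
                                  precursor_intensity=500.0)
        assert not xlms.fragment_acceptance(sp, spec)["accepted"]

    def test_precursor_mismatch_raises(self):
        sp = self.species()
        spec = make_msms_spectrum(sp, 1.0, 1.0, seed=0)
        spec.precursor_mz *= 1.01
        with pytest.raises(xlms.SpeciesError, match="precursor"):
            xlms.fragment_acceptance(sp, spec)


class TestIsotopeDilution:
    def test_equal_intensities_give_unity(self):
        pl = xlms.PeakList(np.array([1623.8, 1641.7]), np.array([5e4, 5e4]))
        res = xlms.isotope_dilution_ratio(pl, 1623.8, 1641.7)
        assert res["ratio"] == pytest.approx(1.0)

    def test_fully_digested_analyte_gives_zero(self):
        pl = xlms.PeakList(np.array([1641.7]), np.array([5e4]))
        res = xlms.isotope_dilution_ratio(pl, 1623.8, 1641.7)
        assert res["ratio"] == 0.0 and res["defined"]

    def test_missing_reference_is_undefined(self):
        pl = xlms.PeakList(np.array([1623.8]), np.array([5e4]))
        assert not xlms.isotope_dilution_ratio(pl, 1623.8, 1641.7)["defined"]

    def test_three_to_one_mixture(self):
        rng = np.random.default_rng(0)
        pl = xlms.PeakList(np.array([1623.8, 1641.7]),
                           np.array([3e4 * (1 + rng.normal() * 0.01), 1e4]))
        res = xlms.isotope_dilution_ratio(pl, 1623.8, 1641.7)
        assert res["ratio"] == pytest.approx(3.0, rel=0.05)
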