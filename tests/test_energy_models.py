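"""Energy matrices, symmetry operations and additive reconstruction."""
import itertools

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

import symmotif as sm
from symmotif.energy_models import (
    FitError,
    InvalidSequenceError,
    _mirror,
    reverse_complement,
)
from symmotif.synthetic_sites import index_to_sequence


def all_kmers(k):
    return ("".join(t) for t in itertools.product("ACGT", repeat=k))


class TestSiteEnergy:
    def test_toy_values(self, toy_matrix):
        assert sm.site_energy(toy_matrix, "CT") == pytest.approx(1.0)
        assert sm.site_energy(toy_matrix, "AT") == 0.0  # consensus

    @pytest.mark.parametrize("mid", sm.DEFAULT_MODEL_IDS)
    def test_consensus_is_zero(self, models, mid):
        m = models[mid]
        assert sm.site_energy(m, m.consensus) == 0.0

    def test_length_mismatch(self, toy_matrix):
        with pytest.raises(InvalidSequenceError, match="length"):
            sm.site_energy(toy_matrix, "ACG")

    def test_bad_base_names_position(self, toy_matrix):
        with pytest.raises(InvalidSequenceError, match="position 2"):
            sm.site_energy(toy_matrix, "AN")

    def test_roundtrip_with_generated_sample(self, models, m7a1_sample):
        m = models["M7A-1"]
        for site, energy in zip(m7a1_sample.sites, m7a1_sample.energies):
            assert sm.site_energy(m, site) == pytest.approx(energy, abs=1e-12)


class TestReverseComplementMatrix:
    @pytest.mark.parametrize("mid", sm.DEFAULT_MODEL_IDS)
    def test_involution(self, models, mid):
        m = models[mid]
        assert sm.reverse_complement_matrix(sm.reverse_complement_matrix(m)) == m

    def test_even_symmetric_fixed_point(self, models):
        m = models["M6S-1"]
        assert sm.reverse_complement_matrix(m) == m

    def test_exhaustive_strand_identity(self, toy_matrix):
        rc = sm.reverse_complement_matrix(toy_matrix)
        for s in all_kmers(2):
            assert sm.site_energy(rc, s) == pytest.approx(
                sm.site_energy(toy_matrix, reverse_complement(s))
            )


class TestClassifySymmetry:
    @pytest.mark.parametrize(
        "mid,expected",
        [
            ("M6S-1", sm.SymmetryClass.EVEN_SYMMETRIC),
            ("M6S-2", sm.SymmetryClass.EVEN_SYMMETRIC),
            ("M7S-1", sm.SymmetryClass.ODD_SYMMETRIC),
            ("M7S-2", sm.SymmetryClass.ODD_SYMMETRIC),
            ("M7A-1", sm.SymmetryClass.ASYMMETRIC),
            ("M6A-1", sm.SymmetryClass.ASYMMETRIC),
        ],
    )
    def test_default_models(self, models, mid, expected):
        assert sm.classify_symmetry(models[mid]) is expected

    def test_toy_is_asymmetric(self, toy_matrix):
        assert sm.classify_symmetry(toy_matrix) is sm.SymmetryClass.ASYMMETRIC


class TestMakeVariant:
    def test_swap_56_relates_asymmetric_and_symmetric_pair(self, models):
        swapped = sm.make_variant(models["M7A-1"], "swap", 5, 6)
        assert swapped.consensus == "GTGGCAC"
        assert swapped == models["M7S-1"]
        assert sm.classify_symmetry(swapped) is sm.SymmetryClass.ODD_SYMMETRIC

    def test_swap_identity(self, models):
        m = models["M7A-1"]
        assert sm.make_variant(m, "swap", 3, 3) == m

    def test_swap_out_of_range(self, models):
        with pytest.raises(ValueError, match="out of range"):
            sm.swap_positions(models["M7A-1"], 0, 3)

    def test_delete_center_energy_identity(self, models):
        """Deleting column 4 must equal the 7-wide energy minus that column's
        contribution, for every 6-mer and every inserted base."""
        m7 = models["M7S-1"]
        m6 = sm.delete_position(m7, 4)
        assert m6.width == 6
        for idx in range(4 ** 6):
            s6 = index_to_sequence(idx, 6)
            e6 = sm.site_energy(m6, s6)
            for b in "ACGT":
                s7 = s6[:3] + b + s6[3:]
                col4 = sm.site_energy(m7, s7) - e6
                expected = m7.energies[3, "ACGT".index(b)]
                assert col4 == pytest.approx(expected, abs=1e-9)


class TestDegenerateConsensus:
    def test_hincii_expansion(self):
        got = sm.expand_degenerate("GTYRAC")
        assert got == {"GTTAAC", "GTCGAC", "GTCAAC", "GTTGAC"}
        palindromes = {s for s in got if sm.is_reverse_palindrome(s)}
        assert palindromes == {"GTTAAC", "GTCGAC"}

    def test_no_degeneracy(self):
        assert sm.expand_degenerate("ACGT") == {"ACGT"}

    def test_full_degeneracy(self):
        assert len(sm.expand_degenerate("NN")) == 16

    def test_unknown_character_rejected(self):
        with pytest.raises(InvalidSequenceError, match="position 2"):
            sm.expand_degenerate("AUC")

    @given(st.text(alphabet="ACGTRYSWKMBDHVN", min_size=1, max_size=6))
    @settings(max_examples=50, derandomize=True)
    def test_expansion_size_and_membership(self, pattern):
        from symmotif.energy_models import IUPAC_CODES

        got = sm.expand_degenerate(pattern)
        assert len(got) == np.prod([len(IUPAC_CODES[c]) for c in pattern])
        for s in got:
            assert all(b in IUPAC_CODES[c] for b, c in zip(s, pattern))


class TestReversePalindrome:
    @pytest.mark.parametrize(
        "seq,expected",
        [("GTTAAC", True), ("GTCGAC", True), ("GTCAAC", False), ("GTTGAC", False)],
    )
    def test_hincii_sites(self, seq, expected):
        assert sm.is_reverse_palindrome(seq) is expected

    @given(st.text(alphabet="ACGT", min_size=1, max_size=9).filter(lambda s: len(s) % 2))
    @settings(max_examples=30, derandomize=True)
    def test_odd_length_never_palindromic(self, seq):
        assert sm.is_reverse_palindrome(seq) is False


class TestFitEnergyMatrix:
    def test_exact_recovery_from_toy(self, toy_matrix):
        sites = ["".join(t) for t in itertools.product("ACGT", repeat=2)]
        energies = [sm.site_energy(toy_matrix, s) for s in sites]
        fit = sm.fit_energy_matrix(sites, energies)
        assert fit.allclose(toy_matrix)

    def test_roundtrip_from_generated_sample(self, models, m7a1_sample):
        fit = sm.fit_energy_matrix(
            list(m7a1_sample.sites), list(m7a1_sample.energies)
        )
        resid = [
            sm.site_energy(fit, s) - e
            for s, e in zip(m7a1_sample.sites, m7a1_sample.energies)
        ]
        assert max(abs(r) for r in resid) < 1e-9
        # the generating matrix is recovered on every observed entry
        mask = ~np.isnan(fit.energies)
        assert np.allclose(
            fit.energies[mask], models["M7A-1"].energies[mask], atol=1e-9
        )

    def test_identical_sites_flag_undetermined(self):
        fit = sm.fit_energy_matrix(["GTG", "GTG"], [0.0, 0.0])
        # one base observed per position: consensus entries 0, rest flagged
        assert len(fit.undetermined) == 9
        assert sm.site_energy(fit, "GTG") == 0.0

    def test_inconsistent_energies_rejected(self, toy_matrix):
        sites = ["".join(t) for t in itertools.product("ACGT", repeat=2)]
        energies = [sm.site_energy(toy_matrix, s) for s in sites]
        energies[5] += 1.0  # break additivity
        with pytest.raises(FitError, match="residual"):
            sm.fit_energy_matrix(sites, energies)


def test_default_family_structure(models):
    """The shipped 6-long models are the centre-deleted 7-long ones and the
    asymmetric/symmetric pairs share their parameter sets."""
    assert sm.delete_position(models["M7A-1"], 4) == models["M6A-1"]
    assert sm.delete_position(models["M7S-2"], 4) == models["M6S-2"]
    for v in ("1", "2"):
        a = np.sort(models[f"M7A-{v}"].energies, axis=1)
        s = np.sort(models[f"M7S-{v}"].energies, axis=1)
        assert np.allclose(np.sort(a, axis=0), np.sort(s, axis=0))


def test_mirror_column_is_complement_reversal():
    assert _mirror((1.0, 2.0, 3.0, 4.0)) == (4.0, 3.0, 2.0, 1.0)
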