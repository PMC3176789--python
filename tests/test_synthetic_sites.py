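"""Occupancy model, landscape enumeration and seeded site sampling."""
import math

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

import symmotif as sm
from symmotif.synthetic_sites import (
    SampleFileError,
    index_to_sequence,
    reverse_complement_index,
    sequence_to_index,
)
from symmotif.energy_models import reverse_complement


class TestOccupancy:
    def test_consensus_operating_point(self):
        # at mu = -0.5 the consensus (E = 0) is bound 38% of the time
        assert sm.occupancy(0.0, -0.5) == pytest.approx(0.3775407, abs=1e-6)

    def test_midpoint(self):
        assert sm.occupancy(-0.5, -0.5) == 0.5

    def test_saturation(self):
        assert sm.occupancy(np.inf, -0.5) == 0.0
        assert sm.occupancy(-np.inf, -0.5) == 1.0
        assert sm.occupancy(5000.0, -0.5) == 0.0  # no overflow

    @given(
        st.floats(-30, 30), st.floats(-30, 30).filter(lambda x: abs(x) > 1e-6)
    )
    @settings(max_examples=100, derandomize=True)
    def test_strictly_decreasing(self, e, de):
        lo, hi = sorted((e, e + de))
        assert sm.occupancy(lo, -0.5) > sm.occupancy(hi, -0.5)


class TestLandscape:
    def test_record_counts(self, models):
        assert sm.enumerate_landscape(models["M6A-1"]).n_sequences == 4096
        assert sm.enumerate_landscape(models["M7A-1"]).n_sequences == 16384

    @pytest.mark.parametrize("mid", ["M7A-1", "M7S-2", "M6S-1"])
    def test_normalized_and_monotone(self, models, mid):
        land = sm.enumerate_landscape(models[mid])
        assert abs(land.probs.sum() - 1.0) < 1e-12
        assert np.all(land.probs > 0)
        order = np.argsort(land.energies, kind="stable")
        # lower energy => strictly higher probability
        probs_sorted = land.probs[order]
        energies_sorted = land.energies[order]
        strict = np.diff(energies_sorted) > 1e-12
        assert np.all(np.diff(probs_sorted)[strict] < 0)

    def test_argmax_is_consensus(self, models):
        for mid in ("M7A-1", "M6S-2"):
            land = sm.enumerate_landscape(models[mid])
            assert land.sequence(land.consensus_index) == models[mid].consensus

    def test_flat_matrix_uniform(self):
        flat = sm.EnergyMatrix("flat", np.zeros((6, 4)))
        land = sm.enumerate_landscape(flat)
        assert np.allclose(land.probs, 4.0 ** -6)

    def test_width_guard(self):
        wide = sm.EnergyMatrix("wide", np.zeros((13, 4)))
        with pytest.raises(ValueError, match="guard"):
            sm.enumerate_landscape(wide)

    def test_index_codec_roundtrip(self):
        for idx in (0, 1, 4095, 2047):
            assert sequence_to_index(index_to_sequence(idx, 6)) == idx

    def test_reverse_complement_index(self):
        rc = reverse_complement_index(4)
        for idx in range(0, 256, 17):
            seq = index_to_sequence(idx, 4)
            assert index_to_sequence(int(rc[idx]), 4) == reverse_complement(seq)


class TestSampling:
    def test_sample_size_and_energies(self, m7a1_sample, models):
        assert m7a1_sample.n == 500
        m = models["M7A-1"]
        for s, e in zip(m7a1_sample.sites[:50], m7a1_sample.energies[:50]):
            assert sm.site_energy(m, s) == pytest.approx(e)

    def test_seed_determinism(self, models):
        land = sm.enumerate_landscape(models["M7S-1"])
        cfg = sm.SampleConfig(n_sites=200, seed=42)
        assert sm.sample_sites(land, cfg) == sm.sample_sites(land, cfg)

    def test_consensus_frequency_matches_landscape(self, models):
        land = sm.enumerate_landscape(models["M7A-1"])
        sample = sm.sample_sites(land, sm.SampleConfig(n_sites=50_000, seed=5))
        cons = models["M7A-1"].consensus
        p = land.probs[land.consensus_index]
        freq = sum(s == cons for s in sample.sites) / sample.n
        se = math.sqrt(p * (1 - p) / sample.n)
        assert abs(freq - p) < 3 * se

    def test_total_variation_against_pi(self, models):
        """Empirical frequencies converge to pi: the observed total-variation
        distance stays below 1.5x the analytic multinomial expectation
        E[TV] ~ sum_i sqrt(p_i (1-p_i) / (2 pi n))."""
        land = sm.enumerate_landscape(models["M7S-1"])
        n = 100_000
        sample = sm.sample_sites(land, sm.SampleConfig(n_sites=n, seed=9))
        counts = np.zeros(land.n_sequences)
        for s in sample.sites:
            counts[sequence_to_index(s)] += 1
        tv = 0.5 * np.abs(counts / n - land.probs).sum()
        p = land.probs
        expected_tv = 0.5 * np.minimum(
            np.sqrt(2 * p * (1 - p) / (np.pi * n)), 2 * p
        ).sum()
        assert tv < 1.5 * expected_tv

    def test_without_replacement_guard(self, models):
        land = sm.enumerate_landscape(models["M6A-1"])
        # nearly all 4096 sequences have positive probability, so 100 is fine
        cfg = sm.SampleConfig(n_sites=100, seed=1, replacement=False)
        assert sm.sample_sites(land, cfg).n == 100

    def test_flat_matrix_empirical_uniformity(self):
        flat = sm.EnergyMatrix("flat", np.zeros((3, 4)))
        land = sm.enumerate_landscape(flat)
        sample = sm.sample_sites(land, sm.SampleConfig(n_sites=64_000, seed=2))
        counts = np.zeros(64)
        for s in sample.sites:
            counts[sequence_to_index(s)] += 1
        expected = 1000.0
        assert np.all(np.abs(counts - expected) < 4 * math.sqrt(expected))


class TestSampleIO:
    def test_roundtrip(self, m7a1_sample, tmp_path):
        path = tmp_path / "sample.tsv"
        sm.write_sample(m7a1_sample, path)
        back = sm.read_sample(path)
        assert back.sites == m7a1_sample.sites
        assert np.array_equal(back.energies, m7a1_sample.energies)
        assert back.model_id == "M7A-1"
        assert back.config.mu == m7a1_sample.config.mu
        assert back.config.seed == m7a1_sample.config.seed

    def test_byte_identical_rewrite(self, models, tmp_path):
        land = sm.enumerate_landscape(models["M6S-1"])
        cfg = sm.SampleConfig(n_sites=100, seed=3)
        p1, p2 = tmp_path / "a.tsv", tmp_path / "b.tsv"
        sm.write_sample(sm.sample_sites(land, cfg), p1)
        sm.write_sample(sm.sample_sites(land, cfg), p2)
        assert p1.read_bytes() == p2.read_bytes()

    def test_width_mismatch_reports_line(self, tmp_path):
        path = tmp_path / "bad.tsv"
        path.write_text("site\tenergy\nACGTAC\t0.1\nACGTA\t0.2\n")
        with pytest.raises(SampleFileError, match="line 3"):
            sm.read_sample(path)

    def test_bad_energy_reports_line(self, tmp_path):
        path = tmp_path / "bad.tsv"
        path.write_text("site\tenergy\nACGTAC\t0.1\nACGTAA\tx\n")
        with pytest.raises(SampleFileError, match="line 3"):
            sm.read_sample(path)

    def test_column_mapping_for_foreign_layout(self, tmp_path, models):
        # supplementary-style file: extra id column, energy before site
        path = tmp_path / "supp.txt"
        path.write_text(
            "id\tenergy\tsite\ns1\t0.0\tGTGGACC\ns2\t0.15\tATGGACC\n"
        )
        sample = sm.read_sample(path, site_col=2, energy_col=1, matrix=models["M7A-1"])
        assert sample.sites == ("GTGGACC", "ATGGACC")

    def test_energy_check_against_matrix(self, tmp_path, models):
        path = tmp_path / "supp.txt"
        path.write_text("site\tenergy\nGTGGACC\t0.5\n")
        with pytest.raises(SampleFileError, match="does not match"):
            sm.read_sample(path, matrix=models["M7A-1"])
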