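"""Coalescent simulators: determinism, limits, and calibration cross-checks."""

import numpy as np
import pytest

from popgenflow.differentiation import amova
from popgenflow.diversity import nucleotide_diversity
from popgenflow.errors import ConfigError
from popgenflow.io import call_haplotypes, pairwise_differences, segregating_sites
from popgenflow.simulate import (
    ExpansionConfig,
    IslandModelConfig,
    MT_SAMPLE_SIZES,
    ITS_SAMPLE_SIZES,
    make_paper_fixture,
    simulate_expansion,
    simulate_island,
    simulate_two_systems,
    two_epoch_pairwise_matrix,
)


def _island_cfg(two_nm, seed, samples=8, demes=10, N=1000, theta_loc=1.0, L=1200):
    return IslandModelConfig(demes, N, two_nm / (2 * N), samples,
                             theta_loc / (2 * N * L), L, seed)


class TestSimulateIsland:
    def test_fixed_seed_reproduces_alignment(self, tmp_path):
        a = simulate_island(_island_cfg(2.0, 99))
        b = simulate_island(_island_cfg(2.0, 99))
        assert np.array_equal(a.matrix, b.matrix)
        a.write_fasta(tmp_path / "a.fa")
        b.write_fasta(tmp_path / "b.fa")
        assert (tmp_path / "a.fa").read_bytes() == (tmp_path / "b.fa").read_bytes()

    def test_zero_migration_rejected_with_multiple_demes(self):
        with pytest.raises(ConfigError):
            IslandModelConfig(5, 100, 0.0, 4, 1e-6, 100, 1)

    def test_near_zero_migration_gives_strong_structure(self):
        # m -> 0 limit: demes nearly monomorphic internally, phi_st -> 1
        vals = []
        for r in range(10):
            aln = simulate_island(_island_cfg(0.02, 300 + r, samples=6, demes=5,
                                              theta_loc=0.02, L=400))
            d = pairwise_differences(aln)
            if d.d.any():
                vals.append(amova(d, n_perm=0).phi_st)
        assert np.mean(vals) > 0.9

    def test_single_deme_pi_matches_theta(self):
        # E[k_hat] = 2 N mu L in a panmictic deme
        khats = []
        for r in range(200):
            cfg = IslandModelConfig(1, 500, 0.0, 12, 2.0 / (2 * 500 * 600), 600, 700 + r)
            d = pairwise_differences(simulate_island(cfg))
            khats.append(nucleotide_diversity(d)[1])
        assert np.mean(khats) == pytest.approx(2.0, abs=0.25)

    def test_phist_decreases_with_migration(self):
        means = []
        for two_nm in (0.3, 2.0, 12.0):
            vals = []
            for r in range(40):
                aln = simulate_island(_island_cfg(two_nm, 1000 + r, samples=6, demes=6))
                vals.append(amova(pairwise_differences(aln), n_perm=0).phi_st)
            means.append(np.mean(vals))
        assert means[0] > means[1] > means[2]


class TestSimulateTwoSystems:
    def test_shared_labels_independent_genealogies(self):
        cfg = _island_cfg(0.5, 42, samples=5, demes=4)
        mat, bip = simulate_two_systems(cfg, ms=cfg.migration, mp=10 * cfg.migration)
        assert mat.sample_ids == bip.sample_ids
        assert mat.population_of == bip.population_of
        assert not np.array_equal(mat.matrix, bip.matrix)

    def test_excessive_rates_rejected(self):
        cfg = _island_cfg(0.5, 1)
        with pytest.raises(ConfigError):
            simulate_two_systems(cfg, ms=0.9, mp=0.9)

    def test_strong_pollen_flow_reduces_biparental_structure(self):
        diffs = []
        for r in range(25):
            cfg = _island_cfg(0.5, 5000 + r, samples=6, demes=8)
            ms = cfg.migration
            m, b = simulate_two_systems(cfg, ms=ms, mp=60 * ms)
            fm = amova(pairwise_differences(m), n_perm=0).phi_st
            fn = amova(pairwise_differences(b), n_perm=0).phi_st
            diffs.append(fm - fn)
        assert (np.array(diffs) > 0).mean() >= 0.95


class TestSimulateExpansion:
    def test_constant_size_reduces_to_stationary(self):
        # N0 = N1: mean Tajima-like skew should be near zero; just check pi
        khats = []
        for r in range(150):
            cfg = ExpansionConfig(400, 400, 0.0, 3.0 / (2 * 400 * 500), 500, 10, 40 + r)
            d = pairwise_differences(simulate_expansion(cfg))
            khats.append(nucleotide_diversity(d)[1])
        assert np.mean(khats) == pytest.approx(3.0, abs=0.45)

    def test_determinism(self):
        cfg = ExpansionConfig(100, 10000, 500, 1e-6, 300, 15, 7)
        a = simulate_expansion(cfg)
        b = simulate_expansion(cfg)
        assert np.array_equal(a.matrix, b.matrix)

    def test_expansion_yields_unimodal_wave(self):
        from popgenflow.demography import mismatch_observed
        rng = np.random.default_rng(3)
        spec = np.zeros(60)
        for _ in range(60):
            d = two_epoch_pairwise_matrix(25, 0.01, 50.0, 10.0, rng)
            s = mismatch_observed(d)
            spec[: s.size] += s
        spec /= 60
        peak = int(np.argmax(spec))
        assert 5 <= peak <= 15  # near tau = 10
        assert spec[peak] > 2 * spec[30] if spec.size > 30 else True


class TestAgainstMsprime:
    def test_single_population_segregating_sites_match_msprime(self):
        msprime = pytest.importorskip("msprime")
        n, theta = 10, 4.0  # theta = 2 N mu L (haploid)
        reps = 250
        ours = []
        for r in range(reps):
            cfg = IslandModelConfig(1, 1000, 0.0, n, theta / (2 * 1000 * 2000), 2000, r)
            ours.append(len(segregating_sites(simulate_island(cfg))))
        ts_vals = []
        replicates = msprime.sim_ancestry(samples=n, ploidy=1, population_size=1000,
                                          num_replicates=reps, random_seed=7)
        for i, ts in enumerate(replicates):
            # haploid theta = 2 N mu; unit sequence length, infinite sites
            mts = msprime.sim_mutations(ts, rate=theta / (2 * 1000),
                                        discrete_genome=False, random_seed=i + 1)
            ts_vals.append(mts.num_sites)
        a1 = sum(1 / i for i in range(1, n))
        assert np.mean(ours) == pytest.approx(theta * a1, rel=0.12)
        assert np.mean(ours) == pytest.approx(np.mean(ts_vals), rel=0.15)


class TestPaperFixture:
    def test_sample_totals(self, study_fixture):
        assert study_fixture.mtdna.n == sum(MT_SAMPLE_SIZES) == 161
        assert study_fixture.its.n == sum(ITS_SAMPLE_SIZES) == 239

    def test_metadata_values(self, study_fixture):
        gz = next(m for m in study_fixture.metadata if m.code == "GZ")
        assert gz.elevation == 10 and gz.aat == 22.1

    def test_four_haplotypes_at_stated_positions(self, study_fixture):
        hap = call_haplotypes(study_fixture.mtdna)
        assert hap.n_haplotypes == 4
        assert hap.site_positions == [318, 647]

    def test_deterministic_and_writes_files(self, tmp_path):
        b1 = make_paper_fixture(5, tmp_path / "f1")
        b2 = make_paper_fixture(5, tmp_path / "f2")
        assert np.array_equal(b1.its.matrix, b2.its.matrix)
        for key in ("mtdna_fasta", "its_fasta", "popmap", "metadata"):
            assert b1.paths[key].exists()
        assert (b1.paths["its_fasta"].read_bytes()
                == b2.paths["its_fasta"].read_bytes())
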