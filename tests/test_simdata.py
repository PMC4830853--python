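"""Synthetic-data generator: genotype LD structure, pedigrees, the numerator
relationship matrix, and trait composition."""

import numpy as np
import pytest

import gmb
from gmb.errors import ConfigError, PedigreeError
from gmb.simdata import Pedigree, SimulationConfig

import oracles


def _adjacent_corr(codes):
    X = codes.astype(float)
    c = [np.corrcoef(X[:, j], X[:, j + 1])[0, 1] for j in range(X.shape[1] - 1)]
    return np.asarray(c)


class TestGenotypes:
    def test_codes_and_determinism(self):
        cfg = SimulationConfig(n_individuals=100, n_snps=50, n_families=5,
                               missing_rate=0.05, seed=1)
        g1 = gmb.simulate_genotypes(cfg)
        g2 = gmb.simulate_genotypes(cfg)
        assert np.array_equal(g1.codes, g2.codes)
        assert set(np.unique(g1.codes)) <= {-9, -1, 0, 1}
        assert g1.missing_mask().any()

    def test_no_missing_when_rate_zero(self):
        cfg = SimulationConfig(n_individuals=100, n_snps=50, n_families=5,
                               missing_rate=0.0, seed=1)
        assert not gmb.simulate_genotypes(cfg).missing_mask().any()

    def test_independent_snps_uncorrelated(self):
        cfg = SimulationConfig(n_individuals=2000, n_snps=60, n_families=2000,
                               adjacent_ld=0.0, missing_rate=0.0, seed=2)
        corr = _adjacent_corr(gmb.simulate_genotypes(cfg).codes)
        assert np.mean(np.abs(corr)) < 0.05

    def test_adjacent_ld_calibration(self):
        # fixed allele frequency 0.5 so the Markov copying gives corr = rho
        cfg = SimulationConfig(n_individuals=5000, n_snps=60, n_families=5000,
                               adjacent_ld=0.9, maf_range=(0.5, 0.5),
                               missing_rate=0.0, seed=3)
        corr = _adjacent_corr(gmb.simulate_genotypes(cfg).codes)
        assert abs(np.mean(corr) - 0.9) < 0.05

    def test_allele_frequencies_inside_range(self):
        cfg = SimulationConfig(n_individuals=4000, n_snps=40, n_families=40,
                               maf_range=(0.2, 0.3), missing_rate=0.0, seed=4)
        g = gmb.simulate_genotypes(cfg)
        freqs = (g.codes.astype(float).mean(axis=0) + 1) / 2
        maf = np.minimum(freqs, 1 - freqs)
        # binomial sampling error around the configured haplotype frequency
        assert (maf > 0.17).all() and (maf < 0.33).all()

    def test_invalid_maf_range_rejected(self):
        with pytest.raises(ConfigError):
            SimulationConfig(maf_range=(0.0, 0.5))
        with pytest.raises(ConfigError):
            SimulationConfig(maf_range=(0.4, 0.2))


class TestPedigree:
    def test_all_founders(self):
        cfg = SimulationConfig(n_individuals=7, n_snps=2, n_families=7, seed=1)
        ped = gmb.simulate_pedigree(cfg)
        assert all(s is None for s in ped.sires)
        A = gmb.relationship_from_pedigree(ped)
        assert np.array_equal(A.values, np.eye(7))

    def test_single_family_half_sibs(self):
        cfg = SimulationConfig(n_individuals=6, n_snps=2, n_families=1, seed=1)
        ped = gmb.simulate_pedigree(cfg)
        assert ped.sires[0] is None
        assert all(s == ped.ids[0] for s in ped.sires[1:])
        A = gmb.relationship_from_pedigree(ped)
        off = A.values[1:, 1:]
        assert np.allclose(off[~np.eye(5, dtype=bool)], 0.25)  # half sibs
        assert np.allclose(A.values[0, 1:], 0.5)  # sire-offspring

    def test_seed_repeatability(self):
        cfg = SimulationConfig(n_individuals=50, n_snps=2, n_families=6, seed=9)
        p1, p2 = gmb.simulate_pedigree(cfg), gmb.simulate_pedigree(cfg)
        assert p1.sires == p2.sires

    def test_too_many_families_rejected(self):
        with pytest.raises(ConfigError):
            gmb.simulate_pedigree(
                SimulationConfig(n_individuals=3, n_snps=2, n_families=4)
            )

    def test_cycle_detected(self):
        ped = Pedigree(ids=["a", "b"], sires=["b", "a"], dams=[None, None])
        with pytest.raises(PedigreeError):
            gmb.relationship_from_pedigree(ped)


class TestRelationshipMatrix:
    def test_tabular_closed_forms(self):
        # founders f1, f2; full sibs c1, c2; their (inbred) offspring x
        ped = Pedigree(
            ids=["f1", "f2", "c1", "c2", "x"],
            sires=["0", "0", "f1", "f1", "c1"],
            dams=[None, None, "f2", "f2", "c2"],
        )
        ped.sires = [None if s == "0" else s for s in ped.sires]
        A = gmb.relationship_from_pedigree(ped).values
        assert A[2, 3] == pytest.approx(0.5)  # full sibs
        assert A[0, 2] == pytest.approx(0.5)  # parent-offspring
        assert A[4, 4] == pytest.approx(1.25)  # 1 + a(c1,c2)/2

    def test_inbred_offspring_of_half_sibs(self):
        ped = Pedigree(
            ids=["s", "h1", "h2", "x"],
            sires=[None, "s", "s", "h1"],
            dams=[None, None, None, "h2"],
        )
        A = gmb.relationship_from_pedigree(ped).values
        assert A[1, 2] == pytest.approx(0.25)
        assert A[3, 3] == pytest.approx(1.125)  # 1 + 0.25/2

    def test_matches_gene_dropping_monte_carlo(self):
        cfg = SimulationConfig(n_individuals=14, n_snps=2, n_families=3, seed=17)
        ped = gmb.simulate_pedigree(cfg)
        A = gmb.relationship_from_pedigree(ped).values
        n_rep = 40_000
        est = oracles.gene_dropping_relationship(ped, n_rep=n_rep, seed=17)
        # binomial-scale Monte Carlo standard error, conservative p(1-p) bound
        se = 2.0 / np.sqrt(n_rep)
        assert np.max(np.abs(est - A)) < 3 * se

    def test_psd_and_diagonal(self, small_population):
        A = small_population["A"].values
        assert (np.diag(A) >= 1).all()
        assert np.linalg.eigvalsh(A).min() > -1e-10


class TestTrait:
    def test_pure_noise_mean(self):
        cfg = SimulationConfig(n_individuals=4000, n_snps=5, n_families=4000,
                               architecture="null", sigma2_alpha=0.0, mu=7.5,
                               missing_rate=0.0, seed=8)
        g = gmb.simulate_genotypes(cfg)
        A = gmb.relationship_from_pedigree(gmb.simulate_pedigree(cfg))
        tr, truth = gmb.simulate_trait(g, A, cfg)
        assert np.all(truth.g == 0) and np.all(truth.alpha == 0)
        se = np.std(tr.values) / np.sqrt(len(tr.values))
        assert abs(np.mean(tr.values) - 7.5) < 4 * se

    def test_variance_decomposition(self):
        cfg = SimulationConfig(n_individuals=5000, n_snps=5, n_families=250,
                               architecture="polygenic", sigma2_alpha=0.4,
                               sigma2_eps=1.0, missing_rate=0.0, seed=9)
        g = gmb.simulate_genotypes(cfg)
        A = gmb.relationship_from_pedigree(gmb.simulate_pedigree(cfg))
        tr, truth = gmb.simulate_trait(g, A, cfg)
        w = tr.weights
        expected = 0.4 / (0.4 + 1.0 * np.mean(1 / w))
        realized = np.var(truth.alpha) / np.var(tr.values - tr.values.mean())
        assert abs(realized - expected) < 0.05

    def test_major_gene_r2(self):
        r2s = []
        for seed in range(5):
            cfg = SimulationConfig(
                n_individuals=2000, n_snps=50, n_families=100,
                architecture="major_gene", major_gene_index=10,
                major_gene_variance_fraction=0.2, sigma2_alpha=0.2,
                missing_rate=0.0, seed=100 + seed,
            )
            g = gmb.simulate_genotypes(cfg)
            A = gmb.relationship_from_pedigree(gmb.simulate_pedigree(cfg))
            tr, truth = gmb.simulate_trait(g, A, cfg)
            assert truth.g[10] > 0 and np.count_nonzero(truth.g) == 1
            r2s.append(np.corrcoef(g.codes[:, 10], tr.values)[0, 1] ** 2)
        assert abs(np.mean(r2s) - 0.2) < 0.05

    def test_explicit_effect_vector_override(self, small_population):
        cfg = small_population["config"]
        g = small_population["geno"]
        A = small_population["A"]
        gvec = np.zeros(g.n_snps)
        gvec[0] = 1.0
        tr, truth = gmb.simulate_trait(g, A, cfg, g=gvec)
        assert np.array_equal(truth.g, gvec)

    def test_determinism(self, small_population):
        cfg = small_population["config"]
        tr2, _ = gmb.simulate_trait(
            small_population["geno"], small_population["A"], cfg
        )
        assert np.array_equal(tr2.values, small_population["traits"].values)
        assert np.array_equal(tr2.weights, small_population["traits"].weights)
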