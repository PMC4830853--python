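import numpy as np
import pytest

import gmb
from gmb.geno import GenotypeMatrix, TraitRecords


def make_geno(codes, positions=None) -> GenotypeMatrix:
    """GenotypeMatrix from a raw code array, with auto-generated metadata."""
    codes = np.asarray(codes)
    if codes.dtype.kind in "iu":
        codes = codes.astype(np.int8)
    n, m = codes.shape
    return GenotypeMatrix(
        codes=codes,
        snp_ids=np.array([f"s{j}" for j in range(m)], dtype=object),
        chromosomes=np.repeat("1", m),
        positions=positions if positions is not None else np.arange(1, m + 1),
        individual_ids=np.array([f"i{k}" for k in range(n)], dtype=object),
    )


def make_traits(values, weights=None, ids=None, trait="trait") -> TraitRecords:
    values = np.asarray(values, dtype=float)
    n = len(values)
    return TraitRecords(
        individual_ids=ids if ids is not None else np.array([f"i{k}" for k in range(n)], dtype=object),
        values=values,
        weights=np.ones(n) if weights is None else np.asarray(weights, dtype=float),
        trait=trait,
    )


@pytest.fixture(scope="session")
def small_population():
    """One simulated half-sib population shared by fast unit tests:
    300 bulls in 10 families, 120 SNPs with adjacent LD, a polygenic trait."""
    cfg = gmb.SimulationConfig(
        n_individuals=300, n_snps=120, n_families=10, adjacent_ld=0.5,
        maf_range=(0.05, 0.5), missing_rate=0.02, architecture="polygenic",
        sigma2_alpha=0.3, sigma2_eps=1.0, seed=20,
    )
    geno = gmb.simulate_genotypes(cfg)
    ped = gmb.simulate_pedigree(cfg)
    A = gmb.relationship_from_pedigree(ped)
    traits, truth = gmb.simulate_trait(geno, A, cfg)
    imputed = gmb.impute_missing_mean(gmb.apply_qc(geno)[0])
    return {
        "config": cfg, "geno": geno, "pedigree": ped, "A": A,
        "traits": traits, "truth": truth, "imputed": imputed,
        "vc": gmb.VarianceComponents(sigma2_alpha=0.3, sigma2_eps=1.0, sigma2_a=0.5),
    }
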