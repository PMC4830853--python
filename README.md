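# gmb — four-model GWAS significant-SNP selection benchmark

When a genome-wide association study is run on a complex trait, the set of
SNPs declared "significant" depends heavily on the model used to estimate
the SNP effects. This package implements and compares the four standard
choices for progeny-tested dairy-cattle data — where each bull's
pseudophenotype is a deregressed proof `y_i` with an effective daughter
contribution (EDC) weight `w_i` scaling its residual variance
(`Var(e_i) = sigma2_e / w_i`, i.e. `D_ii = 1/w_i`):

| model | form | estimation | selection rule |
|-------|------|-----------|----------------|
| M1 | `y = mu + x_j b + e`, one SNP at a time | weighted least squares | Bonferroni-adjusted p <= 0.001 |
| M2 | `y = mu + x_j b + Z a + e`, `a ~ N(0, A s2_a)` | mixed model equations / GLS with pedigree A | Bonferroni-adjusted p <= 0.001 |
| M3 | CAR scores `omega = P^{-1/2} P_xy`, `P = l I + (1-l) R` | shrunken correlation decorrelation | t(kappa-1) nominal p <= 0.001 |
| M4 | `y = mu + Z g + e`, `g ~ N(0, I s2_g/m)` (SNP-BLUP) | Gauss-Seidel with residual update | nominal p <= 0.001 |

Because no such bull dataset is publicly deposited, the package ships a
synthetic-data module that emulates such a study design at any scale: paternal
half-sib families, chip genotypes with blockwise LD (first-order Markov
haplotypes), lognormal EDC weights, and traits with a major gene, a pure
polygenic architecture, a near-zero heritability, or a global null.

Intended users: quantitative geneticists and biostatisticians who want a
tested, desk-scale reference implementation of these four selection
pipelines and of their calibration properties.

## Worked example

```bash
python analysis/01_simulate.py      # 300 bulls x 1,000 SNPs, major gene at snp0500
python analysis/02_qc.py            # MAF >= 0.01, call rate >= 0.90, mean imputation
python analysis/03_fit_models.py    # fit M1-M4
python analysis/04_select_compare.py
```

The last step prints (seed 7):

```
model    n_sel      adjust   meanMAF   mean|r|   meanr2
M1           3  bonferroni     0.304     0.213    0.087
M2           2  bonferroni     0.272     0.497    0.247
M3           3     nominal     0.280     0.198    0.085
M4          44     nominal     0.209     0.048    0.004
common to all models: 2 (union 45)
Hayes-Goddard M = 57.12 (N=10.73, Ne=103)
```

All four models rank the simulated causal SNP (20% of trait variance)
first. The single-SNP models select few, strongly inter-correlated SNPs
(mean pairwise |r| 0.2-0.5 — they pick up the LD block around the causal
variant), while the all-SNP model M4 spreads its selection across the
genome at much lower mutual LD (0.048): its nominal-0.001 rule behaves as a
fixed-proportion filter on shrunken effects. The Hayes-Goddard line is the
`M = N ln((1-p)/p)`, `p = 1/(2 Ne)` estimate of the number of genes
affecting a production trait, evaluated at the standard dairy-cattle inputs.

The same pipeline is scriptable as one command (`gmb run --config cfg.yaml
--out DIR`) or stage by stage (`gmb simulate|qc|fit|select|compare`).

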