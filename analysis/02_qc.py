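#!/usr/bin/env python
"""Quality control of the demo panel.

Applies the chip QC rules — minimum minor allele frequency 0.01 and minimum
call rate 90% — then mean-imputes the surviving missing genotypes so the
model design matrices are complete.  Writes the filtered, imputed panel and
the per-SNP QC log under results/qc/.
"""

import argparse
import os

import gmb
from gmb.geno import load_genotypes, save_genotypes_tsv


def main():
    ap = argparse.ArgumentParser()
    ap.add_argument("--geno", default="results/data/demo")
    ap.add_argument("--out", default="results/qc")
    args = ap.parse_args()

    g = load_genotypes(args.geno)
    kept, log = gmb.apply_qc(g, maf_min=0.01, cr_min=0.90)
    imputed = gmb.impute_missing_mean(kept)

    os.makedirs(args.out, exist_ok=True)
    save_genotypes_tsv(imputed, os.path.join(args.out, "demo_qc"))
    log.to_csv(os.path.join(args.out, "qc_log.tsv"), sep="\t", index=False)

    removed = log.loc[~log["kept"]]
    print(f"QC kept {kept.n_snps} of {g.n_snps} SNPs")
    for reason, count in removed["removal_reason"].value_counts().items():
        print(f"  removed {count} ({reason})")
    print(f"imputed {int(kept.missing_mask().sum())} missing genotypes by SNP means")


if __name__ == "__main__":
    main()
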