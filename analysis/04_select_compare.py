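#!/usr/bin/env python
"""Select significant SNPs per model and compare the selections.

Selection at the 0.001 threshold: Bonferroni-adjusted p for the single-SNP
models M1/M2, nominal p for M3/M4.  Reports per-model counts, Venn overlaps,
mean MAF and mean pairwise LD (|r| and r^2) of each selected set, and the
Hayes-Goddard gene-count estimate M = N ln((1-p)/p) with the dairy-cattle
inputs N = 10.73 heterozygous QTL and Ne = 103.
"""

import argparse
import json
import os

import pandas as pd

import gmb
from gmb.geno import load_genotypes
from gmb.selection import comparison_report, report_to_text


def main():
    ap = argparse.ArgumentParser()
    ap.add_argument("--fits", default="results/fits")
    ap.add_argument("--geno", default="results/qc/demo_qc")
    ap.add_argument("--threshold", type=float, default=0.001)
    ap.add_argument("--out", default="results/comparison")
    args = ap.parse_args()

    g = load_genotypes(args.geno)
    selections = []
    for tag in ("m1", "m2", "m3", "m4"):
        df = pd.read_csv(os.path.join(args.fits, f"results_{tag}.tsv"), sep="\t")
        selections.append(gmb.select_significant(df, threshold=args.threshold))

    report = comparison_report(selections, g, n_qtl=10.73, ne=103)
    os.makedirs(args.out, exist_ok=True)
    with open(os.path.join(args.out, "report.json"), "w") as fh:
        json.dump(report, fh, indent=2, default=float)
    rows = [{"model": s.model, "snp_id": sid}
            for s in selections for sid in sorted(s.snp_ids)]
    pd.DataFrame(rows, columns=["model", "snp_id"]).to_csv(
        os.path.join(args.out, "selections.tsv"), sep="\t", index=False
    )
    text = report_to_text(report)
    with open(os.path.join(args.out, "report.txt"), "w") as fh:
        fh.write(text + "\n")
    print(text)


if __name__ == "__main__":
    main()
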