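"""Significance selection and cross-model comparison of selected SNP sets.

Selection rule: a SNP is significant when its p value does not exceed the
threshold (default 0.001).  Single-SNP models (M1, M2) are Bonferroni-
corrected over the post-QC panel; the CAR-score model (M3) and the all-SNP
model (M4) use the nominal p value.

The comparison report mirrors the usual presentation of such studies:
per-model selected counts, Venn-region overlaps, mean MAF of each selected
set, mean pairwise LD (|r|, with r^2 alongside) within each set, and the
Hayes-Goddard estimate M = N ln((1-p)/p), p = 1/(2 Ne), of the number of
genes affecting the trait.
"""

from __future__ import annotations

from dataclasses import dataclass
from itertools import combinations

import numpy as np
import pandas as pd

from .errors import GmbError
from .geno import GenotypeMatrix, compute_maf_all

DEFAULT_MODES = {"M1": "bonferroni", "M2": "bonferroni", "M3": "nominal", "M4": "nominal"}


@dataclass
class SelectionSet:
    model: str
    trait: str
    threshold: float
    adjustment: str  # bonferroni | nominal | t_null
    snp_ids: frozenset
    panel: frozenset | None = None  # analyzed SNP ids, for overlap sanity checks

    def __post_init__(self):
        self.snp_ids = frozenset(self.snp_ids)
        if self.panel is not None:
            self.panel = frozenset(self.panel)
            if not self.snp_ids <= self.panel:
                raise GmbError("selected SNPs outside the analyzed panel")

    def __len__(self) -> int:
        return len(self.snp_ids)


def bonferroni_adjust(p: np.ndarray, family_size: int) -> np.ndarray:
    """Bonferroni-adjusted p values: min(1, family_size * p)."""
    if family_size < 1:
        raise GmbError("family_size must be >= 1")
    p = np.asarray(p, dtype=float)
    finite = p[~np.isnan(p)]
    if ((finite < 0) | (finite > 1)).any():
        raise GmbError("p values must lie in [0, 1]")
    return np.minimum(1.0, family_size * p)


def select_significant(
    results: pd.DataFrame,
    threshold: float = 0.001,
    mode: str | None = None,
    family_size: int | None = None,
    trait: str = "trait",
) -> SelectionSet:
    """Select SNPs with (adjusted or nominal) p <= threshold.

    ``mode=None`` picks the model's default: Bonferroni for M1/M2, nominal
    for M3/M4.  For the Bonferroni mode the adjusted p column is used if
    present and non-null, else computed over ``family_size`` (default: the
    number of rows, i.e. the post-QC panel).
    """
    models = results["model"].unique()
    if len(models) != 1:
        raise GmbError(f"results table mixes models {models.tolist()}; select per model")
    model = str(models[0])
    if mode is None:
        mode = DEFAULT_MODES.get(model, "nominal")
    if mode not in ("bonferroni", "nominal"):
        raise GmbError(f"unknown selection mode {mode!r}")
    if "p_nominal" not in results.columns:
        raise GmbError("results table lacks the p_nominal column")
    if mode == "bonferroni":
        if "p_adjusted" in results.columns and results["p_adjusted"].notna().any():
            p = results["p_adjusted"].to_numpy(dtype=float)
        else:
            fam = family_size if family_size is not None else len(results)
            p = bonferroni_adjust(results["p_nominal"].to_numpy(dtype=float), fam)
    else:
        p = results["p_nominal"].to_numpy(dtype=float)
    with np.errstate(invalid="ignore"):
        hit = p <= threshold  # NaN (not-estimable) rows never selected
    return SelectionSet(
        model=model,
        trait=trait,
        threshold=threshold,
        adjustment=mode,
        snp_ids=frozenset(results.loc[hit, "snp_id"]),
        panel=frozenset(results["snp_id"]),
    )


def overlap(sets: list[SelectionSet]) -> dict:
    """Counts for every Venn region of 2-4 selection sets.

    Region keys are membership strings over the input order ("110" = in the
    first two sets only).  Also reports, for each ordered pair, the
    percentage of set i's SNPs shared with set j.
    """
    k = len(sets)
    if not (2 <= k <= 4):
        raise GmbError("overlap needs between 2 and 4 selection sets")
    panels = [s.panel for s in sets if s.panel is not None]
    if panels and any(p != panels[0] for p in panels[1:]):
        raise GmbError("selection sets were computed over different panels")
    universe = set().union(*(s.snp_ids for s in sets))
    regions: dict[str, int] = {}
    for snp in universe:
        key = "".join("1" if snp in s.snp_ids else "0" for s in sets)
        regions[key] = regions.get(key, 0) + 1
    # fill empty regions explicitly (excluding the all-zero region)
    for bits in range(1, 2**k):
        key = format(bits, f"0{k}b")
        regions.setdefault(key, 0)
    pairwise = {}
    for i, j in combinations(range(k), 2):
        inter = len(sets[i].snp_ids & sets[j].snp_ids)
        pairwise[(sets[i].model, sets[j].model)] = {
            "count": inter,
            "pct_of_first": 100.0 * inter / len(sets[i]) if len(sets[i]) else np.nan,
            "pct_of_second": 100.0 * inter / len(sets[j]) if len(sets[j]) else np.nan,
        }
    full = len(set.intersection(*(set(s.snp_ids) for s in sets)))
    return {
        "labels": [s.model for s in sets],
        "regions": regions,
        "pairwise": pairwise,
        "all_models": full,
        "union": len(universe),
    }


def mean_maf(selection: SelectionSet, geno: GenotypeMatrix) -> float:
    """Mean minor allele frequency over the selected SNPs (NaN if empty)."""
    if len(selection) == 0:
        return float("nan")
    maf = compute_maf_all(geno)
    idx = _indices(selection, geno)
    return float(np.mean(maf[idx]))


def mean_pairwise_ld(
    selection: SelectionSet, geno: GenotypeMatrix, statistic: str = "abs_r"
) -> float:
    """Mean pairwise LD among selected SNPs: mean |r| (default) or mean r^2.

    Undefined (NaN) for fewer than two selected SNPs.
    """
    if statistic not in ("abs_r", "r2"):
        raise GmbError(f"unknown LD statistic {statistic!r}")
    if len(selection) < 2:
        return float("nan")
    idx = _indices(selection, geno)
    sub = geno.codes[:, idx].astype(float)
    miss = np.isnan(sub) if sub.dtype.kind == "f" else (sub == -9)
    if miss.any():
        col_mean = np.nanmean(np.where(miss, np.nan, sub), axis=0)
        rr, cc = np.nonzero(miss)
        sub[rr, cc] = col_mean[cc]
    R = np.corrcoef(sub, rowvar=False)
    iu = np.triu_indices_from(R, k=1)
    vals = R[iu]
    return float(np.mean(np.abs(vals))) if statistic == "abs_r" else float(np.mean(vals**2))


def _indices(selection: SelectionSet, geno: GenotypeMatrix) -> np.ndarray:
    pos = {sid: j for j, sid in enumerate(geno.snp_ids)}
    missing = [sid for sid in selection.snp_ids if sid not in pos]
    if missing:
        raise GmbError(f"selected SNPs not in genotype panel: {sorted(missing)[:5]}")
    return np.array(sorted(pos[sid] for sid in selection.snp_ids))


def hayes_goddard_m(n_qtl: float, ne: float) -> float:
    """Hayes-Goddard estimate of the number of genes affecting a trait:
    M = N ln((1-p)/p) with p = 1/(2 Ne)."""
    if n_qtl <= 0:
        raise GmbError("N (effective QTL count) must be > 0")
    if ne < 1:
        raise GmbError("effective population size Ne must be >= 1")
    p = 1.0 / (2.0 * ne)
    return float(n_qtl * np.log((1.0 - p) / p))


def comparison_report(
    selections: list[SelectionSet],
    geno: GenotypeMatrix,
    n_qtl: float | None = None,
    ne: float | None = None,
) -> dict:
    """Full cross-model report: counts, overlaps, MAF and LD summaries."""
    per_model = {}
    for s in selections:
        per_model[s.model] = {
            "trait": s.trait,
            "n_selected": len(s),
            "adjustment": s.adjustment,
            "threshold": s.threshold,
            "mean_maf": mean_maf(s, geno),
            "mean_abs_r": mean_pairwise_ld(s, geno, "abs_r"),
            "mean_r2": mean_pairwise_ld(s, geno, "r2"),
        }
    report = {"models": per_model}
    if len(selections) >= 2:
        ov = overlap(selections)
        ov["pairwise"] = {
            f"{a}&{b}": v for (a, b), v in ov["pairwise"].items()
        }
        report["overlap"] = ov
    if n_qtl is not None and ne is not None:
        report["hayes_goddard"] = {
            "n_qtl": n_qtl,
            "ne": ne,
            "m_genes": hayes_goddard_m(n_qtl, ne),
        }
    return report


def report_to_text(report: dict) -> str:
    """Human-readable table: models x (count, MAF, LD) plus overlaps."""
    lines = [f"{'model':<6}{'n_sel':>8}{'adjust':>12}{'meanMAF':>10}{'mean|r|':>10}{'meanr2':>9}"]
    for model, row in report["models"].items():
        lines.append(
            f"{model:<6}{row['n_selected']:>8}{row['adjustment']:>12}"
            f"{row['mean_maf']:>10.3f}{row['mean_abs_r']:>10.3f}{row['mean_r2']:>9.3f}"
        )
    if "overlap" in report:
        ov = report["overlap"]
        lines.append(f"common to all models: {ov['all_models']} (union {ov['union']})")
        for pair, v in ov["pairwise"].items():
            lines.append(f"  {pair}: {v['count']}")
    if "hayes_goddard" in report:
        hg = report["hayes_goddard"]
        lines.append(
            f"Hayes-Goddard M = {hg['m_genes']:.2f} (N={hg['n_qtl']}, Ne={hg['ne']})"
        )
    return "\n".join(lines)
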