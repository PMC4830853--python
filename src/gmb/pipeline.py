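"""End-to-end pipeline: simulate (or load) -> QC -> fit models -> select ->
compare, driven by one YAML config with a single master seed.

Every stage writes its outputs as TSV/JSON into the run directory and never
rewrites a previous stage's files; a manifest records the seed, a hash of
the config, and checksums of all numeric outputs so a rerun with the same
config is verifiably identical.
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
import logging
import os
from dataclasses import dataclass, field

import numpy as np
import yaml

from . import car, geno, selection, simdata, single_snp, snp_blup
from .errors import ConfigError, GmbError

log = logging.getLogger("gmb")

_KNOWN_TOP = {"seed", "simulate", "data", "qc", "variance_components", "models",
              "selection", "car", "gsru", "hayes_goddard", "log_level"}
_KNOWN_SIM = {f.name for f in dataclasses.fields(simdata.SimulationConfig)} - {"seed"}
_KNOWN_DATA = {"genotypes", "traits", "trait", "amatrix", "pedigree"}
_KNOWN_QC = {"maf_min", "cr_min"}
_KNOWN_VC = {"sigma2_alpha", "sigma2_eps", "sigma2_a"}
_KNOWN_SEL = {"threshold", "modes"}
_KNOWN_CAR = {"lam", "kappa"}
_KNOWN_GSRU = {"max_iterations", "tolerance"}
_KNOWN_HG = {"n_qtl", "ne"}
_MODELS = ("m1", "m2", "m3", "m4")


@dataclass
class RunConfig:
    seed: int = 0
    simulate: dict | None = None
    data: dict | None = None
    qc: dict = field(default_factory=lambda: {"maf_min": 0.01, "cr_min": 0.90})
    variance_components: dict = field(
        default_factory=lambda: {"sigma2_alpha": 0.3, "sigma2_eps": 1.0, "sigma2_a": 0.5}
    )
    models: tuple = _MODELS
    selection: dict = field(default_factory=lambda: {"threshold": 0.001, "modes": "auto"})
    car: dict = field(default_factory=dict)  # lam / kappa overrides
    gsru: dict = field(default_factory=dict)
    hayes_goddard: dict | None = None
    log_level: str = "INFO"


def validate_config(raw: dict) -> RunConfig:
    """Schema-check a config mapping; unknown keys and bad values are errors.

    All problems are aggregated into one :class:`ConfigError` listing the
    offending key paths.
    """
    errors: list[str] = []
    if not isinstance(raw, dict):
        raise ConfigError("config must be a mapping")
    for key in raw:
        if key not in _KNOWN_TOP:
            errors.append(f"unknown key {key!r}")

    def check_block(name, block, known):
        if block is None:
            return {}
        if not isinstance(block, dict):
            errors.append(f"{name} must be a mapping")
            return {}
        for k in block:
            if k not in known:
                errors.append(f"unknown key {name}.{k}")
        return block

    sim = raw.get("simulate")
    data = raw.get("data")
    if sim is not None and data is not None:
        errors.append("give either 'simulate' or 'data', not both")
    if sim is None and data is None:
        errors.append("one of 'simulate' or 'data' is required")
    sim = check_block("simulate", sim, _KNOWN_SIM) if sim is not None else None
    data = check_block("data", data, _KNOWN_DATA) if data is not None else None
    if data is not None:
        for k in ("genotypes", "traits"):
            if k not in data:
                errors.append(f"data.{k} is required")
        for k in ("traits", "amatrix", "pedigree"):
            path = data.get(k)
            if path is not None and not os.path.exists(path):
                errors.append(f"data.{k}: file not found: {path}")

    qc = {"maf_min": 0.01, "cr_min": 0.90}
    qc.update(check_block("qc", raw.get("qc"), _KNOWN_QC))
    for k, v in qc.items():
        if not (isinstance(v, (int, float)) and 0 <= v <= 1):
            errors.append(f"qc.{k} must lie in [0, 1]")

    vc = {"sigma2_alpha": 0.3, "sigma2_eps": 1.0, "sigma2_a": 0.5}
    vc.update(check_block("variance_components", raw.get("variance_components"), _KNOWN_VC))
    for k, v in vc.items():
        if not isinstance(v, (int, float)) or v < 0:
            errors.append(f"variance_components.{k} must be a non-negative number")
    if isinstance(vc.get("sigma2_eps"), (int, float)) and vc["sigma2_eps"] <= 0:
        errors.append("variance_components.sigma2_eps must be > 0")

    models = tuple(raw.get("models", _MODELS))
    for mdl in models:
        if mdl not in _MODELS:
            errors.append(f"models: unknown model {mdl!r}")

    sel = {"threshold": 0.001, "modes": "auto"}
    sel.update(check_block("selection", raw.get("selection"), _KNOWN_SEL))
    if not (isinstance(sel["threshold"], (int, float)) and 0 < sel["threshold"] <= 1):
        errors.append("selection.threshold must lie in (0, 1]")

    car_cfg = check_block("car", raw.get("car"), _KNOWN_CAR)
    gsru_cfg = check_block("gsru", raw.get("gsru"), _KNOWN_GSRU)
    hg = raw.get("hayes_goddard")
    hg = check_block("hayes_goddard", hg, _KNOWN_HG) if hg is not None else None

    seed = raw.get("seed", 0)
    if not isinstance(seed, int):
        errors.append("seed must be an integer")

    if errors:
        raise ConfigError("invalid config:\n  " + "\n  ".join(errors))
    return RunConfig(
        seed=seed, simulate=sim, data=data, qc=qc, variance_components=vc,
        models=models, selection=sel, car=dict(car_cfg), gsru=dict(gsru_cfg),
        hayes_goddard=hg, log_level=str(raw.get("log_level", "INFO")),
    )


def load_config(path: str) -> RunConfig:
    with open(path) as fh:
        raw = yaml.safe_load(fh)
    return validate_config(raw or {})


def run_pipeline(config: RunConfig, out_dir: str) -> dict:
    """Execute all configured stages, persisting intermediates under out_dir.

    Returns the comparison report.  Outputs: genotypes/traits (when
    simulated), QC log, per-model result TSVs, selections TSV, report JSON
    and text, and ``manifest.json`` with the seed, config hash and per-file
    checksums.
    """
    os.makedirs(out_dir, exist_ok=True)
    logging.basicConfig(level=getattr(logging, config.log_level.upper(), logging.INFO))
    vc = single_snp.VarianceComponents(**config.variance_components)

    # ---- stage 1: obtain data
    A = None
    if config.simulate is not None:
        sim = simdata.SimulationConfig(seed=config.seed, **config.simulate)
        log.info("simulating %d individuals x %d SNPs", sim.n_individuals, sim.n_snps)
        g0 = simdata.simulate_genotypes(sim)
        ped = simdata.simulate_pedigree(sim)
        A = simdata.relationship_from_pedigree(ped)
        traits, truth = simdata.simulate_trait(g0, A, sim)
        geno.save_genotypes_tsv(g0, os.path.join(out_dir, "sim"))
        geno.save_traits_tsv(traits, os.path.join(out_dir, "sim.traits.tsv"))
        simdata.save_pedigree_tsv(ped, os.path.join(out_dir, "sim.pedigree.tsv"))
        _save_truth(truth, os.path.join(out_dir, "sim.truth.tsv"))
    else:
        g0 = geno.load_genotypes(config.data["genotypes"])
        traits = geno.load_traits_tsv(config.data["traits"], config.data.get("trait"))
        if config.data.get("amatrix"):
            A = simdata.load_relationship_tsv(config.data["amatrix"])
        elif config.data.get("pedigree"):
            ped = simdata.load_pedigree_tsv(config.data["pedigree"])
            A = simdata.relationship_from_pedigree(ped)

    # ---- stage 2: QC + imputation
    g_qc, qc_log = geno.apply_qc(g0, config.qc["maf_min"], config.qc["cr_min"])
    qc_log.to_csv(os.path.join(out_dir, "qc_log.tsv"), sep="\t", index=False)
    log.info("QC kept %d of %d SNPs", g_qc.n_snps, g0.n_snps)
    g_imp = geno.impute_missing_mean(g_qc)

    # ---- stage 3: model fits
    results = {}
    if "m1" in config.models:
        results["M1"] = single_snp.fit_m1(g_imp, traits)
    if "m2" in config.models:
        if A is None:
            raise GmbError("model m2 needs a pedigree or relationship matrix")
        results["M2"] = single_snp.fit_m2(g_imp, traits, A, vc)
    if "m3" in config.models:
        lam = config.car.get("lam")
        if lam is None:
            lam = car.estimate_lambda(g_imp)
        omega = car.car_scores(g_imp, traits, car.CARParameters(lam=lam, kappa=2.0))
        kappa = config.car.get("kappa")
        if kappa is None:
            kappa = car.estimate_kappa(omega, n_individuals=g_imp.n_individuals)
        import pandas as pd

        results["M3"] = pd.DataFrame(
            {
                "snp_id": g_imp.snp_ids,
                "model": "M3",
                "estimate": omega,
                "se": np.nan,
                "stat": car.car_statistic(omega, kappa),
                "p_nominal": car.car_pvalues(omega, kappa),
                "p_adjusted": np.nan,
            }
        )
        with open(os.path.join(out_dir, "m3_params.json"), "w") as fh:
            json.dump({"lambda": float(lam), "kappa": float(kappa)}, fh, indent=2)
    if "m4" in config.models:
        settings = snp_blup.GSRUSettings(**config.gsru) if config.gsru else snp_blup.GSRUSettings()
        fit = snp_blup.fit_m4_gsru(g_imp, traits, vc, settings)
        fit.convergence.to_csv(
            os.path.join(out_dir, "m4_convergence.tsv"), sep="\t", index=False
        )
        results["M4"] = snp_blup.m4_wald(g_imp, traits, vc, fit)

    for tag, df in results.items():
        if tag in ("M1", "M2"):
            df["p_adjusted"] = selection.bonferroni_adjust(
                df["p_nominal"].to_numpy(), g_imp.n_snps
            )
        df.to_csv(os.path.join(out_dir, f"results_{tag.lower()}.tsv"), sep="\t", index=False)

    # ---- stage 4: selection + comparison
    threshold = config.selection["threshold"]
    selections = [
        selection.select_significant(df, threshold=threshold, trait=traits.trait)
        for df in results.values()
    ]
    import pandas as pd

    sel_rows = [
        {"model": s.model, "snp_id": sid} for s in selections for sid in sorted(s.snp_ids)
    ]
    pd.DataFrame(sel_rows, columns=["model", "snp_id"]).to_csv(
        os.path.join(out_dir, "selections.tsv"), sep="\t", index=False
    )
    hg = config.hayes_goddard or {}
    report = selection.comparison_report(
        selections, g_imp, n_qtl=hg.get("n_qtl"), ne=hg.get("ne")
    )
    with open(os.path.join(out_dir, "report.json"), "w") as fh:
        json.dump(report, fh, indent=2, default=float)
    with open(os.path.join(out_dir, "report.txt"), "w") as fh:
        fh.write(selection.report_to_text(report) + "\n")

    _write_manifest(config, out_dir)
    return report


def _save_truth(truth, path):
    import pandas as pd

    pd.DataFrame({"g": truth.g}).to_csv(path, sep="\t", index=False)
    pd.DataFrame({"alpha": truth.alpha}).to_csv(path + ".alpha.tsv", sep="\t", index=False)


def _write_manifest(config: RunConfig, out_dir: str) -> None:
    cfg_json = json.dumps(dataclasses.asdict(config), sort_keys=True, default=str)
    checksums = {}
    for name in sorted(os.listdir(out_dir)):
        if name == "manifest.json":
            continue
        path = os.path.join(out_dir, name)
        with open(path, "rb") as fh:
            checksums[name] = hashlib.sha256(fh.read()).hexdigest()
    manifest = {
        "seed": config.seed,
        "config_sha256": hashlib.sha256(cfg_json.encode()).hexdigest(),
        "checksums": checksums,
    }
    with open(os.path.join(out_dir, "manifest.json"), "w") as fh:
        json.dump(manifest, fh, indent=2)
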