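"""End-to-end pipeline: simulate (optional) -> QC -> GRM -> REML -> CV -> reports.

Configuration is a plain YAML mapping (see ``PipelineConfig``); every stage
writes text artifacts into the output directory and the manifest records
files, seeds and the parameter values actually used, so a rerun with the
same configuration is byte-identical.
"""

from __future__ import annotations

import dataclasses
import json
import logging
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from . import io as gio
from .evaluation import ability_h2_regression, later_age_correlation, run_cv
from .gblup import fit_gblup
from .kinship import blend_grm, vanraden_grm
from .qc import QCThresholds, filter_variants
from .sim import SimConfig, corrupt_for_qc, phenotype_vector, simulate_genotypes, simulate_phenotypes
from .varcomp import reml_fit

logger = logging.getLogger(__name__)

__all__ = ["PipelineConfig", "run_pipeline"]


@dataclass
class PipelineConfig:
    out_dir: str = "gpsel_out"
    seed: int = 0
    # input: either simulate a herd, or point at ped/map + phenotype CSV
    simulate: bool = True
    genotypes_prefix: str | None = None
    phenotypes_path: str | None = None
    # simulated traits (name -> heritability target and scale), shared genotypes
    sim: dict = field(default_factory=dict)
    traits: list = field(
        default_factory=lambda: [
            {"name": "BW6", "h2": 0.35, "mean": 84.18, "sd": 10.31},
            {"name": "WH6", "h2": 0.57, "mean": 94.37, "sd": 5.26},
            {"name": "BW12", "h2": 0.24, "mean": 82.57, "sd": 10.51},
            {"name": "BL12", "h2": 0.07, "mean": 95.93, "sd": 4.96},
        ]
    )
    qc: dict = field(default_factory=dict)
    blend_weight: float = 0.05
    reml_tol: float = 1e-8
    methods: list = field(default_factory=lambda: ["gblup"])
    k: int = 5
    repeats: int = 10
    corrupt: bool = False

    @classmethod
    def from_yaml(cls, path: str | Path) -> "PipelineConfig":
        with open(path) as fh:
            raw = yaml.safe_load(fh) or {}
        known = {f.name for f in dataclasses.fields(cls)}
        unknown = set(raw) - known
        if unknown:
            raise ValueError(f"unknown configuration keys: {sorted(unknown)}")
        return cls(**raw)


def _stage(name):
    logger.info("pipeline stage: %s", name)


def run_pipeline(config: PipelineConfig) -> dict:
    """Execute the full analysis; returns the output manifest."""
    out = Path(config.out_dir)
    out.mkdir(parents=True, exist_ok=True)
    manifest: dict = {"seed": config.seed, "artifacts": {}, "parameters": {}}

    # ------------------------------------------------------------------ input
    if config.simulate:
        _stage("simulate")
        sim_cfg = SimConfig(**{"seed": config.seed, **config.sim})
        genotypes = simulate_genotypes(sim_cfg)
        frames, truth_rows = [], []
        for i, trait_cfg in enumerate(config.traits):
            tcfg = dataclasses.replace(
                sim_cfg,
                h2_target=trait_cfg["h2"],
                trait_mean=trait_cfg.get("mean", sim_cfg.trait_mean),
                trait_sd=trait_cfg.get("sd", sim_cfg.trait_sd),
                trait_name=trait_cfg["name"],
                seed=int((config.seed + 1000003 * (i + 1)) % (2**31)),
            )
            pheno, truth = simulate_phenotypes(genotypes, tcfg)
            frames.append(pheno)
            truth_rows.append(
                {"trait": trait_cfg["name"], "realized_h2": truth.realized_h2,
                 "realized_h2_later": truth.realized_h2_later}
            )
        phenotypes = pd.concat(frames, ignore_index=True)
        if config.corrupt:
            genotypes, inj = corrupt_for_qc(genotypes, seed=config.seed)
            inj.to_csv(out / "injection_manifest.csv", index=False)
            manifest["artifacts"]["injection_manifest"] = "injection_manifest.csv"
        gio.write_plink_text(genotypes, out / "herd")
        gio.write_phenotypes(phenotypes, out / "phenotypes.csv")
        pd.DataFrame(truth_rows).to_csv(out / "truth.csv", index=False)
        manifest["artifacts"].update(
            {"ped": "herd.ped", "map": "herd.map", "phenotypes": "phenotypes.csv",
             "truth": "truth.csv"}
        )
    else:
        _stage("load")
        if not config.genotypes_prefix or not config.phenotypes_path:
            raise ValueError("need genotypes_prefix and phenotypes_path when simulate=false")
        prefix = Path(config.genotypes_prefix)
        genotypes = gio.read_plink_text(prefix.with_suffix(".ped"), prefix.with_suffix(".map"))
        phenotypes = gio.read_phenotypes(config.phenotypes_path)

    # --------------------------------------------------------------------- qc
    _stage("qc")
    thresholds = QCThresholds(**config.qc)
    genotypes, report = filter_variants(genotypes, thresholds)
    report.to_frame().to_csv(out / "qc_report.csv", index=False)
    manifest["artifacts"]["qc_report"] = "qc_report.csv"
    manifest["parameters"]["qc"] = dataclasses.asdict(thresholds)

    # -------------------------------------------------------------------- grm
    _stage("grm")
    grm = blend_grm(vanraden_grm(genotypes), config.blend_weight)
    gio.write_grm(grm, out / "grm.csv")
    manifest["artifacts"]["grm"] = "grm.csv"
    manifest["parameters"]["blend_weight"] = config.blend_weight

    # ----------------------------------------------------------- reml and cv
    _stage("reml+cv")
    varcomp_rows, cv_frames, summaries = [], [], {}
    stages = phenotypes[phenotypes["stage"] != 30][["trait", "stage"]].drop_duplicates()
    for _, (tname, stage) in stages.iterrows():
        label = str(tname)
        y = phenotype_vector(phenotypes, tname, stage, genotypes.animal_ids)
        keep = np.isfinite(y)
        sub = genotypes.take_animals(np.flatnonzero(keep))
        sub_grm = grm.submatrix(np.flatnonzero(keep))
        vc = reml_fit(y[keep], sub_grm, tol=config.reml_tol)
        varcomp_rows.append(
            {"trait": label, "sigma_a2": vc.sigma_a2, "sigma_e2": vc.sigma_e2,
             "h2": vc.h2, "se_h2": vc.se_h2, "converged": vc.converged}
        )
        result = run_cv(
            y[keep], sub, methods=list(config.methods), k=config.k,
            repeats=config.repeats, seed=config.seed, trait=label,
            grm=sub_grm, varcomps=vc,
        )
        cv_frames.append(result.records)
        summaries[label] = result.summary()

    pd.DataFrame(varcomp_rows).to_csv(out / "varcomp.csv", index=False)
    pd.concat(cv_frames, ignore_index=True).to_csv(out / "cv_records.csv", index=False)
    summary = pd.concat(
        [s.assign(trait=t) for t, s in summaries.items()], ignore_index=True
    )[["trait", "method", "ability", "accuracy", "h2"]]
    summary.to_csv(out / "cv_summary.csv", index=False)
    manifest["artifacts"].update(
        {"varcomp": "varcomp.csv", "cv_records": "cv_records.csv", "cv_summary": "cv_summary.csv"}
    )

    # ------------------------------------------------- ability-h2 regression
    if summary["trait"].nunique() >= 3:
        _stage("regression")
        reg_rows = []
        for method, grp in summary.groupby("method"):
            slope, intercept = ability_h2_regression(grp["ability"], grp["h2"])
            reg_rows.append({"method": method, "slope": slope, "intercept": intercept})
        pd.DataFrame(reg_rows).to_csv(out / "ability_h2_regression.csv", index=False)
        manifest["artifacts"]["regression"] = "ability_h2_regression.csv"

    # ------------------------------------------------- later-age correlation
    later = phenotypes[phenotypes["stage"] == 30]
    if len(later):
        _stage("later-age correlation")
        tname = later["trait"].iloc[0]
        early_stage = int(
            phenotypes[(phenotypes["trait"] == tname) & (phenotypes["stage"] != 30)]["stage"].min()
        )
        y_early = phenotype_vector(phenotypes, tname, early_stage, genotypes.animal_ids)
        y_later = phenotype_vector(phenotypes, tname, 30, genotypes.animal_ids)
        keep = np.isfinite(y_early)
        vc = reml_fit(y_early[keep], grm.submatrix(np.flatnonzero(keep)))
        pred = fit_gblup(y_early[keep], grm.submatrix(np.flatnonzero(keep)), vc)
        r, p = later_age_correlation(pred["gebv"].to_numpy(), y_later[keep])
        pd.DataFrame(
            [{"trait": tname, "method": "gblup", "pearson_r": r, "p_value": p}]
        ).to_csv(out / "later_age_correlation.csv", index=False)
        manifest["artifacts"]["later_age_correlation"] = "later_age_correlation.csv"

    manifest["parameters"]["methods"] = list(config.methods)
    manifest["parameters"]["cv"] = {"k": config.k, "repeats": config.repeats}
    with open(out / "manifest.json", "w") as fh:
        json.dump(manifest, fh, indent=2, sort_keys=True)
    return manifest
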