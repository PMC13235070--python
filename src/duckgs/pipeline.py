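"""End-to-end orchestration: simulate/load -> QC -> relationship matrices
-> pre-correction -> REML/BLUP -> forward-validation report.

Each line is analysed separately (per-line QC, matrices, variance
components and validation), matching how distinct selection lines are
handled in practice; PCA is run on all lines jointly for structure
visualization.  A JSON manifest records the configuration, seeds and
per-stage record counts so any run can be reproduced bit-for-bit.
"""

from __future__ import annotations

import dataclasses
import json
import logging
import time
from dataclasses import dataclass
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from . import __version__, io, qc, validation
from .evaluation import (KernelEigen, fit_reml, predict_ebv,
                         variance_component_table)
from .precorrect import FixedEffectsSpec, default_trait_models, fit_fixed_effects
from .relatedness import build_a_matrix, build_g_matrix, pca, regularize
from .simulate import (LINE_A_TRAITS, LINE_D_TRAITS, SimConfig,
                       TraitArchitecture, mask_validation, simulate_genotypes,
                       simulate_pedigree, simulate_phenotypes)

logger = logging.getLogger("duckgs")

_TRAIT_PANELS = {"line_a": LINE_A_TRAITS, "line_d": LINE_D_TRAITS}


@dataclass
class RunConfig:
    """Configuration of one pipeline run.

    Exactly one of ``simulation`` (a dict of :class:`SimConfig` keyword
    overrides plus a ``traits`` entry) or the three input paths must be
    given.  ``traits`` selects a built-in panel (``"line_a"``/``"line_d"``)
    or lists explicit architecture dicts.
    """

    outdir: str = "duckgs_run"
    seed: int = 2024
    simulation: dict | None = None
    genotypes: str | None = None
    pedigree: str | None = None
    phenotypes: str | None = None
    maf_min: float = qc.DEFAULT_MAF_MIN
    hwe_threshold: float = qc.DEFAULT_HWE_P
    target_generation: int | None = None
    matrices: tuple = ("G", "A")
    ridge: float = 0.01
    trait_models: dict | None = None
    traits: list | None = None      # restrict analysis to these traits
    pca_components: int = 10
    write_genotypes: bool = False

    def __post_init__(self):
        has_sim = self.simulation is not None
        has_paths = any(x is not None for x in
                        (self.genotypes, self.pedigree, self.phenotypes))
        if has_sim == has_paths:
            raise ValueError("give exactly one of a simulation block or input paths")
        if has_paths and not all((self.genotypes, self.pedigree, self.phenotypes)):
            raise ValueError("genotypes, pedigree and phenotypes paths are all required")
        self.matrices = tuple(self.matrices)
        for k in self.matrices:
            if k not in ("A", "G"):
                raise ValueError(f"unknown matrix kind {k!r}")

    @classmethod
    def from_dict(cls, d: dict) -> "RunConfig":
        known = {f.name for f in dataclasses.fields(cls)}
        unknown = set(d) - known
        if unknown:
            raise ValueError(f"unknown config keys: {sorted(unknown)}")
        return cls(**d)

    @classmethod
    def from_yaml(cls, path) -> "RunConfig":
        with open(path) as fh:
            return cls.from_dict(yaml.safe_load(fh))

    def to_dict(self) -> dict:
        d = dataclasses.asdict(self)
        d["matrices"] = list(d["matrices"])
        return d


def _harmonize_ids(ped: pd.DataFrame, phenos: pd.DataFrame, geno):
    """Align genotype sample-id dtype with the pedigree id dtype (VCF
    sample names are strings even when ids are numeric)."""
    if pd.api.types.is_integer_dtype(ped["id"]):
        try:
            geno.ids = np.asarray([int(v) for v in geno.ids])
            return geno
        except (TypeError, ValueError):
            pass
    for df in (ped, phenos):
        df["id"] = df["id"].astype(str)
    if "sire" in ped.columns:
        ped["sire"] = ped["sire"].astype(str)
        ped["dam"] = ped["dam"].astype(str)
    geno.ids = np.asarray([str(v) for v in geno.ids], dtype=object)
    return geno


def _build_architectures(sim_block: dict):
    traits = sim_block.get("traits", "line_a")
    if isinstance(traits, str):
        if traits not in _TRAIT_PANELS:
            raise ValueError(f"unknown trait panel {traits!r}")
        return list(_TRAIT_PANELS[traits].values())
    return [TraitArchitecture(**t) if isinstance(t, dict) else t for t in traits]


@dataclass
class RunResult:
    outdir: Path
    reports: dict            # line -> validation report DataFrame
    variance_components: pd.DataFrame
    manifest: dict


def run_pipeline(config: RunConfig) -> RunResult:
    """Execute every stage in order and write all artifacts to
    ``config.outdir``.  Any stage failure aborts with a stage-tagged
    error message."""
    outdir = Path(config.outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    manifest = {"config": config.to_dict(), "version": __version__,
                "seed": config.seed, "stages": [],
                "started": time.strftime("%Y-%m-%dT%H:%M:%S")}

    def stage(name, counts):
        logger.info("stage %s: %s", name, counts)
        manifest["stages"].append({"stage": name, **counts})

    # -- inputs ------------------------------------------------------------
    try:
        if config.simulation is not None:
            sim_kwargs = {k: v for k, v in config.simulation.items()
                          if k not in ("traits",)}
            sim_kwargs.setdefault("seed", config.seed)
            if "gen_sizes" in sim_kwargs:
                sim_kwargs["gen_sizes"] = tuple(sim_kwargs["gen_sizes"])
            sim = SimConfig(**sim_kwargs)
            archs = _build_architectures(config.simulation)
            ped = simulate_pedigree(sim)
            geno, founder_freqs = simulate_genotypes(ped, sim)
            phenos, truth = simulate_phenotypes(ped, geno, archs, seed=sim.seed)
            trait_names = [a.trait_name for a in archs]
        else:
            ped = io.read_pedigree_tsv(config.pedigree)
            geno = io.read_vcf(config.genotypes) if str(config.genotypes).endswith(".vcf") \
                else io.read_ped_map(str(config.genotypes))[0]
            phenos = io.read_phenotypes_tsv(config.phenotypes)
            geno = _harmonize_ids(ped, phenos, geno)
            reserved = {"id", "line", "generation", "sexhatch", "damage", "pen"}
            trait_names = [c for c in phenos.columns if c not in reserved]
        if config.traits:
            trait_names = [t for t in trait_names if t in set(config.traits)]
    except Exception as exc:
        raise RuntimeError(f"[stage input] {exc}") from exc
    per_gen = ped.groupby(["line", "generation"]).size()
    stage("input", {"individuals": len(ped), "snps": geno.n_snps,
                    "traits": trait_names,
                    "per_generation": {f"{l}:{g}": int(c)
                                       for (l, g), c in per_gen.items()}})

    io.write_tsv(ped, outdir / "pedigree.tsv")
    io.write_tsv(phenos, outdir / "phenotypes.tsv")
    if config.write_genotypes:
        io.write_vcf(geno, outdir / "genotypes.vcf")

    target_gen = config.target_generation
    if target_gen is None:
        target_gen = int(ped["generation"].max())

    models = default_trait_models(trait_names)
    if config.trait_models:
        for t, spec in config.trait_models.items():
            if isinstance(spec, dict):
                spec = FixedEffectsSpec(trait=t,
                                        factors=tuple(spec.get("factors", ())),
                                        covariates=tuple(spec.get("covariates", ())))
            models[t] = spec

    lines = list(dict.fromkeys(ped["line"]))
    vc_rows, reports = [], {}
    snp_summaries, trait_summaries = [], []
    kept_by_line = {}

    for line in lines:
        line_ped = ped[ped["line"] == line].reset_index(drop=True)
        line_geno = geno.subset_individuals(line_ped["id"].to_numpy())
        line_phenos = phenos[phenos["id"].isin(line_ped["id"])].reset_index(drop=True)

        # -- qc -------------------------------------------------------------
        try:
            kept, snp_summary = qc.filter_snps(line_geno, config.maf_min,
                                               config.hwe_threshold)
            snp_summary.insert(0, "line", line)
            snp_summaries.append(snp_summary)
            kept_by_line[line] = set(line_geno.snp_ids[kept])
            geno_qc = line_geno.subset_snps(kept)
            ts = qc.trait_summary_table(line_phenos, trait_names)
            ts.insert(0, "line", line)
            trait_summaries.append(ts)
        except Exception as exc:
            raise RuntimeError(f"[stage qc, line {line}] {exc}") from exc
        stage("qc", {"line": line, "snps_pre": line_geno.n_snps,
                     "snps_post": int(len(kept))})

        # -- relationship matrices -----------------------------------------
        try:
            mats = {}
            if "A" in config.matrices:
                mats["A"] = regularize(build_a_matrix(line_ped), config.ridge)
            if "G" in config.matrices:
                mats["G"] = regularize(build_g_matrix(geno_qc), config.ridge)
        except Exception as exc:
            raise RuntimeError(f"[stage relatedness, line {line}] {exc}") from exc
        stage("relatedness", {"line": line,
                              "kinds": list(mats),
                              "ridge_applied": {k: m.ridge_applied
                                                for k, m in mats.items()}})

        # -- pre-correction (all generations jointly) -----------------------
        try:
            adjusted = {t: fit_fixed_effects(line_phenos, models[t])
                        for t in trait_names}
        except Exception as exc:
            raise RuntimeError(f"[stage precorrect, line {line}] {exc}") from exc
        stage("precorrect", {"line": line,
                             "records": {t: int(len(a.y_star))
                                         for t, a in adjusted.items()}})

        # -- forward split ---------------------------------------------------
        try:
            split = mask_validation(line_phenos, line_ped, target_gen)
        except Exception as exc:
            raise RuntimeError(f"[stage mask, line {line}] {exc}") from exc
        stage("mask", {"line": line, "target_generation": target_gen,
                       "training": len(split.training), "masked": len(split.masked)})

        # -- REML + BLUP + validation metrics --------------------------------
        try:
            records = []
            eigens = {}
            vc_by_trait = {}
            for kind, K in mats.items():
                for t in trait_names:
                    y = adjusted[t].y_star
                    y_train = y.loc[y.index.isin(split.training_ids)]
                    y_all = y.loc[y.index.isin(
                        np.concatenate([split.training_ids, split.masked_ids]))]
                    key_t = (kind, "train", tuple(y_train.index))
                    key_a = (kind, "all", tuple(y_all.index))
                    if key_t not in eigens:
                        eigens[key_t] = KernelEigen(K, ids=y_train.index.to_numpy())
                    if key_a not in eigens:
                        eigens[key_a] = KernelEigen(K, ids=y_all.index.to_numpy())
                    vc_train = fit_reml(y_train, eigen=eigens[key_t])
                    vc_whole = fit_reml(y_all, eigen=eigens[key_a])
                    vc_by_trait.setdefault(t, {})[kind] = vc_whole
                    ebv_partial = predict_ebv(y_train, K, vc_train)
                    ebv_whole = predict_ebv(y_all, K, vc_whole)
                    val_ids = [i for i in split.masked_ids if i in y.index]
                    r, acc = validation.prediction_accuracy(
                        ebv_partial.ebv.loc[val_ids], y.loc[val_ids], vc_train.h2)
                    b = validation.dispersion_bias(ebv_whole.ebv,
                                                   ebv_partial.ebv, val_ids)
                    records.append({"trait": t, "matrix_kind": kind,
                                    "h2": vc_train.h2, "se": vc_train.h2_se,
                                    "r": r, "acc": acc, "b": b,
                                    "b_std": validation.standardized_bias(b)})
                    vc_rows.append({"line": line, "trait": t, "matrix_kind": kind,
                                    "scope": "training", "h2": vc_train.h2,
                                    "h2_se": vc_train.h2_se,
                                    "sigma2_genetic": vc_train.sigma2_genetic,
                                    "sigma2_residual": vc_train.sigma2_residual,
                                    "converged": vc_train.converged})
                    vc_rows.append({"line": line, "trait": t, "matrix_kind": kind,
                                    "scope": "whole", "h2": vc_whole.h2,
                                    "h2_se": vc_whole.h2_se,
                                    "sigma2_genetic": vc_whole.sigma2_genetic,
                                    "sigma2_residual": vc_whole.sigma2_residual,
                                    "converged": vc_whole.converged})
                    ebv_out = pd.DataFrame({
                        "id": ebv_partial.ebv.index,
                        "ebv_masked": ebv_partial.ebv.to_numpy(),
                        "ebv_whole": ebv_whole.ebv.reindex(ebv_partial.ebv.index),
                        "phenotyped": ebv_partial.phenotyped.to_numpy()})
                    io.write_tsv(ebv_out, outdir / f"ebv_{line}_{t}_{kind}.tsv")
            report = validation.assemble_report(records)
        except Exception as exc:
            raise RuntimeError(f"[stage evaluation, line {line}] {exc}") from exc
        reports[line] = report
        io.write_tsv(report, outdir / f"validation_report_{line}.tsv")
        io.write_tsv(variance_component_table(vc_by_trait),
                     outdir / f"heritability_table_{line}.tsv")
        stage("evaluation", {"line": line, "traits": len(trait_names),
                             "matrices": list(mats)})

    # -- PCA across lines on jointly retained SNPs ---------------------------
    try:
        common = set.intersection(*kept_by_line.values()) if kept_by_line else set()
        keep_idx = np.where(np.isin(geno.snp_ids, list(common)))[0]
        pca_res = pca(geno.subset_snps(keep_idx), k=config.pca_components)
        scores = pd.DataFrame(pca_res.component_scores,
                              columns=[f"PC{i + 1}" for i in
                                       range(pca_res.component_scores.shape[1])])
        scores.insert(0, "id", geno.ids)
        scores.insert(1, "line", ped.set_index("id").loc[geno.ids, "line"].to_numpy())
        io.write_tsv(scores, outdir / "pca_scores.tsv")
        io.write_tsv(pd.DataFrame({
            "component": [f"PC{i + 1}" for i in range(len(pca_res.variance_explained))],
            "variance_explained_pct": pca_res.variance_explained}),
            outdir / "pca_variance.tsv")
    except Exception as exc:
        raise RuntimeError(f"[stage pca] {exc}") from exc
    stage("pca", {"snps": int(len(keep_idx)),
                  "pc1_pct": float(pca_res.variance_explained[0])})

    vc_table = pd.DataFrame(vc_rows)
    io.write_tsv(vc_table, outdir / "variance_components.tsv")
    io.write_tsv(pd.concat(snp_summaries, ignore_index=True),
                 outdir / "snp_summary.tsv")
    io.write_tsv(pd.concat(trait_summaries, ignore_index=True),
                 outdir / "trait_summary.tsv")
    manifest["finished"] = time.strftime("%Y-%m-%dT%H:%M:%S")
    with open(outdir / "manifest.json", "w") as fh:
        json.dump(manifest, fh, indent=2, default=str)
    return RunResult(outdir=outdir, reports=reports,
                     variance_components=vc_table, manifest=manifest)
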