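"""End-to-end orchestration: QC -> structure -> diversity -> demography ->
environment scans -> trees, from either real inputs (VCF + popmap + env
CSV) or the synthetic generator, with one global seed expanded into
independent per-stage streams and a machine-readable JSON report.
"""

from __future__ import annotations

import json
import logging
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from . import callset as cio
from .demography import (compute_folded_joint_sfs, fit_model,
                         select_complete_subset, select_model)
from .diversity import diversity_table, group_anova, latitude_regression
from .envscan import (bayes_factor_scan, consensus_candidates,
                      control_set_omega, latent_factor_scan,
                      rank_env_importance)
from .models import model_spec
from .qc import QcConfig, run_qc
from .simulate import LINEAGE_DEME, StudyDesign, generate_dataset, write_study_inputs
from .structure import cluster_tree, coancestry_matrix, fst_matrix, pca
from .trees import split_and_compare

log = logging.getLogger("scallop_popgen")

__all__ = ["PipelineConfig", "run_pipeline", "read_inputs"]

_STAGES = ("inputs", "qc", "structure", "diversity", "demography",
           "envscan", "trees")


@dataclass
class PipelineConfig:
    """Exactly one of (``vcf``+``popmap``+``env``) or ``design`` is set."""

    vcf: str | None = None
    popmap: str | None = None
    env: str | None = None
    design: StudyDesign | None = None
    outdir: str = "results"
    rng_seed: int = 0
    qc: QcConfig = field(default_factory=QcConfig)
    fst_permutations: int = 200
    models: tuple[str, ...] = ("M1", "M2", "M3")
    fit_runs: int = 3
    fit_sims: int = 5000
    fit_cycles: int = 10
    sfs_per_deme: int = 8          # diploids per deme entering the SFS
    scan_variables: tuple[str, ...] = ("sst_mean", "doc_mean")
    scan_alpha: float = 0.01
    bf_threshold_db: float = 10.0
    tree_bootstrap: int = 50

    def __post_init__(self) -> None:
        paths = all(x is not None for x in (self.vcf, self.popmap, self.env))
        if self.design is not None and any(
                x is not None for x in (self.vcf, self.popmap, self.env)):
            raise ValueError("set either input paths or a synthetic design, not both")
        if self.design is None and not paths:
            raise ValueError("either input paths or a synthetic design is required")

    @classmethod
    def from_yaml(cls, path) -> "PipelineConfig":
        import yaml
        with open(path) as fh:
            raw = yaml.safe_load(fh) or {}
        if "design" in raw and raw["design"] is not None:
            raw["design"] = StudyDesign(**raw["design"])
        if "qc" in raw:
            raw["qc"] = QcConfig(**raw["qc"])
        for key in ("models", "scan_variables"):
            if key in raw and raw[key] is not None:
                raw[key] = tuple(raw[key])
        return cls(**raw)


def read_inputs(vcf_path, popmap_path, env_path):
    """Load and cross-validate the three study inputs."""
    calls = cio.read_vcf(vcf_path)
    popmap = cio.read_popmap(popmap_path)
    env = cio.read_env_table(env_path)
    calls = cio.attach_populations(calls, popmap)
    missing_env = set(calls.populations) - set(env.index)
    if missing_env:
        raise ValueError(f"populations without environment rows: {sorted(missing_env)}")
    return calls, popmap, env


def _stage_seeds(seed: int) -> dict[str, int]:
    ss = np.random.SeedSequence(int(seed) & 0x7FFFFFFF)
    states = ss.generate_state(len(_STAGES))
    return {name: int(s >> 1) for name, s in zip(_STAGES, states)}


def run_pipeline(config: PipelineConfig) -> dict:
    """Execute every stage, persist intermediates under ``config.outdir``
    and return (and write) the JSON report."""
    out = Path(config.outdir)
    out.mkdir(parents=True, exist_ok=True)
    seeds = _stage_seeds(config.rng_seed)
    report: dict = {"seed": config.rng_seed, "stages": {}}
    stage = "inputs"
    try:
        if config.design is not None:
            design = config.design
            dataset = generate_dataset(design)
            write_study_inputs(dataset, out / "inputs")
            calls, popmap, env = dataset.calls, dataset.popmap, dataset.env
            report["stages"]["inputs"] = {
                "source": "synthetic", "n_individuals": calls.n_individuals,
                "n_loci": calls.n_loci,
                "n_adaptive_truth": len(dataset.truth["adaptive_loci"])}
        else:
            calls, popmap, env = read_inputs(config.vcf, config.popmap, config.env)
            report["stages"]["inputs"] = {
                "source": "files", "n_individuals": calls.n_individuals,
                "n_loci": calls.n_loci}
        lineage_of_pop = dict(zip(popmap["population"], popmap["lineage"]))

        stage = "qc"
        calls, qc_report = run_qc(calls, config.qc)
        qc_report.to_tsv(out / "qc_report.tsv")
        qc_report.to_json(out / "qc_report.json")
        report["stages"]["qc"] = {
            "steps": qc_report.steps,
            "n_individuals": calls.n_individuals, "n_loci": calls.n_loci}

        stage = "structure"
        fst = fst_matrix(calls, config.fst_permutations, seeds["structure"])
        fst.to_tsv(out / "fst.tsv", out / "fst_pvalues.tsv")
        pc = pca(calls, n_components=4)
        pd.DataFrame(pc.scores, index=calls.individuals,
                     columns=[f"PC{i+1}" for i in range(pc.scores.shape[1])]
                     ).to_csv(out / "pca_scores.csv")
        sim = coancestry_matrix(calls)
        ct = cluster_tree(np.nan_to_num(sim, nan=0.0), list(calls.individuals))
        (out / "coancestry_upgma.nwk").write_text(ct.newick() + "\n")
        n_sig = int((fst.pvalues < fst.corrected_alpha).sum() // 2)
        report["stages"]["structure"] = {
            "populations": fst.populations,
            "corrected_alpha": fst.corrected_alpha,
            "n_significant_pairs": n_sig,
            "fst_range": [float(np.nanmin(fst.theta)), float(np.nanmax(fst.theta))],
            "pc_variance": pc.explained_variance_ratio[:4].tolist()}

        stage = "diversity"
        div = diversity_table(calls, rng_seed=seeds["diversity"])
        div.to_csv(out / "diversity.csv")
        lineages = popmap.set_index("individual")["lineage"]
        pop_lineage = [lineage_of_pop[p] for p in div.index]
        species = ["JAC" if l == "JAC" else "MAX" for l in pop_lineage]
        div_block: dict = {"table": div.reset_index().to_dict("records")}
        if len(set(species)) == 2 and min(species.count("JAC"),
                                          species.count("MAX")) >= 2:
            f_npl, p_npl = group_anova(div["npl_mean"].to_numpy(), species)
            f_mlh, p_mlh = group_anova(div["mlh_mean"].to_numpy(), species)
            div_block["species_anova"] = {"npl": [f_npl, p_npl],
                                          "mlh": [f_mlh, p_mlh]}
        env_lat = env.loc[div.index, "latitude"].to_numpy()
        r2_npl, p_lat_npl = latitude_regression(div["npl_mean"].to_numpy(), env_lat)
        r2_mlh, p_lat_mlh = latitude_regression(div["mlh_mean"].to_numpy(), env_lat)
        div_block["latitude_regression"] = {"npl": [r2_npl, p_lat_npl],
                                            "mlh": [r2_mlh, p_lat_mlh]}
        report["stages"]["diversity"] = div_block

        stage = "demography"
        deme_of_ind = {ind: LINEAGE_DEME[lineages[ind]]
                       for ind in calls.individuals}
        deme_sizes: dict[str, int] = {}
        for d in set(deme_of_ind.values()):
            avail = sum(1 for v in deme_of_ind.values() if v == d)
            deme_sizes[d] = min(config.sfs_per_deme, avail)
        subset = select_complete_subset(calls, deme_of_ind, deme_sizes)
        obs = compute_folded_joint_sfs(calls, deme_of_ind, subset)
        obs.to_text(out / "folded_sfs.txt")
        sizes = {n: int(s) for n, s in zip(obs.deme_names, obs.sample_sizes)}
        fits = []
        for mid in config.models:
            spec = model_spec(mid, sample_sizes=sizes)
            fits.append(fit_model(obs, spec, n_runs=config.fit_runs,
                                  n_sims=config.fit_sims,
                                  n_cycles=config.fit_cycles,
                                  rng_seed=seeds["demography"]))
        ranked = select_model(fits)
        with open(out / "demography_fits.json", "w") as fh:
            json.dump([f.to_dict() for f in ranked], fh, indent=1)
        report["stages"]["demography"] = {
            "n_snps_sfs": obs.n_snps, "deme_sizes": sizes,
            "ranking": [{"model": f.model_id, "aic": f.aic,
                         "loglik": f.max_loglik} for f in ranked],
            "best_params": ranked[0].params}

        stage = "envscan"
        importance = rank_env_importance(calls, env, seeds["envscan"])
        importance.to_csv(out / "env_importance.csv", index=False)
        pop_series = pd.Series(list(calls.populations), index=calls.individuals)
        omega = control_set_omega(calls, env, config.scan_variables)
        lf_sets, bf_sets = {}, {}
        scan_rows = []
        for vi, var in enumerate(config.scan_variables):
            env_ind = env.loc[pop_series, var].to_numpy()
            lf = latent_factor_scan(calls, env_ind, n_runs=5,
                                    alpha=config.scan_alpha,
                                    rng_seed=seeds["envscan"] + vi + 1)
            bf = bayes_factor_scan(calls, env[var], omega=omega,
                                   threshold_db=config.bf_threshold_db)
            ids = calls.locus_ids
            lf_sets[var] = set(ids[lf.flags])
            bf_sets[var] = set(ids[bf.flags])
            scan_rows.append(pd.DataFrame({
                "locus": ids, "variable": var, "z": lf.z, "p": lf.p,
                "q": lf.q, "lfmm_flag": lf.flags, "bf_db": bf.bf_db,
                "bf_flag": bf.flags}))
        pd.concat(scan_rows).to_csv(out / "env_scans.tsv", sep="\t", index=False)
        cons = consensus_candidates({"latent": lf_sets, "covariance": bf_sets})
        (out / "consensus_loci.txt").write_text(
            "\n".join(sorted(cons.consensus)) + "\n")
        report["stages"]["envscan"] = {
            "importance_top": importance["variable"].head(3).tolist(),
            "latent_candidates": len(cons.method_sets["latent"]),
            "covariance_candidates": len(cons.method_sets["covariance"]),
            "consensus": len(cons.consensus)}

        stage = "trees"
        comp = split_and_compare(calls, cons.consensus,
                                 n_boot=config.tree_bootstrap,
                                 rng_seed=seeds["trees"])
        (out / "tree_neutral.nwk").write_text(
            comp.neutral_tree.as_string(schema="newick"))
        if comp.candidate_tree is not None:
            (out / "tree_candidate.nwk").write_text(
                comp.candidate_tree.as_string(schema="newick"))
        report["stages"]["trees"] = {
            "rf_distance": comp.rf_distance,
            "n_candidate_loci": len(cons.consensus)}
    except Exception:
        log.exception("pipeline failed in stage %r", stage)
        report["failed_stage"] = stage
        with open(out / "report.json", "w") as fh:
            json.dump(report, fh, indent=1, default=float)
        raise

    with open(out / "report.json", "w") as fh:
        json.dump(report, fh, indent=1, default=float)
    return report
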