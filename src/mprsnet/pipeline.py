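"""End-to-end orchestration: inputs -> candidate modules -> ADMs -> validation.

Stages run in a fixed order (build-network, propagate per trait side,
score modules, select ADMs, annotate, validate), each writing its outputs
plus a manifest recording parameters and derived per-stage seeds.  One
global seed deterministically derives every stage seed by hashing the
stage name, so a rerun with the same config is reproducible.
"""

from __future__ import annotations

import json
import logging
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from . import adm as adm_mod
from . import annotation as annot_mod
from . import clinical, io_formats, mprs as mprs_mod
from .gene_scoring import map_snps_to_genes
from .network import build_weighted_network, largest_connected_component
from .propagation import build_scc_hierarchy, compute_similarity_matrix, select_cut_and_score
from .utils import derive_seed

logger = logging.getLogger("mprsnet.pipeline")

__all__ = ["PipelineConfig", "run_all"]


@dataclass
class PipelineConfig:
    """Input paths and analysis parameters for a full run.

    The numeric defaults are the framework's standard operating point:
    restart probability 0.4, +/-20 kb SNP windows, 800 propagation
    permutations, 1000 co-expression permutations, 5000 mediation
    bootstrap draws, Bonferroni alpha 0.05.
    """

    edges: str
    scores: dict[str, str]  # side label -> gene score table path
    sumstats: dict[str, str]  # meta-GWAS label -> path
    genotypes: str
    annotation: str
    phenotypes: str
    expression_target: str
    expression_other: dict[str, str] = field(default_factory=dict)
    gmt: str | None = None
    target_tissue: str = "amygdala"
    beta: float = 0.4
    convention: str = "hotnet2"
    window_bp: int = 20_000
    n_perm_propagation: int = 800
    n_perm_modularity: int = 1000
    n_boot_mediation: int = 5000
    alpha: float = 0.05
    adm_rule: str = "union"
    min_module_size: int = 3
    seed: int = 0

    @classmethod
    def from_yaml(cls, path: str | Path, **overrides) -> "PipelineConfig":
        with open(path) as fh:
            raw = yaml.safe_load(fh) or {}
        raw.update({k: v for k, v in overrides.items() if v is not None})
        return cls(**raw)


def _mediator_column(side: str) -> str:
    return "amyg_left" if side.upper().startswith("L") else "amyg_right"


def run_all(config: PipelineConfig, outdir: str | Path) -> Path:
    """Run every stage and write results under ``outdir``; returns the path."""
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    manifest: dict = {"parameters": {k: v for k, v in vars(config).items()}, "stages": {}}

    for path in [config.edges, config.genotypes, config.annotation, config.phenotypes,
                 config.expression_target, *config.scores.values(), *config.sumstats.values(),
                 *config.expression_other.values(), *([config.gmt] if config.gmt else [])]:
        if not Path(path).exists():
            raise FileNotFoundError(f"input not found before any computation: {path}")

    edges = io_formats.read_edge_list(config.edges)
    annotation = io_formats.read_annotation(config.annotation)
    phenotypes = io_formats.read_phenotypes(config.phenotypes)
    genotypes = io_formats.read_genotypes(config.genotypes, format="dosage_tsv")
    sumstats = {label: io_formats.read_sumstats(p) for label, p in sorted(config.sumstats.items())}

    # --- propagation per trait side -------------------------------------
    candidates: list[io_formats.ModuleRecord] = []
    networks = {}
    for side, score_path in sorted(config.scores.items()):
        scores = io_formats.read_gene_scores(score_path)
        net = largest_connected_component(build_weighted_network(edges, scores))
        networks[side] = net
        model = compute_similarity_matrix(net, beta=config.beta, convention=config.convention)
        hierarchy = build_scc_hierarchy(model, min_size=config.min_module_size)
        stage_seed = derive_seed(config.seed, f"propagate:{side}")
        delta_star, modules = select_cut_and_score(
            hierarchy, net, beta=config.beta, n_perm=config.n_perm_propagation,
            min_size=config.min_module_size, seed=stage_seed,
            convention=config.convention, side=side,
        )
        manifest["stages"][f"propagate:{side}"] = {
            "seed": stage_seed, "n_nodes": net.n_nodes, "n_edges": net.n_edges,
            "delta_star": delta_star, "n_modules": len(modules),
        }
        for m in modules:
            candidates.append(io_formats.ModuleRecord(
                module_id=m.module_id, side=side, genes=m.genes, perm_p=m.perm_p,
            ))
    if not candidates:
        raise RuntimeError("propagation produced no significant candidate modules")

    # --- MPRS per candidate module and meta-GWAS source ------------------
    first_ss = next(iter(sumstats.values()))
    snp_map = map_snps_to_genes(first_ss, annotation, window_bp=config.window_bp)
    mprs_by_source: dict[str, pd.DataFrame] = {}
    profiles = []
    for label, ss in sumstats.items():
        harmonized = mprs_mod.harmonize(genotypes, ss)
        source_profiles = [
            mprs_mod.compute_mprs(harmonized, rec.genes, snp_map,
                                  module_id=rec.module_id, weight_source=label)
            for rec in candidates
        ]
        profiles.extend(source_profiles)
        mprs_by_source[label] = mprs_mod.mprs_table(source_profiles)
    mprs_long = pd.concat(mprs_by_source.values(), ignore_index=True)
    io_formats.write_report(mprs_long, outdir / "mprs.tsv")

    # --- ADM selection ---------------------------------------------------
    adm_results = adm_mod.identify_adms(
        mprs_by_source, phenotypes, n_candidate_modules=len(candidates),
        alpha=config.alpha, rule=config.adm_rule,
    )
    source_labels = sorted(sumstats)
    by_id = {r.module_id: r for r in adm_results}
    for rec in candidates:
        r = by_id[rec.module_id]
        rec.p_meta1 = r.p_by_source[source_labels[0]]
        rec.p_meta2 = r.p_by_source[source_labels[-1]] if len(source_labels) > 1 else float("nan")
        rec.cohens_d = r.d_by_source[source_labels[0]]
        rec.d_ci_low, rec.d_ci_high = r.d_ci_by_source[source_labels[0]]
    io_formats.write_modules(candidates, outdir / "modules.tsv", metadata={
        "alpha_corrected": adm_results[0].alpha_corrected,
        "sources": source_labels, "rule": config.adm_rule,
    })
    adms = [rec for rec in candidates if by_id[rec.module_id].significant]
    io_formats.write_modules(adms, outdir / "adm.tsv", metadata={
        "alpha_corrected": adm_results[0].alpha_corrected,
        "sources": source_labels, "rule": config.adm_rule,
    })
    manifest["stages"]["select-adm"] = {
        "n_candidates": len(candidates), "n_adms": len(adms),
        "alpha_corrected": adm_results[0].alpha_corrected,
    }
    if not adms:
        logger.warning("no ADMs passed the corrected threshold; validation stages skipped")

    # --- annotation: modularity, tissue specificity, enrichment ----------
    expr_target = io_formats.read_expression(config.expression_target, config.target_tissue)
    expr_others = {lab: io_formats.read_expression(p, lab) for lab, p in sorted(config.expression_other.items())}
    background = sorted({g for net in networks.values() for g in net.nodes})
    seed_mod = derive_seed(config.seed, "modularity")
    modularity_rows = []
    for rec in adms:
        res = annot_mod.modularity_permutation(
            expr_target, rec.genes, background, n_perm=config.n_perm_modularity,
            seed=derive_seed(seed_mod, rec.module_id), module_id=rec.module_id,
        )
        modularity_rows.append({
            "module_id": rec.module_id, "tissue": res.tissue_label,
            "observed_pcc": res.observed_pcc, "null_mean": res.null_mean,
            "null_sd": res.null_sd, "perm_p": res.perm_p, "n_perm": res.n_perm,
        })
    io_formats.write_report(pd.DataFrame(modularity_rows), outdir / "modularity.tsv")

    spec_rows = []
    if len(candidates) >= 2:
        pcc_target = []
        pcc_other: dict[str, list[float]] = {lab: [] for lab in expr_others}
        used_modules = []
        for rec in candidates:
            try:
                pt = annot_mod.module_coexpression(expr_target, rec.genes)
            except ValueError:
                continue
            pcc_target.append(pt)
            used_modules.append(rec.module_id)
            for lab, ex in expr_others.items():
                pcc_other[lab].append(annot_mod.module_coexpression(ex, rec.genes))
        for lab in expr_others:
            t, p = annot_mod.tissue_specificity(pcc_target, pcc_other[lab])
            spec_rows.append({
                "target_tissue": config.target_tissue, "other_tissue": lab,
                "n_modules": len(used_modules), "t": t, "p": p,
            })
    io_formats.write_report(pd.DataFrame(spec_rows), outdir / "specificity.tsv")

    if config.gmt:
        gmt = io_formats.read_gmt(config.gmt)
        enr_frames = []
        for rec in adms:
            rows = annot_mod.hypergeometric_enrichment(rec.genes, gmt, background)
            df = annot_mod.enrichment_table(rows)
            df.insert(0, "module_id", rec.module_id)
            enr_frames.append(df)
        if enr_frames:
            io_formats.write_report(pd.concat(enr_frames, ignore_index=True), outdir / "enrichment.tsv")

    # --- clinical validation ---------------------------------------------
    primary_source = source_labels[0]
    staging_frames, survival_rows, mediation_rows = [], [], []
    pheno_idx = phenotypes.set_index("individual_id")
    for rec in adms:
        scores = mprs_by_source[primary_source]
        sub = scores[scores["module_id"] == rec.module_id].set_index("individual_id")
        score_z = sub["score_z"]

        stage = clinical.staging_comparisons(score_z, phenotypes)
        stage.insert(0, "module_id", rec.module_id)
        staging_frames.append(stage)

        mci = pheno_idx[pheno_idx["diagnosis"].isin(["EMCI", "LMCI"]) & pheno_idx["conv_months"].notna()]
        common = mci.index.intersection(score_z.index)
        mci = mci.loc[common]
        sz = score_z.loc[common]
        groups = clinical.median_split(sz)
        km = clinical.km_logrank(mci["conv_months"], mci["conv_event"].astype(int), groups)
        cov = pd.DataFrame({
            "mprs_z": sz.to_numpy(float),
            "age": mci["age"].to_numpy(float),
            "sex": (mci["sex"] == "M").astype(float).to_numpy(),
            "education": mci["education"].to_numpy(float),
        })
        cox = clinical.cox_ph(mci["conv_months"], mci["conv_event"].astype(int), cov)
        hr_row = cox.cox.set_index("covariate").loc["mprs_z"]
        survival_rows.append({
            "module_id": rec.module_id, "n_mci": len(mci),
            "logrank_chi2": km.logrank_chi2, "logrank_p": km.logrank_p,
            "hr_per_sd": hr_row["hr"], "hr_ci_low": hr_row["ci_low"],
            "hr_ci_high": hr_row["ci_high"], "cox_p": hr_row["p"],
        })

        med_df = pheno_idx.loc[pheno_idx.index.intersection(score_z.index)]
        x = score_z.loc[med_df.index].to_numpy(float)
        m = med_df[_mediator_column(rec.side)].to_numpy(float)
        y = med_df["diagnosis"].isin(["EMCI", "LMCI", "AD"]).astype(int).to_numpy()
        z = np.column_stack([
            med_df["age"].to_numpy(float),
            (med_df["sex"] == "M").astype(float).to_numpy(),
            med_df["education"].to_numpy(float),
        ])
        med = clinical.mediation(
            x, m, y, z, n_boot=config.n_boot_mediation,
            seed=derive_seed(config.seed, f"mediation:{rec.module_id}"),
        )
        mediation_rows.append({
            "module_id": rec.module_id, "acme": med.acme, "ade": med.ade,
            "total_effect": med.total_effect, "prop_mediated": med.prop_mediated,
            "acme_ci_low": med.ci["acme"][0], "acme_ci_high": med.ci["acme"][1],
            "acme_p": med.p["acme"], "ade_p": med.p["ade"],
            "prop_ci_low": med.ci["prop_mediated"][0], "prop_ci_high": med.ci["prop_mediated"][1],
            "n_boot": med.n_boot,
        })
    if staging_frames:
        io_formats.write_report(pd.concat(staging_frames, ignore_index=True), outdir / "staging.tsv")
    io_formats.write_report(pd.DataFrame(survival_rows), outdir / "survival.tsv")
    io_formats.write_report(pd.DataFrame(mediation_rows), outdir / "mediation.tsv")

    manifest["stages"]["validate"] = {"n_adms_validated": len(adms)}
    with open(outdir / "manifest.json", "w") as fh:
        json.dump(manifest, fh, indent=2, sort_keys=True, default=str)
    return outdir
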