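"""Synthetic inputs with planted ground truth for every pipeline stage.

The generator emulates the full data constellation the pipeline consumes
-- an interaction network with planted high-weight modules, gene-level
association scores for two trait sides, individual-level genotypes whose
module scores separate synthetic cases from controls by a target Cohen's
d, disease meta-GWAS weights, tissue expression with planted
within-module correlation, and phenotypes produced by an explicit
mediation-plus-survival model -- so each stage has a parameter-recovery
test with no external downloads.

Ground truth is returned alongside every dataset: planted memberships,
the case/control labels used for the genotype effect-size calibration,
the generative mediation paths with their Monte-Carlo true ACME/ADE, and
the true per-SD hazard ratio.
"""

from __future__ import annotations

import json
from dataclasses import asdict, dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
from scipy import stats

from .io_formats import ExpressionMatrix, GenotypeMatrix
from .utils import derive_seed

__all__ = [
    "PlantedModule",
    "MediationPaths",
    "SurvivalParams",
    "ExpressionParams",
    "SimulationConfig",
    "GenotypeSimulation",
    "generate_network",
    "generate_gene_scores",
    "generate_annotation",
    "generate_genotypes_and_sumstats",
    "generate_phenotypes",
    "generate_expression",
    "true_mediation_effects",
    "simulate_to_dir",
]

_NON_PALINDROMIC_PAIRS = [("A", "C"), ("A", "G"), ("T", "C"), ("T", "G")]


@dataclass
class PlantedModule:
    """One planted module: size, internal edge probability, score effect.

    ``gene_score_alpha`` is the Beta(alpha, 1) shape for planted gene
    p-values; alpha = 1 reduces to the uniform background (null), small
    alpha concentrates p near 0.
    """

    size: int = 10
    p_in: float = 0.8
    gene_score_alpha: float = 0.01


@dataclass
class MediationPaths:
    """Generative x-m-y paths on the latent (standardized-x, logit-y) scale."""

    a: float = 0.5  # x -> m
    b: float = 0.5  # m -> y (logit)
    c: float = 0.82  # direct x -> y (logit); with a, b this mediates ~22% of the total effect
    intercept: float = 0.0
    gamma_age: float = 0.1
    gamma_sex: float = 0.1
    gamma_edu: float = -0.1


@dataclass
class SurvivalParams:
    """Exponential conversion model: hazard = baseline * exp(log_hr_per_sd * x)."""

    baseline_hazard: float = 0.02  # events per month
    log_hr_per_sd: float = float(np.log(1.3))
    censoring_rate: float = 0.4


@dataclass
class ExpressionParams:
    """Latent-factor co-expression: loading sqrt(rho) in the target tissue only."""

    n_samples: int = 80
    rho_target: float = 0.6
    rho_other: float = 0.0
    target_tissue: str = "amygdala"
    other_tissues: tuple[str, ...] = ("cortex", "hippocampus", "blood")


@dataclass
class SimulationConfig:
    """All knobs of the synthetic study, with a mandatory seed."""

    seed: int
    n_genes: int = 150
    edge_prob: float = 0.03
    planted: list[PlantedModule] = field(default_factory=lambda: [PlantedModule()])
    n_individuals: int = 400
    n_snps_per_gene: int = 3
    maf_range: tuple[float, float] = (0.1, 0.4)
    target_cohens_d: float = 0.5
    mediation: MediationPaths = field(default_factory=MediationPaths)
    survival: SurvivalParams = field(default_factory=SurvivalParams)
    expression: ExpressionParams = field(default_factory=ExpressionParams)

    def __post_init__(self) -> None:
        if self.seed is None:
            raise ValueError("seed is mandatory")
        for p in (self.edge_prob, *self.maf_range, self.survival.censoring_rate,
                  self.expression.rho_target, self.expression.rho_other):
            if not 0.0 <= p <= 1.0:
                raise ValueError(f"probability out of [0, 1]: {p}")
        for mod in self.planted:
            if mod.size < 3:
                raise ValueError("planted module size must be >= 3")
            if not 0.0 <= mod.p_in <= 1.0:
                raise ValueError("p_in must be in [0, 1]")
        if sum(m.size for m in self.planted) > self.n_genes:
            raise ValueError("planted module sizes exceed n_genes")

    @classmethod
    def from_dict(cls, d: dict) -> "SimulationConfig":
        d = dict(d)
        if "planted" in d:
            d["planted"] = [PlantedModule(**m) for m in d["planted"]]
        for key, typ in (("mediation", MediationPaths), ("survival", SurvivalParams),
                         ("expression", ExpressionParams)):
            if key in d and isinstance(d[key], dict):
                sub = dict(d[key])
                if "other_tissues" in sub:
                    sub["other_tissues"] = tuple(sub["other_tissues"])
                d[key] = typ(**sub)
        if "maf_range" in d:
            d["maf_range"] = tuple(d["maf_range"])
        return cls(**d)

    def to_dict(self) -> dict:
        d = asdict(self)
        d["maf_range"] = list(self.maf_range)
        d["expression"]["other_tissues"] = list(self.expression.other_tissues)
        return d


def _gene_names(n: int) -> list[str]:
    return [f"G{i:04d}" for i in range(n)]


def generate_network(config: SimulationConfig) -> tuple[list[tuple[str, str]], dict[str, list[str]]]:
    """Random background graph with planted dense modules and a spanning scaffold.

    Background edges appear with probability ``edge_prob``; within each
    planted module the probability is raised to its ``p_in``.  A random
    spanning path over all genes guarantees connectivity (with background
    and planted probabilities at zero, exactly n_genes - 1 edges remain).
    """
    rng = np.random.default_rng(derive_seed(config.seed, "network"))
    genes = _gene_names(config.n_genes)
    planted: dict[str, list[str]] = {}
    offset = 0
    for k, mod in enumerate(config.planted, start=1):
        planted[f"planted{k}"] = genes[offset : offset + mod.size]
        offset += mod.size

    edges: set[tuple[str, str]] = set()
    n = config.n_genes
    iu, ju = np.triu_indices(n, k=1)
    draw = rng.random(len(iu))
    keep = draw < config.edge_prob
    for i, j in zip(iu[keep], ju[keep]):
        edges.add((genes[i], genes[j]))
    for name, members in planted.items():
        mod = config.planted[int(name.removeprefix("planted")) - 1]
        m = len(members)
        mi, mj = np.triu_indices(m, k=1)
        keep = rng.random(len(mi)) < mod.p_in
        for i, j in zip(mi[keep], mj[keep]):
            a, b = members[i], members[j]
            edges.add((a, b) if a < b else (b, a))
    order = rng.permutation(n)
    for t in range(n - 1):
        a, b = genes[order[t]], genes[order[t + 1]]
        edges.add((a, b) if a < b else (b, a))
    return sorted(edges), planted


def generate_gene_scores(
    genes: list[str],
    planted: dict[str, list[str]],
    config: SimulationConfig,
    side: str = "L",
) -> pd.DataFrame:
    """Gene-level p-values: Uniform(0, 1] background, Beta(alpha, 1) planted."""
    rng = np.random.default_rng(derive_seed(config.seed, f"scores:{side}"))
    alpha_by_gene: dict[str, float] = {}
    for name, members in planted.items():
        mod = config.planted[int(name.removeprefix("planted")) - 1]
        for g in members:
            alpha_by_gene[g] = mod.gene_score_alpha
    p = np.empty(len(genes))
    for i, g in enumerate(genes):
        a = alpha_by_gene.get(g)
        if a is None or a == 1.0:
            p[i] = 1.0 - rng.random()  # in (0, 1]
        else:
            p[i] = max(rng.beta(a, 1.0), 1e-300)
    return pd.DataFrame({"gene_id": genes, "p_value": p})


def generate_annotation(genes: list[str], gene_length: int = 20_000, spacing: int = 200_000) -> pd.DataFrame:
    """Deterministic gene placement on one chromosome, 1-based inclusive.

    Genes are spaced so that the default +/-20 kb mapping windows of
    adjacent genes do not overlap.
    """
    starts = 1 + spacing * np.arange(len(genes))
    # first gene starts beyond the window so boundary SNPs stay at pos >= 1
    starts = starts + 100_000
    return pd.DataFrame({
        "gene_id": genes,
        "chrom": "1",
        "start": starts,
        "end": starts + gene_length - 1,
    })


@dataclass
class GenotypeSimulation:
    """Genotypes plus everything needed to verify recovery downstream."""

    genotypes: GenotypeMatrix
    sumstats: dict[str, pd.DataFrame]  # meta-GWAS label -> table
    annotation: pd.DataFrame
    case_status: np.ndarray  # the binary group used for effect-size calibration
    true_mprs: dict[str, np.ndarray]  # planted module -> per-individual score (meta1 weights)
    snps_by_module: dict[str, list[str]]


def _calibrate_maf_shift(beta: np.ndarray, maf: np.ndarray, target_d: float) -> np.ndarray:
    """Case-group MAFs achieving the target Cohen's d of sum(beta * dosage).

    Shifts each MAF by c * sign(beta); c solves
    d = 2 c sum|beta| / sd_pooled analytically, iterating because the
    shift itself perturbs the binomial variances.
    """
    if target_d == 0:
        return maf.copy()
    q = maf.copy()
    c = 0.0
    for _ in range(8):
        var_ctrl = np.sum(beta**2 * 2 * maf * (1 - maf))
        var_case = np.sum(beta**2 * 2 * q * (1 - q))
        sd = np.sqrt(0.5 * (var_ctrl + var_case))
        c = target_d * sd / (2 * np.sum(np.abs(beta)))
        q = np.clip(maf + c * np.sign(beta), 0.01, 0.99)
    return q


def generate_genotypes_and_sumstats(
    config: SimulationConfig,
    planted: dict[str, list[str]],
    genes: list[str] | None = None,
    annotation: pd.DataFrame | None = None,
) -> GenotypeSimulation:
    """Dosages, two meta-GWAS weight tables, and the annotation they index.

    Each gene gets ``n_snps_per_gene`` SNPs, the first placed exactly at
    the lower mapping-window boundary (start - 20 kb) so boundary
    inclusion is exercised.  Dosages are Binomial(2, MAF) with
    independent SNPs; for planted-module SNPs the case-group MAF is
    shifted so the module's true score separates cases from controls by
    ``target_cohens_d``.  The second meta-GWAS is a noisy replicate of
    the first (same SNPs, perturbed effect sizes).
    """
    rng = np.random.default_rng(derive_seed(config.seed, "genotypes"))
    genes = genes if genes is not None else _gene_names(config.n_genes)
    annotation = annotation if annotation is not None else generate_annotation(genes)
    ann = annotation.set_index("gene_id")

    planted_genes = {g for members in planted.values() for g in members}
    snp_ids, snp_gene, positions = [], [], []
    for g in genes:
        start, end = int(ann.at[g, "start"]), int(ann.at[g, "end"])
        pos = [start - 20_000] + sorted(
            rng.integers(start, end + 1, size=config.n_snps_per_gene - 1).tolist()
        )
        for k, p in enumerate(pos):
            snp_ids.append(f"rs_{g}_{k}")
            snp_gene.append(g)
            positions.append(p)
    n_snps = len(snp_ids)
    snp_gene = np.array(snp_gene, dtype=object)

    maf = rng.uniform(*config.maf_range, size=n_snps)
    is_planted = np.isin(snp_gene, list(planted_genes))
    beta = np.where(is_planted, rng.normal(0.0, 0.15, n_snps), rng.normal(0.0, 0.05, n_snps))

    h = (rng.random(config.n_individuals) < 0.5).astype(int)
    maf_case = maf.copy()
    snps_by_module: dict[str, list[str]] = {}
    for name, members in planted.items():
        cols = np.isin(snp_gene, members)
        snps_by_module[name] = [s for s, c in zip(snp_ids, cols) if c]
        maf_case[cols] = _calibrate_maf_shift(beta[cols], maf[cols], config.target_cohens_d)

    p_mat = np.where(h[:, None] == 1, maf_case[None, :], maf[None, :])
    dosages = rng.binomial(2, p_mat).astype(float)

    pair_idx = rng.integers(0, len(_NON_PALINDROMIC_PAIRS), size=n_snps)
    swap = rng.random(n_snps) < 0.5
    eff = np.array([_NON_PALINDROMIC_PAIRS[i][0] for i in pair_idx], dtype=object)
    oth = np.array([_NON_PALINDROMIC_PAIRS[i][1] for i in pair_idx], dtype=object)
    eff, oth = np.where(swap, oth, eff), np.where(swap, eff, oth)

    se = 0.03
    pvals = np.clip(2 * stats.norm.sf(np.abs(beta) / se), 1e-300, 1.0)
    sumstats1 = pd.DataFrame({
        "snp_id": snp_ids, "chrom": [str(ann.at[g, "chrom"]) for g in snp_gene],
        "pos": positions, "effect_allele": eff, "other_allele": oth,
        "beta": beta, "p_value": pvals,
    })
    beta2 = beta * (1.0 + 0.1 * rng.standard_normal(n_snps)) + 0.01 * rng.standard_normal(n_snps)
    sumstats2 = sumstats1.assign(
        beta=beta2, p_value=np.clip(2 * stats.norm.sf(np.abs(beta2) / se), 1e-300, 1.0)
    )

    genotypes = GenotypeMatrix(
        individual_ids=[f"I{i:05d}" for i in range(config.n_individuals)],
        snp_ids=snp_ids,
        dosages=dosages,
        counted_allele=eff.copy(),
        other_allele=oth.copy(),
    )
    true_mprs = {
        name: dosages[:, np.isin(np.array(snp_ids, dtype=object), snps)] @ beta[np.isin(np.array(snp_ids, dtype=object), snps)]
        for name, snps in ((n, np.array(s, dtype=object)) for n, s in snps_by_module.items())
    }
    return GenotypeSimulation(
        genotypes=genotypes,
        sumstats={"meta1": sumstats1, "meta2": sumstats2},
        annotation=annotation,
        case_status=h,
        true_mprs=true_mprs,
        snps_by_module=snps_by_module,
    )


# ---------------------------------------------------------------------------
# phenotypes
# ---------------------------------------------------------------------------


def _sigmoid(v: np.ndarray) -> np.ndarray:
    return 1.0 / (1.0 + np.exp(-v))


def generate_phenotypes(
    mprs_true: np.ndarray,
    config: SimulationConfig,
    individual_ids: list[str] | None = None,
) -> tuple[pd.DataFrame, dict]:
    """Phenotypes from an explicit mediation + survival model.

    With x the standardized true module score: mediator m = a*x + eps,
    eps ~ N(0,1); outcome y ~ Bernoulli(sigmoid(c0 + c*x + b*m + gamma'z));
    diagnosis is CN/SMC (80/20) for y = 0 and EMCI/LMCI/AD by ascending
    terciles of the latent score for y = 1.  MCI (EMCI/LMCI) individuals
    get exponential conversion times with log-hazard theta*x, censored
    administratively at the empirical quantile matching the configured
    censoring rate.  The amygdala grey-matter densities are affine images
    of the latent mediator (mediation effects are invariant to the affine
    map).  Returns the phenotype table and a ground-truth dict including
    Monte-Carlo true ACME/ADE.
    """
    rng = np.random.default_rng(derive_seed(config.seed, "phenotypes"))
    n = len(mprs_true)
    ids = individual_ids if individual_ids is not None else [f"I{i:05d}" for i in range(n)]
    x = np.asarray(mprs_true, dtype=float)
    x_std = (x - x.mean()) / x.std(ddof=1)

    age = rng.normal(73.5, 7.0, n)
    sex = np.where(rng.random(n) < 0.55, "M", "F")
    education = np.clip(rng.normal(16.0, 2.8, n), 6, 22)
    z = np.column_stack([(age - 73.5) / 7.0, (sex == "M").astype(float), (education - 16.0) / 2.8])

    med = config.mediation
    eps = rng.standard_normal(n)
    m_lat = med.a * x_std + eps
    gamma = np.array([med.gamma_age, med.gamma_sex, med.gamma_edu])
    latent = med.intercept + med.c * x_std + med.b * m_lat + z @ gamma
    y = (rng.random(n) < _sigmoid(latent)).astype(int)

    diagnosis = np.empty(n, dtype=object)
    idx0 = np.flatnonzero(y == 0)
    diagnosis[idx0] = np.where(rng.random(len(idx0)) < 0.8, "CN", "SMC")
    idx1 = np.flatnonzero(y == 1)
    if len(idx1):
        terc = np.quantile(latent[idx1], [1 / 3, 2 / 3])
        lab = np.full(len(idx1), "LMCI", dtype=object)
        lab[latent[idx1] <= terc[0]] = "EMCI"
        lab[latent[idx1] > terc[1]] = "AD"
        diagnosis[idx1] = lab

    amyg_left = 0.61 - 0.045 * m_lat
    amyg_right = 0.58 - 0.040 * (0.6 * m_lat + 0.8 * rng.standard_normal(n))

    surv = config.survival
    conv_months = np.full(n, np.nan)
    conv_event = np.full(n, np.nan)
    mci = np.isin(diagnosis, ["EMCI", "LMCI"])
    if mci.any():
        rate = surv.baseline_hazard * np.exp(surv.log_hr_per_sd * x_std[mci])
        t_event = rng.exponential(1.0 / rate)
        if surv.censoring_rate > 0:
            c_admin = np.quantile(t_event, 1.0 - surv.censoring_rate)
        else:
            c_admin = t_event.max()
        observed = np.minimum(t_event, c_admin)
        conv_months[mci] = np.maximum(1, np.ceil(observed))
        conv_event[mci] = (t_event <= c_admin).astype(float)

    pheno = pd.DataFrame({
        "individual_id": ids,
        "diagnosis": diagnosis,
        "age": age,
        "sex": sex,
        "education": education,
        "amyg_left": amyg_left,
        "amyg_right": amyg_right,
        "conv_months": conv_months,
        "conv_event": conv_event,
    })
    truth = {
        "mediation_paths": asdict(med),
        "true_hr_per_sd": float(np.exp(surv.log_hr_per_sd)),
        "censoring_rate": surv.censoring_rate,
        **true_mediation_effects(med, seed=derive_seed(config.seed, "oracle")),
    }
    return pheno, truth


def true_mediation_effects(
    paths: MediationPaths, n_draws: int = 1_000_000, seed: int = 0
) -> dict[str, float]:
    """Monte-Carlo true ACME/ADE/proportion implied by the generative model.

    Integrates the counterfactual contrasts at treatment levels x = -/+1
    (mean +/- 1 SD of the standardized exposure) over the generative
    distributions of the mediator noise and covariates.
    """
    rng = np.random.default_rng(seed)
    eps = rng.standard_normal(n_draws)
    z = np.column_stack([
        rng.standard_normal(n_draws),
        (rng.random(n_draws) < 0.55).astype(float),
        rng.standard_normal(n_draws),
    ])
    gamma = np.array([paths.gamma_age, paths.gamma_sex, paths.gamma_edu])
    zg = z @ gamma

    def y_prob(t, m):
        return _sigmoid(paths.intercept + paths.c * t + paths.b * m + zg)

    m_lo, m_hi = paths.a * (-1.0) + eps, paths.a * (+1.0) + eps
    acme = 0.5 * (
        np.mean(y_prob(-1.0, m_hi) - y_prob(-1.0, m_lo))
        + np.mean(y_prob(1.0, m_hi) - y_prob(1.0, m_lo))
    )
    ade = 0.5 * (
        np.mean(y_prob(1.0, m_lo) - y_prob(-1.0, m_lo))
        + np.mean(y_prob(1.0, m_hi) - y_prob(-1.0, m_hi))
    )
    total = acme + ade
    return {
        "true_acme": float(acme),
        "true_ade": float(ade),
        "true_total_effect": float(total),
        "true_prop_mediated": float(acme / total) if total else float("nan"),
    }


# ---------------------------------------------------------------------------
# expression
# ---------------------------------------------------------------------------


def generate_expression(
    genes: list[str],
    planted: dict[str, list[str]],
    config: SimulationConfig,
) -> dict[str, ExpressionMatrix]:
    """Per-tissue expression with a planted module factor in the target tissue.

    In the target tissue, genes of each planted module load sqrt(rho) on a
    shared latent factor (pairwise correlation rho); in other tissues the
    loading is ``rho_other`` (default zero).  Background genes are
    independent standard normal everywhere.
    """
    ex = config.expression
    rng = np.random.default_rng(derive_seed(config.seed, "expression"))
    out: dict[str, ExpressionMatrix] = {}
    for tissue in (ex.target_tissue, *ex.other_tissues):
        rho = ex.rho_target if tissue == ex.target_tissue else ex.rho_other
        X = rng.standard_normal((len(genes), ex.n_samples))
        if rho > 0:
            gi = {g: i for i, g in enumerate(genes)}
            for members in planted.values():
                factor = rng.standard_normal(ex.n_samples)
                rows = [gi[g] for g in members if g in gi]
                X[rows] = np.sqrt(rho) * factor[None, :] + np.sqrt(1 - rho) * X[rows]
        out[tissue] = ExpressionMatrix(
            tissue_label=tissue,
            values=pd.DataFrame(X, index=genes, columns=[f"S{j:03d}" for j in range(ex.n_samples)]),
        )
    return out


def generate_gene_sets(
    genes: list[str], planted: dict[str, list[str]], config: SimulationConfig
) -> dict[str, tuple[str, list[str]]]:
    """Small GMT-style collection: planted sets (with decoys) plus random sets."""
    rng = np.random.default_rng(derive_seed(config.seed, "genesets"))
    sets: dict[str, tuple[str, list[str]]] = {}
    for name, members in planted.items():
        extra = [g for g in genes if g not in members]
        decoys = list(rng.choice(extra, size=min(3, len(extra)), replace=False))
        sets[f"SET_{name.upper()}"] = (f"planted module {name} plus decoys", sorted(members) + sorted(decoys))
    for k in range(3):
        pick = sorted(rng.choice(genes, size=12, replace=False))
        sets[f"SET_RANDOM{k+1}"] = ("random gene set", pick)
    return sets


# ---------------------------------------------------------------------------
# one-call dataset writer
# ---------------------------------------------------------------------------


def simulate_to_dir(config: SimulationConfig, outdir: str | Path) -> dict:
    """Generate every pipeline input under ``outdir`` plus ground_truth.json.

    Returns the ground-truth dictionary.  Outputs: edges.tsv,
    scores_L.tsv / scores_R.tsv, annotation.tsv, genotypes.tsv (+ allele
    sidecar), sumstats_meta1.tsv / sumstats_meta2.tsv, phenotypes.tsv,
    expression_<tissue>.tsv, genesets.gmt.
    """
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    edges, planted = generate_network(config)
    genes = _gene_names(config.n_genes)

    pd.DataFrame(edges, columns=["gene_a", "gene_b"]).to_csv(
        outdir / "edges.tsv", sep="\t", index=False, header=False
    )
    for side in ("L", "R"):
        generate_gene_scores(genes, planted, config, side=side).to_csv(
            outdir / f"scores_{side}.tsv", sep="\t", index=False
        )
    sim = generate_genotypes_and_sumstats(config, planted, genes=genes)
    sim.annotation.to_csv(outdir / "annotation.tsv", sep="\t", index=False)
    for label, ss in sim.sumstats.items():
        ss.to_csv(outdir / f"sumstats_{label}.tsv", sep="\t", index=False)
    geno = sim.genotypes
    dosage_df = pd.DataFrame(geno.dosages, columns=geno.snp_ids)
    dosage_df.insert(0, "individual_id", geno.individual_ids)
    dosage_df.to_csv(outdir / "genotypes.tsv", sep="\t", index=False)
    pd.DataFrame({
        "snp_id": geno.snp_ids,
        "counted_allele": geno.counted_allele,
        "other_allele": geno.other_allele,
    }).to_csv(outdir / "genotypes.tsv.alleles.tsv", sep="\t", index=False)

    x = sim.true_mprs["planted1"]
    pheno, truth_med = generate_phenotypes(x, config, individual_ids=geno.individual_ids)
    pheno.to_csv(outdir / "phenotypes.tsv", sep="\t", index=False, na_rep="NA")

    for tissue, expr in generate_expression(genes, planted, config).items():
        expr.values.to_csv(outdir / f"expression_{tissue}.tsv", sep="\t", index_label="gene_id")

    gene_sets = generate_gene_sets(genes, planted, config)
    with open(outdir / "genesets.gmt", "w") as fh:
        for set_id, (desc, members) in gene_sets.items():
            fh.write("\t".join([set_id, desc] + list(members)) + "\n")

    truth = {
        "config": config.to_dict(),
        "planted_modules": planted,
        "snps_by_module": sim.snps_by_module,
        "case_status": sim.case_status.tolist(),
        "target_cohens_d": config.target_cohens_d,
        **truth_med,
    }
    with open(outdir / "ground_truth.json", "w") as fh:
        json.dump(truth, fh, indent=2, sort_keys=True)
    return truth
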