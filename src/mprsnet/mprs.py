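"""Module-level polygenic risk scores (MPRS).

The MPRS of a module M for one individual is the weighted sum of dosages
over every SNP lying within the mapping window of any module gene,

    MPRS(M) = sum_{j in genes(M)} sum_{k in SNPs(g_j)} beta_jk * g_jk,

with weights beta taken from a disease meta-GWAS.  A SNP near two genes
of the same module is counted once by default (the literal per-gene
double-count is available behind a flag).  Dosages are harmonized to the
meta-GWAS effect allele before scoring: matching coding is used as-is,
swapped coding is flipped (g -> 2-g), strand-ambiguous (A/T, C/G) SNPs
are dropped, and any other allele pairing is dropped.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
import pandas as pd

from .gene_scoring import SnpGeneMap
from .io_formats import GenotypeMatrix

logger = logging.getLogger("mprsnet.mprs")

__all__ = ["HarmonizedDosages", "MprsProfile", "harmonize", "compute_mprs", "mprs_table"]

_PALINDROMIC = {frozenset(("A", "T")), frozenset(("C", "G"))}


@dataclass
class HarmonizedDosages:
    """Effect-allele-aligned dosage accessor for the SNPs shared with a sumstats table."""

    individual_ids: list[str]
    snp_ids: list[str]  # harmonized SNPs, in genotype-file order
    dosages: np.ndarray  # aligned to effect allele; NaN = missing
    beta: np.ndarray  # per harmonized SNP
    drop_reasons: dict[str, int]  # reason -> count

    def snp_index(self) -> dict[str, int]:
        return {s: k for k, s in enumerate(self.snp_ids)}


def harmonize(
    genotypes: GenotypeMatrix,
    sumstats: pd.DataFrame,
    drop_palindromic: bool = True,
) -> HarmonizedDosages:
    """Align genotype dosages to the meta-GWAS effect allele.

    Per SNP (matched by snp_id): counted == effect -> keep dosage;
    counted == other and other == effect (swapped) -> 2 - dosage;
    palindromic pairs dropped when ``drop_palindromic``; anything else
    (allele mismatch, SNP absent from sumstats) dropped.  Drops are
    tallied, never fatal.
    """
    ss = sumstats.set_index("snp_id")
    keep_idx: list[int] = []
    keep_ids: list[str] = []
    flip: list[bool] = []
    betas: list[float] = []
    reasons = {"absent_from_sumstats": 0, "palindromic": 0, "allele_mismatch": 0}
    for k, snp in enumerate(genotypes.snp_ids):
        if snp not in ss.index:
            reasons["absent_from_sumstats"] += 1
            continue
        ga, gb = genotypes.counted_allele[k].upper(), genotypes.other_allele[k].upper()
        ea, oa = ss.at[snp, "effect_allele"], ss.at[snp, "other_allele"]
        if drop_palindromic and frozenset((ga, gb)) in _PALINDROMIC:
            reasons["palindromic"] += 1
            continue
        if (ga, gb) == (ea, oa):
            do_flip = False
        elif (ga, gb) == (oa, ea):
            do_flip = True
        else:
            reasons["allele_mismatch"] += 1
            continue
        keep_idx.append(k)
        keep_ids.append(snp)
        flip.append(do_flip)
        betas.append(float(ss.at[snp, "beta"]))
    dos = genotypes.dosages[:, keep_idx].astype(float).copy()
    flip_arr = np.array(flip, dtype=bool)
    if flip_arr.any():
        dos[:, flip_arr] = 2.0 - dos[:, flip_arr]
    dropped = {r: c for r, c in reasons.items() if c}
    if dropped:
        logger.info("harmonize: dropped SNPs by reason: %s", dropped)
    return HarmonizedDosages(
        individual_ids=list(genotypes.individual_ids),
        snp_ids=keep_ids,
        dosages=dos,
        beta=np.array(betas, dtype=float),
        drop_reasons=reasons,
    )


@dataclass
class MprsProfile:
    """Per-individual scores of one module under one meta-GWAS weighting."""

    module_id: str
    weight_source: str
    individual_ids: list[str]
    scores: np.ndarray  # raw scores
    scores_z: np.ndarray  # z-standardized across the analysis sample
    n_snps_used: int
    n_snps_dropped: dict[str, int]

    def as_series(self, standardized: bool = False) -> pd.Series:
        vals = self.scores_z if standardized else self.scores
        return pd.Series(vals, index=self.individual_ids, name=self.module_id)


def compute_mprs(
    harmonized: HarmonizedDosages,
    module_genes,
    snp_gene_map: SnpGeneMap,
    module_id: str = "",
    weight_source: str = "",
    missing_policy: str = "mean_impute",
    dedup_snps: bool = True,
) -> MprsProfile:
    """Score every individual on one module.

    The module's SNP set is the union over its genes of window-mapped SNPs
    restricted to the harmonized panel.  ``dedup_snps=False`` restores the
    literal per-gene double-counting of shared SNPs.  Missing dosages are
    handled per ``missing_policy``: "mean_impute" (per-SNP mean over
    non-missing individuals), "zero", or "drop_individual" (score becomes
    NaN for individuals with any missing dosage).
    """
    idx = harmonized.snp_index()
    genes_mapped = [g for g in module_genes if g in snp_gene_map.gene_to_snps]
    if len(genes_mapped) < len(list(module_genes)):
        logger.info(
            "compute_mprs[%s]: %d module gene(s) without mapped SNPs",
            module_id, len(list(module_genes)) - len(genes_mapped),
        )
    if dedup_snps:
        snps = [s for s in snp_gene_map.snps_for_genes(genes_mapped) if s in idx]
        multiplicity = np.ones(len(snps))
    else:
        counts: dict[str, int] = {}
        for g in genes_mapped:
            for s in snp_gene_map.gene_to_snps[g]:
                if s in idx:
                    counts[s] = counts.get(s, 0) + 1
        snps = sorted(counts)
        multiplicity = np.array([counts[s] for s in snps], dtype=float)
    n_dropped_unmapped = harmonized.drop_reasons
    if not snps:
        raise ValueError(f"module {module_id!r}: zero usable SNPs after mapping and harmonization")

    cols = [idx[s] for s in snps]
    dos = harmonized.dosages[:, cols]
    beta = harmonized.beta[cols] * multiplicity

    if missing_policy == "mean_impute":
        col_mean = np.nanmean(dos, axis=0)
        col_mean = np.where(np.isnan(col_mean), 0.0, col_mean)
        dos = np.where(np.isnan(dos), col_mean[None, :], dos)
        scores = dos @ beta
    elif missing_policy == "zero":
        scores = np.where(np.isnan(dos), 0.0, dos) @ beta
    elif missing_policy == "drop_individual":
        scores = dos @ beta  # NaN propagates
    else:
        raise ValueError(f"unknown missing_policy {missing_policy!r}")

    if np.sum(~np.isnan(scores)) > 1:
        sd = float(np.nanstd(scores, ddof=1))
        mu = float(np.nanmean(scores))
    else:
        sd, mu = 0.0, 0.0
    scores_z = (scores - mu) / sd if sd > 0 else np.zeros_like(scores)
    return MprsProfile(
        module_id=module_id,
        weight_source=weight_source,
        individual_ids=list(harmonized.individual_ids),
        scores=scores,
        scores_z=scores_z,
        n_snps_used=len(snps),
        n_snps_dropped=dict(n_dropped_unmapped),
    )


def mprs_table(profiles: list[MprsProfile]) -> pd.DataFrame:
    """Long-format table: individual_id, module_id, weight_source, score, score_z."""
    frames = []
    for p in profiles:
        frames.append(pd.DataFrame({
            "individual_id": p.individual_ids,
            "module_id": p.module_id,
            "weight_source": p.weight_source,
            "score": p.scores,
            "score_z": p.scores_z,
        }))
    if not frames:
        return pd.DataFrame(columns=["individual_id", "module_id", "weight_source", "score", "score_z"])
    return pd.concat(frames, ignore_index=True)
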