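"""SNP-to-gene window mapping and gene-level p-value aggregation.

SNPs are assigned to every gene whose body, extended by a symmetric
window (default +/-20 kb, boundaries inclusive), contains the SNP
position.  For pipelines without an external gene-based association tool,
``aggregate_gene_p`` offers a simple Bonferroni-adjusted minimum-p
combination; precomputed gene-level scores can always be supplied
directly instead.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
import pandas as pd

logger = logging.getLogger("mprsnet.gene_scoring")

__all__ = ["SnpGeneMap", "map_snps_to_genes", "aggregate_gene_p"]

DEFAULT_WINDOW_BP = 20_000


@dataclass
class SnpGeneMap:
    """Bidirectional SNP <-> gene assignment within a window."""

    gene_to_snps: dict[str, list[str]]
    snp_to_genes: dict[str, list[str]]
    window_bp: int = DEFAULT_WINDOW_BP

    def snps_for_genes(self, genes) -> list[str]:
        """Deduplicated, sorted union of SNPs mapped to any of ``genes``."""
        out: set[str] = set()
        for g in genes:
            out.update(self.gene_to_snps.get(g, ()))
        return sorted(out)


def map_snps_to_genes(
    variants: pd.DataFrame,
    annotation: pd.DataFrame,
    window_bp: int = DEFAULT_WINDOW_BP,
) -> SnpGeneMap:
    """Map each SNP to all genes within ``window_bp`` of the gene body.

    ``variants`` needs columns snp_id, chrom, pos (1-based); ``annotation``
    needs gene_id, chrom, start, end.  A SNP maps to a gene iff the
    chromosomes match and start - window <= pos <= end + window, both ends
    inclusive.  SNPs on chromosomes absent from the annotation are left
    unmapped with a warning.
    """
    gene_to_snps: dict[str, list[str]] = {}
    snp_to_genes: dict[str, list[str]] = {s: [] for s in variants["snp_id"]}
    ann_by_chrom = {c: g for c, g in annotation.groupby("chrom")}

    missing_chroms = set(variants["chrom"].unique()) - set(ann_by_chrom)
    if missing_chroms:
        n_unmapped = int(variants["chrom"].isin(missing_chroms).sum())
        logger.warning(
            "map_snps_to_genes: %d SNP(s) on chromosome(s) %s absent from annotation",
            n_unmapped, sorted(missing_chroms),
        )

    for chrom, var in variants.groupby("chrom"):
        ann = ann_by_chrom.get(chrom)
        if ann is None:
            continue
        pos = var["pos"].to_numpy(np.int64)
        snp_ids = var["snp_id"].to_numpy(object)
        lo = ann["start"].to_numpy(np.int64) - window_bp
        hi = ann["end"].to_numpy(np.int64) + window_bp
        gene_ids = ann["gene_id"].to_numpy(object)
        inside = (pos[:, None] >= lo[None, :]) & (pos[:, None] <= hi[None, :])
        snp_idx, gene_idx = np.nonzero(inside)
        for si, gi in zip(snp_idx, gene_idx):
            snp_to_genes[str(snp_ids[si])].append(str(gene_ids[gi]))
            gene_to_snps.setdefault(str(gene_ids[gi]), []).append(str(snp_ids[si]))
    for g in gene_to_snps:
        gene_to_snps[g].sort()
    for s in snp_to_genes:
        snp_to_genes[s].sort()
    return SnpGeneMap(gene_to_snps=gene_to_snps, snp_to_genes=snp_to_genes, window_bp=window_bp)


def aggregate_gene_p(
    sumstats: pd.DataFrame,
    snp_gene_map: SnpGeneMap,
    method: str = "min_p_bonferroni",
) -> pd.DataFrame:
    """Aggregate SNP p-values to gene level.

    ``min_p_bonferroni``: gene p = min(1, k * min_j p_j) over the gene's k
    mapped SNPs.  Genes with no mapped SNP are omitted.  Returns a gene
    score table with the aggregation method recorded in ``df.attrs``.
    """
    if method != "min_p_bonferroni":
        raise ValueError(f"unknown aggregation method {method!r}")
    p_by_snp = dict(zip(sumstats["snp_id"], sumstats["p_value"]))
    rows = []
    for gene, snps in sorted(snp_gene_map.gene_to_snps.items()):
        ps = [p_by_snp[s] for s in snps if s in p_by_snp]
        if not ps:
            continue
        rows.append({"gene_id": gene, "p_value": min(1.0, len(ps) * min(ps))})
    out = pd.DataFrame(rows, columns=["gene_id", "p_value"])
    out.attrs["aggregation_method"] = method
    return out
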