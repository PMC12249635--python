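"""Module co-expression, tissue specificity and gene-set enrichment.

Modularity of a gene module is its mean pairwise Pearson correlation in a
tissue expression matrix, tested against size-matched random gene sets
drawn from the background network.  Tissue specificity compares
per-module correlations between a target tissue and other tissues with a
paired t-test.  Functional annotation is a one-sided hypergeometric test
against user-supplied GMT gene sets with Benjamini-Hochberg correction.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats
from statsmodels.stats.multitest import multipletests

from .io_formats import ExpressionMatrix

logger = logging.getLogger("mprsnet.annotation")

__all__ = [
    "ModularityResult",
    "EnrichmentRow",
    "module_coexpression",
    "modularity_permutation",
    "tissue_specificity",
    "hypergeometric_enrichment",
]


def module_coexpression(expr: ExpressionMatrix, genes) -> float:
    """Mean pairwise Pearson correlation of the module genes in one tissue.

    Genes absent from the matrix are dropped (logged); pairs involving a
    zero-variance gene are skipped.  Requires >= 2 present genes and >= 3
    samples.
    """
    genes = list(genes)
    present = [g for g in genes if g in expr.values.index]
    if len(present) < len(genes):
        logger.info(
            "module_coexpression[%s]: %d gene(s) absent from expression",
            expr.tissue_label, len(genes) - len(present),
        )
    if len(present) < 2:
        raise ValueError("need >= 2 module genes present in the expression matrix")
    if expr.n_samples < 3:
        raise ValueError("need >= 3 samples for correlation")
    X = expr.values.loc[present].to_numpy(float)
    sd = X.std(axis=1)
    nonconst = sd > 0
    if not np.all(nonconst):
        logger.info(
            "module_coexpression[%s]: %d zero-variance gene(s) skipped pairwise",
            expr.tissue_label, int((~nonconst).sum()),
        )
    X = X[nonconst]
    if X.shape[0] < 2:
        raise ValueError("fewer than 2 genes with non-zero variance")
    R = np.corrcoef(X)
    iu = np.triu_indices(R.shape[0], k=1)
    return float(R[iu].mean())


@dataclass
class ModularityResult:
    module_id: str
    tissue_label: str
    observed_pcc: float
    null_mean: float
    null_sd: float
    perm_p: float
    n_perm: int


def modularity_permutation(
    expr: ExpressionMatrix,
    module_genes,
    background_genes,
    n_perm: int = 1000,
    seed: int = 0,
    module_id: str = "",
) -> ModularityResult:
    """Permutation test of module co-expression against random same-size sets.

    Null sets are drawn without replacement from ``background_genes``
    restricted to the expression matrix;
    perm_p = (1 + #{null PCC >= observed}) / (1 + n_perm).
    """
    rng = np.random.default_rng(seed)
    module_genes = [g for g in module_genes if g in expr.values.index]
    bg = sorted(g for g in set(background_genes) if g in expr.values.index)
    size = len(module_genes)
    if size < 2:
        raise ValueError("need >= 2 module genes present in expression")
    if len(bg) < size:
        raise ValueError("background smaller than module size")
    observed = module_coexpression(expr, module_genes)
    bg_arr = np.array(bg, dtype=object)
    null = np.empty(n_perm)
    for b in range(n_perm):
        pick = rng.choice(len(bg_arr), size=size, replace=False)
        null[b] = module_coexpression(expr, bg_arr[pick])
    perm_p = (1 + int(np.sum(null >= observed))) / (1 + n_perm)
    return ModularityResult(
        module_id=module_id, tissue_label=expr.tissue_label,
        observed_pcc=observed, null_mean=float(null.mean()),
        null_sd=float(null.std(ddof=0)), perm_p=perm_p, n_perm=n_perm,
    )


def tissue_specificity(pcc_target, pcc_other) -> tuple[float, float]:
    """Paired t-test of per-module co-expression, target vs other tissue.

    Inputs are per-module PCC vectors over the same module list; returns
    (t, two-sided p).  Positive t means higher co-expression in the target
    tissue.
    """
    a = np.asarray(pcc_target, dtype=float)
    b = np.asarray(pcc_other, dtype=float)
    if a.shape != b.shape or len(a) < 2:
        raise ValueError("need matched PCC vectors over >= 2 modules")
    if np.allclose(a, b):
        return 0.0, 1.0
    res = stats.ttest_rel(a, b)
    return float(res.statistic), float(res.pvalue)


@dataclass
class EnrichmentRow:
    set_id: str
    description: str
    overlap: int
    set_size: int
    module_size: int
    background_size: int
    p: float
    fdr: float
    overlap_genes: list[str]


def hypergeometric_enrichment(
    module_genes,
    gmt: dict[str, tuple[str, list[str]]],
    background_genes,
    fdr_method: str = "BH",
) -> list[EnrichmentRow]:
    """One-sided hypergeometric over-representation test per gene set.

    Gene sets and the module are intersected with the background before
    testing; p = P(X >= overlap) under sampling module_size genes from the
    background.  FDR is Benjamini-Hochberg across all sets in the
    collection.  Rows are sorted by p ascending.
    """
    if fdr_method != "BH":
        raise ValueError(f"unsupported fdr_method {fdr_method!r}")
    bg = set(background_genes)
    mod = set(module_genes) & bg
    N, n = len(bg), len(mod)
    if N == 0 or n == 0:
        raise ValueError("empty background or module after intersection")
    rows = []
    for set_id, (desc, genes) in gmt.items():
        s = set(genes) & bg
        K = len(s)
        k = len(s & mod)
        # P(X >= k), X ~ Hypergeom(N, K, n)
        p = float(stats.hypergeom.sf(k - 1, N, K, n)) if K else 1.0
        rows.append(EnrichmentRow(
            set_id=set_id, description=desc, overlap=k, set_size=K,
            module_size=n, background_size=N, p=min(p, 1.0), fdr=np.nan,
            overlap_genes=sorted(s & mod),
        ))
    if rows:
        _, fdr, _, _ = multipletests([r.p for r in rows], method="fdr_bh")
        for r, q in zip(rows, fdr):
            r.fdr = float(q)
    rows.sort(key=lambda r: (r.p, r.set_id))
    return rows


def enrichment_table(rows: list[EnrichmentRow]) -> pd.DataFrame:
    return pd.DataFrame([
        {
            "set_id": r.set_id, "description": r.description, "overlap": r.overlap,
            "set_size": r.set_size, "module_size": r.module_size,
            "background_size": r.background_size, "p": r.p, "fdr": r.fdr,
            "overlap_genes": ",".join(r.overlap_genes),
        }
        for r in rows
    ])
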