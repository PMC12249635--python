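"""Disease-relevant module (ADM) selection.

Each candidate module's polygenic score distribution is compared between
case (AD) and control (CN) individuals with an independent two-sample
t-test, separately under each meta-GWAS weighting.  Significance is
Bonferroni-corrected over the total number of candidate modules pooled
across trait sides (e.g. 0.05/(196+195) = 1.28e-4 for a study with 196
and 195 candidate modules per side); a module is an ADM when it clears the corrected
threshold under at least one weighting (union rule).  Cohen's d with a
normal-approximation 95% CI quantifies the effect size.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats

__all__ = ["AdmResult", "two_sample_t", "cohens_d_ci", "identify_adms"]


def two_sample_t(x, y, variant: str = "welch") -> tuple[float, float, float]:
    """Independent two-sample t-test; returns (t, df, two-sided p).

    ``welch`` (default) uses the Welch-Satterthwaite df; ``student``
    assumes equal variances.  With zero variance in both groups, equal
    means give p = 1 and unequal means give p -> 0.
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if len(x) < 2 or len(y) < 2:
        raise ValueError("each group needs n >= 2")
    if not (np.all(np.isfinite(x)) and np.all(np.isfinite(y))):
        raise ValueError("non-finite values in input")
    if x.var(ddof=1) == 0 and y.var(ddof=1) == 0:
        if x.mean() == y.mean():
            return 0.0, float(len(x) + len(y) - 2), 1.0
        return float(np.inf if x.mean() > y.mean() else -np.inf), float(len(x) + len(y) - 2), 0.0
    res = stats.ttest_ind(x, y, equal_var=(variant == "student"))
    if variant == "welch":
        df = res.df
    else:
        df = len(x) + len(y) - 2
    return float(res.statistic), float(df), float(res.pvalue)


def cohens_d_ci(x, y, level: float = 0.95) -> tuple[float, float, float]:
    """Cohen's d (pooled SD) with a normal-approximation confidence interval.

    d = (mean(x) - mean(y)) / s_pooled;
    SE = sqrt((n1+n2)/(n1*n2) + d^2 / (2*(n1+n2))); CI = d -/+ z * SE.
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    n1, n2 = len(x), len(y)
    if n1 < 2 or n2 < 2:
        raise ValueError("each group needs n >= 2")
    s_pooled = np.sqrt(((n1 - 1) * x.var(ddof=1) + (n2 - 1) * y.var(ddof=1)) / (n1 + n2 - 2))
    if s_pooled == 0:
        d = 0.0 if x.mean() == y.mean() else float(np.sign(x.mean() - y.mean()) * np.inf)
        return d, d, d
    d = float((x.mean() - y.mean()) / s_pooled)
    se = np.sqrt((n1 + n2) / (n1 * n2) + d**2 / (2 * (n1 + n2)))
    z = stats.norm.ppf(0.5 + level / 2)
    return d, float(d - z * se), float(d + z * se)


@dataclass
class AdmResult:
    """Per-module association summary across meta-GWAS weightings."""

    module_id: str
    p_by_source: dict[str, float]
    d_by_source: dict[str, float]
    d_ci_by_source: dict[str, tuple[float, float]]
    significant: bool
    alpha_corrected: float


def identify_adms(
    mprs_by_source: dict[str, pd.DataFrame],
    phenotypes: pd.DataFrame,
    n_candidate_modules: int | None = None,
    alpha: float = 0.05,
    rule: str = "union",
    case_group: str = "AD",
    control_group: str = "CN",
    variant: str = "welch",
) -> list[AdmResult]:
    """Select ADMs by case/control score differences under Bonferroni control.

    ``mprs_by_source`` maps each meta-GWAS label to a long-format score
    table (individual_id, module_id, score).  The Bonferroni denominator
    is the total candidate-module count pooled over sides, not modules x
    sources.  ``rule='union'`` flags a module significant under >= 1
    source; ``'intersection'`` requires all sources.
    """
    if rule not in ("union", "intersection"):
        raise ValueError(f"unknown rule {rule!r}")
    module_ids: list[str] = []
    for df in mprs_by_source.values():
        for m in df["module_id"].unique():
            if m not in module_ids:
                module_ids.append(str(m))
    m_total = n_candidate_modules if n_candidate_modules is not None else len(module_ids)
    if m_total == 0:
        raise ValueError("no candidate modules (m = 0)")
    threshold = alpha / m_total

    dx = phenotypes.set_index("individual_id")["diagnosis"]
    case_ids = set(dx.index[dx == case_group])
    ctrl_ids = set(dx.index[dx == control_group])

    results: list[AdmResult] = []
    for mid in module_ids:
        p_by, d_by, ci_by = {}, {}, {}
        for source, df in mprs_by_source.items():
            sub = df[df["module_id"] == mid]
            scores = sub.set_index("individual_id")["score"]
            x = scores[scores.index.isin(case_ids)].to_numpy(float)
            y = scores[scores.index.isin(ctrl_ids)].to_numpy(float)
            _, _, p = two_sample_t(x, y, variant=variant)
            d, lo, hi = cohens_d_ci(x, y)
            p_by[source], d_by[source], ci_by[source] = p, d, (lo, hi)
        hits = [p < threshold for p in p_by.values()]
        sig = any(hits) if rule == "union" else all(hits)
        results.append(AdmResult(
            module_id=mid, p_by_source=p_by, d_by_source=d_by,
            d_ci_by_source=ci_by, significant=sig, alpha_corrected=threshold,
        ))
    return results
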