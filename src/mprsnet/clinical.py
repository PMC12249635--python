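"""Clinical validation: staging, conversion survival, and mediation.

Three complementary checks of a disease-relevant module's score:

* staging sensitivity -- pairwise Welch t-tests of the score across the
  five diagnostic groups (CN, SMC, EMCI, LMCI, AD);
* MCI-to-AD conversion -- Kaplan-Meier curves and log-rank test for the
  median-split high/low score groups, and a Cox proportional-hazards
  model of conversion risk per SD of score, adjusted for age, sex and
  education (Efron tie handling; conversion times are monthly, so ties
  are guaranteed);
* causal mediation -- the score (x) acts on diagnosis (y, binary) partly
  through the imaging trait (m): a linear mediator model and a logistic
  outcome model are combined by counterfactual simulation into the
  average causal mediation effect (ACME), average direct effect (ADE)
  and proportion mediated, with nonparametric-bootstrap intervals.
"""

from __future__ import annotations

import itertools
import logging
from dataclasses import dataclass

import numpy as np
import pandas as pd
from lifelines import CoxPHFitter, KaplanMeierFitter
from lifelines.statistics import multivariate_logrank_test
import statsmodels.api as sm

from .adm import two_sample_t
from .io_formats import DIAGNOSIS_LEVELS

logger = logging.getLogger("mprsnet.clinical")

__all__ = [
    "SurvivalResult",
    "MediationResult",
    "staging_comparisons",
    "median_split",
    "km_logrank",
    "cox_ph",
    "mediation",
]


def staging_comparisons(
    values: pd.Series,
    phenotypes: pd.DataFrame,
    groups: list[str] | None = None,
) -> pd.DataFrame:
    """Welch t-test of a score between every unordered pair of diagnostic groups.

    ``values`` is indexed by individual_id.  Raw two-sided p-values are
    reported without multiplicity adjustment.  Pairs where either group
    has n < 2 are skipped.
    """
    groups = groups if groups is not None else list(DIAGNOSIS_LEVELS)
    dx = phenotypes.set_index("individual_id")["diagnosis"]
    common = values.index.intersection(dx.index)
    vals, dx = values.loc[common], dx.loc[common]
    rows = []
    for g1, g2 in itertools.combinations(groups, 2):
        x = vals[dx == g1].to_numpy(float)
        y = vals[dx == g2].to_numpy(float)
        if len(x) < 2 or len(y) < 2:
            logger.info("staging_comparisons: skipping %s vs %s (n < 2)", g1, g2)
            continue
        t, _, p = two_sample_t(x, y, variant="welch")
        rows.append({"group1": g1, "group2": g2, "n1": len(x), "n2": len(y), "t": t, "p": p})
    return pd.DataFrame(rows, columns=["group1", "group2", "n1", "n2", "t", "p"])


def median_split(scores: pd.Series) -> pd.Series:
    """Split into 'high'/'low' risk at the median; ties go to 'low'."""
    med = scores.median()
    return pd.Series(np.where(scores > med, "high", "low"), index=scores.index, name="risk_group")


@dataclass
class SurvivalResult:
    """KM curves, log-rank test and Cox summary for one module score."""

    km_curves: dict[str, pd.DataFrame]  # group -> columns (time, survival)
    logrank_chi2: float
    logrank_p: float
    cox: pd.DataFrame | None = None  # per covariate: coef, hr, ci_low, ci_high, p


def km_logrank(times, events, group_labels) -> SurvivalResult:
    """Product-limit survival curves per group plus the two-group log-rank test.

    Right-censored observations (event 0) contribute to risk sets until
    their censoring time.  Exactly two groups are required for the 1-df
    log-rank chi-square.
    """
    times = np.asarray(times, dtype=float)
    events = np.asarray(events, dtype=int)
    group_labels = np.asarray(group_labels)
    if np.any(times < 0):
        raise ValueError("times must be >= 0")
    if not set(np.unique(events)) <= {0, 1}:
        raise ValueError("events must be 0/1")
    uniq = sorted(set(group_labels.tolist()))
    if len(uniq) != 2:
        raise ValueError(f"log-rank requires exactly 2 groups, got {uniq}")
    curves: dict[str, pd.DataFrame] = {}
    for g in uniq:
        mask = group_labels == g
        if events[mask].sum() == 0:
            logger.info("km_logrank: group %r has no events", g)
        kmf = KaplanMeierFitter()
        kmf.fit(times[mask], events[mask])
        sf = kmf.survival_function_
        curves[str(g)] = pd.DataFrame(
            {"time": sf.index.to_numpy(float), "survival": sf.iloc[:, 0].to_numpy(float)}
        )
    res = multivariate_logrank_test(times, group_labels, events)
    return SurvivalResult(
        km_curves=curves,
        logrank_chi2=float(res.test_statistic),
        logrank_p=float(res.p_value),
    )


def cox_ph(
    times,
    events,
    covariates: pd.DataFrame,
    ties: str = "efron",
) -> SurvivalResult:
    """Cox proportional-hazards fit; returns Wald CIs and hazard ratios.

    ``covariates`` holds the design (e.g. mprs_z, age, sex, education);
    standardize the score beforehand so its HR is per SD.  Constant
    covariates, non-convergence and separation (|coef| > 20) raise.
    """
    if ties != "efron":
        raise ValueError("only Efron tie handling is supported")
    cov = covariates.reset_index(drop=True).astype(float)
    const = [c for c in cov.columns if cov[c].nunique() <= 1]
    if const:
        raise ValueError(f"constant covariate(s): {const}")
    events = np.asarray(events, dtype=int)
    if events.sum() < 1:
        raise ValueError("need at least one event")
    df = cov.copy()
    df["_time"] = np.asarray(times, dtype=float)
    df["_event"] = events
    cph = CoxPHFitter()
    # lifelines uses Efron tie handling; tighten the stopping rule so the
    # partial-likelihood optimum is resolved well past reporting precision
    cph.fit(df, duration_col="_time", event_col="_event",
            fit_options={"precision": 1e-11})
    summ = cph.summary
    if (summ["coef"].abs() > 20).any():
        bad = summ.index[summ["coef"].abs() > 20].tolist()
        raise ValueError(f"separation suspected: |coef| > 20 for {bad}")
    cox = pd.DataFrame({
        "covariate": summ.index,
        "coef": summ["coef"].to_numpy(),
        "hr": summ["exp(coef)"].to_numpy(),
        "ci_low": np.exp(summ["coef lower 95%"].to_numpy()),
        "ci_high": np.exp(summ["coef upper 95%"].to_numpy()),
        "p": summ["p"].to_numpy(),
    }).reset_index(drop=True)
    return SurvivalResult(km_curves={}, logrank_chi2=np.nan, logrank_p=np.nan, cox=cox)


# ---------------------------------------------------------------------------
# mediation
# ---------------------------------------------------------------------------


@dataclass
class MediationResult:
    acme: float
    ade: float
    total_effect: float
    prop_mediated: float
    ci: dict[str, tuple[float, float]]
    p: dict[str, float]
    n_boot: int
    n_discarded: int


def _fit_mediation_models(x, m, y, z):
    """Fit mediator OLS and outcome logit; returns (alpha, sigma, gamma, ok)."""
    n = len(x)
    Xm = np.column_stack([np.ones(n), x] + ([z] if z is not None else []))
    ols = sm.OLS(m, Xm).fit()
    alpha = ols.params
    dof = max(n - Xm.shape[1], 1)
    sigma = float(np.sqrt(ols.ssr / dof))
    Xy = np.column_stack([np.ones(n), x, m] + ([z] if z is not None else []))
    try:
        logit = sm.Logit(y, Xy).fit(disp=0, maxiter=200)
        ok = bool(logit.mle_retvals.get("converged", True)) and np.all(
            np.abs(logit.params) < 50
        )
        gamma = logit.params
    except Exception:  # perfect separation or singular design in a bootstrap draw
        ok, gamma = False, None
    return alpha, sigma, gamma, ok


def _mediation_effects(x, z, alpha, sigma, gamma, x_lo, x_hi, rng, n_mc):
    """Counterfactual-simulation ACME/ADE on the probability scale.

    Mediator draws use common random numbers across treatment levels; the
    averaged two-arm decomposition makes acme + ade = total exactly.
    """
    n = len(x)
    q = z.shape[1] if z is not None else 0
    eps = rng.standard_normal((n, n_mc)) * sigma
    z_term_m = z @ alpha[2 : 2 + q] if q else 0.0
    z_term_y = z @ gamma[3 : 3 + q] if q else 0.0

    def m_draws(t):
        mu = alpha[0] + alpha[1] * t + z_term_m
        return np.asarray(mu).reshape(-1, 1) + eps

    def y_prob(t, M):
        lin = gamma[0] + gamma[1] * t + gamma[2] * M + np.asarray(z_term_y).reshape(-1, 1)
        return 1.0 / (1.0 + np.exp(-lin))

    M_lo, M_hi = m_draws(x_lo), m_draws(x_hi)
    acme = 0.5 * (
        np.mean(y_prob(x_lo, M_hi) - y_prob(x_lo, M_lo))
        + np.mean(y_prob(x_hi, M_hi) - y_prob(x_hi, M_lo))
    )
    ade = 0.5 * (
        np.mean(y_prob(x_hi, M_lo) - y_prob(x_lo, M_lo))
        + np.mean(y_prob(x_hi, M_hi) - y_prob(x_lo, M_hi))
    )
    return float(acme), float(ade)


def mediation(
    x,
    m,
    y,
    z=None,
    n_boot: int = 5000,
    n_mc: int = 100,
    seed: int = 0,
) -> MediationResult:
    """Bootstrap causal mediation analysis with a binary outcome.

    Models: m = a0 + a1 x + a2'z + eps (OLS) and
    logit P(y=1) = g0 + g1 x + g2 m + g3'z.  Treatment contrast is
    mean(x) -/+ 1 SD.  Effects are averaged over both treatment arms, the
    empirical covariate distribution and ``n_mc`` Monte-Carlo mediator
    draws, so ACME + ADE equals the total effect by construction.
    Percentile CIs and sign-crossing p-values come from ``n_boot``
    nonparametric bootstrap resamples (non-convergent draws are
    re-sampled, up to a 10% budget).
    """
    x = np.asarray(x, dtype=float)
    m = np.asarray(m, dtype=float)
    y = np.asarray(y, dtype=float)
    if set(np.unique(y)) - {0.0, 1.0}:
        raise ValueError("y must be binary 0/1")
    z = None if z is None else np.asarray(z, dtype=float).reshape(len(x), -1)
    n = len(x)
    x_lo, x_hi = x.mean() - x.std(ddof=1), x.mean() + x.std(ddof=1)
    rng = np.random.default_rng(seed)

    alpha, sigma, gamma, ok = _fit_mediation_models(x, m, y, z)
    if not ok:
        raise ValueError("outcome logistic model failed to converge on the full data")
    acme, ade = _mediation_effects(x, z, alpha, sigma, gamma, x_lo, x_hi, rng, n_mc)
    total = acme + ade
    prop = acme / total if total != 0 else np.nan

    boots = {"acme": [], "ade": [], "total_effect": [], "prop_mediated": []}
    n_discarded = 0
    max_discard = max(1, n_boot // 10)
    b = 0
    while b < n_boot:
        idx = rng.integers(0, n, size=n)
        zb = z[idx] if z is not None else None
        a_b, s_b, g_b, ok_b = _fit_mediation_models(x[idx], m[idx], y[idx], zb)
        if not ok_b:
            n_discarded += 1
            if n_discarded > max_discard:
                raise RuntimeError("more than 10% of bootstrap draws failed to converge")
            continue
        ac, ad = _mediation_effects(x[idx], zb, a_b, s_b, g_b, x_lo, x_hi, rng, n_mc)
        boots["acme"].append(ac)
        boots["ade"].append(ad)
        boots["total_effect"].append(ac + ad)
        boots["prop_mediated"].append(ac / (ac + ad) if (ac + ad) != 0 else np.nan)
        b += 1
    if n_discarded:
        logger.info("mediation: %d non-convergent bootstrap draw(s) re-sampled", n_discarded)

    ci, pvals = {}, {}
    for key, vals in boots.items():
        arr = np.asarray(vals, dtype=float)
        arr = arr[np.isfinite(arr)]
        lo, hi = np.percentile(arr, [2.5, 97.5])
        ci[key] = (float(lo), float(hi))
        p = 2.0 * min(np.mean(arr <= 0), np.mean(arr >= 0))
        pvals[key] = float(min(1.0, max(p, 1.0 / n_boot)))
    return MediationResult(
        acme=acme, ade=ade, total_effect=total, prop_mediated=float(prop),
        ci=ci, p=pvals, n_boot=n_boot, n_discarded=n_discarded,
    )
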