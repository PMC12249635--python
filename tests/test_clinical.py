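import numpy as np
import pandas as pd
import pytest

from mprsnet.clinical import (
    cox_ph,
    km_logrank,
    median_split,
    mediation,
    staging_comparisons,
)


# ---------------------------------------------------------------------------
# independent oracles
# ---------------------------------------------------------------------------


def logrank_oracle(times, events, groups):
    """Two-group log-rank chi-square by direct risk-table enumeration."""
    times = np.asarray(times, float)
    events = np.asarray(events, int)
    groups = np.asarray(groups)
    g0 = sorted(set(groups))[0]
    O = E = V = 0.0
    for t in sorted(set(times[events == 1])):
        at_risk = times >= t
        n = at_risk.sum()
        n1 = (at_risk & (groups == g0)).sum()
        d = ((times == t) & (events == 1)).sum()
        d1 = ((times == t) & (events == 1) & (groups == g0)).sum()
        O += d1
        E += d * n1 / n
        if n > 1:
            V += d * (n1 / n) * (1 - n1 / n) * (n - d) / (n - 1)
    return (O - E) ** 2 / V


def cox_newton_oracle(times, events, X, n_iter=60):
    """Efron partial-likelihood Newton-Raphson, written independently."""
    times = np.asarray(times, float)
    events = np.asarray(events, int)
    X = np.asarray(X, float)
    beta = np.zeros(X.shape[1])
    order = np.argsort(times)
    times, events, X = times[order], events[order], X[order]
    for _ in range(n_iter):
        eta = X @ beta
        w = np.exp(eta)
        grad = np.zeros_like(beta)
        hess = np.zeros((len(beta), len(beta)))
        for t in np.unique(times[events == 1]):
            D = (times == t) & (events == 1)
            R = times >= t
            d = D.sum()
            s0R, s1R = w[R].sum(), (w[R, None] * X[R]).sum(0)
            s2R = (w[R, None, None] * X[R][:, :, None] * X[R][:, None, :]).sum(0)
            s0D, s1D = w[D].sum(), (w[D, None] * X[D]).sum(0)
            s2D = (w[D, None, None] * X[D][:, :, None] * X[D][:, None, :]).sum(0)
            grad += X[D].sum(0)
            for l in range(d):
                f = l / d
                s0 = s0R - f * s0D
                s1 = s1R - f * s1D
                s2 = s2R - f * s2D
                grad -= s1 / s0
                hess -= s2 / s0 - np.outer(s1, s1) / s0**2
        step = np.linalg.solve(hess, grad)
        beta = beta - step
        if np.abs(step).max() < 1e-12:
            break
    return beta


# ---------------------------------------------------------------------------
# staging
# ---------------------------------------------------------------------------


def _pheno_from_groups(group_sizes: dict[str, int]):
    rows, i = [], 0
    for g, n in group_sizes.items():
        for _ in range(n):
            rows.append({"individual_id": f"I{i}", "diagnosis": g})
            i += 1
    return pd.DataFrame(rows)


class TestStaging:
    def test_five_groups_give_ten_pairs(self):
        rng = np.random.default_rng(0)
        pheno = _pheno_from_groups({"CN": 10, "SMC": 10, "EMCI": 10, "LMCI": 10, "AD": 10})
        vals = pd.Series(rng.standard_normal(50), index=pheno["individual_id"])
        assert len(staging_comparisons(vals, pheno)) == 10

    def test_identical_groups_p_one(self):
        pheno = _pheno_from_groups({"CN": 3, "AD": 3})
        vals = pd.Series([1.0, 2.0, 3.0, 1.0, 2.0, 3.0], index=pheno["individual_id"])
        out = staging_comparisons(vals, pheno)
        assert len(out) == 1 and out.loc[0, "p"] == 1.0

    def test_monotone_shift_detected_between_adjacent_stages(self):
        rng = np.random.default_rng(1)
        hits = 0
        for rep in range(20):
            pheno = _pheno_from_groups({g: 200 for g in ["CN", "SMC", "EMCI", "LMCI", "AD"]})
            shift = np.repeat([0.0, 0.5, 1.0, 1.5, 2.0], 200)
            vals = pd.Series(shift + rng.standard_normal(1000), index=pheno["individual_id"])
            out = staging_comparisons(vals, pheno).set_index(["group1", "group2"])
            adjacent = [("CN", "SMC"), ("SMC", "EMCI"), ("EMCI", "LMCI"), ("LMCI", "AD")]
            hits += all(out.loc[pair, "p"] < 0.05 for pair in adjacent)
        assert hits >= 18

    def test_small_group_skipped(self):
        pheno = _pheno_from_groups({"CN": 5, "AD": 1})
        vals = pd.Series(np.arange(6.0), index=pheno["individual_id"])
        assert len(staging_comparisons(vals, pheno)) == 0


class TestMedianSplit:
    def test_ties_at_median_go_low(self):
        s = pd.Series([1.0, 2.0, 2.0, 3.0], index=list("abcd"))
        out = median_split(s)
        assert out["b"] == "low" and out["c"] == "low" and out["d"] == "high"

    def test_split_reproducible(self):
        s = pd.Series(np.random.default_rng(0).standard_normal(101))
        assert median_split(s).equals(median_split(s.copy()))


class TestKmLogrank:
    def test_km_without_censoring_is_empirical_survival(self):
        res = km_logrank([1, 2, 3, 1, 2, 3], [1] * 6, ["a"] * 3 + ["b"] * 3)
        surv = res.km_curves["a"].set_index("time")["survival"]
        assert surv.loc[1.0] == pytest.approx(2 / 3)
        assert surv.loc[2.0] == pytest.approx(1 / 3)
        assert surv.loc[3.0] == pytest.approx(0.0)

    def test_km_curves_start_at_one_and_decrease(self):
        rng = np.random.default_rng(2)
        t = rng.exponential(10, 80).round() + 1
        e = rng.integers(0, 2, 80)
        g = np.where(rng.random(80) < 0.5, "hi", "lo")
        e[:2] = 1  # ensure both groups have an event somewhere
        res = km_logrank(t, e, g)
        for curve in res.km_curves.values():
            s = curve["survival"].to_numpy()
            assert s[0] == 1.0
            assert np.all(np.diff(s) <= 1e-12)

    def test_identical_groups_chi2_zero(self):
        res = km_logrank([1, 2, 3, 1, 2, 3], [1] * 6, ["a", "a", "a", "b", "b", "b"])
        assert res.logrank_chi2 == pytest.approx(0.0, abs=1e-12)
        assert res.logrank_p == pytest.approx(1.0)

    def test_matches_risk_table_oracle(self):
        cases = [
            ([1, 2, 3, 4], [1, 1, 1, 1], ["a", "a", "b", "b"]),
        ]
        rng = np.random.default_rng(3)
        for _ in range(10):
            n = 40
            t = rng.exponential(5, n).round() + 1
            e = rng.integers(0, 2, n)
            g = np.where(rng.random(n) < 0.5, "a", "b")
            if e[g == "a"].sum() and e[g == "b"].sum():
                cases.append((t, e, g))
        for t, e, g in cases:
            res = km_logrank(t, e, g)
            assert res.logrank_chi2 == pytest.approx(logrank_oracle(t, e, g), rel=1e-8)

    def test_label_swap_symmetry(self):
        t = [1, 2, 3, 4, 5, 6]
        e = [1, 1, 0, 1, 1, 0]
        res1 = km_logrank(t, e, ["a", "a", "a", "b", "b", "b"])
        res2 = km_logrank(t, e, ["b", "b", "b", "a", "a", "a"])
        assert res1.logrank_chi2 == pytest.approx(res2.logrank_chi2)

    def test_requires_two_groups(self):
        with pytest.raises(ValueError, match="2 groups"):
            km_logrank([1, 2], [1, 1], ["a", "a"])


class TestCoxPh:
    def test_duplicated_symmetric_data_gives_null_coefficient(self):
        t = [1, 2, 3, 4, 1, 2, 3, 4]
        e = [1, 1, 1, 0, 1, 1, 1, 0]
        cov = pd.DataFrame({"x": [0, 0, 0, 0, 1, 1, 1, 1]})
        res = cox_ph(t, e, cov)
        row = res.cox.set_index("covariate").loc["x"]
        assert row["coef"] == pytest.approx(0.0, abs=1e-8)
        assert row["hr"] == pytest.approx(1.0, abs=1e-8)

    def test_matches_newton_partial_likelihood_oracle(self):
        rng = np.random.default_rng(4)
        for _ in range(20):
            n = 60
            X = rng.standard_normal((n, 2))
            t = rng.exponential(np.exp(-(0.5 * X[:, 0] - 0.3 * X[:, 1])))
            t = np.ceil(t * 10)  # monthly-style ties
            e = (rng.random(n) < 0.7).astype(int)
            e[0] = 1
            cov = pd.DataFrame(X, columns=["x1", "x2"])
            res = cox_ph(t, e, cov)
            ref = cox_newton_oracle(t, e, X)
            assert res.cox["coef"].to_numpy() == pytest.approx(ref, abs=1e-6)

    def test_constant_covariate_rejected(self):
        cov = pd.DataFrame({"x": [1.0, 1.0, 1.0]})
        with pytest.raises(ValueError, match="constant"):
            cox_ph([1, 2, 3], [1, 1, 0], cov)

    def test_no_events_rejected(self):
        cov = pd.DataFrame({"x": [0.0, 1.0, 2.0]})
        with pytest.raises(ValueError, match="event"):
            cox_ph([1, 2, 3], [0, 0, 0], cov)


class TestMediation:
    def _simulate(self, n, a, b, c, seed):
        rng = np.random.default_rng(seed)
        x = rng.standard_normal(n)
        m = a * x + rng.standard_normal(n)
        p = 1 / (1 + np.exp(-(c * x + b * m)))
        y = (rng.random(n) < p).astype(float)
        return x, m, y

    def test_decomposition_exact(self):
        x, m, y = self._simulate(500, 0.5, 0.5, 0.8, 0)
        res = mediation(x, m, y, n_boot=30, n_mc=20, seed=1)
        assert abs(res.acme + res.ade - res.total_effect) < 1e-10

    def test_null_mediator_path_covered_by_ci(self):
        hits = 0
        for seed in range(10):
            x, m, y = self._simulate(800, 0.0, 0.5, 0.8, seed)
            res = mediation(x, m, y, n_boot=60, n_mc=20, seed=seed)
            lo, hi = res.ci["acme"]
            hits += lo <= 0 <= hi
        assert hits >= 9

    def test_full_mediation_when_direct_path_absent(self):
        x, m, y = self._simulate(3000, 0.7, 0.7, 0.0, 3)
        res = mediation(x, m, y, n_boot=80, n_mc=40, seed=2)
        lo, hi = res.ci["prop_mediated"]
        assert lo <= 1.0 <= hi or res.prop_mediated > 0.85

    def test_recovers_generative_acme_direction(self):
        x, m, y = self._simulate(2000, 0.5, 0.5, 0.8, 5)
        res = mediation(x, m, y, n_boot=50, n_mc=30, seed=3)
        assert res.acme > 0 and res.ade > 0
        assert res.p["acme"] >= 1 / 50

    def test_binary_y_required(self):
        with pytest.raises(ValueError, match="binary"):
            mediation([0.0, 1.0], [0.0, 1.0], [0.1, 0.9], n_boot=10, seed=0)
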