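"""Enrichment, t-tests, survival and Cox regression."""

import math
from fractions import Fraction

import numpy as np
import pandas as pd
import pytest

from nucleomorph.stats import (
    ContingencyCounts,
    cox_fit,
    cox_treatment,
    enrichment_table,
    expression_split_compare,
    hypergeom_p,
    km_logrank,
    two_sample_t,
)


def exact_hypergeom_tail(N, K, n, k, side):
    """Independent oracle: exact rational tail probability via binomials."""
    lo = max(0, K + n - N)
    hi = min(K, n)
    rng = range(k, hi + 1) if side == "enrichment" else range(lo, k + 1)
    total = sum(Fraction(math.comb(K, j) * math.comb(N - K, n - j), 1) for j in rng)
    return float(total / math.comb(N, n))


class TestHypergeom:
    def test_enrichment_at_zero_is_one(self):
        c = ContingencyCounts(N=20, K=5, n=4, k=0)
        assert hypergeom_p(c, "enrichment") == pytest.approx(1.0, abs=1e-12)

    def test_small_case_matches_enumeration(self):
        # N=10, K=5, n=4, k=4: C(5,4)*C(5,0)/C(10,4) = 5/210
        c = ContingencyCounts(N=10, K=5, n=4, k=4)
        assert hypergeom_p(c, "enrichment") == pytest.approx(5 / 210, abs=1e-12)

    def test_all_small_instances_match_exact_oracle(self):
        for N in range(1, 13):
            for K in range(N + 1):
                for n in range(N + 1):
                    lo = max(0, K + n - N)
                    hi = min(K, n)
                    for k in range(lo, hi + 1):
                        c = ContingencyCounts(N=N, K=K, n=n, k=k)
                        for side in ("enrichment", "depletion"):
                            want = exact_hypergeom_tail(N, K, n, k, side)
                            assert hypergeom_p(c, side) == pytest.approx(
                                want, abs=1e-12), (N, K, n, k, side)

    def test_tail_identity(self):
        rng = np.random.default_rng(0)
        from scipy.stats import hypergeom as hg

        for _ in range(100):
            N = int(rng.integers(2, 200))
            K = int(rng.integers(0, N + 1))
            n = int(rng.integers(0, N + 1))
            lo = max(0, K + n - N)
            hi = min(K, n)
            k = int(rng.integers(lo, hi + 1))
            c = ContingencyCounts(N=N, K=K, n=n, k=k)
            total = (hypergeom_p(c, "enrichment") + hypergeom_p(c, "depletion")
                     - hg.pmf(k, N, K, n))
            assert total == pytest.approx(1.0, abs=1e-9)

    def test_invalid_counts_rejected(self):
        with pytest.raises(ValueError):
            ContingencyCounts(N=10, K=5, n=4, k=5)


class TestEnrichmentTable:
    def test_identical_partitions_diagonal_strongest(self):
        labels = pd.Series(
            ["a"] * 10 + ["b"] * 10 + ["c"] * 10,
            index=[f"p{i}" for i in range(30)],
        )
        out = enrichment_table(labels, labels)
        out = out.set_index(["category_a", "category_b"])
        for ca in "abc":
            diag = out.loc[(ca, ca), "p_enrich"]
            off = [out.loc[(ca, cb), "p_enrich"] for cb in "abc" if cb != ca]
            assert diag <= min(off)

    def test_full_set_in_itself_p_one(self):
        labels = pd.Series(["x"] * 8, index=[f"p{i}" for i in range(8)])
        out = enrichment_table(labels, labels)
        assert out.loc[0, "p_enrich"] == pytest.approx(1.0)

    def test_null_flag_rate_near_alpha(self):
        rng = np.random.default_rng(1)
        n_flagged = 0
        n_tests = 0
        for _ in range(200):
            idx = [f"p{i}" for i in range(40)]
            a = pd.Series(rng.choice(["a", "b"], 40), index=idx)
            b = pd.Series(rng.choice(["x", "y"], 40), index=idx)
            out = enrichment_table(a, b, alpha=0.05)
            n_flagged += out["enriched"].sum()
            n_tests += len(out)
        rate = n_flagged / n_tests
        # discrete test is conservative; the flag rate must not exceed
        # alpha by more than binomial noise
        assert rate < 0.05 + 2 * math.sqrt(0.05 * 0.95 / n_tests)

    def test_empty_intersection_rejected(self):
        a = pd.Series(["x"], index=["p1"])
        b = pd.Series(["y"], index=["p2"])
        with pytest.raises(ValueError):
            enrichment_table(a, b)


class TestTwoSampleT:
    def test_identical_samples(self):
        x = np.array([1.0, 2.0, 3.0])
        t, p, _ = two_sample_t(x, x)
        assert (t, p) == (0.0, 1.0)

    def test_textbook_pooled_case(self):
        t, p, df = two_sample_t([1, 2, 3], [4, 5, 6], flavor="pooled")
        assert t == pytest.approx(-3.674, abs=1e-3)
        assert p == pytest.approx(0.0214, abs=1e-3)
        assert df == 4

    def test_null_rejection_rate(self):
        rng = np.random.default_rng(3)
        rejections = 0
        reps = 4000
        for _ in range(reps):
            x = rng.standard_normal(20)
            y = rng.standard_normal(20)
            rejections += two_sample_t(x, y)[1] < 0.05
        assert 0.04 <= rejections / reps <= 0.06

    def test_zero_variance_conventions(self):
        assert two_sample_t([1.0, 1.0], [1.0, 1.0])[1] == 1.0
        assert two_sample_t([1.0, 1.0], [2.0, 2.0])[1] == 0.0


def _logrank_statistic_oracle(time, event, group):
    """Direct O-E / V computation at distinct event times."""
    time = np.asarray(time, float)
    event = np.asarray(event, int)
    group = np.asarray(group, int)
    O = E = V = 0.0
    o_minus_e = 0.0
    var = 0.0
    for t in np.unique(time[event == 1]):
        at_risk = time >= t
        n = at_risk.sum()
        n1 = (at_risk & (group == 1)).sum()
        d = ((time == t) & (event == 1)).sum()
        d1 = ((time == t) & (event == 1) & (group == 1)).sum()
        o_minus_e += d1 - d * n1 / n
        if n > 1:
            var += d * (n1 / n) * (1 - n1 / n) * (n - d) / (n - 1)
    return o_minus_e**2 / var


class TestKmLogrank:
    def test_identical_groups_statistic_zero(self):
        rng = np.random.default_rng(0)
        days = rng.exponential(300, 25)
        rec = pd.DataFrame({
            "days": np.r_[days, days],
            "event": 1,
            "group": ["a"] * 25 + ["b"] * 25,
        })
        _, chi2, p = km_logrank(rec)
        assert chi2 == pytest.approx(0.0, abs=1e-12)
        assert p == pytest.approx(1.0, abs=1e-12)

    def test_strict_separation_significant(self):
        rec = pd.DataFrame({
            "days": np.r_[np.arange(1, 21), np.arange(100, 120)],
            "event": 1,
            "group": ["a"] * 20 + ["b"] * 20,
        })
        _, chi2, p = km_logrank(rec)
        assert p < 0.01

    def test_km_without_censoring_is_empirical_survival(self):
        rng = np.random.default_rng(5)
        days = rng.exponential(100, 30).round(2)
        rec = pd.DataFrame({"days": np.r_[days, days], "event": 1,
                            "group": ["a"] * 30 + ["b"] * 30})
        curves, _, _ = km_logrank(rec)
        sf = curves["a"].survival_function_.iloc[:, 0]
        for t in days:
            assert sf.loc[t] == pytest.approx((days > t).mean(), abs=1e-12)

    def test_matches_direct_statistic_and_permutation_reference(self):
        rng = np.random.default_rng(7)
        days = rng.exponential(200, 30)
        event = (rng.random(30) < 0.8).astype(int)
        group = np.r_[np.zeros(15, int), np.ones(15, int)]
        rec = pd.DataFrame({"days": days, "event": event,
                            "group": np.where(group == 1, "b", "a")})
        _, chi2, p = km_logrank(rec)
        oracle = _logrank_statistic_oracle(days, event, group)
        assert chi2 == pytest.approx(oracle, rel=1e-9)
        # permutation reference p-value
        B = 5000
        exceed = 0
        for _ in range(B):
            gp = rng.permutation(group)
            exceed += _logrank_statistic_oracle(days, event, gp) >= chi2
        p_perm = exceed / B
        mc_sd = math.sqrt(max(p_perm * (1 - p_perm), 1e-4) / B)
        assert abs(p - p_perm) <= 0.02 + 3 * mc_sd

    def test_rank_invariance_under_time_rescaling(self):
        rng = np.random.default_rng(2)
        days = rng.exponential(100, 40)
        event = (rng.random(40) < 0.7).astype(int)
        rec = pd.DataFrame({"days": days, "event": event,
                            "group": ["a"] * 20 + ["b"] * 20})
        _, chi2a, _ = km_logrank(rec)
        rec2 = rec.assign(days=rec.days**1.5 * 3.7)  # monotone rescaling
        _, chi2b, _ = km_logrank(rec2)
        assert chi2a == pytest.approx(chi2b, rel=1e-12)

    def test_group_without_events_rejected(self):
        rec = pd.DataFrame({"days": [1.0, 2.0, 3.0, 4.0], "event": [1, 1, 0, 0],
                            "group": ["a", "a", "b", "b"]})
        with pytest.raises(ValueError, match="no events"):
            km_logrank(rec)


class TestCox:
    def test_matches_lifelines_on_tie_free_data(self):
        from lifelines import CoxPHFitter

        rng = np.random.default_rng(0)
        n = 150
        treat = (rng.random(n) < 0.5).astype(float)
        days = rng.exponential(300 * np.exp(-0.5 * treat))
        rec = pd.DataFrame({"days": days, "event": 1, "treatment": treat})
        ours = cox_treatment(rec)
        cph = CoxPHFitter().fit(rec, duration_col="days", event_col="event")
        assert ours.coefficients[0] == pytest.approx(
            float(cph.params_["treatment"]), abs=1e-6)
        assert ours.se[0] == pytest.approx(
            float(cph.standard_errors_["treatment"]), abs=1e-6)

    def test_duplicated_dataset_same_beta(self):
        # Breslow tie handling makes the duplicated dataset an exact fixed point
        rng = np.random.default_rng(7)
        n = 60
        treat = (rng.random(n) < 0.5).astype(float)
        days = rng.exponential(300, n)
        b1, *_ = cox_fit(days, np.ones(n), treat)
        b2, *_ = cox_fit(np.r_[days, days], np.ones(2 * n), np.r_[treat, treat])
        assert b1[0] == pytest.approx(b2[0], abs=1e-9)

    def test_null_treatment_ci_coverage(self):
        rng = np.random.default_rng(42)
        cover = 0
        reps = 200
        for _ in range(reps):
            n = 200
            treat = (rng.random(n) < 0.5).astype(float)
            t_ev = rng.exponential(400, n)
            days = np.minimum(t_ev, 800)
            rec = pd.DataFrame({"days": days, "event": (t_ev <= 800).astype(int),
                                "treatment": treat})
            res = cox_treatment(rec)
            cover += res.ci_low <= 1.0 <= res.ci_high
        assert 0.92 <= cover / reps <= 0.98

    def test_planted_hazard_ratio_recovered(self):
        inside = 0
        for seed in range(100):
            rng = np.random.default_rng(seed)
            n = 500
            treat = (rng.random(n) < 0.5).astype(float)
            lam = (1 / 400) * np.exp(math.log(0.5) * treat)
            days = rng.exponential(1 / lam)
            rec = pd.DataFrame({"days": days, "event": 1, "treatment": treat})
            res = cox_treatment(rec)
            inside += 0.4 <= res.hazard_ratio <= 0.625
        assert inside >= 90

    def test_constant_covariate_rejected(self):
        rec = pd.DataFrame({"days": [1.0, 2, 3, 4], "event": [1, 1, 1, 0],
                            "treatment": [1.0, 1.0, 1.0, 1.0]})
        with pytest.raises(ValueError, match="constant|absent"):
            cox_treatment(rec)
        # the low-level fit names the constant column explicitly
        with pytest.raises(ValueError, match="constant"):
            cox_fit(rec["days"], rec["event"], np.ones((4, 1)))

    def test_missing_treatment_level_rejected(self):
        rec = pd.DataFrame({"days": [1.0, 2, 3], "event": [1, 1, 1],
                            "treatment": [0.0, 0.0, 0.0]})
        with pytest.raises(ValueError):
            cox_treatment(rec)


class TestExpressionSplitCompare:
    def _feature_means(self, rng, n=60):
        idx = [f"p{i}" for i in range(n)]
        return pd.DataFrame({
            "Eccentricity": rng.random(n),
            "Circularity": rng.random(n),
        }, index=idx)

    def test_identical_groups_p_one(self):
        rng = np.random.default_rng(0)
        fm = self._feature_means(rng, 8)
        fm.loc[:, :] = 0.5
        expr = pd.Series(np.arange(8, dtype=float), index=fm.index)
        out = expression_split_compare(expr, fm)
        assert (out["p"] == 1.0).all()

    def test_null_rejection_rate_near_alpha(self):
        rng = np.random.default_rng(1)
        rejections = 0
        total = 0
        for _ in range(300):
            fm = self._feature_means(rng, 30)
            expr = pd.Series(rng.standard_normal(30), index=fm.index)
            out = expression_split_compare(expr, fm)
            rejections += (out["p"] < 0.05).sum()
            total += len(out)
        assert abs(rejections / total - 0.05) < 0.025

    def test_planted_effect_detected_one_sided(self):
        # high-expression patients have lower eccentricity (1 sd effect, 30/30)
        rng = np.random.default_rng(4)
        idx = [f"p{i}" for i in range(60)]
        expr = pd.Series(np.r_[np.zeros(30), np.ones(30)]
                         + 0.01 * rng.standard_normal(60), index=idx)
        ecc = np.r_[rng.normal(0.6, 0.1, 30), rng.normal(0.5, 0.1, 30)]
        fm = pd.DataFrame({"Eccentricity": ecc}, index=idx)
        out = expression_split_compare(expr, fm).set_index("feature")
        row = out.loc["Eccentricity"]
        assert row["mean_high"] < row["mean_low"]
        assert row["p"] / 2 < 0.05

    def test_ties_go_to_low_group(self):
        rng = np.random.default_rng(2)
        fm = self._feature_means(rng, 6)
        expr = pd.Series([1.0, 1.0, 1.0, 2.0, 3.0, 4.0], index=fm.index)
        out = expression_split_compare(expr, fm)
        # median is 1.5; the three tied 1.0 values all land low
        assert out["n_low"].iloc[0] == 3
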