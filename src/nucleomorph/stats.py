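"""Integrative statistics: enrichment, t-tests, survival, Cox regression.

These are the tests used to relate OC groups to molecular and clinical
endpoints:

* exact hypergeometric enrichment (upper tail) / depletion (lower tail)
  p-values between categorical patient labelings from different platforms,
  reported raw (no multiplicity adjustment) with a 0.05 significance flag;
* two-sample t-tests (Welch default, pooled optional) for feature-mean and
  OC% comparisons;
* Kaplan-Meier curves and the log-rank test (via lifelines);
* Cox proportional hazards for treatment effect with Breslow tie handling,
  reporting the hazard ratio and its 95% CI for a one-unit treatment change;
* median-split expression-group comparisons of per-patient feature means.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from lifelines import KaplanMeierFitter
from lifelines.statistics import logrank_test
from scipy import stats as sps
from scipy.special import logsumexp

__all__ = [
    "ContingencyCounts",
    "CoxResult",
    "hypergeom_p",
    "enrichment_table",
    "two_sample_t",
    "km_logrank",
    "cox_fit",
    "cox_treatment",
    "expression_split_compare",
]


@dataclass(frozen=True)
class ContingencyCounts:
    """Overlap counts for a hypergeometric test.

    ``N`` patients total; ``K`` in category A, ``n`` in category B, ``k`` in
    both.  Invariants: ``0 <= k <= min(K, n)``, ``K, n <= N`` and
    ``k >= K + n - N`` (the overlap cannot be smaller than forced).
    """

    N: int
    K: int
    n: int
    k: int

    def __post_init__(self) -> None:
        ok = (
            0 <= self.K <= self.N
            and 0 <= self.n <= self.N
            and max(0, self.K + self.n - self.N) <= self.k <= min(self.K, self.n)
        )
        if not ok:
            raise ValueError(f"invalid contingency counts {self}")


def hypergeom_p(c: ContingencyCounts, side: str = "enrichment") -> float:
    """Exact hypergeometric tail p-value by log-space pmf summation.

    ``enrichment`` is the upper tail ``P(X >= k)``; ``depletion`` the lower
    tail ``P(X <= k)``, for ``X ~ Hypergeom(N, K, n)``.
    """
    lo = max(0, c.K + c.n - c.N)
    hi = min(c.K, c.n)
    if side == "enrichment":
        ks = np.arange(c.k, hi + 1)
    elif side == "depletion":
        ks = np.arange(lo, c.k + 1)
    else:
        raise ValueError("side must be 'enrichment' or 'depletion'")
    logp = sps.hypergeom.logpmf(ks, c.N, c.K, c.n)
    return float(min(np.exp(logsumexp(logp)), 1.0))


def enrichment_table(labelsA, labelsB, alpha: float = 0.05) -> pd.DataFrame:
    """All-pairs enrichment/depletion tests between two categorical labelings.

    The population is the intersection of patients labeled in both inputs.
    Raw p-values are reported with significance flags at ``alpha``; no
    multiple-testing adjustment is applied.
    """
    a = pd.Series(labelsA).dropna()
    b = pd.Series(labelsB).dropna()
    universe = a.index.intersection(b.index)
    if len(universe) == 0:
        raise ValueError("no patients labeled in both inputs")
    a = a.loc[universe]
    b = b.loc[universe]
    N = len(universe)
    rows = []
    for ca in sorted(a.unique(), key=str):
        in_a = a == ca
        for cb in sorted(b.unique(), key=str):
            in_b = b == cb
            c = ContingencyCounts(N=N, K=int(in_a.sum()), n=int(in_b.sum()),
                                  k=int((in_a & in_b).sum()))
            pe = hypergeom_p(c, "enrichment")
            pdep = hypergeom_p(c, "depletion")
            rows.append({
                "category_a": ca, "category_b": cb,
                "N": c.N, "K": c.K, "n": c.n, "k": c.k,
                "p_enrich": pe, "p_deplete": pdep,
                "enriched": pe < alpha, "depleted": pdep < alpha,
            })
    return pd.DataFrame(rows)


def two_sample_t(x, y, flavor: str = "welch") -> tuple[float, float, float]:
    """Two-sided two-sample t-test; returns ``(t, p, df)``.

    ``flavor`` is ``"welch"`` (unequal variances, Satterthwaite df; default)
    or ``"pooled"``.  If both samples have zero variance, the test is decided
    by the means alone: equal means give ``(0, 1)`` by convention, unequal
    means ``(+-inf, 0)``.
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if len(x) < 2 or len(y) < 2:
        raise ValueError("need at least 2 observations per sample")
    if flavor not in ("welch", "pooled"):
        raise ValueError("flavor must be 'welch' or 'pooled'")
    if x.var(ddof=1) == 0.0 and y.var(ddof=1) == 0.0:
        if x.mean() == y.mean():
            return 0.0, 1.0, float(len(x) + len(y) - 2)
        return float(np.sign(x.mean() - y.mean()) * np.inf), 0.0, float(len(x) + len(y) - 2)
    res = sps.ttest_ind(x, y, equal_var=(flavor == "pooled"))
    return float(res.statistic), float(res.pvalue), float(res.df)


def km_logrank(records: pd.DataFrame, group_column: str = "group"):
    """Kaplan-Meier curves per group and the two-group log-rank test.

    ``records`` needs columns ``days`` (time), ``event`` (1 = death,
    0 = right-censored at last follow-up) and the two-level ``group_column``.
    Returns ``(curves, chi2, p)`` where ``curves`` maps group -> fitted
    :class:`lifelines.KaplanMeierFitter`.
    """
    groups = sorted(records[group_column].unique(), key=str)
    if len(groups) != 2:
        raise ValueError(f"expected exactly 2 groups, got {groups}")
    curves = {}
    for g in groups:
        sub = records[records[group_column] == g]
        if sub["event"].sum() < 1:
            raise ValueError(f"group {g!r} has no events")
        kmf = KaplanMeierFitter(label=str(g))
        kmf.fit(sub["days"], event_observed=sub["event"])
        curves[g] = kmf
    g0 = records[group_column] == groups[0]
    res = logrank_test(
        records.loc[g0, "days"], records.loc[~g0, "days"],
        event_observed_A=records.loc[g0, "event"],
        event_observed_B=records.loc[~g0, "event"],
    )
    return curves, float(res.test_statistic), float(res.p_value)


@dataclass
class CoxResult:
    hazard_ratio: float  # exp(beta) for the treatment covariate
    ci_low: float
    ci_high: float
    coefficients: np.ndarray
    se: np.ndarray
    n_iter: int
    converged: bool
    flags: list


def cox_fit(time, event, X, tol: float = 1e-9, max_iter: int = 50):
    """Cox proportional-hazards partial likelihood, Breslow tie handling.

    Newton-Raphson with step halving.  Returns ``(beta, se, n_iter,
    converged, flags)``; monotone-likelihood/separation symptoms (diverging
    coefficients) and non-invertible information matrices are flagged rather
    than silently reported.
    """
    time = np.asarray(time, dtype=float)
    event = np.asarray(event, dtype=float)
    X = np.atleast_2d(np.asarray(X, dtype=float))
    if X.shape[0] != len(time):
        X = X.T
    n, p = X.shape
    flags: list[str] = []
    const = X.std(axis=0) < 1e-12
    if const.any():
        raise ValueError(
            f"covariate column(s) {np.nonzero(const)[0].tolist()} constant across subjects"
        )

    order = np.argsort(-time, kind="stable")  # descending time
    t_s, e_s, X_s = time[order], event[order], X[order]

    def loglik_grad_hess(beta):
        eta = X_s @ beta
        eta = np.clip(eta, -500, 500)
        w = np.exp(eta)
        cs_w = np.cumsum(w)  # risk-set sums (descending time => cumulative)
        cs_wx = np.cumsum(w[:, None] * X_s, axis=0)
        cs_wxx = np.cumsum(w[:, None, None] * (X_s[:, :, None] * X_s[:, None, :]), axis=0)
        # Breslow: all events at a tied time share the full risk set.  Using
        # cumulative sums up to the last index with each distinct time.
        ll = 0.0
        g = np.zeros(p)
        H = np.zeros((p, p))
        i = 0
        while i < n:
            j = i
            while j + 1 < n and t_s[j + 1] == t_s[i]:
                j += 1
            d_idx = np.arange(i, j + 1)[e_s[i : j + 1] > 0]
            if d_idx.size:
                S0 = cs_w[j]
                S1 = cs_wx[j]
                S2 = cs_wxx[j]
                d = d_idx.size
                ll += eta[d_idx].sum() - d * np.log(S0)
                g += X_s[d_idx].sum(axis=0) - d * S1 / S0
                H -= d * (S2 / S0 - np.outer(S1, S1) / S0**2)
            i = j + 1
        return ll, g, H

    beta = np.zeros(p)
    ll, g, H = loglik_grad_hess(beta)
    converged = False
    it = 0
    for it in range(1, max_iter + 1):
        try:
            step = np.linalg.solve(-H, g)
        except np.linalg.LinAlgError:
            flags.append("singular information matrix")
            break
        # step halving
        new_beta = beta + step
        new_ll, new_g, new_H = loglik_grad_hess(new_beta)
        halvings = 0
        while new_ll < ll - 1e-12 and halvings < 20:
            step /= 2.0
            new_beta = beta + step
            new_ll, new_g, new_H = loglik_grad_hess(new_beta)
            halvings += 1
        delta = np.max(np.abs(new_beta - beta))
        beta, ll, g, H = new_beta, new_ll, new_g, new_H
        if delta < tol:
            converged = True
            break
    if np.any(np.abs(beta) > 10):
        flags.append("possible monotone likelihood / complete separation (|beta| > 10)")
    try:
        cov = np.linalg.inv(-H)
        se = np.sqrt(np.clip(np.diag(cov), 0, None))
    except np.linalg.LinAlgError:
        flags.append("information matrix not invertible at optimum")
        se = np.full(p, np.nan)
    if not converged and "singular information matrix" not in flags:
        flags.append(f"Newton did not converge in {max_iter} iterations")
    return beta, se, it, converged, flags


def cox_treatment(records: pd.DataFrame, include_group: bool = False) -> CoxResult:
    """Treatment-effect Cox model; HR and 95% CI for one treatment unit.

    ``records`` needs ``days``, ``event`` and a 0/1 ``treatment`` column
    (0 standard, 1 aggressive); with ``include_group`` the OC group label
    column ``group`` enters as a second (numeric) covariate.  Requires both
    treatment levels present with at least one event each.
    """
    for level in (0, 1):
        sub = records[records["treatment"] == level]
        if len(sub) == 0 or sub["event"].sum() < 1:
            raise ValueError(f"treatment level {level} absent or has no events")
    cols = ["treatment"] + (["group"] if include_group else [])
    X = records[cols].to_numpy(dtype=float)
    beta, se, it, conv, flags = cox_fit(records["days"], records["event"], X)
    hr = float(np.exp(beta[0]))
    ci = (float(np.exp(beta[0] - 1.96 * se[0])), float(np.exp(beta[0] + 1.96 * se[0])))
    return CoxResult(
        hazard_ratio=hr,
        ci_low=ci[0],
        ci_high=ci[1],
        coefficients=beta,
        se=se,
        n_iter=it,
        converged=conv,
        flags=flags,
    )


def expression_split_compare(
    expr_row: pd.Series,
    feature_means: pd.DataFrame,
    quantile: float = 0.5,
    flavor: str = "welch",
) -> pd.DataFrame:
    """Per-feature t-tests between low and high gene-expression patients.

    Patients are split at the ``quantile`` (default median) of the gene's
    expression; ties at the cut go to the low group (``<=``).  Returns a
    table with one row per feature-mean column: means per group, t, p.
    """
    common = expr_row.index.intersection(feature_means.index)
    expr = expr_row.loc[common].astype(float)
    fm = feature_means.loc[common]
    cut = float(expr.quantile(quantile))
    low = expr <= cut
    if low.sum() < 2 or (~low).sum() < 2:
        raise ValueError("need >= 2 patients in each expression group")
    rows = []
    for col in fm.columns:
        x = fm.loc[low, col].dropna().to_numpy()
        y = fm.loc[~low, col].dropna().to_numpy()
        t, p, df = two_sample_t(x, y, flavor=flavor)
        rows.append({
            "feature": col, "mean_low": float(np.mean(x)), "mean_high": float(np.mean(y)),
            "t": t, "p": p, "df": df, "n_low": len(x), "n_high": len(y),
        })
    return pd.DataFrame(rows)
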