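"""Patient-level aggregation: OC%, interval optimization, MOC stratification.

Per-nucleus Nuclear Scores are reduced to a per-patient Oligodendroglioma
Component percentage::

    OC% = (# nuclei with NS in the low interval) /
          (# in low interval + # in high interval)

with closed low (oligodendroglioma, default [1, 2]) and high (astrocytoma,
default [6, 10]) intervals; nuclei in the open gap between them are
deliberately uncounted.  The interval pair and the regression weighting
function are selected to minimize the two-sample t-test p-value between the
human-annotated extreme groups (HOC 0 vs HOC 2), with a seeded 80% subsample
stability check.  Patients are then clustered on OC% into three
machine-derived OC groups (MOC 0/1/2) by 1-D K-means restarted from many
seeded initializations, labels ordered by ascending centroid so MOC 2 is the
highest-OC% (most oligodendroglial) group.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
from sklearn.cluster import KMeans

from nucleomorph.stats import two_sample_t

__all__ = [
    "IntervalSpec",
    "PatientAggregate",
    "CohortStratification",
    "IntervalOptimizationResult",
    "aggregate_patient",
    "optimize_intervals",
    "kmeans_cluster",
    "fit_group_gaussians",
    "patient_feature_means",
    "qc_nucleus_panels",
    "DEFAULT_INTERVAL_GRID",
]

#: Unit-width histogram bins spanning the NS range [1, 10].
NS_BINS = np.arange(1.0, 11.0)


@dataclass(frozen=True)
class IntervalSpec:
    """Closed low/high NS intervals; low ends strictly below high's start."""

    low: tuple[float, float] = (1.0, 2.0)
    high: tuple[float, float] = (6.0, 10.0)

    def __post_init__(self) -> None:
        a, b = self.low
        c, d = self.high
        if not (1.0 <= a <= b < c <= d <= 10.0):
            raise ValueError(
                f"require 1 <= low[0] <= low[1] < high[0] <= high[1] <= 10, got {self}"
            )

    def __str__(self) -> str:
        return f"low[{self.low[0]:g},{self.low[1]:g}]/high[{self.high[0]:g},{self.high[1]:g}]"


#: Default candidate grid for interval optimization.
DEFAULT_INTERVAL_GRID = [
    IntervalSpec(low=lo, high=hi)
    for lo in [(1.0, 1.0), (1.0, 2.0), (1.0, 3.0)]
    for hi in [(5.0, 10.0), (6.0, 10.0), (7.0, 10.0)]
]


@dataclass
class PatientAggregate:
    patient_id: str
    ns_histogram: np.ndarray  # counts over NS_BINS (9 unit bins)
    n_low: int
    n_high: int
    oc_pct: float  # in [0, 1]; NaN when n_low + n_high == 0
    total: int

    @property
    def defined(self) -> bool:
        return not np.isnan(self.oc_pct)


@dataclass
class CohortStratification:
    labels: pd.Series  # patient -> MOC in {0, 1, 2}, ascending-centroid order
    centroids: np.ndarray  # ascending OC% centroids
    wcss: float  # within-cluster sum of squares of the best restart
    seed0: int
    n_seeds: int
    best_restart: int  # index of the winning restart


@dataclass
class IntervalOptimizationResult:
    best: tuple[IntervalSpec, str]  # (intervals, weight_function)
    pvalues: pd.DataFrame  # candidate table with p per candidate
    stability: float  # fraction of subsamples agreeing with the full-data argmin
    subsample_winners: list[tuple[IntervalSpec, str]]


def aggregate_patient(
    scores, intervals: IntervalSpec = IntervalSpec(), patient_id: str = ""
) -> PatientAggregate:
    """Count nuclei in the closed low/high NS intervals and form OC%.

    When no nucleus falls in either interval OC% is undefined: the aggregate
    carries NaN and a warning is emitted (such patients are excluded from
    downstream stratification).
    """
    s = np.asarray(scores, dtype=float)
    if s.size and (s.min() < NS_BINS[0] or s.max() > NS_BINS[-1]):
        raise ValueError("scores must lie in [1, 10]")
    a, b = intervals.low
    c, d = intervals.high
    n_low = int(((s >= a) & (s <= b)).sum())
    n_high = int(((s >= c) & (s <= d)).sum())
    # 9 unit-width bins over [1, 10]; numpy closes the last bin so NS == 10
    # lands in [9, 10]
    hist, _ = np.histogram(s, bins=NS_BINS)
    if n_low + n_high == 0:
        warnings.warn(
            f"patient {patient_id or '<unnamed>'}: no nuclei in low/high NS intervals; "
            "OC% undefined",
            stacklevel=2,
        )
        oc = float("nan")
    else:
        oc = n_low / (n_low + n_high)
    return PatientAggregate(
        patient_id=patient_id,
        ns_histogram=hist,
        n_low=n_low,
        n_high=n_high,
        oc_pct=oc,
        total=int(s.size),
    )


def _oc_by_patient(scores_by_patient: dict, intervals: IntervalSpec) -> pd.Series:
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        vals = {
            pid: aggregate_patient(s, intervals, patient_id=str(pid)).oc_pct
            for pid, s in scores_by_patient.items()
        }
    return pd.Series(vals, dtype=float)


def optimize_intervals(
    patient_scores: dict,
    hoc_labels,
    candidates=None,
    holdout_folds: int = 5,
    seed: int = 0,
    flavor: str = "welch",
) -> IntervalOptimizationResult:
    """Pick the (interval pair, weighting function) best separating HOC 0 / HOC 2.

    ``patient_scores`` maps each weighting-function name to a mapping of
    patient id -> per-nucleus NS array scored under that weighting function;
    ``candidates`` is a list of ``(IntervalSpec, weight_function)`` pairs
    (defaults to the documented grid crossed with the provided weighting
    functions).  For each candidate the per-patient OC% values are recomputed
    and the two-sample t-test p between HOC 0 and HOC 2 patients evaluated;
    the argmin-p candidate wins (ties to the first listed).  Stability is the
    fraction of ``holdout_folds`` seeded 80% patient subsamples whose own
    argmin agrees with the full-data winner.
    """
    hoc = pd.Series(hoc_labels)
    if (hoc == 0).sum() < 2 or (hoc == 2).sum() < 2:
        raise ValueError("need >= 2 patients in each of HOC 0 and HOC 2")
    if candidates is None:
        candidates = [(iv, wf) for wf in patient_scores for iv in DEFAULT_INTERVAL_GRID]

    oc_tables = {}
    rows = []
    for iv, wf in candidates:
        if wf not in patient_scores:
            raise KeyError(f"no scores provided for weight function {wf!r}")
        oc = _oc_by_patient(patient_scores[wf], iv)
        oc_tables[(iv, wf)] = oc
        p = _separation_p(oc, hoc, flavor)
        rows.append({"intervals": str(iv), "weight_function": wf, "p": p})
    pvals = pd.DataFrame(rows)
    best_idx = int(np.argmin(pvals["p"].to_numpy()))  # first minimum wins
    best = candidates[best_idx]

    rng = np.random.default_rng(seed)
    patients = hoc.index.to_numpy()
    winners = []
    for _ in range(holdout_folds):
        sub = rng.choice(patients, size=max(int(round(0.8 * len(patients))), 2), replace=False)
        ps = [
            _separation_p(oc_tables[cand].loc[np.intersect1d(sub, oc_tables[cand].index)],
                          hoc.loc[np.intersect1d(sub, hoc.index)], flavor)
            for cand in candidates
        ]
        winners.append(candidates[int(np.argmin(ps))])
    stability = float(np.mean([w == best for w in winners]))
    return IntervalOptimizationResult(
        best=best, pvalues=pvals, stability=stability, subsample_winners=winners
    )


def _separation_p(oc: pd.Series, hoc: pd.Series, flavor: str) -> float:
    common = oc.index.intersection(hoc.index)
    oc = oc.loc[common]
    hoc = hoc.loc[common]
    x = oc[(hoc == 0) & oc.notna()].to_numpy()
    y = oc[(hoc == 2) & oc.notna()].to_numpy()
    if len(x) < 2 or len(y) < 2:
        return 1.0
    if np.ptp(np.concatenate([x, y])) < 1e-15:
        return 1.0  # degenerate candidate: all OC% identical
    return two_sample_t(x, y, flavor=flavor)[1]


def kmeans_cluster(
    oc_values, k: int = 3, n_seeds: int = 10000, seed0: int = 0
) -> CohortStratification:
    """1-D K-means on OC% restarted from ``n_seeds`` seeded initializations.

    Each restart draws ``k`` initial centers uniformly (without replacement)
    from the data values using a child seed derived from ``seed0`` and the
    restart index, runs Lloyd iterations to convergence, and the restart with
    the lowest within-cluster sum of squares wins.  Because restart ``i`` is
    seeded identically regardless of ``n_seeds``, the best-of-restarts WCSS
    is non-increasing in ``n_seeds``.  Clusters are relabeled by ascending
    centroid OC%, so MOC 0 has the lowest OC% (least oligodendroglial) and
    MOC ``k-1`` the highest.
    """
    if isinstance(oc_values, dict):
        oc_values = pd.Series(oc_values, dtype=float)
    if isinstance(oc_values, pd.Series):
        index = oc_values.index
        x = oc_values.to_numpy(dtype=float)
    else:
        x = np.asarray(oc_values, dtype=float)
        index = pd.RangeIndex(len(x))
    keep = ~np.isnan(x)
    xv = x[keep]
    if np.unique(xv).size < k:
        raise ValueError(f"need at least {k} distinct OC% values, got {np.unique(xv).size}")

    best_wcss = np.inf
    best_centers = None
    best_restart = -1
    n = xv.size
    for i in range(n_seeds):
        rng = np.random.default_rng(np.random.SeedSequence(entropy=seed0, spawn_key=(i,)))
        centers = rng.choice(np.unique(xv), size=k, replace=False)
        for _ in range(300):
            assign = np.argmin(np.abs(xv[:, None] - centers[None, :]), axis=1)
            new_centers = centers.copy()
            for j in range(k):
                sel = assign == j
                if sel.any():
                    new_centers[j] = xv[sel].mean()
            if np.array_equal(new_centers, centers):
                break
            centers = new_centers
        assign = np.argmin(np.abs(xv[:, None] - centers[None, :]), axis=1)
        wcss = float(np.sum((xv - centers[assign]) ** 2))
        if wcss < best_wcss - 1e-15:
            best_wcss = wcss
            best_centers = centers.copy()
            best_restart = i

    order = np.argsort(best_centers)
    rank = np.empty(k, dtype=int)
    rank[order] = np.arange(k)
    assign = rank[np.argmin(np.abs(xv[:, None] - best_centers[None, :]), axis=1)]
    labels = pd.Series(np.full(len(x), -1, dtype=int), index=index)
    labels.iloc[np.nonzero(keep)[0]] = assign
    labels = labels[labels >= 0]
    return CohortStratification(
        labels=labels,
        centroids=np.sort(best_centers),
        wcss=best_wcss,
        seed0=seed0,
        n_seeds=n_seeds,
        best_restart=best_restart,
    )


def fit_group_gaussians(oc_by_group: dict) -> pd.DataFrame:
    """Sample mean and sd of OC% per group (for Gaussian density display).

    Groups of size 1 get ``sd = NaN`` with a warning flag column.
    """
    rows = []
    for g, vals in oc_by_group.items():
        v = np.asarray(vals, dtype=float)
        v = v[~np.isnan(v)]
        if v.size == 0:
            raise ValueError(f"group {g!r} has no defined OC% values")
        sd = float(v.std(ddof=1)) if v.size >= 2 else float("nan")
        rows.append({"group": g, "n": v.size, "mean": float(v.mean()), "sd": sd,
                     "sd_defined": v.size >= 2})
        if v.size < 2:
            warnings.warn(f"group {g!r} has a single value; sd undefined", stacklevel=2)
    return pd.DataFrame(rows).set_index("group")


def patient_feature_means(
    feature_table: pd.DataFrame,
    scores,
    intervals: IntervalSpec = IntervalSpec(),
    feature_columns=None,
    patient_column: str = "patient_id",
) -> pd.DataFrame:
    """Per-patient mean of each feature over nuclei inside low OR high intervals.

    ``scores`` must align row-wise with ``feature_table``.  Patients with no
    in-interval nuclei are omitted (logged via warning).
    """
    s = np.asarray(scores, dtype=float)
    if len(s) != len(feature_table):
        raise ValueError("scores must align with feature table rows")
    a, b = intervals.low
    c, d = intervals.high
    in_iv = ((s >= a) & (s <= b)) | ((s >= c) & (s <= d))
    if feature_columns is None:
        feature_columns = [
            col for col in feature_table.columns
            if col != patient_column and pd.api.types.is_numeric_dtype(feature_table[col])
        ]
    sub = feature_table.loc[in_iv, [patient_column, *feature_columns]]
    dropped = set(feature_table[patient_column]) - set(sub[patient_column])
    if dropped:
        warnings.warn(
            f"{len(dropped)} patient(s) with no in-interval nuclei omitted: "
            f"{', '.join(sorted(map(str, dropped))[:5])}",
            stacklevel=2,
        )
    return sub.groupby(patient_column)[list(feature_columns)].mean()


@dataclass
class QcPanels:
    assignments: np.ndarray  # cluster id per nucleus, ordered by mean NS
    cluster_mean_ns: np.ndarray  # ascending
    exemplars: dict[int, np.ndarray]  # cluster -> sampled row indices


def qc_nucleus_panels(
    feature_table: pd.DataFrame,
    scores,
    k: int = 30,
    per_cluster: int = 5,
    seed: int = 0,
    feature_columns=None,
) -> QcPanels:
    """Feature-space K-means panels for visual NS quality control.

    Nuclei are clustered on z-scored features into ``k`` clusters, clusters
    sorted by ascending mean NS, and ``per_cluster`` seeded exemplars sampled
    per cluster for review.  Fewer nuclei than ``k`` reduces ``k`` with a
    warning.
    """
    s = np.asarray(scores, dtype=float)
    if feature_columns is None:
        feature_columns = [c for c in feature_table.columns
                           if pd.api.types.is_numeric_dtype(feature_table[c])]
    X = feature_table[list(feature_columns)].to_numpy(dtype=float)
    if len(X) < k:
        warnings.warn(f"only {len(X)} nuclei; reducing k from {k}", stacklevel=2)
        k = len(X)
    sd = X.std(axis=0)
    sd[sd < 1e-12] = 1.0
    Z = (X - X.mean(axis=0)) / sd
    km = KMeans(n_clusters=k, n_init=10, random_state=seed)
    raw = km.fit_predict(Z)
    mean_ns = np.array([s[raw == j].mean() for j in range(k)])
    order = np.argsort(mean_ns, kind="stable")
    rank = np.empty(k, dtype=int)
    rank[order] = np.arange(k)
    assign = rank[raw]
    rng = np.random.default_rng(seed)
    exemplars = {}
    for j in range(k):
        idx = np.nonzero(assign == j)[0]
        take = min(per_cluster, idx.size)
        exemplars[j] = np.sort(rng.choice(idx, size=take, replace=False))
    return QcPanels(
        assignments=assign,
        cluster_mean_ns=np.sort(mean_ns),
        exemplars=exemplars,
    )
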