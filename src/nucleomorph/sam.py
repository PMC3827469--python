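"""Significance Analysis of Microarrays (SAM) with permutation FDR.

Implements the two-class (unpaired) and quantitative-response modes of the
moderated-statistic permutation scheme:

* per-gene statistic ``d_i = r_i / (s_i + s0)`` where ``r_i`` is the
  between-class mean difference (two-class) or the least-squares slope on
  the response (quantitative), ``s_i`` the corresponding standard error and
  ``s0`` an exchangeability ("fudge") factor chosen from a percentile grid of
  the ``s_i`` to minimize the coefficient of variation of the windowed
  median absolute deviations of ``d`` (the Tusher scheme);
* repeated label/response permutations produce expected order statistics
  ``dbar`` and a null ensemble;
* for a symmetric threshold ``Delta``, genes beyond the first sorted
  positions where ``|d_(i) - dbar_(i)| >= Delta`` are called, and the false
  discovery rate is estimated as ``pi0`` times the median permutation count
  of calls divided by the observed count; the smallest ``Delta`` whose
  estimated FDR is below the cutoff defines the significant set;
* per-gene q-values are the lowest estimated FDR at which the gene is called.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd

__all__ = ["SamResult", "sam_two_class", "sam_quantitative"]


@dataclass
class SamResult:
    scores: pd.Series  # observed d per gene
    qvalues: pd.Series  # in [0, 1]
    s0: float
    n_perm: int
    delta: float  # chosen symmetric threshold (inf when nothing is called)
    fdr: float  # estimated median FDR at the chosen delta (nan if no calls)
    fdr_cutoff: float
    pi0: float
    significant: pd.Index
    positive: pd.Index  # significant with d > 0
    negative: pd.Index  # significant with d < 0

    @property
    def n_significant(self) -> int:
        return len(self.significant)


def _moderated(r: np.ndarray, s: np.ndarray, s0: float) -> np.ndarray:
    """d = r / (s + s0) with the 0/0 of an all-constant gene defined as 0."""
    denom = s + s0
    return np.divide(r, denom, out=np.zeros_like(r), where=denom > 0)


def _choose_s0(r: np.ndarray, s: np.ndarray) -> float:
    """Fudge factor from the percentile grid minimizing the CV of windowed
    MADs of the moderated statistic."""
    alphas = np.arange(0.0, 1.01, 0.05)
    m = s.size
    n_windows = 100 if m >= 500 else max(min(m // 5, 20), 2)
    order = np.argsort(s, kind="stable")
    windows = np.array_split(order, n_windows)
    best_cv, best_s0 = np.inf, float(np.median(s))
    for a in alphas:
        s0 = float(np.quantile(s, a))
        d = _moderated(r, s, s0)
        mads = np.array([
            np.median(np.abs(d[w] - np.median(d[w]))) for w in windows if w.size
        ])
        mu = mads.mean()
        if mu <= 0:
            continue
        cv = mads.std() / mu
        if cv < best_cv:
            best_cv, best_s0 = cv, s0
    return best_s0


def _two_class_stats(X: np.ndarray, grp2: np.ndarray):
    """(r, s) for an unpaired two-class design; grp2 is the boolean mask of
    the second class.  r = mean2 - mean1, s = pooled-sd standard error."""
    n2 = int(grp2.sum())
    n1 = X.shape[1] - n2
    x1 = X[:, ~grp2]
    x2 = X[:, grp2]
    m1 = x1.mean(axis=1)
    m2 = x2.mean(axis=1)
    ss = ((x1 - m1[:, None]) ** 2).sum(axis=1) + ((x2 - m2[:, None]) ** 2).sum(axis=1)
    s = np.sqrt((1.0 / n1 + 1.0 / n2) * ss / (n1 + n2 - 2))
    return m2 - m1, s


def _quantitative_stats(X: np.ndarray, z: np.ndarray):
    """(r, s) for the quantitative mode: least-squares slope of each gene on
    the centered response and its residual standard error."""
    zc = z - z.mean()
    szz = float(zc @ zc)
    slope = (X @ zc) / szz
    intercept = X.mean(axis=1)
    resid = X - intercept[:, None] - slope[:, None] * zc[None, :]
    n = X.shape[1]
    sse = (resid**2).sum(axis=1)
    s = np.sqrt(sse / (n - 2) / szz)
    return slope, s


def _sam_calls(d_obs: np.ndarray, d_perm: np.ndarray, fdr_cutoff: float):
    """Shared thresholding machinery; returns call mask, delta, fdr, pi0, q."""
    m = d_obs.size
    B = d_perm.shape[0]
    order = np.argsort(d_obs, kind="stable")
    d_sorted = d_obs[order]
    dbar = np.sort(d_perm, axis=1).mean(axis=0)
    res = d_sorted - dbar

    q25, q75 = np.quantile(d_obs, [0.25, 0.75])
    pi0 = float(min(1.0, ((d_perm > q25) & (d_perm < q75)).sum() / (0.5 * B * m)))

    # Delta grid: distinct |residual| values (subsampled for speed) plus 0.
    grid = np.unique(np.abs(res))
    if grid.size > 200:
        grid = np.quantile(grid, np.linspace(0, 1, 200))
    grid = np.unique(np.concatenate([[0.0], grid]))

    per_perm = np.sort(d_perm, axis=1)

    best = None  # (delta, fdr, called_mask)
    qvals = np.full(m, 1.0)
    for delta in grid:
        up = res >= delta
        lo = res <= -delta
        cutup = d_sorted[up].min() if up.any() else np.inf
        cutlo = d_sorted[lo].max() if lo.any() else -np.inf
        called = (d_obs >= cutup) | (d_obs <= cutlo)
        n_called = int(called.sum())
        if n_called == 0:
            continue
        false_counts = (per_perm >= cutup).sum(axis=1) + (per_perm <= cutlo).sum(axis=1)
        fdr = float(min(pi0 * np.median(false_counts) / n_called, 1.0))
        qvals[called] = np.minimum(qvals[called], fdr)
        if best is None and fdr <= fdr_cutoff:
            best = (float(delta), fdr, called.copy())
    if best is None:
        return np.zeros(m, dtype=bool), float("inf"), float("nan"), pi0, qvals
    delta, fdr, called = best
    return called, delta, fdr, pi0, qvals


def _finish(genes, d, called, delta, fdr, pi0, qvals, s0, n_perm, fdr_cutoff) -> SamResult:
    scores = pd.Series(d, index=genes, name="d")
    q = pd.Series(qvals, index=genes, name="q")
    sig = genes[called]
    return SamResult(
        scores=scores,
        qvalues=q,
        s0=s0,
        n_perm=n_perm,
        delta=delta,
        fdr=fdr,
        fdr_cutoff=fdr_cutoff,
        pi0=pi0,
        significant=sig,
        positive=genes[called & (d > 0)],
        negative=genes[called & (d < 0)],
    )


def sam_two_class(
    expr: pd.DataFrame,
    labels,
    n_perm: int = 200,
    fdr_cutoff: float = 0.05,
    seed: int = 0,
) -> SamResult:
    """Two-class unpaired SAM on a genes x samples expression matrix.

    ``labels`` assigns each sample column one of exactly two classes;
    ``d > 0`` means higher expression in the second class (sorted order).
    """
    lab = pd.Series(labels, index=expr.columns if not isinstance(labels, pd.Series) else None)
    if isinstance(labels, pd.Series):
        lab = labels.loc[expr.columns]
    classes = sorted(pd.unique(lab), key=str)
    if len(classes) != 2:
        raise ValueError(f"expected exactly 2 classes, got {classes}")
    grp2 = (lab == classes[1]).to_numpy()
    if grp2.sum() < 2 or (~grp2).sum() < 2:
        raise ValueError("need >= 2 samples per class")
    if n_perm < 25:
        warnings.warn("n_perm < 25: FDR estimates will be unstable", stacklevel=2)
    X = expr.to_numpy(dtype=float)
    r, s = _two_class_stats(X, grp2)
    s0 = _choose_s0(r, s)
    d = _moderated(r, s, s0)

    rng = np.random.default_rng(seed)
    d_perm = np.empty((n_perm, X.shape[0]))
    for b in range(n_perm):
        pg = rng.permutation(grp2)
        rp, sp = _two_class_stats(X, pg)
        d_perm[b] = _moderated(rp, sp, s0)

    called, delta, fdr, pi0, qvals = _sam_calls(d, d_perm, fdr_cutoff)
    return _finish(expr.index, d, called, delta, fdr, pi0, qvals, s0, n_perm, fdr_cutoff)


def sam_quantitative(
    expr: pd.DataFrame,
    response,
    n_perm: int = 200,
    fdr_cutoff: float = 0.05,
    seed: int = 0,
) -> SamResult:
    """Quantitative-response SAM: genes correlated with a per-sample value
    (e.g. OC%).  Positive/negative sets hold the significantly positively and
    negatively correlated genes."""
    z = pd.Series(response)
    if isinstance(response, pd.Series):
        z = response.loc[expr.columns]
    zv = np.asarray(z, dtype=float)
    if zv.size != expr.shape[1]:
        raise ValueError("response length must match sample count")
    if np.ptp(zv) < 1e-15:
        raise ValueError("response is constant")
    if n_perm < 25:
        warnings.warn("n_perm < 25: FDR estimates will be unstable", stacklevel=2)
    X = expr.to_numpy(dtype=float)
    r, s = _quantitative_stats(X, zv)
    s0 = _choose_s0(r, s)
    d = _moderated(r, s, s0)

    rng = np.random.default_rng(seed)
    d_perm = np.empty((n_perm, X.shape[0]))
    for b in range(n_perm):
        zp = rng.permutation(zv)
        rp, sp = _quantitative_stats(X, zp)
        d_perm[b] = _moderated(rp, sp, s0)

    called, delta, fdr, pi0, qvals = _sam_calls(d, d_perm, fdr_cutoff)
    return _finish(expr.index, d, called, delta, fdr, pi0, qvals, s0, n_perm, fdr_cutoff)
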