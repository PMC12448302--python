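"""Community-ecology statistics over vOTU abundance tables.

Abundance tables are :class:`pandas.DataFrame` with vOTU ids as the index
(rows) and sample ids as columns; values are nonnegative relative abundances
(RPKM). Dissimilarity matrices are square symmetric DataFrames indexed by
sample id with a zero diagonal.
"""

from __future__ import annotations

import itertools
import math
from typing import Sequence

import numpy as np
import pandas as pd
from scipy.spatial.distance import pdist, squareform
from scipy.stats import linregress, rankdata, spearmanr

EARTH_RADIUS_KM = 6371.0088

__all__ = [
    "bray_curtis",
    "alpha_diversity",
    "anosim",
    "haversine_km",
    "distance_decay",
    "wilcoxon_rank_sum",
    "spearman",
]


def _validate_table(table: pd.DataFrame) -> None:
    if (table.values < 0).any():
        raise ValueError("abundance table contains negative entries")
    if table.index.duplicated().any() or table.columns.duplicated().any():
        raise ValueError("abundance table contains duplicate ids")


def bray_curtis(table: pd.DataFrame) -> pd.DataFrame:
    """Pairwise Bray–Curtis dissimilarity between samples (columns).

    BC(i, j) = sum |x - y| / sum (x + y) over taxa; values lie in [0, 1].
    Raises on samples with zero total, naming them.
    """
    _validate_table(table)
    if table.shape[1] < 2:
        raise ValueError("need at least two samples")
    totals = table.sum(axis=0)
    empty = totals[totals <= 0].index.tolist()
    if empty:
        raise ValueError(f"all-zero sample(s): {empty}")
    dm = squareform(pdist(table.values.T, metric="braycurtis"))
    return pd.DataFrame(dm, index=table.columns, columns=table.columns)


def alpha_diversity(table: pd.DataFrame) -> pd.DataFrame:
    """Per-sample Shannon H (natural log) and Simpson (1 - sum p^2)."""
    _validate_table(table)
    totals = table.sum(axis=0)
    empty = totals[totals <= 0].index.tolist()
    if empty:
        raise ValueError(f"empty sample(s): {empty}")
    p = table.values / totals.values
    with np.errstate(divide="ignore", invalid="ignore"):
        plogp = np.where(p > 0, p * np.log(p), 0.0)
    shannon = -plogp.sum(axis=0)
    simpson = 1.0 - (p**2).sum(axis=0)
    return pd.DataFrame(
        {"shannon": shannon, "simpson": simpson}, index=table.columns
    )


def _anosim_r(condensed_ranks: np.ndarray, within: np.ndarray, n: int) -> float:
    m = n * (n - 1) // 2
    rb = condensed_ranks[~within].mean()
    rw = condensed_ranks[within].mean()
    return (rb - rw) / (m / 2.0)


def anosim(
    dm: pd.DataFrame,
    groups: Sequence,
    n_perm: int = 999,
    seed: int | None = None,
) -> tuple[float, float]:
    """ANOSIM R and permutation p for grouped samples.

    R = (mean between-group rank - mean within-group rank) / (M/4) with
    M = n(n-1)/2 and mid-ranks over all pairwise dissimilarities;
    p = (1 + #{perm R >= R_obs}) / (1 + n_perm).
    """
    groups = np.asarray(groups)
    n = dm.shape[0]
    if len(groups) != n:
        raise ValueError("group labels must match the matrix dimension")
    labels, counts = np.unique(groups, return_counts=True)
    if len(labels) < 2:
        raise ValueError("need at least two groups")
    if (counts < 2).any():
        bad = labels[counts < 2].tolist()
        raise ValueError(f"group(s) of size 1: {bad}")
    condensed = squareform(dm.values, checks=False)
    ranks = rankdata(condensed)
    iu, ju = np.triu_indices(n, k=1)

    def r_for(g: np.ndarray) -> float:
        within = g[iu] == g[ju]
        return _anosim_r(ranks, within, n)

    r_obs = r_for(groups)
    rng = np.random.default_rng(seed)
    hits = 0
    for _ in range(n_perm):
        if r_for(rng.permutation(groups)) >= r_obs:
            hits += 1
    p = (1 + hits) / (1 + n_perm)
    return float(r_obs), float(p)


def haversine_km(lat1: float, lon1: float, lat2: float, lon2: float) -> float:
    """Great-circle distance in km on a sphere of radius 6371.0088 km."""
    phi1, phi2 = math.radians(lat1), math.radians(lat2)
    dphi = phi2 - phi1
    dlam = math.radians(lon2 - lon1)
    a = math.sin(dphi / 2) ** 2 + math.cos(phi1) * math.cos(phi2) * math.sin(dlam / 2) ** 2
    return 2 * EARTH_RADIUS_KM * math.asin(min(1.0, math.sqrt(a)))


def pairwise_geographic_km(meta: pd.DataFrame) -> pd.DataFrame:
    """Pairwise haversine distances from a metadata frame with
    ``latitude``/``longitude`` columns, indexed by sample id."""
    ids = meta.index
    out = np.zeros((len(ids), len(ids)))
    for (a, ra), (b, rb) in itertools.combinations(enumerate(meta.itertuples()), 2):
        d = haversine_km(ra.latitude, ra.longitude, rb.latitude, rb.longitude)
        out[a, b] = out[b, a] = d
    return pd.DataFrame(out, index=ids, columns=ids)


def distance_decay(
    dm: pd.DataFrame, predictor: pd.DataFrame
) -> tuple[float, float, float, float]:
    """OLS of community dissimilarity on a pairwise predictor.

    Both arguments are square matrices over the same samples; the regression
    runs over all unordered pairs. Returns (slope, intercept, r^2, p) with p
    from the slope's t-test.
    """
    if list(dm.index) != list(predictor.index):
        predictor = predictor.loc[dm.index, dm.index]
    y = squareform(dm.values, checks=False)
    x = squareform(predictor.values, checks=False)
    if len(x) < 3:
        raise ValueError("need at least three sample pairs")
    if np.var(x) == 0:
        raise ValueError("predictor has zero variance")
    fit = linregress(x, y)
    return float(fit.slope), float(fit.intercept), float(fit.rvalue**2), float(fit.pvalue)


def _rank_sum_exact_p(pooled: np.ndarray, n1: int, w_obs: float) -> float:
    """Two-sided exact p for the rank-sum W of the first sample.

    Enumerates the permutation distribution of W over all C(n, n1) subsets by
    dynamic programming on doubled mid-ranks (integers even under ties), which
    is equivalent to full enumeration. Two-sided p doubles the smaller tail
    (capped at 1), counting the observed value in both tails.
    """
    ranks2 = np.round(rankdata(pooled) * 2).astype(int)
    n = len(ranks2)
    # dp[k] maps doubled-rank-sum -> number of k-subsets achieving it
    dp: list[dict[int, int]] = [dict() for _ in range(n1 + 1)]
    dp[0][0] = 1
    for r in ranks2:
        for k in range(min(n1, n) - 1, -1, -1):
            if not dp[k]:
                continue
            nxt = dp[k + 1]
            for s, c in dp[k].items():
                nxt[s + r] = nxt.get(s + r, 0) + c
    dist = dp[n1]
    total = sum(dist.values())
    w2 = int(round(w_obs * 2))
    lo = sum(c for s, c in dist.items() if s <= w2)
    hi = sum(c for s, c in dist.items() if s >= w2)
    return min(1.0, 2.0 * min(lo, hi) / total)


def wilcoxon_rank_sum(
    x: Sequence[float], y: Sequence[float]
) -> tuple[float, float]:
    """Two-sided Wilcoxon rank-sum test with mid-ranks for ties.

    Returns (U statistic of the first sample, p). For samples with more than
    20 observations each, p comes from the normal approximation with tie
    correction and continuity correction; otherwise from the exact
    permutation distribution of the rank-sum.
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if len(x) == 0 or len(y) == 0:
        raise ValueError("both samples must be nonempty")
    n1, n2 = len(x), len(y)
    pooled = np.concatenate([x, y])
    ranks = rankdata(pooled)
    w = ranks[:n1].sum()
    u = w - n1 * (n1 + 1) / 2.0
    if max(n1, n2) <= 20:
        p = _rank_sum_exact_p(pooled, n1, w)
    else:
        mu = n1 * n2 / 2.0
        n = n1 + n2
        _, tie_counts = np.unique(pooled, return_counts=True)
        tie_term = ((tie_counts**3 - tie_counts).sum()) / (n * (n - 1))
        sigma2 = n1 * n2 / 12.0 * (n + 1 - tie_term)
        if sigma2 == 0:
            return float(u), 1.0
        z = (abs(u - mu) - 0.5) / math.sqrt(sigma2)
        z = max(z, 0.0)
        p = float(2 * (1 - _norm_cdf(z)))
        p = min(1.0, p)
    return float(u), float(p)


def _norm_cdf(z: float) -> float:
    return 0.5 * (1.0 + math.erf(z / math.sqrt(2.0)))


def spearman(x: Sequence[float], y: Sequence[float]) -> tuple[float, float]:
    """Spearman rank correlation (mid-ranks) with t-approximation p."""
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if len(x) < 3 or len(y) != len(x):
        raise ValueError("need paired vectors of length >= 3")
    if np.var(rankdata(x)) == 0 or np.var(rankdata(y)) == 0:
        raise ValueError("zero rank variance")
    rho, p = spearmanr(x, y)
    return float(rho), float(p)
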