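"""Null-model partition of viral community assembly into five processes.

The framework compares each pair of communities against two null models:

* **βNTI** — the z-score of the between-community mean nearest taxon distance
  (βMNTD) against a null built by shuffling taxon labels across the tips of
  the phylogeny. |βNTI| > 2 signals selection (heterogeneous when > 2,
  homogeneous when < −2).
* **RC_Bray** — the Raup–Crick metric on Bray–Curtis, from probabilistic
  reassembly of both communities out of the regional species pool,
  rescaled to [−1, 1]. Among pairs with |βNTI| < 2, RC_Bray > 0.95 signals
  dispersal limitation, RC_Bray < −0.95 homogenizing dispersal, and
  |RC_Bray| < 0.95 drift.

Abundance tables are taxa × samples DataFrames (see :mod:`.ecology`); trees
are :class:`dendropy.Tree` with tip labels matching the table index.
"""

from __future__ import annotations

import itertools
import logging
import math
import warnings
from dataclasses import dataclass

import dendropy
import numpy as np
import pandas as pd

from .ecology import bray_curtis

logger = logging.getLogger(__name__)

PROCESSES = (
    "heterogeneous_selection",
    "homogeneous_selection",
    "dispersal_limitation",
    "homogenizing_dispersal",
    "drift",
)

__all__ = [
    "patristic_matrix",
    "beta_mntd",
    "beta_nti",
    "rc_bray",
    "classify_pair",
    "partition",
    "ProcessPartition",
    "PROCESSES",
]


def patristic_matrix(tree: dendropy.Tree, taxa: list[str]) -> np.ndarray:
    """Dense patristic (branch-length path) distance matrix over ``taxa``.

    Raises if any taxon lacks a matching tip.
    """
    pdm = tree.phylogenetic_distance_matrix()
    by_label = {t.label: t for t in tree.taxon_namespace}
    missing = [t for t in taxa if t not in by_label]
    if missing:
        raise ValueError(f"taxa missing from tree: {missing[:10]}")
    n = len(taxa)
    out = np.zeros((n, n))
    objs = [by_label[t] for t in taxa]
    for i in range(n):
        for j in range(i + 1, n):
            d = pdm.patristic_distance(objs[i], objs[j])
            out[i, j] = out[j, i] = d
    return out


def _weights(table: pd.DataFrame, weighted: bool) -> np.ndarray:
    """Per-sample taxon weights: relative abundance, or 1/richness."""
    x = table.values.astype(float)
    if weighted:
        return x / x.sum(axis=0, keepdims=True)
    pres = (x > 0).astype(float)
    return pres / pres.sum(axis=0, keepdims=True)


def _beta_mntd_all_pairs(
    dist: np.ndarray, weights: np.ndarray, presence: np.ndarray
) -> np.ndarray:
    """βMNTD for every sample pair given a taxon distance matrix.

    ``dmin[i, s]`` is the distance from taxon i to its nearest taxon present
    in sample s; a taxon present in s is its own (zero-distance) neighbour.
    βMNTD(k, m) = ½ (w[:,k]·dmin[:,m] + w[:,m]·dmin[:,k]).
    """
    n_taxa, n_samp = weights.shape
    dmin = np.empty((n_taxa, n_samp))
    for s in range(n_samp):
        dmin[:, s] = dist[:, presence[:, s]].min(axis=1)
    cross = weights.T @ dmin  # cross[k, m] = sum_i w_ik * dmin[i, m]
    return 0.5 * (cross + cross.T)


def beta_mntd(
    table: pd.DataFrame,
    tree: dendropy.Tree,
    weighted: bool = True,
) -> pd.DataFrame:
    """Observed βMNTD between all sample pairs."""
    taxa = list(table.index)
    dist = patristic_matrix(tree, taxa)
    w = _weights(table, weighted)
    pres = table.values > 0
    bm = _beta_mntd_all_pairs(dist, w, pres)
    np.fill_diagonal(bm, 0.0)
    return pd.DataFrame(bm, index=table.columns, columns=table.columns)


def beta_nti(
    table: pd.DataFrame,
    tree: dendropy.Tree,
    n_null: int = 999,
    seed: int | None = None,
    weighted: bool = True,
    exhaustive: bool = False,
) -> pd.DataFrame:
    """βNTI for every sample pair.

    The null distribution of βMNTD comes from shuffling taxon labels across
    all tips of the tree (one global shuffle per randomization, shared by
    every pair). βNTI = (βMNTD_obs − mean_null) / sd_null. Pairs whose null
    has zero spread are reported NaN with a warning and must be excluded
    from downstream process fractions.

    With ``exhaustive=True`` every distinct tip permutation is enumerated
    instead of sampled (feasible only for small taxon sets).
    """
    taxa = list(table.index)
    dist = patristic_matrix(tree, taxa)
    w = _weights(table, weighted)
    pres = table.values > 0
    obs = _beta_mntd_all_pairs(dist, w, pres)

    n_taxa = len(taxa)
    if exhaustive:
        perms = [np.array(p) for p in itertools.permutations(range(n_taxa))]
    else:
        rng = np.random.default_rng(seed)
        perms = [rng.permutation(n_taxa) for _ in range(n_null)]

    null_sum = np.zeros_like(obs)
    null_sq = np.zeros_like(obs)
    for perm in perms:
        dp = dist[np.ix_(perm, perm)]
        bm = _beta_mntd_all_pairs(dp, w, pres)
        null_sum += bm
        null_sq += bm**2
    k = len(perms)
    mean = null_sum / k
    var = null_sq / k - mean**2
    sd = np.sqrt(np.maximum(var, 0.0))
    if not exhaustive:  # sample sd for a sampled null, population sd for a full enumeration
        sd *= math.sqrt(k / max(k - 1, 1))
    with np.errstate(divide="ignore", invalid="ignore"):
        z = (obs - mean) / sd
    degenerate = sd <= 1e-12
    if degenerate[np.triu_indices_from(degenerate, k=1)].any():
        n_bad = int(degenerate[np.triu_indices_from(degenerate, k=1)].sum())
        logger.warning("beta_nti: %d pair(s) with degenerate null; reported NaN", n_bad)
    z[degenerate] = np.nan
    np.fill_diagonal(z, np.nan)
    return pd.DataFrame(z, index=table.columns, columns=table.columns)


def integerize(table: pd.DataFrame, total: int = 1000) -> pd.DataFrame:
    """Scale each sample to a fixed total and round to counts.

    Richness is preserved: any positive abundance rounds to at least 1.
    Samples already summing to ``total`` with integer values pass through
    unchanged.
    """
    x = table.values.astype(float)
    totals = x.sum(axis=0)
    if (totals <= 0).any():
        raise ValueError("sample with zero total")
    scaled = x / totals * total
    counts = np.round(scaled).astype(int)
    counts[(x > 0) & (counts == 0)] = 1
    return pd.DataFrame(counts, index=table.index, columns=table.columns)


def assemble_null_community(
    rng: np.random.Generator,
    occupancy: np.ndarray,
    pool_abundance: np.ndarray,
    richness: int,
    total: int,
) -> np.ndarray:
    """Assemble one community from the regional pool, Raup–Crick style.

    Species are drawn without replacement with probability proportional to
    ``occupancy`` until ``richness`` species are present (each drawn species
    starts with one individual); the remaining ``total − richness`` abundance
    quanta are then assigned multinomially with probability proportional to
    the pool relative abundance of the drawn species.
    """
    n = len(occupancy)
    if not (0 < richness <= n):
        raise ValueError("richness must be in (0, n_taxa]")
    if total < richness:
        raise ValueError("total must be >= richness")
    # Gumbel top-k == weighted draw without replacement
    occ = np.asarray(occupancy, dtype=float)
    with np.errstate(divide="ignore"):
        keys = np.log(occ) + rng.gumbel(size=n)
    chosen = np.argpartition(-keys, richness - 1)[:richness]
    out = np.zeros(n, dtype=np.int64)
    out[chosen] = 1
    extra = total - richness
    if extra > 0:
        p = np.asarray(pool_abundance, dtype=float)[chosen]
        p = p / p.sum()
        out[chosen] += rng.multinomial(extra, p)
    return out


def _bc_pairs(a: np.ndarray, b: np.ndarray) -> np.ndarray:
    """Bray–Curtis between row-wise community pairs (reps × taxa arrays)."""
    num = np.abs(a - b).sum(axis=1)
    den = (a + b).sum(axis=1)
    return num / den


def rc_bray(
    table: pd.DataFrame,
    n_null: int = 999,
    seed: int | None = None,
    total: int = 1000,
    occupancy: np.ndarray | None = None,
    pool_abundance: np.ndarray | None = None,
) -> pd.DataFrame:
    """Raup–Crick RC_Bray for every sample pair, in [−1, 1].

    Abundances are first integerized (each sample scaled to ``total`` counts,
    richness-preserving). For each pair, ``n_null`` replicates reassemble
    both communities from the regional pool (occupancy-weighted species
    draws, abundance-weighted quanta; see :func:`assemble_null_community`)
    conditioned on each sample's observed richness and total. Then

        RC_raw = (#{null < obs} + ½ #{null = obs}) / n_null
        RC_Bray = 2 (RC_raw − 0.5).

    ``occupancy`` and ``pool_abundance`` default to the empirical pool
    (occupancy = fraction of samples occupied, abundance = taxon totals);
    pass explicit vectors to condition on a known regional pool.
    """
    counts = integerize(table, total=total)
    x = counts.values
    n_taxa, n_samp = x.shape
    if n_samp < 2:
        raise ValueError("need at least two samples")
    rich = (x > 0).sum(axis=0)
    if (rich == 0).any():
        raise ValueError("sample with zero richness")
    tots = x.sum(axis=0)
    if occupancy is None:
        occupancy = (x > 0).mean(axis=1)
    if pool_abundance is None:
        pool_abundance = x.sum(axis=1).astype(float)
    occupancy = np.asarray(occupancy, dtype=float)
    pool_abundance = np.asarray(pool_abundance, dtype=float)

    rng = np.random.default_rng(seed)
    out = np.zeros((n_samp, n_samp))
    for i in range(n_samp):
        for j in range(i + 1, n_samp):
            xi, xj = x[:, i].astype(float), x[:, j].astype(float)
            obs = np.abs(xi - xj).sum() / (xi + xj).sum()
            null_i = np.empty((n_null, n_taxa), dtype=np.int64)
            null_j = np.empty((n_null, n_taxa), dtype=np.int64)
            for r in range(n_null):
                null_i[r] = assemble_null_community(
                    rng, occupancy, pool_abundance, int(rich[i]), int(tots[i])
                )
                null_j[r] = assemble_null_community(
                    rng, occupancy, pool_abundance, int(rich[j]), int(tots[j])
                )
            null_bc = _bc_pairs(null_i, null_j)
            below = (null_bc < obs - 1e-12).sum()
            ties = (np.abs(null_bc - obs) <= 1e-12).sum()
            rc_raw = (below + 0.5 * ties) / n_null
            out[i, j] = out[j, i] = 2.0 * (rc_raw - 0.5)
    return pd.DataFrame(out, index=table.columns, columns=table.columns)


def classify_pair(bnti: float, rc: float) -> str:
    """Five-process classification from (βNTI, RC_Bray).

    βNTI > 2 → heterogeneous selection; βNTI < −2 → homogeneous selection;
    otherwise RC_Bray > 0.95 → dispersal limitation, RC_Bray < −0.95 →
    homogenizing dispersal, |RC_Bray| < 0.95 → drift. Strict inequalities
    exactly as stated; boundary values fall through to the next rule, so a
    pair at βNTI = 2 with RC = 0 classifies as drift.
    """
    if math.isnan(bnti):
        raise ValueError("bnti undefined; exclude pair upstream")
    if bnti > 2:
        return "heterogeneous_selection"
    if bnti < -2:
        return "homogeneous_selection"
    if rc > 0.95:
        return "dispersal_limitation"
    if rc < -0.95:
        return "homogenizing_dispersal"
    return "drift"


@dataclass
class ProcessPartition:
    """Per-pair process calls plus per-group process fractions."""

    pairs: pd.DataFrame  # sample_i, sample_j, group, bnti, rc_bray, process
    fractions: pd.DataFrame  # group × process fractions (classified pairs)
    undefined: dict  # group -> count of NaN-βNTI pairs excluded


def partition(
    table: pd.DataFrame,
    tree: dendropy.Tree,
    metadata: pd.DataFrame,
    grouping: str,
    n_null: int = 999,
    seed: int | None = None,
    weighted: bool = True,
    total: int = 1000,
) -> ProcessPartition:
    """Process partition over within-group sample pairs.

    ``metadata`` is indexed by sample id and must contain the ``grouping``
    column. Groups with fewer than two samples are skipped with a warning.
    Fractions are over classified (defined-βNTI) pairs and sum to 1 per
    group; NaN-βNTI pairs are tallied separately.
    """
    if grouping not in metadata.columns:
        raise ValueError(f"grouping column {grouping!r} not in metadata")
    ss = np.random.SeedSequence(seed)
    s_nti, s_rc = ss.spawn(2)
    bnti = beta_nti(
        table, tree, n_null=n_null,
        seed=int(s_nti.generate_state(1)[0] % (2**31)), weighted=weighted,
    )
    rc = rc_bray(
        table, n_null=n_null,
        seed=int(s_rc.generate_state(1)[0] % (2**31)), total=total,
    )

    rows = []
    undefined: dict = {}
    for group, members in metadata.groupby(grouping).groups.items():
        members = [m for m in members if m in table.columns]
        if len(members) < 2:
            warnings.warn(f"group {group!r} has <2 samples; skipped")
            continue
        undefined[group] = 0
        for a, b in itertools.combinations(members, 2):
            z = bnti.loc[a, b]
            r = rc.loc[a, b]
            if math.isnan(z):
                undefined[group] += 1
                continue
            rows.append(
                {"sample_i": a, "sample_j": b, "group": group,
                 "bnti": z, "rc_bray": r, "process": classify_pair(z, r)}
            )
    pairs = pd.DataFrame(rows, columns=["sample_i", "sample_j", "group",
                                        "bnti", "rc_bray", "process"])
    if len(pairs):
        frac = (
            pairs.groupby("group")["process"]
            .value_counts(normalize=True)
            .unstack(fill_value=0.0)
            .reindex(columns=PROCESSES, fill_value=0.0)
        )
    else:
        frac = pd.DataFrame(columns=PROCESSES)
    return ProcessPartition(pairs=pairs, fractions=frac, undefined=undefined)
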