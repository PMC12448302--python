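"""Community scenarios with known assembly regimes.

Each regime plants a different assembly signal into a vOTU × sample table:

* ``selection_gradient`` — taxa carry a phylogenetically conserved trait
  (Brownian motion on the tree); each sample filters the shared pool through
  a Gaussian kernel around its environmental optimum, so communities at
  opposite ends of the gradient occupy different clades (selection).
* ``dispersal_limited_islands`` — samples belong to islands drawing from
  disjoint(-biased) subsets of the pool (dispersal limitation between
  islands, homogenizing dispersal within).
* ``well_mixed`` — every sample is an independent multinomial draw from one
  pool, blind to the phylogeny (drift-like, null calibration).
* ``rc_null_process`` — samples are produced by exactly the Raup–Crick null
  assembly routine of :mod:`hadalvirome.assembly`, so downstream RC_Bray is
  uniform by construction when conditioned on the same pool.
"""

from __future__ import annotations

import random
from dataclasses import dataclass, field

import dendropy
import numpy as np
import pandas as pd

from ..assembly import assemble_null_community

REGIMES = (
    "selection_gradient",
    "dispersal_limited_islands",
    "well_mixed",
    "rc_null_process",
)

__all__ = ["ScenarioConfig", "generate_community", "REGIMES"]


@dataclass
class ScenarioConfig:
    """Parameters of one simulated community scenario.

    ``gradient_strength`` scales the selection filter (niche breadth =
    trait sd / strength); ``island_overlap`` is the fraction of taxa shared
    between island pools; ``richness``/``total`` condition the
    ``rc_null_process`` regime (defaults: n_taxa // 3 species, 1000
    abundance quanta — the same discretization the RC_Bray null uses).
    """

    seed: int
    n_samples: int = 30
    n_taxa: int = 200
    regime: str = "well_mixed"
    gradient_strength: float = 4.0
    n_islands: int = 2
    island_overlap: float = 0.0
    richness: int | None = None
    total: int = 1000
    birth_rate: float = 1.0
    occupancy: np.ndarray | None = None
    pool_abundance: np.ndarray | None = None

    def validate(self) -> None:
        if self.n_samples < 2 or self.n_taxa < 2:
            raise ValueError("need n_samples >= 2 and n_taxa >= 2")
        if self.regime not in REGIMES:
            raise ValueError(f"unknown regime {self.regime!r}")
        if self.n_islands > self.n_samples:
            raise ValueError("n_islands must not exceed n_samples")
        if self.n_islands < 1 or self.birth_rate <= 0 or self.total <= 0:
            raise ValueError("nonpositive scenario parameter")
        if self.gradient_strength <= 0:
            raise ValueError("gradient_strength must be positive")
        if not (0 <= self.island_overlap <= 1):
            raise ValueError("island_overlap must be in [0, 1]")
        if self.richness is not None and not (2 <= self.richness <= self.n_taxa):
            raise ValueError("richness must be in [2, n_taxa]")


def _yule_tree(n_taxa: int, birth_rate: float, seed: int) -> dendropy.Tree:
    """Pure-birth tree with ``n_taxa`` extant tips labelled vOTU_0001…"""
    rng = random.Random(seed)
    tree = dendropy.model.birthdeath.birth_death_tree(
        birth_rate=birth_rate,
        death_rate=0.0,
        num_extant_tips=n_taxa,
        rng=rng,
    )
    for i, leaf in enumerate(tree.leaf_node_iter()):
        leaf.taxon.label = f"vOTU_{i + 1:04d}"
    return tree


def _brownian_trait(tree: dendropy.Tree, rng: np.random.Generator) -> dict[str, float]:
    """Brownian-motion trait values at the tips (rate 1, root 0)."""
    value = {tree.seed_node: 0.0}
    for node in tree.preorder_node_iter():
        if node is tree.seed_node:
            continue
        bl = node.edge.length or 0.0
        value[node] = value[node.parent_node] + rng.normal(0.0, np.sqrt(max(bl, 0.0)))
    return {leaf.taxon.label: value[leaf] for leaf in tree.leaf_node_iter()}


def _metadata(config: ScenarioConfig, rng: np.random.Generator,
              islands: np.ndarray | None) -> pd.DataFrame:
    """Invented hadal-style sample metadata (two trenches, depth, layer)."""
    n = config.n_samples
    trench = np.where(np.arange(n) < n // 2, "Kermadec", "Diamantina")
    base = {"Kermadec": (-32.2, -177.4), "Diamantina": (-34.7, 104.5)}
    lat = np.array([base[t][0] for t in trench]) + rng.uniform(-0.5, 0.5, n)
    lon = np.array([base[t][1] for t in trench]) + rng.uniform(-0.5, 0.5, n)
    depth = rng.uniform(6000.0, 10000.0, n).round(1)
    layer = (np.arange(n) % 5) + 1
    meta = pd.DataFrame({
        "latitude": lat.round(4),
        "longitude": lon.round(4),
        "water_depth": depth,
        "layer": layer,
        "trench": trench,
    }, index=[f"S{i + 1:02d}" for i in range(n)])
    meta.index.name = "sample"
    if islands is not None:
        meta["island"] = islands
    return meta


def generate_community(
    config: ScenarioConfig,
) -> tuple[pd.DataFrame, dendropy.Tree, pd.DataFrame]:
    """Simulate (abundance table, phylogeny, sample metadata) for a scenario.

    The table is taxa × samples with nonnegative values (abundance quanta on
    an RPKM-like scale); every taxon is a tip of the returned tree.
    """
    config.validate()
    root = np.random.SeedSequence(config.seed)
    s_tree, s_pool, s_trait, s_comm, s_meta = root.spawn(5)

    tree = _yule_tree(config.n_taxa, config.birth_rate,
                      int(s_tree.generate_state(1)[0] % (2**31)))
    taxa = [leaf.taxon.label for leaf in tree.leaf_node_iter()]
    rng_pool = np.random.default_rng(s_pool)
    pool = (np.asarray(config.pool_abundance, dtype=float)
            if config.pool_abundance is not None
            else rng_pool.lognormal(0.0, 1.0, config.n_taxa))
    pool_p = pool / pool.sum()
    # expose the realized pool so RC_Bray can condition on the same
    # parameters (streams are independent, so re-running the updated config
    # reproduces identical outputs)
    config.pool_abundance = pool
    if config.regime == "rc_null_process" and config.occupancy is None:
        config.occupancy = np.ones(config.n_taxa)

    rng = np.random.default_rng(s_comm)
    n, S = config.n_samples, config.n_taxa
    X = np.zeros((S, n), dtype=np.int64)
    islands: np.ndarray | None = None

    if config.regime == "well_mixed":
        for s in range(n):
            X[:, s] = rng.multinomial(config.total, pool_p)

    elif config.regime == "selection_gradient":
        trait_rng = np.random.default_rng(s_trait)
        tip_trait = _brownian_trait(tree, trait_rng)
        trait = np.array([tip_trait[t] for t in taxa])
        sd = trait.std()
        sigma = max(sd, 1e-9) / config.gradient_strength
        optima = np.linspace(np.quantile(trait, 0.05), np.quantile(trait, 0.95), n)
        for s in range(n):
            w = pool_p * np.exp(-((trait - optima[s]) ** 2) / (2 * sigma**2))
            if w.sum() <= 0:
                w = pool_p
            X[:, s] = rng.multinomial(config.total, w / w.sum())

    elif config.regime == "dispersal_limited_islands":
        k = config.n_islands
        perm = rng.permutation(S)
        shared = int(round(config.island_overlap * S))
        shared_taxa = perm[:shared]
        rest = perm[shared:]
        blocks = np.array_split(rest, k)
        islands = np.arange(n) % k
        for s in range(n):
            members = np.concatenate([shared_taxa, blocks[islands[s]]]).astype(int)
            w = np.zeros(S)
            w[members] = pool_p[members]
            X[:, s] = rng.multinomial(config.total, w / w.sum())

    else:  # rc_null_process
        occupancy = (np.asarray(config.occupancy, dtype=float)
                     if config.occupancy is not None else np.ones(S))
        richness = config.richness or max(2, S // 3)
        for s in range(n):
            X[:, s] = assemble_null_community(
                rng, occupancy, pool, richness, config.total)

    table = pd.DataFrame(X.astype(float), index=taxa,
                         columns=[f"S{i + 1:02d}" for i in range(n)])
    table.index.name = "vOTU"
    meta = _metadata(config, np.random.default_rng(s_meta), islands)
    return table, tree, meta
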