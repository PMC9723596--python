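"""Synthetic gradient-transfer communities assembled under known processes.

The generator emulates a sequential-transfer incubation design: a regional
pool of taxa with a shared phylogeny and niche traits, and four sites along
an environmental gradient (a salinity proxy), each sampled with replicate
communities of fixed sequencing depth.  The default site environments are
the standardized log-conductivities of a riverine-to-coastal transect, which
fall into two regimes (two near-fresh sites, two marine sites) separated by
a large jump.

Which ecological process governs assembly is an explicit, known input, so
the downstream null-model inference (betaNTI / Raup-Crick) can be tested by
process recovery:

``homogeneous_selection``
    Gaussian environmental filtering of the niche trait with the *same*
    environment at every site (the whole series stays in the first site's
    conditions).
``variable_selection``
    The same filter, with the environment following the site gradient, so
    contrasting sites select contrasting portions of the trait axis.
``dispersal_limitation``
    No selection; each pool taxon belongs to one site's subpool and sites
    recruit almost exclusively from their own subpool (a small mixing
    fraction of the global pool leaks in), so sites hold nearly disjoint
    taxon sets.
``homogenizing_dispersal``
    No selection; mass effects couple every sample to a single realized
    metacommunity composition.
``drift``
    No selection and no dispersal structure: every sample is an independent
    random assemblage from the regional pool.

Two design points matter for why process recovery works at all at this
scale.  First, recruitment is a two-step lottery: a hard per-sample draw of
*which* taxa establish (Bernoulli establishment within the suitable set, or
a weighted subset for drift), then a multinomial allocation of reads.  At a
fixed depth of 2000 reads, any taxon with non-negligible weight is detected,
so without the establishment lottery replicate communities would share
virtually every taxon and no turnover-based statistic could see anything.
Second, the niche trait is Brownian motion evolved on a depth-biased
(Pagel-delta) transform of the phylogeny, concentrating trait variance on
deep branches.  This emulates a deeply conserved niche axis (salinity
preference is a canonically conserved trait in bacteria) and is the
generator's "phylogenetic signal" knob: delta -> 1 recovers plain Brownian
motion, small delta makes the trait nearly constant within deep clades.

All randomness flows from explicit seeds; per-stage and per-sample child
streams are derived from the scenario seed so that, e.g., adding a
replicate never perturbs the draws of existing samples.
"""

from __future__ import annotations

import random as _random
from dataclasses import dataclass
from io import StringIO

import numpy as np
import pandas as pd
from dendropy.simulate import treesim
from skbio import TreeNode

from .data_model import CommunityTable, ValidationError

__all__ = [
    "PROCESSES",
    "Scenario",
    "simulate_phylogeny",
    "evolve_traits",
    "depth_biased_tree",
    "assemble_dataset",
    "scenario_from_dict",
]

PROCESSES = (
    "homogeneous_selection",
    "variable_selection",
    "dispersal_limitation",
    "homogenizing_dispersal",
    "drift",
)

_DEFAULT_SITES = ("Bremen", "Brake", "Bremerhaven", "Helgoland")

# Standardized log daily-mean conductivities of the four incubation sites
# (two near-fresh riverine sites, then two saline sites past the estuary).
_DEFAULT_ENV = (-1.2, -0.7, 0.8, 1.1)


@dataclass(frozen=True)
class Scenario:
    """Complete configuration of one synthetic dataset.

    Parameters
    ----------
    process : str
        Assembly regime governing the transfer series (one of
        :data:`PROCESSES`).
    n_pool_taxa : int
        Size of the regional taxon pool (default 64).
    tree_seed, community_seed : int
        Seeds for the phylogeny/trait stage and the community-draw stage.
    trait_sigma : float
        Brownian-motion rate of niche-trait evolution per square-root unit
        of branch length.  Traits are standardized to zero mean and unit
        variance across the pool before filtering, so ``env_values`` are in
        pool-trait standard deviations and ``trait_sigma`` only sets the raw
        scale.
    env_values : tuple of float
        Environment value per site (monotone gradient), in standardized
        trait units.
    selection_strength : float
        Inverse-squared width of the Gaussian environmental filter
        ``w ~ exp(-selection_strength * (optimum - env)^2)``.  The default 4
        gives a filter standard deviation of 0.35 trait units, about a third
        of the pool trait spread.
    niche_conservatism : float
        Depth-bias exponent (Pagel's delta) of the tree on which the niche
        trait evolves.  The default 0.05 concentrates essentially all trait
        variance on the deepest splits (strong niche conservatism); 1 gives
        plain Brownian motion.
    establishment_prob : float
        Selection regimes: probability that a suitable taxon establishes in
        any one sample (the colonization lottery; default 0.7).
    occupancy_fraction : float
        Drift and the shared metacommunity realization: fraction of the
        pool present in one assemblage (default 0.5).
    coupling_retention : float
        Homogenizing dispersal: per-sample retention probability of the
        shared composition's taxa (default 0.85; slightly below 1 so
        samples are not bit-identical in support).
    mixing_fraction : float
        Dispersal limitation: fraction of recruitment drawn from the global
        pool rather than the site subpool (default 0.02).
    band_coverage : float
        Fraction of total filter weight that defines the set of "suitable"
        taxa under selection (default 0.99).
    n_replicates, reads_per_sample
        Design dimensions: 3 replicates x 2000 reads per sample by default,
        at the four transect sites.
    """

    process: str
    n_pool_taxa: int = 64
    tree_seed: int = 0
    community_seed: int = 0
    trait_sigma: float = 1.0
    env_values: tuple[float, ...] = _DEFAULT_ENV
    selection_strength: float = 4.0
    niche_conservatism: float = 0.05
    establishment_prob: float = 0.7
    occupancy_fraction: float = 0.5
    coupling_retention: float = 0.85
    mixing_fraction: float = 0.02
    band_coverage: float = 0.99
    n_replicates: int = 3
    reads_per_sample: int = 2000
    sites: tuple[str, ...] = _DEFAULT_SITES
    sample_type: str = "HDPE"

    def __post_init__(self) -> None:
        if self.process not in PROCESSES:
            raise ValidationError(
                f"unknown process {self.process!r}; expected one of {PROCESSES}"
            )
        if len(self.env_values) != len(self.sites):
            raise ValidationError(
                f"{len(self.env_values)} env values for {len(self.sites)} sites"
            )
        if self.n_pool_taxa < 2:
            raise ValidationError("n_pool_taxa must be >= 2")
        if self.n_replicates < 1 or self.reads_per_sample < 1:
            raise ValidationError("n_replicates and reads_per_sample must be positive")
        if self.selection_strength < 0:
            raise ValidationError("selection_strength must be non-negative")
        for name in (
            "establishment_prob",
            "occupancy_fraction",
            "coupling_retention",
            "mixing_fraction",
            "band_coverage",
        ):
            value = getattr(self, name)
            if not 0 <= value <= 1:
                raise ValidationError(f"{name} must be in [0, 1], got {value}")

    def child_rng(self, *tags: int) -> np.random.Generator:
        """Deterministic child stream of the community seed."""
        return np.random.default_rng([self.community_seed, *tags])


def simulate_phylogeny(n_taxa: int, seed: int) -> TreeNode:
    """Simulate a rooted ultrametric pure-birth (Yule) tree of unit depth.

    Tips are labelled ``t000, t001, ...``.  The tree is rescaled so every
    tip sits at depth exactly 1, which makes nearest-taxon statistics
    comparable across independently simulated pools.
    """
    if n_taxa < 2:
        raise ValidationError("a phylogeny needs at least 2 taxa")
    if n_taxa == 2:
        return TreeNode.read(StringIO("(t000:1.0,t001:1.0):0.0;"))
    dtree = treesim.birth_death_tree(
        birth_rate=1.0,
        death_rate=0.0,
        num_extant_tips=n_taxa,
        rng=_random.Random(seed),
    )
    dtree.seed_node.edge.length = 0.0
    for i, leaf in enumerate(dtree.leaf_node_iter()):
        leaf.taxon.label = f"t{i:03d}"
    newick = dtree.as_string(schema="newick", suppress_rooting=True)
    tree = TreeNode.read(StringIO(newick))
    for node in tree.traverse():
        if node.length is None:
            node.length = 0.0
    depth = max(_tip_depths(tree).values())
    for node in tree.traverse(include_self=False):
        node.length /= depth
    # absorb floating error so the tree is exactly ultrametric
    for tip, d in _tip_depths(tree).items():
        tip.length += 1.0 - d
    return tree


def _tip_depths(tree: TreeNode) -> dict:
    depths = {}
    for tip in tree.tips():
        d, node = 0.0, tip
        while node.parent is not None:
            d += node.length or 0.0
            node = node.parent
        depths[tip] = d
    return depths


def depth_biased_tree(tree: TreeNode, delta: float) -> TreeNode:
    """Power-transform node depths of an ultrametric tree (Pagel's delta).

    Node depths d (root = 0) become ``d ** delta``; with delta < 1 internal
    nodes move toward the tips, so branch lengths — and hence Brownian trait
    variance — concentrate on the deepest splits.  Used to evolve deeply
    conserved niche traits; the assembly phylogeny itself is left untouched.
    """
    if delta <= 0:
        raise ValidationError("delta must be positive")
    if delta == 1:
        return tree
    out = tree.copy()
    depths: dict[int, float] = {}
    for node in out.preorder(include_self=True):
        parent_depth = 0.0 if node.parent is None else depths[id(node.parent)]
        depths[id(node)] = parent_depth + (node.length or 0.0)
    for node in out.preorder(include_self=False):
        node.length = depths[id(node)] ** delta - depths[id(node.parent)] ** delta
    return out


def evolve_traits(tree: TreeNode, sigma: float, seed: int) -> pd.Series:
    """Brownian-motion niche optimum at each tip.

    Starting from 0 at the root, each branch adds an independent normal
    increment with variance ``sigma**2 * branch_length``.  Under this model
    trait distance correlates with phylogenetic distance — the phylogenetic
    signal that nearest-taxon null models presuppose.
    """
    if sigma <= 0:
        raise ValidationError("sigma must be positive")
    rng = np.random.default_rng(seed)
    values: dict[int, float] = {id(tree): 0.0}
    out = {}
    for node in tree.preorder(include_self=False):
        parent_val = values[id(node.parent)]
        val = parent_val + rng.normal(0.0, sigma * np.sqrt(node.length or 0.0))
        values[id(node)] = val
        if node.is_tip():
            out[node.name] = val
    return pd.Series(out, name="niche_optimum").sort_index()


# ---------------------------------------------------------------------------
# Community assembly
# ---------------------------------------------------------------------------

def _bernoulli_support(rng: np.random.Generator, candidate: np.ndarray, p: float) -> np.ndarray:
    """Random establishment mask within a candidate set; never fewer than 2."""
    keep = candidate & (rng.random(candidate.size) < p)
    if keep.sum() < 2:
        keep = candidate.copy()
    return keep


def assemble_dataset(
    scenario: Scenario,
) -> tuple[CommunityTable, pd.DataFrame, TreeNode, pd.Series]:
    """Generate one dataset: table, metadata, phylogeny, and trait map.

    Every sample holds exactly ``reads_per_sample`` individuals.  Returns
    the community table (zero-total taxa retained so the table indexes the
    full pool), a metadata frame (site, sample type, cage, replicate, and
    the site environment), the pool phylogeny, and the standardized niche
    trait per taxon.
    """
    sc = scenario
    tree = simulate_phylogeny(sc.n_pool_taxa, sc.tree_seed)
    trait_tree = depth_biased_tree(tree, sc.niche_conservatism)
    traits = evolve_traits(trait_tree, sc.trait_sigma, seed=sc.tree_seed + 1)
    traits = (traits - traits.mean()) / traits.std()
    taxa = list(traits.index)
    n = len(taxa)
    opt = traits.to_numpy()

    rng_pool = sc.child_rng(0)
    pool = rng_pool.lognormal(mean=0.0, sigma=1.0, size=n)
    pool /= pool.sum()

    n_sites = len(sc.sites)
    if sc.process == "homogeneous_selection":
        env = np.full(n_sites, float(sc.env_values[0]))
    else:
        env = np.asarray(sc.env_values, dtype=float)

    subpool = None
    if sc.process == "dispersal_limitation":
        subpool = sc.child_rng(1).integers(0, n_sites, size=n)

    shared = None
    if sc.process == "homogenizing_dispersal":
        rng_shared = sc.child_rng(2)
        keep = rng_shared.random(n) < sc.occupancy_fraction
        if keep.sum() < 2:
            keep = np.ones(n, dtype=bool)
        shared = np.where(keep, pool, 0.0)
        shared /= shared.sum()

    rows, meta_rows = [], []
    for i, site in enumerate(sc.sites):
        for rep in range(1, sc.n_replicates + 1):
            rng = sc.child_rng(3, i, rep)
            if sc.process in ("homogeneous_selection", "variable_selection"):
                w = np.exp(-sc.selection_strength * (opt - env[i]) ** 2) * pool
                w /= w.sum()
                order = np.argsort(-w)
                m = int(np.searchsorted(np.cumsum(w[order]), sc.band_coverage)) + 1
                band = np.zeros(n, dtype=bool)
                band[order[:m]] = True
                keep = _bernoulli_support(rng, band, sc.establishment_prob)
                weights = np.where(keep, w, 0.0)
            elif sc.process == "dispersal_limitation":
                own = pool * (subpool == i)
                local = own / own.sum() if own.sum() > 0 else pool
                weights = (1.0 - sc.mixing_fraction) * local + sc.mixing_fraction * pool
            elif sc.process == "homogenizing_dispersal":
                keep = _bernoulli_support(rng, shared > 0, sc.coupling_retention)
                weights = np.where(keep, shared, 0.0)
            else:  # drift: independent random assemblage from the pool
                keep = _bernoulli_support(
                    rng, np.ones(n, dtype=bool), sc.occupancy_fraction
                )
                weights = np.where(keep, pool, 0.0)
            weights = weights / weights.sum()
            counts = rng.multinomial(sc.reads_per_sample, weights)
            sample_id = f"{site}_r{rep}"
            rows.append(pd.Series(counts, index=taxa, name=sample_id))
            meta_rows.append(
                {
                    "sample_id": sample_id,
                    "sample_type": sc.sample_type,
                    "site": site,
                    "cage": "Transfer",
                    "replicate": rep,
                    "env": env[i],
                }
            )
    data = pd.DataFrame(rows)
    table = CommunityTable(data, keep_empty_taxa=True)
    meta = pd.DataFrame(meta_rows).set_index("sample_id")
    return table, meta, tree, traits


def scenario_from_dict(cfg: dict) -> Scenario:
    """Build a Scenario from a plain mapping (e.g., parsed YAML)."""
    cfg = dict(cfg)
    for key in ("env_values", "sites"):
        if key in cfg:
            cfg[key] = tuple(cfg[key])
    return Scenario(**cfg)
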