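"""Null-model inference of community assembly processes.

The inference chain follows the Stegen-style framework: after confirming
phylogenetic signal (Mantel correlogram between taxon niche differences and
phylogenetic distance), between-sample phylogenetic turnover is measured by
the beta mean nearest taxon distance (betaMNTD) and standardized against a
tip-shuffle null into betaNTI.  Pairs with |betaNTI| > 2 are attributed to
selection (variable if > 2, homogeneous if < -2); the remaining pairs are
attributed to dispersal limitation (RC_bray > 0.95), homogenizing dispersal
(RC_bray < -0.95), or ecological drift (otherwise), where RC_bray is the
Raup-Crick metric computed on Bray-Curtis dissimilarities against a null
that reassembles each sample at fixed richness and fixed total abundance
from the regional pool.
"""

from __future__ import annotations

import logging
from itertools import combinations
from typing import Callable, Mapping

import numpy as np
import pandas as pd
from scipy.spatial.distance import squareform
from skbio import DistanceMatrix, TreeNode

from .data_model import CommunityTable, NullConfig, ValidationError, cophenetic_matrix

logger = logging.getLogger(__name__)

__all__ = [
    "estimate_niche_optima",
    "mantel_correlogram",
    "beta_mntd",
    "beta_nti",
    "raup_crick_bray",
    "classify_assembly",
    "classify_pairs",
    "process_contributions",
    "BNTI_THRESHOLD",
    "RC_THRESHOLD",
]

BNTI_THRESHOLD = 2.0
RC_THRESHOLD = 0.95


# ---------------------------------------------------------------------------
# Phylogenetic signal
# ---------------------------------------------------------------------------

def estimate_niche_optima(
    table: CommunityTable, env: Mapping | pd.Series
) -> pd.Series:
    """Abundance-weighted mean environment of each taxon's occurrences."""
    env = pd.Series(env).loc[table.sample_ids].to_numpy(dtype=float)
    counts = table.matrix()
    totals = counts.sum(axis=0)
    zero = totals == 0
    if zero.any():
        names = [t for t, z in zip(table.taxon_ids, zero) if z]
        logger.warning("excluding %d taxa with zero total abundance: %s", len(names), names)
    optima = np.full(totals.shape, np.nan)
    optima[~zero] = (counts.T @ env)[~zero] / totals[~zero]
    out = pd.Series(optima, index=table.taxon_ids, name="niche_optimum")
    return out.dropna()


def mantel_correlogram(
    d_trait: DistanceMatrix,
    d_phylo: DistanceMatrix,
    n_classes: int,
    config: NullConfig,
    equal_width: bool = False,
) -> pd.DataFrame:
    """Mantel correlogram of niche differences against phylogenetic distance.

    Phylogenetic distances are binned into ``n_classes`` contiguous classes
    (equal-frequency by default).  Per class, the Mantel statistic is the
    negated Pearson correlation between the trait-distance vector and the
    class-membership indicator, so that similar traits at short phylogenetic
    distance give a positive r in the first classes.  Two-tailed permutation
    p-values share one set of ``config.n_reps`` taxon permutations across
    classes and are adjusted progressively (Bonferroni along classes).
    Classes with fewer than 2 pairs are flagged and left without a
    statistic.
    """
    if set(d_trait.ids) != set(d_phylo.ids):
        raise ValidationError("trait and phylogeny matrices cover different taxa")
    d_phylo = d_phylo.filter(list(d_trait.ids))
    n = len(d_trait.ids)
    trait_mat = d_trait.data
    phylo_cond = squareform(d_phylo.data, checks=False)
    if equal_width:
        edges = np.linspace(phylo_cond.min(), phylo_cond.max(), n_classes + 1)
    else:
        edges = np.quantile(phylo_cond, np.linspace(0, 1, n_classes + 1))
    edges[0] -= 1e-12
    edges[-1] += 1e-12
    which = np.digitize(phylo_cond, edges[1:-1])

    indicators, centered_ind, ind_norm = [], [], []
    for k in range(n_classes):
        ind = (which == k).astype(float)
        indicators.append(ind)
        c = ind - ind.mean()
        centered_ind.append(c)
        ind_norm.append(np.sqrt((c**2).sum()))

    def class_r(cond: np.ndarray) -> np.ndarray:
        c = cond - cond.mean()
        norm = np.sqrt((c**2).sum())
        out = np.full(n_classes, np.nan)
        for k in range(n_classes):
            if indicators[k].sum() >= 2 and ind_norm[k] > 0 and norm > 0:
                out[k] = -(c @ centered_ind[k]) / (norm * ind_norm[k])
        return out

    obs = class_r(squareform(trait_mat, checks=False))
    rng = config.rng()
    exceed = np.zeros(n_classes)
    for _ in range(config.n_reps):
        perm = rng.permutation(n)
        perm_cond = squareform(trait_mat[np.ix_(perm, perm)], checks=False)
        r_perm = class_r(perm_cond)
        exceed += np.abs(r_perm) >= np.abs(obs)
    pvals = (exceed + 1.0) / (config.n_reps + 1.0)
    pvals[np.isnan(obs)] = np.nan
    rows = []
    for k in range(n_classes):
        n_pairs = int(indicators[k].sum())
        rows.append(
            {
                "class_low": edges[k],
                "class_high": edges[k + 1],
                "n_pairs": n_pairs,
                "mantel_r": obs[k],
                "p": pvals[k] if n_pairs >= 2 else np.nan,
                "p_adj": min(1.0, pvals[k] * (k + 1)) if n_pairs >= 2 else np.nan,
                "flagged": n_pairs < 2,
            }
        )
    return pd.DataFrame(rows)


# ---------------------------------------------------------------------------
# betaMNTD / betaNTI
# ---------------------------------------------------------------------------

def _weight_matrix(table: CommunityTable, taxa: list, abundance_weighted: bool) -> np.ndarray:
    counts = table.data.reindex(columns=taxa, fill_value=0.0).to_numpy(dtype=float)
    if (counts.sum(axis=1) == 0).any():
        raise ValidationError("empty sample in betaMNTD input")
    if abundance_weighted:
        return counts / counts.sum(axis=1, keepdims=True)
    presence = counts > 0
    return presence / presence.sum(axis=1, keepdims=True)


def _bmntd_from_weights(weights: np.ndarray, d: np.ndarray) -> np.ndarray:
    """betaMNTD matrix for a samples x taxa weight matrix over distances d.

    Uses min-distance profiles: with ``M[t, s] = min over taxa present in
    sample s of d(t, u)``, the one-directional sum is a single matrix
    product, and betaMNTD is the symmetrized average.
    """
    n_samples, _ = weights.shape
    profiles = np.empty((d.shape[0], n_samples))
    for s in range(n_samples):
        idx = np.flatnonzero(weights[s] > 0)
        profiles[:, s] = d[:, idx].min(axis=1)
    x = weights @ profiles
    return 0.5 * (x + x.T)


def beta_mntd(
    table: CommunityTable,
    tree: TreeNode,
    abundance_weighted: bool = True,
) -> DistanceMatrix:
    """Between-sample mean nearest taxon distance.

    For each taxon of one sample, the patristic distance to its closest
    relative in the other sample (0 when shared), weighted by relative
    abundance (or equally when unweighted), averaged over both directions.
    """
    dm = cophenetic_matrix(tree)
    taxa = [t for t in dm.ids if t in set(table.taxon_ids)]
    missing = set(table.data.columns[(table.matrix() > 0).any(axis=0)]) - set(dm.ids)
    if missing:
        raise ValidationError(f"taxa missing from tree: {sorted(missing)}")
    d = dm.filter(taxa).data
    weights = _weight_matrix(table, taxa, abundance_weighted)
    bmntd = _bmntd_from_weights(weights, d)
    np.fill_diagonal(bmntd, 0.0)
    return DistanceMatrix(bmntd, table.sample_ids)


def beta_nti(
    table: CommunityTable,
    tree: TreeNode,
    config: NullConfig,
    within_pair_union: bool = False,
) -> pd.DataFrame:
    """betaNTI z-scores for every sample pair.

    The null shuffles taxon identities across the tips of the whole supplied
    tree (the regional pool), preserving each sample's richness and
    abundances, with one shared shuffle per replicate.  With
    ``within_pair_union`` the shuffle is instead restricted, per pair, to
    the tips occupied by that pair's union of taxa (a more conservative
    null).  Pairs whose null has zero variance are left as NaN (flagged
    undefined).  Returns a square DataFrame (diagonal 0).
    """
    dm = cophenetic_matrix(tree)
    taxa = list(dm.ids)
    extra = set(t for t, any_ in
                zip(table.taxon_ids, (table.matrix() > 0).any(axis=0)) if any_) - set(taxa)
    if extra:
        raise ValidationError(f"taxa missing from tree: {sorted(extra)}")
    d = dm.data
    weights = _weight_matrix(table, taxa, config.abundance_weighted)
    obs = _bmntd_from_weights(weights, d)
    rng = config.rng()
    n_taxa = len(taxa)
    if within_pair_union:
        return _beta_nti_pair_union(table, weights, d, obs, config, rng)
    total = np.zeros_like(obs)
    total_sq = np.zeros_like(obs)
    for _ in range(config.n_reps):
        perm = rng.permutation(n_taxa)
        shuffled = np.empty_like(weights)
        shuffled[:, perm] = weights
        null = _bmntd_from_weights(shuffled, d)
        total += null
        total_sq += null**2
    mean = total / config.n_reps
    var = (total_sq - config.n_reps * mean**2) / (config.n_reps - 1)
    sd = np.sqrt(np.maximum(var, 0.0))
    with np.errstate(divide="ignore", invalid="ignore"):
        z = (obs - mean) / sd
    z[sd == 0] = np.nan
    np.fill_diagonal(z, 0.0)
    n_undef = int(np.sum(np.isnan(z[np.triu_indices_from(z, k=1)])))
    if n_undef:
        logger.warning("betaNTI undefined (zero null variance) for %d pair(s)", n_undef)
    return pd.DataFrame(z, index=table.sample_ids, columns=table.sample_ids)


def _beta_nti_pair_union(
    table: CommunityTable,
    weights: np.ndarray,
    d: np.ndarray,
    obs: np.ndarray,
    config: NullConfig,
    rng: np.random.Generator,
) -> pd.DataFrame:
    """Per-pair null restricted to the tips of the pair's union of taxa."""
    n_samples = weights.shape[0]
    z = np.zeros((n_samples, n_samples))
    for i, j in combinations(range(n_samples), 2):
        union = np.flatnonzero((weights[i] > 0) | (weights[j] > 0))
        w_pair = weights[[i, j]][:, union]
        d_sub = d[np.ix_(union, union)]
        null = np.empty(config.n_reps)
        for r in range(config.n_reps):
            perm = rng.permutation(union.size)
            shuffled = np.empty_like(w_pair)
            shuffled[:, perm] = w_pair
            null[r] = _bmntd_from_weights(shuffled, d_sub)[0, 1]
        sd = null.std(ddof=1)
        z[i, j] = z[j, i] = np.nan if sd == 0 else (obs[i, j] - null.mean()) / sd
    return pd.DataFrame(z, index=table.sample_ids, columns=table.sample_ids)


# ---------------------------------------------------------------------------
# Raup-Crick on Bray-Curtis
# ---------------------------------------------------------------------------

def raup_crick_bray(table: CommunityTable, config: NullConfig) -> pd.DataFrame:
    """Raup-Crick metric on Bray-Curtis dissimilarities, in [-1, 1].

    Each null replicate reassembles every sample from the regional pool:
    the sample's observed richness of taxa is drawn without replacement with
    probability proportional to occupancy (fraction of samples occupied),
    each drawn taxon receives one individual, and the remaining observed
    total abundance is allocated multinomially with probability proportional
    to regional relative abundance.  RC compares the observed Bray-Curtis of
    a pair with the null distribution: ``RC = 2 * (fraction of null values
    below the observed, ties at half weight) - 1``.
    """
    counts = table.matrix()
    n_samples, n_taxa = counts.shape
    if n_samples < 2:
        raise ValidationError("RC_bray needs >= 2 samples")
    occupancy = (counts > 0).sum(axis=0).astype(float)
    pool = np.flatnonzero(occupancy > 0)
    if pool.size < 2:
        raise ValidationError("regional pool has fewer than 2 taxa")
    regional = counts.sum(axis=0)
    richness = (counts > 0).sum(axis=1)
    totals = np.rint(counts.sum(axis=1)).astype(int)
    rng = config.rng()
    reps = config.n_reps

    nulls = np.zeros((n_samples, reps, n_taxa))
    log_occ = np.full(n_taxa, -np.inf)
    log_occ[pool] = np.log(occupancy[pool])
    for s in range(n_samples):
        k = int(richness[s])
        if k > pool.size:
            raise ValidationError("sample richer than the regional pool")
        keys = log_occ[np.newaxis, :] + rng.gumbel(size=(reps, n_taxa))
        chosen = np.argpartition(-keys, k - 1, axis=1)[:, :k]
        base = np.zeros((reps, n_taxa))
        np.put_along_axis(base, chosen, 1.0, axis=1)
        remaining = totals[s] - k
        if remaining > 0:
            pvals = base * regional[np.newaxis, :]
            pvals = np.where(pvals.sum(axis=1, keepdims=True) > 0,
                             pvals / pvals.sum(axis=1, keepdims=True), 0.0)
            extra = rng.multinomial(remaining, pvals)
            base += extra
        nulls[s] = base

    def braycurtis_rows(a: np.ndarray, b: np.ndarray) -> np.ndarray:
        return np.abs(a - b).sum(axis=-1) / (a + b).sum(axis=-1)

    rc = np.zeros((n_samples, n_samples))
    for i, j in combinations(range(n_samples), 2):
        obs = braycurtis_rows(counts[i], counts[j])
        null = braycurtis_rows(nulls[i], nulls[j])
        frac = (np.sum(null < obs) + 0.5 * np.sum(null == obs)) / reps
        rc[i, j] = rc[j, i] = 2.0 * (frac - 0.5)
    return pd.DataFrame(rc, index=table.sample_ids, columns=table.sample_ids)


# ---------------------------------------------------------------------------
# Classification and contributions
# ---------------------------------------------------------------------------

def classify_assembly(bnti: float, rc: float) -> str:
    """Map a (betaNTI, RC_bray) pair to its assembly-process label."""
    if not np.isfinite(bnti) or not np.isfinite(rc):
        raise ValidationError("classify_assembly requires finite inputs")
    if bnti > BNTI_THRESHOLD:
        return "variable_selection"
    if bnti < -BNTI_THRESHOLD:
        return "homogeneous_selection"
    if rc > RC_THRESHOLD:
        return "dispersal_limitation"
    if rc < -RC_THRESHOLD:
        return "homogenizing_dispersal"
    return "drift"


def classify_pairs(bnti: pd.DataFrame, rc: pd.DataFrame) -> pd.DataFrame:
    """Per-pair process labels; pairs with undefined betaNTI are excluded.

    Returns a frame with one row per unordered sample pair (columns
    ``sample_1, sample_2, beta_nti, rc_bray, process``); the number of
    excluded pairs is stored in ``.attrs['n_excluded']``.
    """
    ids = list(bnti.index)
    if list(rc.index) != ids:
        rc = rc.loc[ids, ids]
    rows, excluded = [], 0
    for s1, s2 in combinations(ids, 2):
        b = bnti.loc[s1, s2]
        r = rc.loc[s1, s2]
        if not np.isfinite(b) or not np.isfinite(r):
            excluded += 1
            continue
        rows.append(
            {
                "sample_1": s1,
                "sample_2": s2,
                "beta_nti": float(b),
                "rc_bray": float(r),
                "process": classify_assembly(float(b), float(r)),
            }
        )
    if excluded:
        logger.warning("excluded %d pair(s) with undefined betaNTI/RC", excluded)
    out = pd.DataFrame(rows)
    out.attrs["n_excluded"] = excluded
    return out


def process_contributions(
    results: pd.DataFrame,
    grouping: Callable[[str, str], str] | None = None,
) -> pd.DataFrame:
    """Percent of pairs per stratum carrying each process label.

    ``grouping`` maps a sample pair to its stratum (e.g., a site transition);
    when omitted all pairs form a single stratum.  Percentages per stratum
    sum to 100.
    """
    if results.empty:
        raise ValidationError("no classified pairs")
    frame = results.copy()
    if grouping is None:
        frame["stratum"] = "all"
    else:
        frame["stratum"] = [
            grouping(s1, s2) for s1, s2 in zip(frame["sample_1"], frame["sample_2"])
        ]
    frame = frame[frame["stratum"].notna()]
    if frame.empty:
        raise ValidationError("grouping left no pairs in any stratum")
    pct = (
        frame.groupby("stratum")["process"]
        .value_counts(normalize=True)
        .unstack(fill_value=0.0)
        * 100.0
    )
    from .synthetic import PROCESSES

    for proc in PROCESSES:
        if proc not in pct.columns:
            pct[proc] = 0.0
    return pct[list(PROCESSES)]
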