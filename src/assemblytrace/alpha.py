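"""Library-size normalization (SRS) and alpha diversity.

Taxonomic diversity (Shannon, Gini-Simpson) is delegated to scikit-bio.
Phylogenetic diversity (Faith's PD, ses.PD, NTI) is computed here with a
shared tip-shuffle null machinery: taxon labels are shuffled across the tips
of the whole supplied tree, which preserves each sample's richness and
abundances while randomizing phylogenetic relatedness.

Sign conventions follow the standard ones: negative ses.PD means less
lineage diversity than expected by chance; positive NTI means the taxa of a
sample are phylogenetically clustered (observed mean nearest-taxon distance
below the null mean).
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats
from skbio import TreeNode
from skbio.diversity.alpha import shannon as _shannon
from skbio.diversity.alpha import simpson as _simpson

from .data_model import CommunityTable, NullConfig, ValidationError, cophenetic_matrix

logger = logging.getLogger(__name__)

__all__ = [
    "srs_normalize",
    "taxonomic_alpha",
    "faith_pd",
    "ses_pd",
    "nti",
    "alpha_summary",
    "kruskal_dunn",
]


# ---------------------------------------------------------------------------
# Scaling with ranked subsampling
# ---------------------------------------------------------------------------

def srs_normalize(
    table: CommunityTable,
    c_min: int | None = None,
    seed: int = 0,
) -> CommunityTable:
    """Normalize every sample to exactly ``c_min`` counts by SRS.

    Counts are scaled by ``c_min / total``; integer parts are kept and the
    remaining deficit is distributed one unit at a time to the taxa with the
    largest fractional parts (ties broken by a seeded random draw among the
    tied taxa).  Samples whose total is below ``c_min`` are dropped with a
    warning.  ``c_min`` defaults to the minimum sample total.
    """
    totals = table.sample_totals()
    if c_min is None:
        c_min = int(totals.min())
        logger.info("SRS c_min defaulting to minimum sample total: %d", c_min)
    if c_min <= 0:
        raise ValidationError(f"c_min must be positive, got {c_min}")
    low = totals[totals < c_min].index.tolist()
    if low:
        logger.warning("dropping %d sample(s) below c_min=%d: %s", len(low), c_min, low)
    keep = [s for s in table.sample_ids if s not in set(low)]
    if not keep:
        raise ValidationError("no samples at or above c_min")
    data = table.data.loc[keep]
    rng = np.random.default_rng(seed)
    out = np.empty(data.shape, dtype=float)
    for i, (_, row) in enumerate(data.iterrows()):
        counts = row.to_numpy(dtype=float)
        scaled = counts * (c_min / counts.sum())
        floors = np.floor(scaled)
        frac = scaled - floors
        deficit = int(round(c_min - floors.sum()))
        alloc = floors
        if deficit > 0:
            # stable rank by descending fractional part; seeded tiebreak
            order = np.lexsort((rng.random(frac.size), -frac))
            alloc = floors.copy()
            alloc[order[:deficit]] += 1
        out[i] = alloc
    return CommunityTable(pd.DataFrame(out, index=data.index, columns=data.columns))


# ---------------------------------------------------------------------------
# Taxonomic alpha diversity
# ---------------------------------------------------------------------------

def taxonomic_alpha(table: CommunityTable) -> pd.DataFrame:
    """Shannon entropy (nats) and Gini-Simpson index per sample."""
    records = {}
    for sid, row in table.data.iterrows():
        counts = row.to_numpy(dtype=float)
        records[sid] = {
            "shannon": float(_shannon(counts, base=np.e)),
            "gini_simpson": float(_simpson(counts)),
        }
    return pd.DataFrame.from_dict(records, orient="index").loc[table.sample_ids]


# ---------------------------------------------------------------------------
# Phylogenetic alpha diversity
# ---------------------------------------------------------------------------

@dataclass
class _EdgeStructure:
    """Edge incidence of a tree over a fixed taxon order.

    ``incidence[e, t]`` is 1 when tip ``t`` descends from edge ``e``;
    ``lengths[e]`` is the branch length of edge ``e``.  Faith's PD of a
    presence mask m is then ``lengths @ (incidence @ m >= 1)`` (include-root
    convention) minus the stem edges above the MRCA when the root is
    excluded.
    """

    incidence: np.ndarray
    lengths: np.ndarray
    taxa: list

    @classmethod
    def from_tree(cls, tree: TreeNode, taxon_order: list) -> "_EdgeStructure":
        index = {t: i for i, t in enumerate(taxon_order)}
        rows, lengths = [], []
        tipsets: dict[int, np.ndarray] = {}
        for node in tree.postorder(include_self=True):
            if node.is_tip():
                mask = np.zeros(len(taxon_order), dtype=bool)
                if node.name not in index:
                    raise ValidationError(f"tree tip {node.name!r} not in taxon set")
                mask[index[node.name]] = True
            else:
                mask = np.zeros(len(taxon_order), dtype=bool)
                for child in node.children:
                    mask |= tipsets[id(child)]
            tipsets[id(node)] = mask
            if node.parent is not None:
                rows.append(mask)
                lengths.append(float(node.length or 0.0))
        return cls(
            incidence=np.asarray(rows, dtype=np.int16),
            lengths=np.asarray(lengths, dtype=float),
            taxa=list(taxon_order),
        )

    def pd_of_masks(self, masks: np.ndarray, include_root: bool) -> np.ndarray:
        """Faith's PD for each column of a boolean taxa x k mask matrix."""
        counts = self.incidence @ masks.astype(np.int16)  # edges x k
        pd_root = self.lengths @ (counts >= 1)
        if include_root:
            return pd_root
        n_present = masks.sum(axis=0)
        stem = self.lengths @ (counts == n_present[np.newaxis, :])
        return pd_root - stem


def _check_taxa_are_tips(table: CommunityTable, tree: TreeNode) -> None:
    tips = {t.name for t in tree.tips()}
    missing = [t for t in table.taxon_ids if t not in tips]
    if missing:
        raise ValidationError(f"table taxa missing from tree: {missing}")


def faith_pd(
    table: CommunityTable,
    tree: TreeNode,
    include_root: bool = True,
) -> pd.Series:
    """Faith's phylogenetic diversity per sample.

    PD is the total branch length of the minimal subtree spanning the
    sample's present taxa; with ``include_root`` (the default, matching the
    common convention) the path from that subtree to the tree root is
    included.
    """
    _check_taxa_are_tips(table, tree)
    taxa = [t.name for t in tree.tips()]
    struct = _EdgeStructure.from_tree(tree, taxa)
    presence = (
        table.data.reindex(columns=taxa, fill_value=0.0).to_numpy() > 0
    )
    if (presence.sum(axis=1) == 0).any():
        raise ValidationError("sample with zero present taxa")
    values = struct.pd_of_masks(presence.T, include_root)
    return pd.Series(values, index=table.sample_ids, name="faith_pd")


def ses_pd(
    table: CommunityTable,
    tree: TreeNode,
    config: NullConfig,
    include_root: bool = True,
) -> pd.DataFrame:
    """Standardized effect size of Faith's PD against a tip-shuffle null.

    For presence data, shuffling taxon labels across all tips makes the null
    community an equally rich, uniformly random subset of tips.  Returns a
    frame with observed PD, null mean/sd, the z-score ``ses_pd``, and an
    ``undefined`` flag set where the null has zero variance (e.g., a sample
    spanning every tip).
    """
    _check_taxa_are_tips(table, tree)
    taxa = [t.name for t in tree.tips()]
    struct = _EdgeStructure.from_tree(tree, taxa)
    n = len(taxa)
    presence = table.data.reindex(columns=taxa, fill_value=0.0).to_numpy() > 0
    richness = presence.sum(axis=1)
    if (richness < 2).any():
        raise ValidationError("ses.PD requires >= 2 taxa per sample")
    obs = struct.pd_of_masks(presence.T, include_root)
    rng = config.rng()
    rows = []
    for s, k in enumerate(richness):
        null_masks = np.zeros((n, config.n_reps), dtype=bool)
        for r in range(config.n_reps):
            null_masks[rng.permutation(n)[:k], r] = True
        null_pd = struct.pd_of_masks(null_masks, include_root)
        mean, sd = null_pd.mean(), null_pd.std(ddof=1)
        undefined = sd == 0
        ses = np.nan if undefined else (obs[s] - mean) / sd
        rows.append(
            {
                "pd_obs": obs[s],
                "null_mean": mean,
                "null_sd": sd,
                "ses_pd": ses,
                "undefined": bool(undefined),
            }
        )
    return pd.DataFrame(rows, index=table.sample_ids)


def _mntd_from_positions(
    d: np.ndarray, positions: np.ndarray, weights: np.ndarray
) -> float:
    sub = d[np.ix_(positions, positions)].copy()
    np.fill_diagonal(sub, np.inf)
    return float(weights @ sub.min(axis=1))


def nti(
    table: CommunityTable,
    tree: TreeNode,
    config: NullConfig,
) -> pd.DataFrame:
    """Nearest taxon index per sample.

    MNTD is the (abundance-weighted, per ``config.abundance_weighted``) mean
    distance of each present taxon to its nearest present neighbour;
    NTI = -(MNTD_obs - mean(MNTD_null)) / sd(MNTD_null) with a tip-shuffle
    null, so clustering gives NTI > 0.
    """
    _check_taxa_are_tips(table, tree)
    dm = cophenetic_matrix(tree)
    taxa = list(dm.ids)
    d = dm.data
    n = len(taxa)
    data = table.data.reindex(columns=taxa, fill_value=0.0)
    rng = config.rng()
    rows = []
    for sid, row in data.iterrows():
        counts = row.to_numpy(dtype=float)
        idx = np.flatnonzero(counts > 0)
        if idx.size < 2:
            raise ValidationError(f"NTI requires >= 2 taxa in sample {sid!r}")
        if config.abundance_weighted:
            weights = counts[idx] / counts[idx].sum()
        else:
            weights = np.full(idx.size, 1.0 / idx.size)
        obs = _mntd_from_positions(d, idx, weights)
        null = np.empty(config.n_reps)
        for r in range(config.n_reps):
            null[r] = _mntd_from_positions(d, rng.permutation(n)[: idx.size], weights)
        mean, sd = null.mean(), null.std(ddof=1)
        undefined = sd == 0
        value = np.nan if undefined else -(obs - mean) / sd
        rows.append(
            {
                "mntd_obs": obs,
                "null_mean": mean,
                "null_sd": sd,
                "nti": value,
                "undefined": bool(undefined),
            }
        )
    return pd.DataFrame(rows, index=table.sample_ids)


def alpha_summary(
    table: CommunityTable,
    tree: TreeNode | None = None,
    config: NullConfig | None = None,
    include_root: bool = True,
) -> pd.DataFrame:
    """One row per sample with all alpha metrics the pipeline reports."""
    out = taxonomic_alpha(table)
    if tree is not None:
        config = config or NullConfig()
        out["faith_pd"] = faith_pd(table, tree, include_root)
        out["ses_pd"] = ses_pd(table, tree, config, include_root)["ses_pd"]
        out["nti"] = nti(table, tree, config)["nti"]
    return out


# ---------------------------------------------------------------------------
# Group comparisons (thin reporting utility over standard statistics)
# ---------------------------------------------------------------------------

def kruskal_dunn(values: pd.Series, groups: pd.Series) -> dict:
    """Kruskal-Wallis test plus Dunn's post-hoc z-tests with BH adjustment."""
    from .ordination import bh_adjust

    aligned = pd.DataFrame({"value": values, "group": groups}).dropna()
    levels = sorted(aligned["group"].unique())
    if len(levels) < 2:
        raise ValidationError("need >= 2 groups")
    samples = [aligned.loc[aligned["group"] == g, "value"].to_numpy() for g in levels]
    h_stat, p_kw = stats.kruskal(*samples)

    ranks = stats.rankdata(aligned["value"].to_numpy())
    big_n = ranks.size
    _, tie_counts = np.unique(aligned["value"].to_numpy(), return_counts=True)
    tie_term = np.sum(tie_counts**3 - tie_counts) / (12.0 * (big_n - 1))
    mean_ranks = {
        g: ranks[(aligned["group"] == g).to_numpy()].mean() for g in levels
    }
    sizes = {g: int((aligned["group"] == g).sum()) for g in levels}
    rows = []
    for i, gi in enumerate(levels):
        for gj in levels[i + 1 :]:
            sigma = np.sqrt(
                (big_n * (big_n + 1) / 12.0 - tie_term)
                * (1.0 / sizes[gi] + 1.0 / sizes[gj])
            )
            z = (mean_ranks[gi] - mean_ranks[gj]) / sigma
            p = 2.0 * stats.norm.sf(abs(z))
            rows.append({"group_1": gi, "group_2": gj, "z": z, "p": p})
    dunn = pd.DataFrame(rows)
    dunn["p_adj"] = bh_adjust(dunn["p"].to_numpy())
    return {"kruskal_h": float(h_stat), "kruskal_p": float(p_kw), "dunn": dunn}
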