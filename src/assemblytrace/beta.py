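"""Pairwise dissimilarities, Baselga partition, SIMPER, and shared-taxon counts.

Bray-Curtis, Jaccard, and both UniFrac variants are delegated to scikit-bio;
the Jaccard-family turnover/nestedness partition, SIMPER decomposition, and
UpSet-style exclusive intersection counts are implemented here.
"""

from __future__ import annotations

from itertools import combinations
from typing import Mapping

import numpy as np
import pandas as pd
from skbio import DistanceMatrix, TreeNode
from skbio.diversity import beta_diversity

from .data_model import CommunityTable, ValidationError

__all__ = [
    "pairwise_dissimilarity",
    "unifrac",
    "baselga_partition",
    "simper",
    "shared_taxa_intersections",
]

_METRICS = ("bray_curtis", "jaccard")


def pairwise_dissimilarity(table: CommunityTable, metric: str) -> DistanceMatrix:
    """Bray-Curtis (abundance) or Jaccard (presence/absence) dissimilarities."""
    if metric not in _METRICS:
        raise ValidationError(f"unknown metric {metric!r}; expected one of {_METRICS}")
    if metric == "bray_curtis":
        return beta_diversity("braycurtis", table.matrix(), ids=table.sample_ids)
    presence = table.presence().to_numpy().astype(int)
    return beta_diversity("jaccard", presence, ids=table.sample_ids)


def unifrac(
    table: CommunityTable,
    tree: TreeNode,
    weighted: bool,
    normalized: bool = True,
) -> DistanceMatrix:
    """UniFrac distances between samples.

    Unweighted UniFrac is the fraction of branch length spanned by exactly
    one of the two samples; weighted UniFrac moves relative abundance along
    branches (normalized to [0, 1] by default).
    """
    counts = table.matrix()
    kwargs = dict(ids=table.sample_ids, taxa=table.taxon_ids, tree=tree)
    if weighted:
        return beta_diversity("weighted_unifrac", counts, normalized=normalized, **kwargs)
    return beta_diversity("unweighted_unifrac", counts, **kwargs)


def baselga_partition(table: CommunityTable) -> pd.DataFrame:
    """Partition pairwise Jaccard dissimilarity into turnover and nestedness.

    With a = shared taxa and b, c = taxa unique to either sample:
    ``beta_jac = (b + c) / (a + b + c)`` splits into the pure species
    replacement component ``beta_jtu = 2 min(b,c) / (a + 2 min(b,c))`` and
    the nestedness-resultant remainder ``beta_jne = beta_jac - beta_jtu``.
    Returns one row per unordered sample pair.
    """
    presence = table.presence().to_numpy()
    ids = table.sample_ids
    rows = []
    for i, j in combinations(range(len(ids)), 2):
        x, y = presence[i], presence[j]
        a = int(np.sum(x & y))
        b = int(np.sum(x & ~y))
        c = int(np.sum(~x & y))
        if a + b + c == 0:
            raise ValidationError(f"both samples empty: {ids[i]!r}, {ids[j]!r}")
        beta_jac = (b + c) / (a + b + c)
        m = min(b, c)
        beta_jtu = 2 * m / (a + 2 * m) if m > 0 else 0.0
        rows.append(
            {
                "sample_1": ids[i],
                "sample_2": ids[j],
                "beta_jac": beta_jac,
                "beta_jtu": beta_jtu,
                "beta_jne": beta_jac - beta_jtu,
            }
        )
    return pd.DataFrame(rows)


def simper(
    table: CommunityTable,
    groups: Mapping | pd.Series,
    relative: bool = True,
) -> dict[tuple, pd.DataFrame]:
    """Similarity-percentage decomposition of between-group Bray-Curtis.

    For each pair of groups, the contribution of taxon t averaged over all
    between-group sample pairs (x, y) is ``|x_t - y_t| / sum_i(x_i + y_i)``,
    so contributions sum exactly to the mean between-group Bray-Curtis
    dissimilarity.  Samples are converted to relative abundances first
    unless ``relative=False``.  Returns, per group pair, a frame ranked by
    contribution with percent and cumulative percent columns.
    """
    groups = pd.Series(groups)
    missing = [s for s in table.sample_ids if s not in groups.index]
    if missing:
        raise ValidationError(f"samples without group label: {missing}")
    data = table.relative() if relative else table.data
    levels = sorted(groups.loc[table.sample_ids].unique())
    out: dict[tuple, pd.DataFrame] = {}
    for g1, g2 in combinations(levels, 2):
        ids1 = [s for s in table.sample_ids if groups[s] == g1]
        ids2 = [s for s in table.sample_ids if groups[s] == g2]
        if not ids1 or not ids2:
            raise ValidationError(f"empty group among {g1!r}, {g2!r}")
        contrib = np.zeros(len(table.taxon_ids))
        n_pairs = 0
        for s1 in ids1:
            x = data.loc[s1].to_numpy()
            for s2 in ids2:
                y = data.loc[s2].to_numpy()
                denom = float(np.sum(x + y))
                contrib += np.abs(x - y) / denom
                n_pairs += 1
        contrib /= n_pairs
        total = contrib.sum()
        frame = pd.DataFrame(
            {"taxon": table.taxon_ids, "contribution": contrib}
        ).sort_values("contribution", ascending=False, kind="stable")
        frame["percent"] = 100.0 * frame["contribution"] / total if total > 0 else 0.0
        frame["cumulative_percent"] = frame["percent"].cumsum()
        frame.attrs["mean_dissimilarity"] = float(total)
        out[(g1, g2)] = frame.reset_index(drop=True)
    return out


def shared_taxa_intersections(
    table: CommunityTable,
    groups: Mapping | pd.Series,
) -> pd.DataFrame:
    """Exclusive taxon counts per subset of groups (UpSet semantics).

    A taxon belongs to a group when it is detected (abundance > 0) in any of
    the group's samples.  Each detected taxon is counted once, in the row of
    the exact set of groups containing it; rows also carry the fraction of
    each listed group's richness that the intersection represents.
    """
    groups = pd.Series(groups)
    missing = [s for s in table.sample_ids if s not in groups.index]
    if missing:
        raise ValidationError(f"samples without group label: {missing}")
    presence = table.presence()
    levels = sorted(groups.loc[table.sample_ids].unique())
    membership = {}
    for g in levels:
        ids = [s for s in table.sample_ids if groups[s] == g]
        membership[g] = presence.loc[ids].any(axis=0)
    member_frame = pd.DataFrame(membership)
    detected = member_frame.any(axis=1)
    richness = {g: int(member_frame[g].sum()) for g in levels}
    rows = []
    for r in range(1, len(levels) + 1):
        for subset in combinations(levels, r):
            in_subset = member_frame[list(subset)].all(axis=1)
            out_subset = ~member_frame[[g for g in levels if g not in subset]].any(axis=1) \
                if len(subset) < len(levels) else pd.Series(True, index=member_frame.index)
            count = int((in_subset & out_subset & detected).sum())
            rows.append(
                {
                    "groups": subset,
                    "exclusive_count": count,
                    "fractions": {
                        g: (count / richness[g] if richness[g] else np.nan)
                        for g in subset
                    },
                }
            )
    return pd.DataFrame(rows)
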