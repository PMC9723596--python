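"""Ordination and permutation statistics on distance matrices.

Principal coordinate analysis by classical scaling (negative eigenvalues
reported, not corrected), one- and two-way PERMANOVA on the Gower-centred
matrix with permutation of residuals under the reduced model for the crossed
design, PERMDISP with the imaginary-axis correction for non-Euclidean
distances, and Benjamini-Hochberg adjustment.
"""

from __future__ import annotations

from dataclasses import dataclass
from itertools import permutations as _permutations
from math import factorial

import numpy as np
import pandas as pd
from scipy import linalg, stats
from skbio import DistanceMatrix

from .data_model import ValidationError

__all__ = [
    "OrdinationResult",
    "pcoa",
    "permanova",
    "permdisp",
    "bh_adjust",
    "pairwise_permanova",
]


# ---------------------------------------------------------------------------
# PCoA
# ---------------------------------------------------------------------------

@dataclass
class OrdinationResult:
    """Classical-scaling ordination.

    ``coordinates`` holds samples x axes scores for positive-eigenvalue axes
    only; ``explained`` is the percent of the positive-eigenvalue total per
    axis; ``negative_mass`` is the percent of total absolute eigenvalue mass
    carried by negative eigenvalues (0 for Euclidean input).
    """

    coordinates: pd.DataFrame
    eigenvalues: np.ndarray
    explained: np.ndarray
    negative_mass: float


def _gower_center(d: np.ndarray) -> np.ndarray:
    a = -0.5 * d**2
    row = a.mean(axis=0, keepdims=True)
    col = a.mean(axis=1, keepdims=True)
    return a - row - col + a.mean()


def pcoa(dm: DistanceMatrix, eps: float = 1e-10) -> OrdinationResult:
    """Principal coordinate analysis of a distance matrix.

    Eigendecomposition of the double-centred squared-distance matrix; axes
    are ordered by decreasing eigenvalue and scaled by the square root of
    their eigenvalue.  Negative eigenvalues (non-Euclidean input) are not
    corrected; their mass is reported.
    """
    n = dm.shape[0]
    if n < 3:
        raise ValidationError("PCoA needs at least 3 samples")
    g = _gower_center(dm.data)
    eigvals, eigvecs = linalg.eigh(g)
    order = np.argsort(eigvals)[::-1]
    eigvals, eigvecs = eigvals[order], eigvecs[:, order]
    scale = max(abs(eigvals[0]), 1.0)
    pos = eigvals > eps * scale
    coords = eigvecs[:, pos] * np.sqrt(eigvals[pos])
    explained = 100.0 * eigvals[pos] / eigvals[pos].sum()
    neg = eigvals < -eps * scale
    negative_mass = 100.0 * np.abs(eigvals[neg]).sum() / np.abs(eigvals).sum()
    frame = pd.DataFrame(
        coords,
        index=list(dm.ids),
        columns=[f"PC{i + 1}" for i in range(coords.shape[1])],
    )
    return OrdinationResult(
        coordinates=frame,
        eigenvalues=eigvals,
        explained=explained,
        negative_mass=float(negative_mass),
    )


# ---------------------------------------------------------------------------
# PERMANOVA
# ---------------------------------------------------------------------------

def _hat(x: np.ndarray) -> np.ndarray:
    """Projection matrix onto the column space of x."""
    q, r = np.linalg.qr(x)
    rank = np.sum(np.abs(np.diag(r)) > 1e-10 * max(1.0, np.abs(r).max()))
    q = q[:, :rank]
    return q @ q.T


def _dummies(labels: pd.Series) -> np.ndarray:
    return pd.get_dummies(labels.astype(str)).to_numpy(dtype=float)


def _design_projections(design: pd.DataFrame, factors: list[str], interaction: bool):
    """Sequential (balanced-orthogonal) projections for each model term."""
    n = len(design)
    ones = np.ones((n, 1))
    mats = {"1": ones}
    h_prev = _hat(ones)
    terms, projections, dfs = [], [], []
    cum = [ones]
    for name in factors:
        cum.append(_dummies(design[name]))
        h_cur = _hat(np.hstack(cum))
        projections.append(h_cur - h_prev)
        dfs.append(int(round(np.trace(h_cur - h_prev))))
        terms.append(name)
        h_prev = h_cur
    if interaction:
        if len(factors) != 2:
            raise ValidationError("interaction requires exactly two factors")
        cells = design[factors[0]].astype(str) + "\x1f" + design[factors[1]].astype(str)
        expected = {
            f"{a}\x1f{b}"
            for a in design[factors[0]].astype(str).unique()
            for b in design[factors[1]].astype(str).unique()
        }
        missing = sorted(expected - set(cells))
        if missing:
            pretty = [m.replace("\x1f", " x ") for m in missing]
            raise ValidationError(f"empty cell(s) in crossed design: {pretty}")
        cum.append(_dummies(cells))
        h_cur = _hat(np.hstack(cum))
        projections.append(h_cur - h_prev)
        dfs.append(int(round(np.trace(h_cur - h_prev))))
        terms.append(f"{factors[0]} x {factors[1]}")
        h_prev = h_cur
    residual_proj = np.eye(n) - h_prev
    return terms, projections, dfs, residual_proj


def permanova(
    dm: DistanceMatrix,
    design: pd.DataFrame,
    factors: list[str] | str,
    interaction: bool = False,
    n_perm: int = 999,
    seed: int = 0,
    exact_threshold: int = 10_000,
) -> pd.DataFrame:
    """Distance-based permutational multivariate analysis of variance.

    Sums of squares are traces of term projections applied to the
    Gower-centred matrix (sequential terms; orthogonal, hence
    order-independent, in balanced designs).  One-way p-values come from raw
    permutation of observations — or from exhaustive enumeration of all
    label arrangements when their number is at most ``exact_threshold``.
    In the two-way (optionally crossed) design each term is tested by
    permutation of residuals under the reduced model excluding that term.

    Returns a Table-1-style frame: one row per term plus residual and total,
    with degrees of freedom, SS, pseudo-F, p, and square-root SS.
    """
    if isinstance(factors, str):
        factors = [factors]
    ids = list(dm.ids)
    design = design.loc[ids]
    for f in factors:
        if design[f].nunique() < 2:
            raise ValidationError(f"factor {f!r} needs >= 2 levels")
    n = len(ids)
    g = _gower_center(dm.data)
    terms, projections, dfs, resid_proj = _design_projections(design, factors, interaction)
    df_res = int(round(np.trace(resid_proj)))
    if df_res <= 0:
        raise ValidationError("no residual degrees of freedom")

    def term_stats(gmat: np.ndarray) -> tuple[np.ndarray, float]:
        ss_terms = np.array([np.sum(p * gmat) for p in projections])
        ss_res = float(np.sum(resid_proj * gmat))
        return ss_terms, ss_res

    ss_terms, ss_res = term_stats(g)
    ss_total = float(np.trace(g))
    f_obs = (ss_terms / np.array(dfs)) / (ss_res / df_res)

    rng = np.random.default_rng(seed)
    pvals = np.empty(len(terms))
    one_way = len(terms) == 1
    if one_way:
        labels = design[factors[0]].to_numpy()
        if factorial(n) <= exact_threshold:
            count = 0
            n_arr = 0
            for perm in _permutations(range(n)):
                idx = np.array(perm)
                gp = g[np.ix_(idx, idx)]
                ss_t, ss_r = term_stats(gp)
                f_perm = (ss_t[0] / dfs[0]) / (ss_r / df_res)
                count += f_perm >= f_obs[0] - 1e-12
                n_arr += 1
            pvals[0] = count / n_arr
        else:
            count = 0
            for _ in range(n_perm):
                idx = rng.permutation(n)
                gp = g[np.ix_(idx, idx)]
                ss_t, ss_r = term_stats(gp)
                f_perm = (ss_t[0] / dfs[0]) / (ss_r / df_res)
                count += f_perm >= f_obs[0]
            pvals[0] = (count + 1.0) / (n_perm + 1.0)
    else:
        # permutation of residuals under the reduced model, per term
        for t_idx in range(len(terms)):
            reduced_keep = [k for k in range(len(terms)) if k != t_idx]
            h_red = sum(projections[k] for k in reduced_keep) + _hat(np.ones((n, 1)))
            r_red = np.eye(n) - h_red
            g_res = r_red @ g @ r_red
            count = 0
            for _ in range(n_perm):
                idx = rng.permutation(n)
                gp = g_res[np.ix_(idx, idx)]
                ss_t, ss_r = term_stats(gp)
                f_perm = (ss_t[t_idx] / dfs[t_idx]) / (ss_r / df_res)
                count += f_perm >= f_obs[t_idx]
            pvals[t_idx] = (count + 1.0) / (n_perm + 1.0)

    rows = []
    for k, term in enumerate(terms):
        rows.append(
            {
                "term": term,
                "df": dfs[k],
                "ss": ss_terms[k],
                "pseudo_f": f_obs[k],
                "p": pvals[k],
                "sqrt_ss": np.sqrt(max(ss_terms[k], 0.0)),
            }
        )
    rows.append(
        {
            "term": "residual",
            "df": df_res,
            "ss": ss_res,
            "pseudo_f": np.nan,
            "p": np.nan,
            "sqrt_ss": np.sqrt(max(ss_res, 0.0)),
        }
    )
    rows.append(
        {
            "term": "total",
            "df": n - 1,
            "ss": ss_total,
            "pseudo_f": np.nan,
            "p": np.nan,
            "sqrt_ss": np.sqrt(max(ss_total, 0.0)),
        }
    )
    return pd.DataFrame(rows).set_index("term")


def pairwise_permanova(
    dm: DistanceMatrix,
    design: pd.DataFrame,
    factor: str,
    n_perm: int = 999,
    seed: int = 0,
) -> pd.DataFrame:
    """Post-hoc one-way PERMANOVAs between all level pairs, BH-adjusted."""
    from itertools import combinations

    ids = list(dm.ids)
    design = design.loc[ids]
    levels = sorted(design[factor].astype(str).unique())
    rows = []
    for a, b in combinations(levels, 2):
        keep = [s for s in ids if str(design.loc[s, factor]) in (a, b)]
        sub = dm.filter(keep)
        res = permanova(sub, design, factor, n_perm=n_perm, seed=seed)
        rows.append(
            {
                "level_1": a,
                "level_2": b,
                "pseudo_f": res.loc[factor, "pseudo_f"],
                "p": res.loc[factor, "p"],
            }
        )
    out = pd.DataFrame(rows)
    out["p_adj"] = bh_adjust(out["p"].to_numpy())
    return out


# ---------------------------------------------------------------------------
# PERMDISP
# ---------------------------------------------------------------------------

def _centroid_distances(dm: DistanceMatrix, groups: pd.Series) -> np.ndarray:
    """Distance of each sample to its group centroid in full PCoA space.

    Negative eigenvalues contribute imaginary axes; squared distances on
    those axes are subtracted (the standard correction for non-Euclidean
    dissimilarities), and any slightly negative result is clamped to 0.
    """
    g = _gower_center(dm.data)
    eigvals, eigvecs = linalg.eigh(g)
    scale = max(np.abs(eigvals).max(), 1.0)
    keep = np.abs(eigvals) > 1e-10 * scale
    eigvals, eigvecs = eigvals[keep], eigvecs[:, keep]
    coords = eigvecs * np.sqrt(np.abs(eigvals))
    is_real = eigvals > 0
    labels = groups.to_numpy()
    dist2 = np.empty(len(labels))
    for level in np.unique(labels):
        mask = labels == level
        centroid = coords[mask].mean(axis=0)
        delta2 = (coords[mask] - centroid) ** 2
        dist2[mask] = delta2[:, is_real].sum(axis=1) - delta2[:, ~is_real].sum(axis=1)
    return np.sqrt(np.maximum(dist2, 0.0))


def permdisp(
    dm: DistanceMatrix,
    groups: pd.Series,
    n_perm: int = 999,
    seed: int = 0,
) -> dict:
    """Homogeneity of multivariate dispersions (centroid version).

    One-way ANOVA F on sample-to-centroid distances in PCoA space, with a
    permutation p-value obtained by shuffling group labels.
    """
    groups = pd.Series(groups).loc[list(dm.ids)]
    sizes = groups.value_counts()
    if len(sizes) < 2:
        raise ValidationError("PERMDISP needs >= 2 groups")
    if (sizes < 2).any():
        small = sizes[sizes < 2].index.tolist()
        raise ValidationError(f"group(s) of size 1: {small}")
    dists = _centroid_distances(dm, groups)
    labels = groups.to_numpy()

    def anova_f(values: np.ndarray, labs: np.ndarray) -> float:
        grand = values.mean()
        ss_between = ss_within = 0.0
        for level in np.unique(labs):
            grp = values[labs == level]
            ss_between += grp.size * (grp.mean() - grand) ** 2
            ss_within += np.sum((grp - grp.mean()) ** 2)
        df_b = len(np.unique(labs)) - 1
        df_w = values.size - len(np.unique(labs))
        if ss_within == 0:
            return np.inf if ss_between > 0 else 0.0
        return (ss_between / df_b) / (ss_within / df_w)

    f_obs = anova_f(dists, labels)
    rng = np.random.default_rng(seed)
    count = 0
    for _ in range(n_perm):
        count += anova_f(dists, rng.permutation(labels)) >= f_obs
    p = (count + 1.0) / (n_perm + 1.0)
    return {"f": float(f_obs), "p": float(p), "distances": pd.Series(dists, index=dm.ids)}


# ---------------------------------------------------------------------------
# Multiple testing
# ---------------------------------------------------------------------------

def bh_adjust(pvalues) -> np.ndarray:
    """Benjamini-Hochberg step-up adjusted p-values, in input order."""
    p = np.asarray(pvalues, dtype=float)
    if p.ndim != 1:
        raise ValidationError("pvalues must be one-dimensional")
    if np.any((p < 0) | (p > 1) | ~np.isfinite(p)):
        raise ValidationError("p-values must lie in [0, 1]")
    m = p.size
    order = np.argsort(p, kind="stable")
    ranked = p[order] * m / np.arange(1, m + 1)
    adjusted = np.minimum.accumulate(ranked[::-1])[::-1]
    out = np.empty(m)
    out[order] = np.minimum(adjusted, 1.0)
    return out
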