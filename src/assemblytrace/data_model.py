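"""Core containers and I/O for community tables, phylogenies, and metadata.

The canonical in-memory form of a community table is a pandas DataFrame with
samples as rows and taxa (ASVs) as columns; phylogenies are scikit-bio
``TreeNode`` objects and pairwise dissimilarities are scikit-bio
``DistanceMatrix`` objects.  Everything downstream (diversity, null models,
ordination statistics) consumes these validated objects.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd
from skbio import DistanceMatrix, TreeNode

logger = logging.getLogger(__name__)

__all__ = [
    "ValidationError",
    "CommunityTable",
    "NullConfig",
    "METADATA_COLUMNS",
    "DEFAULT_VOCABULARIES",
    "read_community_table",
    "write_community_table",
    "read_newick",
    "write_newick",
    "read_metadata",
    "validate_metadata",
    "align_inputs",
]


class ValidationError(ValueError):
    """Raised when an input violates a structural invariant."""


# Factor vocabularies of the gradient-transfer incubation design: three
# substrata plus two pooled water fractions, four sites along the salinity
# gradient, and the transferred vs. stationary cage.  Extensible via the
# ``vocabularies`` argument of :func:`validate_metadata`.
DEFAULT_VOCABULARIES: dict[str, tuple[str, ...]] = {
    "sample_type": ("HDPE", "TW", "Wood", "Water3", "Water02"),
    "site": ("Bremen", "Brake", "Bremerhaven", "Helgoland"),
    "cage": ("Transfer", "Stationary"),
}

METADATA_COLUMNS = ("sample_id", "sample_type", "site", "cage", "replicate")


@dataclass(frozen=True)
class NullConfig:
    """Configuration of a permutation null model.

    Parameters
    ----------
    n_reps : int
        Number of null randomizations (default 999).
    seed : int
        Seed for the random number generator; identical seed and inputs give
        identical outputs.
    abundance_weighted : bool
        Whether nearest-taxon statistics weight taxa by relative abundance.
    """

    n_reps: int = 999
    seed: int = 0
    abundance_weighted: bool = True

    def __post_init__(self) -> None:
        if self.n_reps < 1:
            raise ValidationError(f"n_reps must be >= 1, got {self.n_reps}")

    def rng(self) -> np.random.Generator:
        return np.random.default_rng(self.seed)


class CommunityTable:
    """Sample x taxon matrix of non-negative abundances.

    Wraps a pandas DataFrame (samples as rows).  Construction validates that
    identifiers are unique, entries are non-negative and finite, and that no
    retained sample is empty.  Taxa that are absent from every sample are
    dropped (their count is logged) because they carry no information and
    distort presence/absence metrics.
    """

    def __init__(
        self,
        data: pd.DataFrame,
        *,
        drop_empty_samples: bool = False,
        keep_empty_taxa: bool = False,
    ) -> None:
        if data.index.has_duplicates:
            dups = data.index[data.index.duplicated()].unique().tolist()
            raise ValidationError(f"duplicate sample identifiers: {dups}")
        if data.columns.has_duplicates:
            dups = data.columns[data.columns.duplicated()].unique().tolist()
            raise ValidationError(f"duplicate taxon identifiers: {dups}")
        values = data.to_numpy(dtype=float)
        if not np.isfinite(values).all():
            raise ValidationError("community table contains non-finite entries")
        if (values < 0).any():
            bad = data.columns[(values < 0).any(axis=0)].tolist()
            raise ValidationError(f"negative abundances in taxa: {bad}")
        empty = values.sum(axis=1) == 0
        if empty.any():
            names = data.index[empty].tolist()
            if drop_empty_samples:
                logger.warning("dropping %d empty sample(s): %s", len(names), names)
                data = data.loc[~empty]
            else:
                raise ValidationError(f"samples with zero total abundance: {names}")
        if not keep_empty_taxa:
            dead = data.to_numpy(dtype=float).sum(axis=0) == 0
            if dead.any():
                logger.warning("dropping %d taxa absent from all samples", int(dead.sum()))
                data = data.loc[:, ~dead]
        self._data = data.astype(float)

    # -- accessors ---------------------------------------------------------
    @property
    def data(self) -> pd.DataFrame:
        return self._data

    @property
    def sample_ids(self) -> list:
        return list(self._data.index)

    @property
    def taxon_ids(self) -> list:
        return list(self._data.columns)

    @property
    def shape(self) -> tuple[int, int]:
        return self._data.shape

    def matrix(self) -> np.ndarray:
        return self._data.to_numpy(dtype=float)

    def sample_totals(self) -> pd.Series:
        return self._data.sum(axis=1)

    def relative(self) -> pd.DataFrame:
        """Within-sample relative abundances (rows sum to 1)."""
        return self._data.div(self._data.sum(axis=1), axis=0)

    def presence(self) -> pd.DataFrame:
        return self._data > 0

    def select_samples(self, ids: Sequence) -> "CommunityTable":
        missing = [s for s in ids if s not in self._data.index]
        if missing:
            raise ValidationError(f"unknown sample identifiers: {missing}")
        return CommunityTable(self._data.loc[list(ids)])

    def __eq__(self, other: object) -> bool:
        if not isinstance(other, CommunityTable):
            return NotImplemented
        return self._data.equals(other._data)

    def __repr__(self) -> str:
        n, m = self._data.shape
        return f"CommunityTable({n} samples x {m} taxa)"


# ---------------------------------------------------------------------------
# Readers / writers
# ---------------------------------------------------------------------------

def read_community_table(
    path: str | Path,
    *,
    samples_as_rows: bool | None = None,
    drop_empty_samples: bool = False,
) -> CommunityTable:
    """Read a TSV community table (plain or dense BIOM-style).

    The file must have a header row and a first column of identifiers.  Dense
    BIOM-style exports (first line ``# Constructed from biom file``, row ids =
    taxa) are recognized and transposed to the canonical samples-as-rows
    orientation.  With ``samples_as_rows=None`` the orientation is taken as
    samples-as-rows unless the BIOM marker line is present.
    """
    path = Path(path)
    with open(path) as fh:
        first = fh.readline()
        biom_style = first.startswith("#") and "biom" in first.lower()
        skip = 1 if biom_style else 0
        header = (fh.readline() if biom_style else first).rstrip("\n").split("\t")[1:]
    if len(header) != len(set(header)):
        dups = sorted({h for h in header if header.count(h) > 1})
        raise ValidationError(f"duplicate column identifiers in {path.name}: {dups}")
    df = pd.read_csv(path, sep="\t", index_col=0, skiprows=skip)
    df.index = df.index.astype(str)
    df.columns = df.columns.astype(str)
    if df.index.has_duplicates:
        dups = df.index[df.index.duplicated()].unique().tolist()
        raise ValidationError(f"duplicate row identifiers in {path.name}: {dups}")
    if df.columns.has_duplicates:
        dups = df.columns[df.columns.duplicated()].unique().tolist()
        raise ValidationError(f"duplicate column identifiers in {path.name}: {dups}")
    if samples_as_rows is None:
        samples_as_rows = not biom_style
    if not samples_as_rows:
        df = df.T
    return CommunityTable(df, drop_empty_samples=drop_empty_samples)


def write_community_table(table: CommunityTable, path: str | Path) -> None:
    df = table.data
    # store counts as integers when exact
    if np.allclose(df.to_numpy(), np.round(df.to_numpy())):
        df = df.round().astype(int)
    df.to_csv(path, sep="\t", index_label="sample_id")


def read_newick(path_or_str: str | Path) -> TreeNode:
    """Read a rooted Newick tree with branch lengths.

    Every edge except the root's must carry an explicit branch length; a
    missing length is an error rather than an imputed 0 or 1, because every
    phylogenetic metric downstream sums branch lengths.  A missing root
    length is taken as 0 (the root has no edge).
    """
    src = str(path_or_str)
    if "(" in src or src.rstrip().endswith(";"):
        import io

        tree = TreeNode.read(io.StringIO(src))
    else:
        tree = TreeNode.read(src)
    if tree.length is None:
        tree.length = 0.0
    missing = [
        (n.name or "<unnamed internal>")
        for n in tree.traverse(include_self=False)
        if n.length is None
    ]
    if missing:
        raise ValidationError(f"edges without branch length: {missing}")
    neg = [n.name for n in tree.traverse() if n.length is not None and n.length < 0]
    if neg:
        raise ValidationError(f"negative branch lengths at: {neg}")
    tips = [t.name for t in tree.tips()]
    if len(tips) != len(set(tips)):
        dups = sorted({t for t in tips if tips.count(t) > 1})
        raise ValidationError(f"duplicate tip labels in tree: {dups}")
    return tree


def write_newick(tree: TreeNode, path: str | Path) -> None:
    tree.write(str(path))


def read_metadata(
    path: str | Path,
    *,
    vocabularies: Mapping[str, Iterable[str]] | None = None,
) -> pd.DataFrame:
    df = pd.read_csv(path, sep="\t", dtype={"sample_id": str})
    return validate_metadata(df, vocabularies=vocabularies)


def validate_metadata(
    meta: pd.DataFrame,
    *,
    vocabularies: Mapping[str, Iterable[str]] | None = None,
) -> pd.DataFrame:
    """Validate the sample metadata table and index it by sample_id."""
    vocab = dict(DEFAULT_VOCABULARIES)
    if vocabularies:
        vocab.update({k: tuple(v) for k, v in vocabularies.items()})
    meta = meta.copy()
    if meta.index.name == "sample_id":
        meta = meta.reset_index()
    missing_cols = [c for c in METADATA_COLUMNS if c not in meta.columns]
    if missing_cols:
        raise ValidationError(f"metadata missing required columns: {missing_cols}")
    if meta["sample_id"].duplicated().any():
        dups = meta.loc[meta["sample_id"].duplicated(), "sample_id"].tolist()
        raise ValidationError(f"duplicate sample_id in metadata: {dups}")
    for col, levels in vocab.items():
        bad = sorted(set(meta[col].astype(str)) - set(levels))
        if bad:
            raise ValidationError(
                f"metadata column {col!r} has levels outside the vocabulary: {bad}"
            )
    return meta.set_index("sample_id")


# ---------------------------------------------------------------------------
# Alignment
# ---------------------------------------------------------------------------

@dataclass
class AlignedInputs:
    table: CommunityTable
    tree: TreeNode
    meta: pd.DataFrame
    dropped_taxa: list = field(default_factory=list)
    pruned_tips: list = field(default_factory=list)


def align_inputs(
    table: CommunityTable,
    tree: TreeNode | None = None,
    meta: pd.DataFrame | None = None,
    *,
    strict: bool = False,
) -> AlignedInputs:
    """Harmonize a community table with a phylogeny and metadata.

    In strict mode any mismatch between table taxa and tree tips, or between
    table samples and metadata rows, raises a :class:`ValidationError` naming
    the offending identifiers.  Otherwise tree tips absent from the table are
    pruned, table taxa absent from the tree are dropped, and both events are
    logged; samples without metadata always raise.
    """
    dropped_taxa: list = []
    pruned_tips: list = []
    if tree is not None:
        tip_names = {t.name for t in tree.tips()}
        table_taxa = set(table.taxon_ids)
        extra_in_table = sorted(table_taxa - tip_names)
        extra_in_tree = sorted(tip_names - table_taxa)
        if strict and (extra_in_table or extra_in_tree):
            raise ValidationError(
                "table/tree mismatch: "
                f"taxa missing from tree {extra_in_table}; "
                f"tips missing from table {extra_in_tree}"
            )
        if extra_in_table:
            logger.warning(
                "dropping %d table taxa absent from the tree: %s",
                len(extra_in_table), extra_in_table,
            )
            keep = [t for t in table.taxon_ids if t in tip_names]
            table = CommunityTable(table.data[keep])
            dropped_taxa = extra_in_table
        if extra_in_tree:
            logger.warning(
                "pruning %d tree tips absent from the table: %s",
                len(extra_in_tree), extra_in_tree,
            )
            tree = tree.shear(set(table.taxon_ids))
            pruned_tips = extra_in_tree
    if meta is not None:
        missing = [s for s in table.sample_ids if s not in meta.index]
        if missing:
            raise ValidationError(f"samples missing from metadata: {missing}")
        meta = meta.loc[table.sample_ids]
    return AlignedInputs(
        table=table,
        tree=tree,
        meta=meta,
        dropped_taxa=dropped_taxa,
        pruned_tips=pruned_tips,
    )


def cophenetic_matrix(tree: TreeNode, taxon_order: Sequence | None = None) -> DistanceMatrix:
    """Tip-to-tip patristic distance matrix, optionally in a given taxon order."""
    dm = tree.tip_tip_distances()
    if taxon_order is not None:
        dm = dm.filter(list(taxon_order))
    return dm
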