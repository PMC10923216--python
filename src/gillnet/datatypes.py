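"""Core domain objects shared by every stage of the pipeline.

The central container is the :class:`FeatureTable` — a features x samples
matrix of nonnegative numbers (integer transcript counts for raw tables,
per-sample proportions after normalization to relative activity).  Around it
sit a taxonomy map, per-sample metadata, a rooted phylogeny over the features,
and a symmetric sample-by-sample distance matrix.
"""
from __future__ import annotations

import dataclasses
import json
from typing import Iterable, Sequence

import dendropy
import numpy as np
import pandas as pd

CANONICAL_RANKS = ("kingdom", "phylum", "class", "order", "family", "genus", "species")
UNASSIGNED = "unassigned"
WATER_TYPES = ("Freshwater", "Saltwater")


class GillnetError(Exception):
    """Base class for all package errors."""


class DataValidationError(GillnetError):
    """An input object violates a structural invariant."""


def _check_unique(labels: Sequence, what: str) -> None:
    seen = set()
    for lab in labels:
        if lab in seen:
            raise DataValidationError(f"duplicate {what} identifier: {lab!r}")
        seen.add(lab)


class FeatureTable:
    """Feature (ASV/taxon) x sample table of nonnegative counts or proportions.

    Parameters
    ----------
    data:
        DataFrame with features as rows and samples as columns.
    is_relative:
        True once every sample column has been normalized to sum to one
        (all-zero columns are tolerated and listed in :attr:`empty_samples`).
    """

    def __init__(self, data: pd.DataFrame, is_relative: bool = False):
        if not isinstance(data, pd.DataFrame):
            data = pd.DataFrame(data)
        _check_unique(list(data.index), "feature")
        _check_unique(list(data.columns), "sample")
        values = data.to_numpy(dtype=float, copy=False)
        if not np.all(np.isfinite(values)):
            bad = np.argwhere(~np.isfinite(values))[0]
            raise DataValidationError(
                f"non-finite value at feature {data.index[bad[0]]!r}, "
                f"sample {data.columns[bad[1]]!r}"
            )
        if (values < 0).any():
            bad = np.argwhere(values < 0)[0]
            raise DataValidationError(
                f"negative value at feature {data.index[bad[0]]!r}, "
                f"sample {data.columns[bad[1]]!r}"
            )
        self.data = data.astype(float)
        self.is_relative = bool(is_relative)
        if self.is_relative:
            totals = values.sum(axis=0)
            bad = (np.abs(totals - 1.0) > 1e-9) & (totals != 0.0)
            if bad.any():
                raise DataValidationError(
                    "relative table columns must sum to 1 (or be empty); offending "
                    f"samples: {list(np.asarray(data.columns)[bad])[:5]}"
                )

    # -- basic views ---------------------------------------------------
    @property
    def feature_ids(self) -> list:
        return list(self.data.index)

    @property
    def sample_ids(self) -> list:
        return list(self.data.columns)

    @property
    def values(self) -> np.ndarray:
        return self.data.to_numpy(dtype=float)

    @property
    def n_features(self) -> int:
        return self.data.shape[0]

    @property
    def n_samples(self) -> int:
        return self.data.shape[1]

    @property
    def empty_samples(self) -> list:
        totals = self.data.sum(axis=0)
        return list(totals.index[totals == 0.0])

    def sample_totals(self) -> pd.Series:
        return self.data.sum(axis=0)

    def copy(self) -> "FeatureTable":
        return FeatureTable(self.data.copy(), is_relative=self.is_relative)

    def select(self, features: Iterable | None = None,
               samples: Iterable | None = None) -> "FeatureTable":
        data = self.data
        if features is not None:
            data = data.loc[list(features)]
        if samples is not None:
            data = data[list(samples)]
        return FeatureTable(data, is_relative=self.is_relative)

    def __repr__(self) -> str:  # pragma: no cover - cosmetic
        kind = "relative" if self.is_relative else "count"
        return (f"<FeatureTable {self.n_features} features x "
                f"{self.n_samples} samples ({kind})>")


class TaxonomyMap:
    """Feature -> ranked lineage (kingdom ... species).

    Missing or empty rank cells are stored as the explicit ``"unassigned"``
    token so that downstream aggregation always has a bucket to fall into.
    """

    def __init__(self, df: pd.DataFrame):
        _check_unique(list(df.index), "feature")
        unknown = [c for c in df.columns if c.lower() not in CANONICAL_RANKS]
        if unknown:
            raise DataValidationError(f"unknown taxonomy rank header(s): {unknown}")
        df = df.copy()
        df.columns = [c.lower() for c in df.columns]
        for rank in CANONICAL_RANKS:
            if rank not in df.columns:
                df[rank] = UNASSIGNED
        df = df[list(CANONICAL_RANKS)]
        df = df.fillna(UNASSIGNED)
        df = df.map(lambda v: UNASSIGNED if str(v).strip() == "" else str(v))
        self.df = df

    @property
    def feature_ids(self) -> list:
        return list(self.df.index)

    def lineage(self, feature_id) -> dict:
        if feature_id not in self.df.index:
            raise KeyError(feature_id)
        return self.df.loc[feature_id].to_dict()

    def rank_names(self, feature_ids: Sequence, rank: str) -> np.ndarray:
        """Names at ``rank`` for each feature; unknown features -> unassigned."""
        rank = rank.lower()
        if rank not in CANONICAL_RANKS:
            raise DataValidationError(f"unknown rank: {rank!r}")
        col = self.df[rank]
        return np.array([col.get(f, UNASSIGNED) for f in feature_ids], dtype=object)


class SampleMetadata:
    """Per-sample metadata: site (community), water type, environment, fish morphometrics.

    Missing values stay missing (NaN); nothing is imputed.  Operations that
    need a variable are expected to drop incomplete samples and say so.
    """

    NUMERIC_COLUMNS = ("latitude", "longitude", "air_temperature",
                       "water_temperature", "salinity", "pH", "chlorophyll_a",
                       "O2_concentration", "weight", "fork_length")

    def __init__(self, df: pd.DataFrame):
        _check_unique(list(df.index), "sample")
        if "community" not in df.columns:
            raise DataValidationError("metadata must contain a 'community' column")
        df = df.copy()
        if df["community"].isna().any():
            bad = list(df.index[df["community"].isna()])
            raise DataValidationError(f"samples without a community: {bad[:5]}")
        if "water_type" in df.columns:
            vals = df["water_type"].dropna()
            bad = sorted(set(vals) - set(WATER_TYPES))
            if bad:
                raise DataValidationError(
                    f"water_type must be one of {WATER_TYPES}; found {bad}")
        for col in self.NUMERIC_COLUMNS:
            if col in df.columns:
                df[col] = pd.to_numeric(df[col], errors="raise")
        self.df = df

    @property
    def sample_ids(self) -> list:
        return list(self.df.index)

    @property
    def communities(self) -> pd.Series:
        return self.df["community"]

    def select(self, samples: Iterable) -> "SampleMetadata":
        return SampleMetadata(self.df.loc[list(samples)])


class PhyloTree:
    """Rooted phylogeny with branch lengths; leaves are feature identifiers.

    Thin wrapper over a :class:`dendropy.Tree` adding the invariants the
    pipeline relies on (unique leaf labels, finite nonnegative branch
    lengths) and fast branch/leaf incidence extraction for UniFrac and
    Faith's PD.
    """

    def __init__(self, tree: dendropy.Tree):
        self._tree = tree
        self._tree.is_rooted = True
        self._validate()

    # -- construction --------------------------------------------------
    @classmethod
    def from_newick(cls, newick: str) -> "PhyloTree":
        try:
            tree = dendropy.Tree.get(
                data=newick, schema="newick", preserve_underscores=True,
                rooting="force-rooted",
            )
        except Exception as exc:  # dendropy raises several parse error types
            raise DataValidationError(f"invalid Newick: {exc}") from exc
        return cls(tree)

    def to_newick(self) -> str:
        s = self._tree.as_string(
            schema="newick", suppress_rooting=True, unquoted_underscores=True,
            real_value_format_specifier=".17g",
        )
        return s.strip() + "\n"

    # -- validation ----------------------------------------------------
    @staticmethod
    def _leaf_label(node) -> str | None:
        if node.taxon is not None and node.taxon.label is not None:
            return node.taxon.label
        return node.label

    def _validate(self) -> None:
        labels = []
        for node in self._tree.leaf_node_iter():
            lab = self._leaf_label(node)
            if lab is None or str(lab).strip() == "":
                raise DataValidationError("tree has an unlabeled leaf")
            labels.append(str(lab))
        _check_unique(labels, "tree leaf")
        if not labels:
            raise DataValidationError("tree has no leaves")
        for node in self._tree.preorder_node_iter():
            if node is self._tree.seed_node:
                continue
            length = node.edge.length
            if length is None:
                raise DataValidationError(
                    f"missing branch length above node {self._leaf_label(node)!r}")
            if not np.isfinite(length) or length < 0:
                raise DataValidationError(
                    f"invalid branch length {length!r} above node "
                    f"{self._leaf_label(node)!r}")
        self._leaves = labels

    # -- views ---------------------------------------------------------
    @property
    def leaf_names(self) -> list:
        return list(self._leaves)

    @property
    def dendropy_tree(self) -> dendropy.Tree:
        return self._tree

    def total_branch_length(self) -> float:
        return float(sum(
            node.edge.length or 0.0
            for node in self._tree.preorder_node_iter()
            if node is not self._tree.seed_node))

    def branch_matrix(self, feature_ids: Sequence | None = None):
        """Branch lengths and branch x feature leaf-descent incidence.

        Returns ``(lengths, incidence)`` where ``incidence[b, f]`` is True iff
        feature ``f`` is a leaf descendant of branch ``b``.  Every edge below
        the root is a branch; the root itself carries no branch.
        """
        if feature_ids is None:
            feature_ids = self.leaf_names
        index = {f: i for i, f in enumerate(feature_ids)}
        n = len(index)
        lengths: list[float] = []
        rows: list[np.ndarray] = []
        masks: dict = {}
        for node in self._tree.postorder_node_iter():
            if node.is_leaf():
                mask = np.zeros(n, dtype=bool)
                lab = self._leaf_label(node)
                if lab in index:
                    mask[index[lab]] = True
            else:
                mask = np.zeros(n, dtype=bool)
                for child in node.child_nodes():
                    mask |= masks[child]
            masks[node] = mask
            if node is not self._tree.seed_node:
                lengths.append(float(node.edge.length or 0.0))
                rows.append(mask)
        return np.asarray(lengths, dtype=float), np.asarray(rows, dtype=bool)

    def path_distance_matrix(self) -> "DistanceMatrix":
        """Leaf-to-leaf path-length (patristic) distances."""
        ids = self.leaf_names
        lengths, inc = self.branch_matrix(ids)
        n = len(ids)
        dist = np.zeros((n, n))
        for b in range(len(lengths)):
            mask = inc[b]
            # branch separates descendants from the rest
            dist += lengths[b] * (mask[:, None] ^ mask[None, :])
        return DistanceMatrix(dist, ids)

    def midpoint_root(self) -> "PhyloTree":
        tree = self._tree.clone(depth=1)
        tree.reroot_at_midpoint(update_bipartitions=False)
        return PhyloTree(tree)

    def __repr__(self) -> str:  # pragma: no cover - cosmetic
        return f"<PhyloTree {len(self._leaves)} leaves>"


class DistanceMatrix:
    """Symmetric nonnegative distance matrix with zero diagonal, keyed by ids."""

    def __init__(self, values, ids: Sequence, validate: bool = True):
        arr = np.asarray(values, dtype=float)
        ids = list(ids)
        if validate:
            if arr.ndim != 2 or arr.shape[0] != arr.shape[1]:
                raise DataValidationError("distance matrix must be square")
            if arr.shape[0] != len(ids):
                raise DataValidationError("distance matrix / id length mismatch")
            _check_unique(ids, "distance-matrix")
            if not np.all(np.isfinite(arr)):
                raise DataValidationError("distance matrix has non-finite entries")
            if (arr < -1e-12).any():
                raise DataValidationError("distance matrix has negative entries")
            if not np.allclose(arr, arr.T, atol=1e-8, rtol=1e-8):
                raise DataValidationError("distance matrix is not symmetric")
            scale = np.abs(arr).max() if arr.size else 0.0
            if np.abs(np.diag(arr)).max(initial=0.0) > 1e-8 * max(scale, 1.0):
                raise DataValidationError("distance matrix diagonal is not zero")
        arr = np.clip((arr + arr.T) / 2.0, 0.0, None)
        np.fill_diagonal(arr, 0.0)
        self.values = arr
        self.ids = ids
        self._index = {s: i for i, s in enumerate(ids)}

    def __len__(self) -> int:
        return len(self.ids)

    def __getitem__(self, pair) -> float:
        i, j = pair
        return float(self.values[self._index[i], self._index[j]])

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(self.values, index=self.ids, columns=self.ids)

    def submatrix(self, ids: Sequence) -> "DistanceMatrix":
        idx = [self._index[s] for s in ids]
        return DistanceMatrix(self.values[np.ix_(idx, idx)], list(ids), validate=False)

    def reorder(self, ids: Sequence) -> "DistanceMatrix":
        if set(ids) != set(self.ids):
            raise DataValidationError("reorder requires the same id set")
        return self.submatrix(ids)

    def condensed(self) -> np.ndarray:
        n = len(self.ids)
        iu = np.triu_indices(n, k=1)
        return self.values[iu]


@dataclasses.dataclass
class GroupTestResult:
    """Kruskal-Wallis statistic plus BH-adjusted pairwise rank-sum p-values."""

    statistic: float
    df: int
    p_value: float
    pairwise: pd.DataFrame | None = None
    excluded_groups: list = dataclasses.field(default_factory=list)

    def to_dict(self) -> dict:
        out = {
            "statistic": None if self.statistic is None else float(self.statistic),
            "df": int(self.df),
            "p_value": None if self.p_value is None else float(self.p_value),
            "excluded_groups": list(self.excluded_groups),
        }
        if self.pairwise is not None:
            out["pairwise_p_adjusted"] = {
                str(a): {str(b): (None if pd.isna(v) else float(v))
                         for b, v in row.items()}
                for a, row in self.pairwise.iterrows()
            }
        return out


@dataclasses.dataclass
class ValidationReport:
    """Cross-object consistency report produced by ``validate_dataset``."""

    features_missing_from_taxonomy: list = dataclasses.field(default_factory=list)
    features_missing_from_tree: list = dataclasses.field(default_factory=list)
    samples_missing_from_metadata: list = dataclasses.field(default_factory=list)
    taxonomy_features_not_in_table: list = dataclasses.field(default_factory=list)
    tree_leaves_not_in_table: list = dataclasses.field(default_factory=list)
    metadata_samples_not_in_table: list = dataclasses.field(default_factory=list)
    dropped_features: list = dataclasses.field(default_factory=list)
    dropped_samples: list = dataclasses.field(default_factory=list)

    @property
    def is_consistent(self) -> bool:
        return not (self.features_missing_from_taxonomy
                    or self.features_missing_from_tree
                    or self.samples_missing_from_metadata
                    or self.taxonomy_features_not_in_table
                    or self.tree_leaves_not_in_table
                    or self.metadata_samples_not_in_table)

    def to_json(self, **kwargs) -> str:
        return json.dumps(dataclasses.asdict(self), **kwargs)
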