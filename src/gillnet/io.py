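"""Readers and writers for the plain-text formats the pipeline exchanges.

Tables (counts, taxonomy, metadata, distance matrices) travel as
tab-separated text with a header row and an identifier column; trees travel
as Newick.  Every reader validates on the way in and every ``write``/``read``
pair round-trips identifiers and values.
"""
from __future__ import annotations

import csv
import logging
from pathlib import Path
from typing import Sequence

import numpy as np
import pandas as pd

from .datatypes import (
    CANONICAL_RANKS,
    DataValidationError,
    DistanceMatrix,
    FeatureTable,
    PhyloTree,
    SampleMetadata,
    TaxonomyMap,
    ValidationReport,
)

logger = logging.getLogger(__name__)

_NA_TOKENS = ("NA", "NaN", "nan", "")


def _read_tsv_strict(path) -> pd.DataFrame:
    """Read a TSV with an id column, reporting ragged rows and duplicates."""
    path = Path(path)
    with path.open(newline="") as handle:
        rows = list(csv.reader(handle, delimiter="\t"))
    if not rows:
        raise DataValidationError(f"{path}: empty file")
    header = rows[0]
    width = len(header)
    for lineno, row in enumerate(rows[1:], start=2):
        if len(row) != width:
            raise DataValidationError(
                f"{path}: ragged row at line {lineno} "
                f"({len(row)} fields, expected {width})")
    body = rows[1:]
    df = pd.DataFrame(body, columns=header)
    df = df.set_index(header[0])
    return df


def read_feature_table(path, orientation: str = "features-in-rows") -> FeatureTable:
    """Read a count table; ``orientation`` names what the file's rows hold."""
    if orientation not in ("features-in-rows", "samples-in-rows"):
        raise ValueError(f"unknown orientation: {orientation!r}")
    df = _read_tsv_strict(path)
    numeric = pd.DataFrame(index=df.index, columns=df.columns, dtype=float)
    for col in df.columns:
        try:
            numeric[col] = pd.to_numeric(df[col])
        except (ValueError, TypeError) as exc:
            bad = df.index[pd.to_numeric(df[col], errors="coerce").isna()][0]
            raise DataValidationError(
                f"{path}: non-numeric cell at row {bad!r}, column {col!r}"
            ) from exc
    if orientation == "samples-in-rows":
        numeric = numeric.T
    return FeatureTable(numeric)


def write_feature_table(table: FeatureTable, path,
                        orientation: str = "features-in-rows") -> None:
    df = table.data if orientation == "features-in-rows" else table.data.T
    df.to_csv(path, sep="\t", index_label="id", float_format="%.12g")


def read_taxonomy(path) -> TaxonomyMap:
    df = _read_tsv_strict(path)
    unknown = [c for c in df.columns if c.lower() not in CANONICAL_RANKS]
    if unknown:
        raise DataValidationError(f"{path}: unknown rank header(s): {unknown}")
    df = df.replace(list(_NA_TOKENS), np.nan)
    return TaxonomyMap(df)


def write_taxonomy(taxonomy: TaxonomyMap, path) -> None:
    taxonomy.df.to_csv(path, sep="\t", index_label="feature_id")


def read_metadata(path) -> SampleMetadata:
    df = _read_tsv_strict(path)
    df = df.replace(list(_NA_TOKENS), np.nan)
    return SampleMetadata(df)


def write_metadata(metadata: SampleMetadata, path) -> None:
    metadata.df.to_csv(path, sep="\t", index_label="sample_id", na_rep="NA")


def read_tree(path) -> PhyloTree:
    return PhyloTree.from_newick(Path(path).read_text())


def write_tree(tree: PhyloTree, path) -> None:
    Path(path).write_text(tree.to_newick())


def read_distance_matrix(path) -> DistanceMatrix:
    df = _read_tsv_strict(path).astype(float)
    if list(df.index) != list(df.columns):
        raise DataValidationError(f"{path}: row and column ids differ")
    return DistanceMatrix(df.to_numpy(), list(df.index))


def write_distance_matrix(dm: DistanceMatrix, path) -> None:
    dm.to_frame().to_csv(path, sep="\t", index_label="id", float_format="%.12g")


def validate_dataset(table: FeatureTable,
                     taxonomy: TaxonomyMap | None = None,
                     metadata: SampleMetadata | None = None,
                     tree: PhyloTree | None = None,
                     strict: bool = False):
    """Cross-check the four pipeline inputs.

    Strict mode raises on any mismatch; permissive mode subsets the table to
    the features/samples covered by every supplied companion object, logs
    what was dropped, and returns ``(subset_table, report)``.
    """
    report = ValidationReport()
    features = set(table.feature_ids)
    samples = set(table.sample_ids)

    keep_features = set(features)
    keep_samples = set(samples)
    if taxonomy is not None:
        tax = set(taxonomy.feature_ids)
        report.features_missing_from_taxonomy = sorted(features - tax)
        report.taxonomy_features_not_in_table = sorted(tax - features)
        keep_features &= tax
    if tree is not None:
        leaves = set(tree.leaf_names)
        report.features_missing_from_tree = sorted(features - leaves)
        report.tree_leaves_not_in_table = sorted(leaves - features)
        keep_features &= leaves
    if metadata is not None:
        meta = set(metadata.sample_ids)
        report.samples_missing_from_metadata = sorted(samples - meta)
        report.metadata_samples_not_in_table = sorted(meta - samples)
        keep_samples &= meta

    if strict:
        problems = (report.features_missing_from_taxonomy
                    + report.features_missing_from_tree
                    + report.samples_missing_from_metadata)
        if problems:
            raise DataValidationError(
                "dataset is inconsistent; first offenders: "
                f"{problems[:5]} (run permissive validation for the full report)")
        return table, report

    report.dropped_features = sorted(features - keep_features)
    report.dropped_samples = sorted(samples - keep_samples)
    if report.dropped_features:
        logger.warning("validate_dataset: dropping %d feature(s) not covered "
                       "by all inputs", len(report.dropped_features))
    if report.dropped_samples:
        logger.warning("validate_dataset: dropping %d sample(s) not covered "
                       "by all inputs", len(report.dropped_samples))
    subset = table.select(
        features=[f for f in table.feature_ids if f in keep_features],
        samples=[s for s in table.sample_ids if s in keep_samples],
    )
    return subset, report
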