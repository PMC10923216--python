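"""Everything between the raw count table and the statistics.

Covers per-sample normalization to relative activity, the two-stage
abundance filter (low-depth samples, then rare features), taxonomic
aggregation, top-N selection, heatmap preparation (zero/IQR variable
filters, Pareto scaling, Ward clustering on Pearson distances), the
environmental Spearman screen, the Fulton condition index, and the shared
Kruskal-Wallis + pairwise Wilcoxon group-comparison machinery.
"""
from __future__ import annotations

import dataclasses
import logging
import warnings
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
import scipy.cluster.hierarchy as sch
import scipy.stats as sps

from .datatypes import (
    CANONICAL_RANKS,
    DataValidationError,
    FeatureTable,
    GillnetError,
    GroupTestResult,
    SampleMetadata,
    TaxonomyMap,
    UNASSIGNED,
)

logger = logging.getLogger(__name__)


# ---------------------------------------------------------------------------
# normalization and filtering
# ---------------------------------------------------------------------------

def to_relative_activity(table: FeatureTable) -> FeatureTable:
    """Divide every sample column by its total (closure to proportions)."""
    if table.is_relative:
        return table.copy()
    totals = table.sample_totals()
    zero = totals.index[totals == 0.0]
    if len(zero):
        raise DataValidationError(
            f"cannot normalize sample(s) with zero total: {list(zero)[:5]}")
    return FeatureTable(table.data / totals, is_relative=True)


@dataclasses.dataclass
class FilterReport:
    removed_samples: list
    removed_features: list
    min_sample_total: float
    min_mean_relative: float

    def to_frame(self) -> pd.DataFrame:
        rows = ([("sample", s) for s in self.removed_samples]
                + [("feature", f) for f in self.removed_features])
        return pd.DataFrame(rows, columns=["kind", "id"])


def filter_dataset(table: FeatureTable,
                   min_sample_total: float = 10_000,
                   min_mean_relative: float = 1e-5,
                   order: str = "samples_first"):
    """Drop shallow samples and rare features from a raw count table.

    With the default ``samples_first`` order, samples whose total count is
    below ``min_sample_total`` are removed first; features whose mean
    relative activity across the *retained* samples is below
    ``min_mean_relative`` are removed second.  ``features_first`` applies the
    same two rules in the opposite order.
    """
    if table.is_relative:
        raise DataValidationError("filter_dataset expects a raw count table")
    if order not in ("samples_first", "features_first"):
        raise ValueError(f"unknown filter order: {order!r}")

    def _drop_samples(tab: FeatureTable) -> tuple[FeatureTable, list]:
        totals = tab.sample_totals()
        keep = totals.index[totals >= min_sample_total]
        removed = [s for s in tab.sample_ids if s not in set(keep)]
        if not len(keep):
            raise GillnetError("sample filter removed every sample")
        return tab.select(samples=list(keep)), removed

    def _drop_features(tab: FeatureTable) -> tuple[FeatureTable, list]:
        rel = to_relative_activity(tab)
        mean_rel = rel.data.mean(axis=1)
        keep = mean_rel.index[mean_rel >= min_mean_relative]
        removed = [f for f in tab.feature_ids if f not in set(keep)]
        if not len(keep):
            raise GillnetError("feature filter removed every feature")
        return tab.select(features=list(keep)), removed

    if order == "samples_first":
        table2, removed_samples = _drop_samples(table)
        table3, removed_features = _drop_features(table2)
    else:
        table2, removed_features = _drop_features(table)
        table3, removed_samples = _drop_samples(table2)
    report = FilterReport(removed_samples, removed_features,
                          min_sample_total, min_mean_relative)
    if removed_samples or removed_features:
        logger.info("filter_dataset: removed %d sample(s), %d feature(s)",
                    len(removed_samples), len(removed_features))
    return table3, report


# ---------------------------------------------------------------------------
# aggregation and selection
# ---------------------------------------------------------------------------

def aggregate_by_rank(table: FeatureTable, taxonomy: TaxonomyMap,
                      rank: str) -> FeatureTable:
    """Sum features sharing a name at ``rank``; unresolved -> 'unassigned'."""
    rank = rank.lower()
    if rank not in CANONICAL_RANKS:
        raise DataValidationError(f"unknown rank: {rank!r}")
    names = taxonomy.rank_names(table.feature_ids, rank)
    grouped = table.data.groupby(names, sort=True).sum()
    grouped.index.name = rank
    return FeatureTable(grouped, is_relative=table.is_relative)


def top_n_features(table: FeatureTable, n: int = 50) -> FeatureTable:
    """The ``n`` features with highest mean relative activity (ties by id)."""
    if n < 1:
        raise ValueError("n must be >= 1")
    if n > table.n_features:
        warnings.warn(f"requested top {n} of {table.n_features} features; "
                      "returning all", stacklevel=2)
        n = table.n_features
    rel = table if table.is_relative else to_relative_activity(table)
    score = rel.data.mean(axis=1)
    order = sorted(score.index, key=lambda f: (-score[f], str(f)))
    return table.select(features=order[:n])


# ---------------------------------------------------------------------------
# heatmap preparation
# ---------------------------------------------------------------------------

@dataclasses.dataclass
class HeatmapPrepResult:
    """Pareto-scaled matrix (samples x variables) plus clustering orders."""

    scaled: pd.DataFrame
    retained_variables: list
    removed_zero_fraction: list
    removed_iqr: list
    row_order: list
    column_order: list
    row_linkage: np.ndarray
    column_linkage: np.ndarray


def _pearson_condensed(matrix: np.ndarray) -> np.ndarray:
    """Condensed 1 - Pearson distance between the rows of ``matrix``."""
    with np.errstate(invalid="ignore"):
        corr = np.corrcoef(matrix)
    corr = np.nan_to_num(corr, nan=0.0)
    dist = 1.0 - corr
    np.fill_diagonal(dist, 0.0)
    n = dist.shape[0]
    return np.clip(dist[np.triu_indices(n, k=1)], 0.0, None)


def heatmap_prep(table: FeatureTable,
                 max_zero_fraction: float = 0.5,
                 iqr_filter: bool = True,
                 iqr_quantile: float = 0.10) -> HeatmapPrepResult:
    """Variable filtering, Pareto scaling, and Ward/Pearson biclustering.

    Variables (features) with at least ``max_zero_fraction`` zeros are
    removed; then, if ``iqr_filter``, variables whose interquartile range
    falls below the ``iqr_quantile`` quantile of IQRs are removed.  Survivors
    are Pareto scaled per variable: (x - mean) / sqrt(sd).
    """
    X = table.data  # features x samples
    zero_frac = (X == 0).sum(axis=1) / X.shape[1]
    removed_zero = list(X.index[zero_frac >= max_zero_fraction])
    X = X.drop(index=removed_zero)

    removed_iqr: list = []
    if iqr_filter and X.shape[0] > 1:
        iqr = X.quantile(0.75, axis=1) - X.quantile(0.25, axis=1)
        cut = iqr.quantile(iqr_quantile)
        removed_iqr = list(X.index[iqr < cut])
        X = X.drop(index=removed_iqr)

    # constants cannot be Pareto scaled
    sd = X.std(axis=1, ddof=1)
    constant = list(X.index[sd == 0.0])
    if constant:
        warnings.warn(f"dropping {len(constant)} constant variable(s) before "
                      "Pareto scaling", stacklevel=2)
        X = X.drop(index=constant)
        sd = sd.drop(index=constant)
        removed_iqr += constant
    if X.shape[0] < 2:
        raise GillnetError("fewer than 2 variables survive heatmap filtering")

    scaled = X.sub(X.mean(axis=1), axis=0).div(np.sqrt(sd), axis=0)
    scaled = scaled.T  # samples x variables; each column now has mean 0

    col_link = sch.linkage(_pearson_condensed(scaled.T.to_numpy()), method="ward")
    row_link = sch.linkage(_pearson_condensed(scaled.to_numpy()), method="ward")
    col_order = [scaled.columns[i] for i in sch.leaves_list(col_link)]
    row_order = [scaled.index[i] for i in sch.leaves_list(row_link)]
    return HeatmapPrepResult(
        scaled=scaled,
        retained_variables=list(scaled.columns),
        removed_zero_fraction=removed_zero,
        removed_iqr=removed_iqr,
        row_order=row_order,
        column_order=col_order,
        row_linkage=row_link,
        column_linkage=col_link,
    )


# ---------------------------------------------------------------------------
# environmental screen and fish condition
# ---------------------------------------------------------------------------

def env_correlation_screen(metadata: SampleMetadata,
                           variables: Sequence[str],
                           rho_threshold: float = 0.21,
                           alpha: float = 0.05) -> pd.DataFrame:
    """Pairwise Spearman screen across environmental variables.

    NA samples are dropped pairwise.  Pairs with fewer than 3 complete
    samples, or with a constant member, get an undefined (NaN) correlation.
    Pairs with |rho| > ``rho_threshold`` and p < ``alpha`` are flagged.
    """
    rows = []
    df = metadata.df
    missing = [v for v in variables if v not in df.columns]
    if missing:
        raise DataValidationError(f"metadata lacks variable(s): {missing}")
    for i, a in enumerate(variables):
        for b in variables[i:]:
            sub = df[[a, b]].dropna() if a != b else df[[a]].dropna()
            n = len(sub)
            if n < 3 or sub.nunique().min() <= 1:
                rho, p = np.nan, np.nan
            elif a == b:
                rho, p = 1.0, 0.0
            else:
                rho, p = sps.spearmanr(sub[a], sub[b])
            flagged = bool(np.isfinite(rho) and abs(rho) > rho_threshold
                           and np.isfinite(p) and p < alpha)
            rows.append((a, b, n, rho, p, flagged))
    return pd.DataFrame(rows, columns=["variable_a", "variable_b", "n",
                                       "rho", "p_value", "flagged"])


def fulton_index(weight_g, fork_length_cm, cubed_ratio: bool = False):
    """Fulton condition factor K = 100 W / L^3 (W in g, L in cm).

    ``cubed_ratio=True`` computes 100 (W/L)^3 instead — a variant that
    circulates in some reports but is inconsistent with the conventional
    definition and with typical healthy salmonid values near 1.
    """
    W = np.asarray(weight_g, dtype=float)
    L = np.asarray(fork_length_cm, dtype=float)
    if np.any(W <= 0) or np.any(L <= 0):
        raise DataValidationError("weight and fork length must be positive")
    if cubed_ratio:
        K = 100.0 * (W / L) ** 3
    else:
        K = 100.0 * W / L ** 3
    return float(K) if K.ndim == 0 else K


# ---------------------------------------------------------------------------
# group comparison (Kruskal-Wallis + pairwise Wilcoxon, BH)
# ---------------------------------------------------------------------------

def benjamini_hochberg(p_values) -> np.ndarray:
    """BH step-up adjusted p-values (NaNs passed through)."""
    p = np.asarray(p_values, dtype=float)
    out = np.full_like(p, np.nan)
    mask = np.isfinite(p)
    if mask.any():
        out[mask] = sps.false_discovery_control(p[mask], method="bh")
    return out


def _rank_sum_p(x: np.ndarray, y: np.ndarray, exact_max_n: int = 20) -> float:
    """Two-sided Wilcoxon rank-sum p: exact for small tie-free samples,
    normal approximation with continuity and tie correction otherwise."""
    pooled = np.concatenate([x, y])
    has_ties = len(np.unique(pooled)) < len(pooled)
    if not has_ties and max(len(x), len(y)) <= exact_max_n:
        method = "exact"
    else:
        method = "asymptotic"
    res = sps.mannwhitneyu(x, y, alternative="two-sided", method=method,
                           use_continuity=True)
    return float(res.pvalue)


def group_compare(values_by_group: Mapping[str, Sequence[float]]) -> GroupTestResult:
    """Kruskal-Wallis across groups plus BH-adjusted pairwise rank-sum tests.

    Groups with fewer than 2 observations are excluded with a warning and
    listed on the result.
    """
    groups = {str(g): np.asarray(v, dtype=float)
              for g, v in values_by_group.items()}
    excluded = [g for g, v in groups.items() if len(v) < 2]
    if excluded:
        warnings.warn(f"excluding group(s) with < 2 observations: {excluded}",
                      stacklevel=2)
    groups = {g: v for g, v in groups.items() if len(v) >= 2}
    names = sorted(groups)
    if len(names) < 2:
        raise GillnetError("group_compare needs at least 2 usable groups")

    samples = [groups[g] for g in names]
    pooled = np.concatenate(samples)
    if np.all(pooled == pooled[0]):
        stat, p = 0.0, 1.0
    else:
        stat, p = sps.kruskal(*samples)
    df = len(names) - 1

    raw = []
    pairs = []
    for i, a in enumerate(names):
        for b in names[i + 1:]:
            pairs.append((a, b))
            raw.append(_rank_sum_p(groups[a], groups[b]))
    adjusted = benjamini_hochberg(raw)
    pairwise = pd.DataFrame(np.nan, index=names, columns=names)
    for (a, b), padj in zip(pairs, adjusted):
        pairwise.loc[a, b] = padj
        pairwise.loc[b, a] = padj
    return GroupTestResult(statistic=float(stat), df=df, p_value=float(p),
                           pairwise=pairwise, excluded_groups=excluded)
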