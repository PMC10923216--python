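"""Indicator-taxon (IndVal) analysis associating taxa with sites.

For a taxon and a target site group, specificity A is the target group's
mean abundance divided by the sum of all group means (means, not sums, so
unbalanced designs do not bias the statistic toward big groups), and
sensitivity B is the fraction of target samples where the taxon occurs.
IndVal = sqrt(A * B).  Significance comes from permuting sample-to-group
labels and recomputing each taxon's best-group IndVal.
"""
from __future__ import annotations

import dataclasses
import itertools
import warnings
from typing import Sequence

import numpy as np
import pandas as pd

from .datatypes import (
    DataValidationError,
    FeatureTable,
    GillnetError,
)
from .preprocess import benjamini_hochberg, to_relative_activity

__all__ = ["indval_components", "indval_analysis", "IndValRecord"]


@dataclasses.dataclass
class IndValRecord:
    taxon: str
    group: tuple
    A: float
    B: float
    indval: float
    p_value: float
    significant: bool


def _group_structures(table: FeatureTable, groups) -> tuple[np.ndarray, np.ndarray, list]:
    if isinstance(groups, dict):
        groups = pd.Series(groups)
    labels = groups.reindex(table.sample_ids)
    if labels.isna().any():
        missing = list(np.asarray(table.sample_ids)[labels.isna()])
        raise DataValidationError(f"group label missing for sample(s): {missing[:5]}")
    names = sorted(set(map(str, labels)))
    codes = np.array([names.index(str(g)) for g in labels])
    sizes = np.bincount(codes, minlength=len(names))
    if (sizes == 0).any():
        raise GillnetError("every group needs at least one sample")
    if (sizes == 1).any():
        warnings.warn("group(s) with a single sample: sensitivity is 0/1 and "
                      "the permutation null is degenerate", stacklevel=2)
    return codes, sizes, names


def _stats_matrices(values: np.ndarray, presence: np.ndarray,
                    codes: np.ndarray, k: int):
    """Per-group mean abundance and prevalence, taxa x groups."""
    n = values.shape[1]
    onehot = np.zeros((n, k))
    onehot[np.arange(n), codes] = 1.0
    sizes = onehot.sum(axis=0)
    means = (values @ onehot) / sizes
    prev = (presence @ onehot) / sizes
    return means, prev


def _indval_single(means: np.ndarray, prev: np.ndarray):
    """Best single-group IndVal per taxon; ties to lexicographically first group."""
    totals = means.sum(axis=1, keepdims=True)
    with np.errstate(invalid="ignore", divide="ignore"):
        A = np.where(totals > 0, means / totals, np.nan)
    indval = np.sqrt(np.where(np.isnan(A), 0.0, A) * prev)
    best = np.argmax(indval, axis=1)  # argmax takes the first maximum
    stat = indval[np.arange(indval.shape[0]), best]
    return stat, best, A, prev


def indval_components(table: FeatureTable, groups, taxon, target) -> tuple[float, float]:
    """Specificity A and sensitivity B for one taxon against one target group
    (or a tuple/list of groups forming a combination)."""
    if taxon not in table.data.index:
        raise DataValidationError(f"unknown taxon: {taxon!r}")
    codes, sizes, names = _group_structures(table, groups)
    targets = (target,) if isinstance(target, str) else tuple(target)
    unknown = [t for t in targets if str(t) not in names]
    if unknown:
        raise DataValidationError(f"unknown group(s): {unknown}")
    rel = table if table.is_relative else to_relative_activity(table)
    x = rel.data.loc[taxon].to_numpy()
    pres = x > 0
    k = len(names)
    means = np.array([x[codes == g].mean() for g in range(k)])
    total = means.sum()
    if total == 0:
        raise GillnetError(f"taxon {taxon!r} is absent from every sample")
    tmask = np.array([names[g] in set(map(str, targets)) for g in range(k)])
    A = means[tmask].mean() / (means[tmask].mean() + means[~tmask].sum()) \
        if tmask.sum() > 1 else means[tmask][0] / total
    in_target = np.isin(codes, np.where(tmask)[0])
    B = float(pres[in_target].mean())
    return float(A), B


def indval_analysis(table: FeatureTable, groups, n_permutations: int = 9999,
                    seed: int | None = None, allow_combinations: bool = False,
                    indval_threshold: float = 0.5,
                    alpha: float = 0.05) -> pd.DataFrame:
    """IndVal for every taxon against its best group (or group combination).

    Returns one row per taxon with the maximizing group, A, B, IndVal, the
    permutation p-value, and a ``significant`` flag (IndVal > threshold and
    p < alpha).  Taxa absent from every sample are reported with NaN
    statistics.  No correction across taxa is applied by default; pass the
    result through :func:`gillnet.preprocess.benjamini_hochberg` if wanted.
    """
    codes, sizes, names = _group_structures(table, groups)
    k = len(names)
    if k < 2:
        raise GillnetError("indicator analysis needs at least 2 groups")
    rel = table if table.is_relative else to_relative_activity(table)
    values = rel.values
    presence = (values > 0).astype(float)
    absent = values.sum(axis=1) == 0

    combos: list[tuple[int, ...]] = [(g,) for g in range(k)]
    if allow_combinations:
        for r in range(2, k):
            combos += list(itertools.combinations(range(k), r))
        # smaller combinations first, then lexicographic: already the order
        combos.sort(key=lambda c: (len(c), tuple(names[g] for g in c)))

    def _stat(codes_: np.ndarray) -> np.ndarray:
        means, prev = _stats_matrices(values, presence, codes_, k)
        if not allow_combinations:
            stat, _, _, _ = _indval_single(means, prev)
            return stat
        return _combo_stat(means, prev, codes_, presence, combos)[0]

    means, prev = _stats_matrices(values, presence, codes, k)
    if not allow_combinations:
        stat_obs, best_idx, A_mat, B_mat = _indval_single(means, prev)
        best_groups = [(names[g],) for g in best_idx]
        A_best = A_mat[np.arange(len(best_idx)), best_idx]
        B_best = B_mat[np.arange(len(best_idx)), best_idx]
    else:
        stat_obs, best_combo, A_best, B_best = _combo_stat(
            means, prev, codes, presence, combos)
        best_groups = [tuple(names[g] for g in combos[c]) for c in best_combo]

    rng = np.random.default_rng(seed)
    exceed = np.zeros(len(stat_obs))
    n = len(codes)
    for _ in range(n_permutations):
        perm_stat = _stat(codes[rng.permutation(n)])
        exceed += perm_stat >= stat_obs - 1e-15
    p = (1.0 + exceed) / (1.0 + n_permutations)

    out = pd.DataFrame({
        "taxon": table.feature_ids,
        "group": ["+".join(g) for g in best_groups],
        "A": A_best,
        "B": B_best,
        "indval": stat_obs,
        "p_value": p,
    })
    out.loc[absent, ["A", "B", "indval", "p_value"]] = np.nan
    if absent.any():
        warnings.warn(f"{int(absent.sum())} taxa absent everywhere; "
                      "records flagged undefined", stacklevel=2)
    out["significant"] = ((out["indval"] > indval_threshold)
                          & (out["p_value"] < alpha)).fillna(False)
    return out


def _combo_stat(means: np.ndarray, prev: np.ndarray, codes: np.ndarray,
                presence: np.ndarray, combos: list):
    """IndVal maximized over group combinations (proper nonempty subsets)."""
    k = means.shape[1]
    sizes = np.bincount(codes, minlength=k).astype(float)
    n_taxa = means.shape[0]
    best_stat = np.zeros(n_taxa)
    best_combo = np.zeros(n_taxa, dtype=int)
    best_A = np.zeros(n_taxa)
    best_B = np.zeros(n_taxa)
    for ci, combo in enumerate(combos):
        mask = np.zeros(k, dtype=bool)
        mask[list(combo)] = True
        inside = means[:, mask].mean(axis=1)
        outside = means[:, ~mask].sum(axis=1)
        with np.errstate(invalid="ignore", divide="ignore"):
            A = np.where(inside + outside > 0, inside / (inside + outside), 0.0)
        # prevalence over the union of the combined groups
        weights = sizes[mask] / sizes[mask].sum()
        B = prev[:, mask] @ weights
        stat = np.sqrt(A * B)
        better = stat > best_stat + 1e-15
        best_stat = np.where(better, stat, best_stat)
        best_combo = np.where(better, ci, best_combo)
        best_A = np.where(better, A, best_A)
        best_B = np.where(better, B, best_B)
    return best_stat, best_combo, best_A, best_B
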