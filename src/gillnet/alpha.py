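"""Alpha diversity: evenness, richness, and phylogenetic diversity.

Shannon entropy uses the natural logarithm throughout, so Pielou evenness is
J = H / ln(S_obs).  Chao1 defaults to the bias-corrected estimator
S_obs + F1 (F1 - 1) / (2 (F2 + 1)).  Faith's PD follows the rooted
convention: the branch path from the root to the spanning subtree counts.
The module also houses the classical Saitou-Nei neighbor-joining tree
builder used to obtain a phylogeny from a taxa distance matrix.
"""
from __future__ import annotations

import warnings
from typing import Mapping, Sequence

import numpy as np
import pandas as pd

from .datatypes import (
    DataValidationError,
    DistanceMatrix,
    FeatureTable,
    GillnetError,
    GroupTestResult,
    PhyloTree,
    SampleMetadata,
)
from .preprocess import group_compare

ALPHA_INDICES = ("shannon", "observed_richness", "pielou", "F1", "F2",
                 "chao1", "faith_pd")


def shannon(counts: Sequence[float]) -> float:
    """Shannon entropy H = -sum p ln p (nats) over nonzero proportions."""
    x = np.asarray(counts, dtype=float)
    if (x < 0).any():
        raise DataValidationError("counts must be nonnegative")
    total = x.sum()
    if total == 0:
        raise DataValidationError("cannot compute Shannon entropy of an empty sample")
    p = x[x > 0] / total
    return float(-(p * np.log(p)).sum())


def observed_richness(counts: Sequence[float]) -> int:
    x = np.asarray(counts, dtype=float)
    return int((x > 0).sum())


def pielou(counts: Sequence[float]) -> float:
    """Pielou evenness J = H / ln(S_obs); NaN when only one taxon is observed."""
    s = observed_richness(counts)
    if s <= 1:
        return float("nan")
    return shannon(counts) / np.log(s)


def chao1(counts: Sequence[float], bias_corrected: bool = True) -> float:
    """Chao1 richness estimate from singleton/doubleton counts.

    Requires integer counts; the estimator is undefined on proportions.
    """
    x = np.asarray(counts, dtype=float)
    if (x < 0).any():
        raise DataValidationError("counts must be nonnegative")
    if not np.allclose(x, np.round(x)):
        raise DataValidationError("Chao1 requires integer counts")
    x = np.round(x)
    s_obs = int((x > 0).sum())
    f1 = int((x == 1).sum())
    f2 = int((x == 2).sum())
    if bias_corrected:
        return s_obs + f1 * (f1 - 1) / (2.0 * (f2 + 1))
    if f1 == 0:
        return float(s_obs)
    if f2 == 0:
        return float("inf")
    return s_obs + f1 ** 2 / (2.0 * f2)


def faith_pd(presence: Mapping | Sequence, tree: PhyloTree) -> float:
    """Faith's phylogenetic diversity of the present features.

    Sums the branch lengths of the minimal subtree spanning the present
    leaves and the root.  ``presence`` is either a mapping feature -> value
    (nonzero means present) or an iterable of present feature ids.
    """
    if isinstance(presence, Mapping):
        present = [f for f, v in presence.items() if v]
    else:
        present = list(presence)
    if not present:
        warnings.warn("empty sample: PD = 0", stacklevel=2)
        return 0.0
    leaves = set(tree.leaf_names)
    missing = [f for f in present if f not in leaves]
    if missing:
        raise DataValidationError(
            f"feature(s) absent from the tree: {missing[:5]}")
    lengths, inc = tree.branch_matrix(present)
    spanned = inc.any(axis=1)
    return float(lengths[spanned].sum())


# ---------------------------------------------------------------------------
# neighbor joining
# ---------------------------------------------------------------------------

def nj_tree(dm: DistanceMatrix, clamp_negative: bool = True,
            midpoint_root: bool = False) -> PhyloTree:
    """Classical Saitou-Nei neighbor joining over a taxa distance matrix.

    Iteratively joins the pair minimizing the Q criterion
    Q(i,j) = (n-2) d(i,j) - r_i - r_j, with branch lengths from the standard
    two-point formulas.  Negative branch-length estimates are clamped to
    zero with the deficit moved to the sister branch (disable with
    ``clamp_negative=False``).  The returned tree is rooted at the last
    join (a trifurcation for >3 taxa collapses to the final internal node);
    ``midpoint_root=True`` reroots at the midpoint of the longest leaf path.
    """
    n = len(dm)
    if n < 3:
        raise GillnetError("neighbor joining needs at least 3 taxa")
    D = dm.values.copy()
    # each active cluster is a newick fragment
    frags = [_quote(lab) for lab in dm.ids]

    def fmt(x: float) -> str:
        return format(float(x), ".17g")

    while len(frags) > 3:
        m = D.shape[0]
        r = D.sum(axis=1)
        Q = (m - 2) * D - r[:, None] - r[None, :]
        np.fill_diagonal(Q, np.inf)
        i, j = np.unravel_index(np.argmin(Q), Q.shape)
        if i > j:
            i, j = j, i
        li = 0.5 * D[i, j] + (r[i] - r[j]) / (2.0 * (m - 2))
        lj = D[i, j] - li
        if clamp_negative:
            li, lj = _clamp_pair(li, lj)
        merged = f"({frags[i]}:{fmt(li)},{frags[j]}:{fmt(lj)})"
        dnew = 0.5 * (D[i, :] + D[j, :] - D[i, j])
        dnew = np.delete(dnew, [i, j])
        if clamp_negative:
            dnew = np.clip(dnew, 0.0, None)
        keep = [k for k in range(m) if k not in (i, j)]
        D = D[np.ix_(keep, keep)]
        D = np.pad(D, ((0, 1), (0, 1)))
        D[-1, :-1] = dnew
        D[:-1, -1] = dnew
        frags = [frags[k] for k in keep] + [merged]

    # final three-taxon join: attach all remaining clusters to the root
    if len(frags) == 3:
        d01, d02, d12 = D[0, 1], D[0, 2], D[1, 2]
        l0 = 0.5 * (d01 + d02 - d12)
        l1 = 0.5 * (d01 + d12 - d02)
        l2 = 0.5 * (d02 + d12 - d01)
        if clamp_negative:
            l0, l1, l2 = (max(v, 0.0) for v in (l0, l1, l2))
        newick = (f"({frags[0]}:{fmt(l0)},{frags[1]}:{fmt(l1)},"
                  f"{frags[2]}:{fmt(l2)});")
    else:  # exactly 2 remain (only possible for n == 4 after one join? no: n>=3 keeps 3) — defensive
        newick = f"({frags[0]}:{fmt(D[0, 1] / 2)},{frags[1]}:{fmt(D[0, 1] / 2)});"
    tree = PhyloTree.from_newick(newick)
    if midpoint_root:
        tree = tree.midpoint_root()
    return tree


def _clamp_pair(li: float, lj: float) -> tuple[float, float]:
    if li < 0:
        lj += li
        li = 0.0
    if lj < 0:
        li += lj
        lj = 0.0
    return max(li, 0.0), max(lj, 0.0)


def _quote(label: str) -> str:
    label = str(label)
    if any(c in label for c in "():,; \t'"):
        return "'" + label.replace("'", "''") + "'"
    return label


# ---------------------------------------------------------------------------
# per-sample pipeline
# ---------------------------------------------------------------------------

def alpha_diversity_table(table: FeatureTable, tree: PhyloTree | None = None) -> pd.DataFrame:
    """All alpha indices per sample (rows = samples).

    Chao1 is only computed for integer count tables; on relative tables the
    column is NaN.  Faith's PD requires ``tree``.
    """
    counts_ok = not table.is_relative and np.allclose(
        table.values, np.round(table.values))
    branch = tree.branch_matrix(table.feature_ids) if tree is not None else None
    rows = {}
    for sample in table.sample_ids:
        x = table.data[sample].to_numpy()
        if x.sum() == 0:
            warnings.warn(f"sample {sample!r} is empty; indices undefined",
                          stacklevel=2)
            rows[sample] = {k: (0.0 if k == "faith_pd" else np.nan)
                            for k in ALPHA_INDICES}
            continue
        h = shannon(x)
        s = observed_richness(x)
        rec = {
            "shannon": h,
            "observed_richness": float(s),
            "pielou": h / np.log(s) if s > 1 else np.nan,
            "F1": float((np.round(x) == 1).sum()) if counts_ok else np.nan,
            "F2": float((np.round(x) == 2).sum()) if counts_ok else np.nan,
            "chao1": chao1(x) if counts_ok else np.nan,
        }
        if branch is not None:
            lengths, inc = branch
            spanned = (inc[:, x > 0]).any(axis=1)
            rec["faith_pd"] = float(lengths[spanned].sum())
        else:
            rec["faith_pd"] = np.nan
        rows[sample] = rec
    return pd.DataFrame.from_dict(rows, orient="index")[list(ALPHA_INDICES)]


def alpha_pipeline(table: FeatureTable, tree: PhyloTree | None,
                   metadata: SampleMetadata,
                   indices: Sequence[str] = ("pielou", "chao1", "faith_pd")):
    """Per-sample alpha indices plus Kruskal-Wallis group tests per index.

    Returns ``(per_sample_frame, {index: GroupTestResult})`` with groups
    taken from the metadata ``community`` column.
    """
    if tree is not None:
        missing = set(table.feature_ids) - set(tree.leaf_names)
        if missing:
            raise DataValidationError(
                f"table feature(s) absent from tree: {sorted(missing)[:5]}")
    frame = alpha_diversity_table(table, tree)
    communities = metadata.communities.reindex(frame.index)
    if communities.isna().any():
        missing = list(frame.index[communities.isna()])
        raise DataValidationError(
            f"sample(s) missing from metadata: {missing[:5]}")
    tests: dict[str, GroupTestResult] = {}
    for index in indices:
        if index not in frame.columns:
            raise GillnetError(f"unknown alpha index: {index!r}")
        vals = frame[index]
        by_group = {g: vals[communities == g].dropna().to_numpy()
                    for g in sorted(communities.unique())}
        tests[index] = group_compare(by_group)
    return frame, tests
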