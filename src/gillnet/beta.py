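"""Beta diversity: UniFrac distances, ordination, and permutation inference.

Distances
---------
Unweighted UniFrac is the fraction of shared-tree branch length leading to
taxa observed in exactly one of the two samples.  Weighted UniFrac sums
branch lengths times the absolute difference in the fraction of each
sample's total descending the branch; the normalized variant divides by the
same sum over the *total* branch-wise fractions, bounding it by 1.

Inference
---------
All permutation p-values use the (1 + exceedances) / (1 + permutations)
estimator, so the smallest attainable p is 1/(B+1).  Permutation streams
are generated over samples sorted by identifier, which makes every result
independent of input row order for a fixed seed.
"""
from __future__ import annotations

import dataclasses
import itertools
import warnings
from typing import Sequence

import numpy as np
import pandas as pd
import scipy.stats as sps
from scipy.optimize import isotonic_regression

from .datatypes import (
    DataValidationError,
    DistanceMatrix,
    FeatureTable,
    GillnetError,
    PhyloTree,
)
from .preprocess import benjamini_hochberg

__all__ = [
    "unifrac", "pcoa", "permanova", "pairwise_permanova", "betadisper",
    "nmds", "envfit", "OrdinationResult", "PermanovaResult",
    "BetadisperResult",
]


# ---------------------------------------------------------------------------
# UniFrac
# ---------------------------------------------------------------------------

def unifrac(table: FeatureTable, tree: PhyloTree, weighted: bool,
            normalized: bool = True) -> DistanceMatrix:
    """UniFrac distances between all sample pairs of ``table``.

    ``weighted=False`` gives unweighted UniFrac (``normalized`` is ignored;
    the statistic is a ratio by construction).  ``weighted=True`` gives raw
    weighted UniFrac, divided by the total branch-wise mass when
    ``normalized``.
    """
    missing = set(table.feature_ids) - set(tree.leaf_names)
    if missing:
        raise DataValidationError(
            f"table feature(s) absent from tree: {sorted(missing)[:5]}")
    totals = table.sample_totals().to_numpy()
    if (totals == 0).any():
        empty = [s for s, t in zip(table.sample_ids, totals) if t == 0]
        raise DataValidationError(f"empty sample(s): {empty[:5]}")

    lengths, inc = tree.branch_matrix(table.feature_ids)
    counts = table.values
    props = counts / totals  # features x samples
    branch_prop = inc.astype(float) @ props          # branches x samples
    branch_pres = (inc.astype(float) @ (counts > 0)) > 0

    n = table.n_samples
    dist = np.zeros((n, n))
    for i in range(n):
        for j in range(i + 1, n):
            if weighted:
                num = float(lengths @ np.abs(branch_prop[:, i] - branch_prop[:, j]))
                if normalized:
                    den = float(lengths @ (branch_prop[:, i] + branch_prop[:, j]))
                    d = num / den if den > 0 else 0.0
                else:
                    d = num
            else:
                a, b = branch_pres[:, i], branch_pres[:, j]
                den = float(lengths @ (a | b))
                d = float(lengths @ (a ^ b)) / den if den > 0 else 0.0
            dist[i, j] = dist[j, i] = d
    return DistanceMatrix(dist, table.sample_ids, validate=False)


# ---------------------------------------------------------------------------
# ordination
# ---------------------------------------------------------------------------

@dataclasses.dataclass
class OrdinationResult:
    """Coordinates plus method-specific diagnostics."""

    method: str
    coordinates: pd.DataFrame
    eigenvalues: np.ndarray | None = None
    proportion_explained: np.ndarray | None = None
    negative_eigenvalues: np.ndarray | None = None
    stress: float | None = None
    converged: bool | None = None
    trace: list | None = None
    seed: int | None = None


def _gower_center(dm: DistanceMatrix) -> np.ndarray:
    d2 = dm.values ** 2
    n = d2.shape[0]
    J = np.eye(n) - np.ones((n, n)) / n
    return -0.5 * J @ d2 @ J


def pcoa(dm: DistanceMatrix, negative_eig: str = "drop") -> OrdinationResult:
    """Principal coordinates analysis (metric MDS by eigendecomposition).

    ``negative_eig='drop'`` discards axes with negative eigenvalues and
    reports them; ``'lingoes'`` adds the Lingoes constant to off-diagonal
    squared distances to make the matrix Euclidean first.
    """
    n = len(dm)
    if n < 3:
        raise GillnetError("PCoA needs at least 3 samples")
    if negative_eig not in ("drop", "lingoes"):
        raise ValueError(f"unknown negative_eig policy: {negative_eig!r}")
    G = _gower_center(dm)
    eigval, eigvec = np.linalg.eigh((G + G.T) / 2.0)
    order = np.argsort(eigval)[::-1]
    eigval, eigvec = eigval[order], eigvec[:, order]
    if negative_eig == "lingoes" and eigval[-1] < -1e-12:
        c = -eigval[-1]
        d2 = dm.values ** 2 + 2.0 * c
        np.fill_diagonal(d2, 0.0)
        corrected = DistanceMatrix(np.sqrt(d2), dm.ids, validate=False)
        return pcoa(corrected, negative_eig="drop")

    tol = max(np.abs(eigval).max(), 1.0) * 1e-12
    pos = eigval > tol
    neg = eigval < -tol
    if neg.any():
        warnings.warn(f"{int(neg.sum())} negative eigenvalue(s) dropped "
                      "(non-Euclidean distances)", stacklevel=2)
    coords = eigvec[:, pos] * np.sqrt(eigval[pos])
    axes = [f"PC{i + 1}" for i in range(coords.shape[1])]
    pos_sum = eigval[pos].sum()
    return OrdinationResult(
        method="pcoa",
        coordinates=pd.DataFrame(coords, index=dm.ids, columns=axes),
        eigenvalues=eigval,
        proportion_explained=(eigval[pos] / pos_sum if pos_sum > 0
                              else np.zeros(int(pos.sum()))),
        negative_eigenvalues=eigval[neg],
    )


# ---------------------------------------------------------------------------
# PERMANOVA
# ---------------------------------------------------------------------------

@dataclasses.dataclass
class PermanovaResult:
    pseudo_F: float
    R2: float
    p_value: float
    n_permutations: int
    seed: int | None
    n_samples: int
    n_groups: int

    def to_dict(self) -> dict:
        return dataclasses.asdict(self)


def _canonical_groups(dm: DistanceMatrix, groups) -> tuple[DistanceMatrix, np.ndarray, list]:
    """Reorder by sorted sample id and encode group labels."""
    ids = sorted(dm.ids, key=str)
    dm = dm.reorder(ids)
    if isinstance(groups, pd.Series):
        labels = groups.reindex(ids)
        if labels.isna().any():
            raise DataValidationError("group label missing for some sample(s)")
        labels = labels.to_numpy()
    elif isinstance(groups, dict):
        labels = np.array([groups[s] for s in ids], dtype=object)
    else:
        raise TypeError("groups must be a pandas Series or a dict keyed by sample id")
    names = sorted(set(map(str, labels)))
    codes = np.array([names.index(str(g)) for g in labels])
    return dm, codes, names


def _permanova_f(d2: np.ndarray, codes: np.ndarray, k: int) -> tuple[float, float]:
    """Pseudo-F and R^2 from squared distances and integer group codes."""
    n = d2.shape[0]
    ss_t = d2.sum() / (2.0 * n)
    onehot = np.zeros((n, k))
    onehot[np.arange(n), codes] = 1.0
    sizes = onehot.sum(axis=0)
    within = ((d2 @ onehot) * onehot).sum(axis=0) / 2.0
    ss_w = float((within / sizes).sum())
    ss_a = ss_t - ss_w
    f = (ss_a / (k - 1)) / (ss_w / (n - k)) if ss_w > 0 else np.inf
    r2 = ss_a / ss_t if ss_t > 0 else 0.0
    return f, r2


def permanova(dm: DistanceMatrix, groups, n_permutations: int = 9999,
              seed: int | None = None) -> PermanovaResult:
    """One-way PERMANOVA with whole-sample label permutation.

    p = (1 + #{F_perm >= F_obs}) / (1 + B).
    """
    dm, codes, names = _canonical_groups(dm, groups)
    k = len(names)
    if k < 2:
        raise GillnetError("PERMANOVA needs at least 2 groups")
    sizes = np.bincount(codes, minlength=k)
    if (sizes < 2).any():
        small = [names[i] for i in np.where(sizes < 2)[0]]
        raise GillnetError(f"singleton group(s): {small}")
    d2 = dm.values ** 2
    if not d2.any():
        raise GillnetError("degenerate distance matrix (all zeros)")
    n = d2.shape[0]
    f_obs, r2 = _permanova_f(d2, codes, k)
    rng = np.random.default_rng(seed)
    exceed = 0
    for _ in range(n_permutations):
        perm = rng.permutation(n)
        f_perm, _ = _permanova_f(d2, codes[perm], k)
        if f_perm >= f_obs:
            exceed += 1
    p = (1.0 + exceed) / (1.0 + n_permutations)
    return PermanovaResult(pseudo_F=float(f_obs), R2=float(r2), p_value=p,
                           n_permutations=n_permutations, seed=seed,
                           n_samples=n, n_groups=k)


def pairwise_permanova(dm: DistanceMatrix, groups, n_permutations: int = 9999,
                       seed: int | None = None) -> pd.DataFrame:
    """PERMANOVA on every group pair, BH-adjusted across pairs."""
    _, codes, names = _canonical_groups(dm, groups)
    if isinstance(groups, dict):
        groups = pd.Series(groups)
    rows = []
    seeds = np.random.SeedSequence(seed).spawn(
        len(list(itertools.combinations(names, 2))))
    for (a, b), ss in zip(itertools.combinations(names, 2), seeds):
        ids = [s for s in dm.ids if str(groups[s]) in (a, b)]
        sub = dm.submatrix(ids)
        res = permanova(sub, groups.loc[ids], n_permutations,
                        seed=int(ss.generate_state(1)[0] % (2 ** 31)))
        rows.append((a, b, res.pseudo_F, res.R2, res.p_value))
    out = pd.DataFrame(rows, columns=["group_a", "group_b", "pseudo_F",
                                      "R2", "p_value"])
    out["p_adjusted"] = benjamini_hochberg(out["p_value"])
    return out


# ---------------------------------------------------------------------------
# betadisper
# ---------------------------------------------------------------------------

@dataclasses.dataclass
class BetadisperResult:
    statistic: float
    p_value: float
    n_permutations: int
    seed: int | None
    distances: pd.Series = None
    group_means: pd.Series = None

    def to_dict(self) -> dict:
        return {
            "statistic": float(self.statistic),
            "p_value": float(self.p_value),
            "n_permutations": self.n_permutations,
            "seed": self.seed,
            "group_means": {str(k): float(v)
                            for k, v in self.group_means.items()},
        }


def _centroid_distances(dm: DistanceMatrix, codes: np.ndarray, k: int) -> np.ndarray:
    """Per-sample distance to its group centroid in the PCoA embedding.

    Negative-eigenvalue axes contribute with a minus sign (the standard
    reduction for non-Euclidean dissimilarities); negative squared distances
    are clamped at zero.
    """
    G = _gower_center(dm)
    eigval, eigvec = np.linalg.eigh((G + G.T) / 2.0)
    tol = max(np.abs(eigval).max(), 1.0) * 1e-12
    pos = eigval > tol
    neg = eigval < -tol
    xpos = eigvec[:, pos] * np.sqrt(eigval[pos])
    xneg = eigvec[:, neg] * np.sqrt(-eigval[neg])
    d2 = np.zeros(len(codes))
    for g in range(k):
        mask = codes == g
        cpos = xpos[mask].mean(axis=0)
        cneg = xneg[mask].mean(axis=0) if xneg.size else np.zeros(0)
        d2[mask] = (((xpos[mask] - cpos) ** 2).sum(axis=1)
                    - ((xneg[mask] - cneg) ** 2).sum(axis=1))
    return np.sqrt(np.clip(d2, 0.0, None))


def _anova_f(values: np.ndarray, codes: np.ndarray, k: int) -> float:
    n = len(values)
    grand = values.mean()
    ss_b = 0.0
    ss_w = 0.0
    for g in range(k):
        v = values[codes == g]
        ss_b += len(v) * (v.mean() - grand) ** 2
        ss_w += ((v - v.mean()) ** 2).sum()
    if ss_w == 0:
        return 0.0 if ss_b == 0 else np.inf
    return (ss_b / (k - 1)) / (ss_w / (n - k))


def betadisper(dm: DistanceMatrix, groups, n_permutations: int = 9999,
               seed: int | None = None) -> BetadisperResult:
    """Homogeneity of multivariate dispersion (distance-to-centroid test)."""
    dm, codes, names = _canonical_groups(dm, groups)
    k = len(names)
    if k < 2:
        raise GillnetError("betadisper needs at least 2 groups")
    dists = _centroid_distances(dm, codes, k)
    f_obs = _anova_f(dists, codes, k)
    rng = np.random.default_rng(seed)
    exceed = 0
    for _ in range(n_permutations):
        f_perm = _anova_f(dists, codes[rng.permutation(len(codes))], k)
        if f_perm >= f_obs:
            exceed += 1
    p = (1.0 + exceed) / (1.0 + n_permutations)
    series = pd.Series(dists, index=dm.ids)
    means = pd.Series({names[g]: dists[codes == g].mean() for g in range(k)})
    return BetadisperResult(statistic=float(f_obs), p_value=p,
                            n_permutations=n_permutations, seed=seed,
                            distances=series, group_means=means)


# ---------------------------------------------------------------------------
# NMDS
# ---------------------------------------------------------------------------

def _condensed(x: np.ndarray) -> np.ndarray:
    iu = np.triu_indices(x.shape[0], k=1)
    return x[iu]


def _config_distances(X: np.ndarray) -> np.ndarray:
    diff = X[:, None, :] - X[None, :, :]
    return _condensed(np.sqrt((diff ** 2).sum(axis=-1)))


def _smacof_once(d0: np.ndarray, n: int, k: int, rng: np.random.Generator,
                 max_iter: int, tol: float):
    """One SMACOF run: monotone (PAVA) regression + Guttman transforms.

    Returns (configuration, stress1, raw-stress trace, converged).  The raw
    stress sum((d_hat - d)^2), evaluated after each isotonic fit, is
    non-increasing by construction and is what the trace records.
    """
    X = rng.uniform(-1.0, 1.0, size=(n, k))
    iu = np.triu_indices(n, k=1)
    trace = []
    prev_stress1 = np.inf
    converged = False
    for _ in range(max_iter):
        dvec = _config_distances(X)
        # primary (ties-pooled-by-configuration) approach: stable sort by
        # dissimilarity, then within ties follow configuration order
        tie_order = np.lexsort((dvec, d0))
        dhat = np.empty_like(dvec)
        dhat[tie_order] = isotonic_regression(dvec[tie_order]).x
        raw = float(((dvec - dhat) ** 2).sum())
        trace.append(raw)
        denom = float((dvec ** 2).sum())
        stress1 = np.sqrt(raw / denom) if denom > 0 else 0.0
        if abs(prev_stress1 - stress1) < tol:
            converged = True
            break
        prev_stress1 = stress1
        # Guttman transform
        with np.errstate(divide="ignore", invalid="ignore"):
            ratio = np.where(dvec > 0, dhat / dvec, 0.0)
        B = np.zeros((n, n))
        B[iu] = -ratio
        B = B + B.T
        np.fill_diagonal(B, -B.sum(axis=1))
        X = (B @ X) / n
    dvec = _config_distances(X)
    tie_order = np.lexsort((dvec, d0))
    dhat = np.empty_like(dvec)
    dhat[tie_order] = isotonic_regression(dvec[tie_order]).x
    raw = float(((dvec - dhat) ** 2).sum())
    denom = float((dvec ** 2).sum())
    stress1 = float(np.sqrt(raw / denom)) if denom > 0 else 0.0
    return X, stress1, trace, converged


def nmds(dm: DistanceMatrix, k: int = 2, n_starts: int = 20,
         seed: int | None = None, max_iter: int = 500,
         tol: float = 1e-9) -> OrdinationResult:
    """Nonmetric MDS minimizing Kruskal stress-1 by majorization (SMACOF).

    Best of ``n_starts`` seeded random initializations; the winning
    configuration is centered and rotated to its principal axes.
    """
    n = len(dm)
    if n <= k + 1:
        raise GillnetError("NMDS needs more samples than axes + 1")
    d0 = dm.condensed()
    rng = np.random.default_rng(seed)
    best = None
    for _ in range(n_starts):
        X, stress1, trace, conv = _smacof_once(d0, n, k, rng, max_iter, tol)
        if best is None or stress1 < best[1]:
            best = (X, stress1, trace, conv)
    X, stress1, trace, conv = best
    if not conv:
        warnings.warn("NMDS did not converge in any start; returning best "
                      "configuration", stacklevel=2)
    X = X - X.mean(axis=0)
    _, _, vt = np.linalg.svd(X, full_matrices=False)
    X = X @ vt.T
    axes = [f"NMDS{i + 1}" for i in range(k)]
    return OrdinationResult(
        method="nmds",
        coordinates=pd.DataFrame(X, index=dm.ids, columns=axes),
        stress=float(stress1), converged=bool(conv), trace=trace, seed=seed)


# ---------------------------------------------------------------------------
# envfit
# ---------------------------------------------------------------------------

def envfit(coordinates: pd.DataFrame, env: pd.DataFrame,
           n_permutations: int = 9999, seed: int | None = None) -> pd.DataFrame:
    """Least-squares fit of environmental variables onto ordination axes.

    Per variable: OLS of the (complete-case) variable on the centered axes;
    R^2 is the squared multiple correlation, the direction the unit
    coefficient vector.  p-values come from permuting the variable;
    Bonferroni adjusts across the tested variables.
    """
    axes = list(coordinates.columns)
    rows = []
    rng_seq = np.random.SeedSequence(seed).spawn(max(env.shape[1], 1))
    tested = 0
    for var, ss in zip(env.columns, rng_seq):
        y_all = pd.to_numeric(env[var], errors="coerce")
        joined = coordinates.join(y_all.rename("_y"), how="inner").dropna()
        n = len(joined)
        if n < len(axes) + 2:
            warnings.warn(f"envfit: too few complete samples for {var!r}",
                          stacklevel=2)
            rows.append((var, *([np.nan] * len(axes)), np.nan, np.nan, n))
            continue
        X = joined[axes].to_numpy()
        y = joined["_y"].to_numpy()
        if np.all(y == y[0]):
            warnings.warn(f"envfit: variable {var!r} is constant", stacklevel=2)
            rows.append((var, *([np.nan] * len(axes)), np.nan, np.nan, n))
            continue
        Xc = X - X.mean(axis=0)
        yc = y - y.mean()

        def _r2(yy: np.ndarray) -> tuple[float, np.ndarray]:
            beta, *_ = np.linalg.lstsq(Xc, yy, rcond=None)
            fitted = Xc @ beta
            sst = float((yy ** 2).sum())
            return (float((fitted ** 2).sum()) / sst if sst > 0 else 0.0), beta

        r2_obs, beta = _r2(yc)
        norm = np.linalg.norm(beta)
        direction = beta / norm if norm > 0 else beta
        rng = np.random.default_rng(int(ss.generate_state(1)[0] % (2 ** 31)))
        exceed = 0
        for _ in range(n_permutations):
            yp = yc[rng.permutation(n)]
            if _r2(yp)[0] >= r2_obs:
                exceed += 1
        p = (1.0 + exceed) / (1.0 + n_permutations)
        tested += 1
        rows.append((var, *direction, r2_obs, p, n))
    out = pd.DataFrame(rows, columns=["variable", *axes, "r2", "p_value", "n"])
    out["p_adjusted"] = np.minimum(out["p_value"] * max(tested, 1), 1.0)
    return out
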