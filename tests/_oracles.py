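"""Independent brute-force oracles used to validate the implementations.

Everything here is written from first principles (explicit loops, textbook
formulas, exhaustive enumeration) and deliberately shares no code with the
package paths it checks.
"""
from __future__ import annotations

import itertools
from collections import deque

import numpy as np


# -- tree helpers (pure dendropy traversal) ---------------------------------

def _branches(phylo_tree):
    """(length, frozenset of descendant leaf labels) for every non-root edge."""
    tree = phylo_tree.dendropy_tree
    out = []
    for node in tree.preorder_node_iter():
        if node is tree.seed_node:
            continue
        leaves = frozenset(
            (lf.taxon.label if lf.taxon is not None else lf.label)
            for lf in node.leaf_iter())
        out.append((float(node.edge.length or 0.0), leaves))
    return out


def oracle_faith_pd(present_features, phylo_tree) -> float:
    present = set(present_features)
    total = 0.0
    for length, leaves in _branches(phylo_tree):
        if leaves & present:
            total += length
    return total


def oracle_unifrac_pair(counts_a: dict, counts_b: dict, phylo_tree,
                        weighted: bool, normalized: bool) -> float:
    branches = _branches(phylo_tree)
    ta = sum(counts_a.values())
    tb = sum(counts_b.values())
    if weighted:
        num = den = 0.0
        for length, leaves in branches:
            pa = sum(counts_a.get(f, 0) for f in leaves) / ta
            pb = sum(counts_b.get(f, 0) for f in leaves) / tb
            num += length * abs(pa - pb)
            den += length * (pa + pb)
        if not normalized:
            return num
        return num / den if den > 0 else 0.0
    num = den = 0.0
    for length, leaves in branches:
        ina = any(counts_a.get(f, 0) > 0 for f in leaves)
        inb = any(counts_b.get(f, 0) > 0 for f in leaves)
        if ina or inb:
            den += length
            if ina != inb:
                num += length
    return num / den if den > 0 else 0.0


def oracle_path_distances(phylo_tree) -> dict:
    """Leaf pair -> path length, via per-branch separation counting."""
    branches = _branches(phylo_tree)
    leaves = sorted(phylo_tree.leaf_names)
    out = {}
    for a, b in itertools.combinations(leaves, 2):
        d = sum(length for length, under in branches
                if (a in under) != (b in under))
        out[(a, b)] = d
    return out


# -- PERMANOVA ---------------------------------------------------------------

def oracle_permanova_f(dist: np.ndarray, labels) -> float:
    """Pseudo-F from explicit pair loops."""
    labels = list(labels)
    n = len(labels)
    groups = sorted(set(labels))
    ss_t = 0.0
    for i in range(n):
        for j in range(i + 1, n):
            ss_t += dist[i, j] ** 2
    ss_t /= n
    ss_w = 0.0
    for grp in groups:
        idx = [i for i, lab in enumerate(labels) if lab == grp]
        s = 0.0
        for i, j in itertools.combinations(idx, 2):
            s += dist[i, j] ** 2
        ss_w += s / len(idx)
    a = len(groups)
    return ((ss_t - ss_w) / (a - 1)) / (ss_w / (n - a))


def oracle_permanova_exact_p(dist: np.ndarray, labels) -> float:
    """Exact permutation p by enumerating all distinct label assignments."""
    f_obs = oracle_permanova_f(dist, labels)
    perms = set(itertools.permutations(labels))
    count = sum(1 for perm in perms
                if oracle_permanova_f(dist, perm) >= f_obs - 1e-12)
    return count / len(perms)


# -- rank statistics ---------------------------------------------------------

def oracle_average_ranks(x) -> np.ndarray:
    x = np.asarray(x, dtype=float)
    order = np.argsort(x, kind="stable")
    ranks = np.empty(len(x))
    i = 0
    while i < len(x):
        j = i
        while j + 1 < len(x) and x[order[j + 1]] == x[order[i]]:
            j += 1
        avg = (i + j) / 2.0 + 1.0
        for k in range(i, j + 1):
            ranks[order[k]] = avg
        i = j + 1
    return ranks


def oracle_spearman(x, y) -> float:
    rx = oracle_average_ranks(x)
    ry = oracle_average_ranks(y)
    rx = rx - rx.mean()
    ry = ry - ry.mean()
    return float((rx * ry).sum() / np.sqrt((rx ** 2).sum() * (ry ** 2).sum()))


# -- OLS ---------------------------------------------------------------------

def oracle_ols_r2(X: np.ndarray, y: np.ndarray) -> float:
    """Squared multiple correlation by the normal equations."""
    X1 = np.column_stack([np.ones(len(y)), X])
    beta = np.linalg.solve(X1.T @ X1, X1.T @ y)
    fitted = X1 @ beta
    ss_res = float(((y - fitted) ** 2).sum())
    ss_tot = float(((y - y.mean()) ** 2).sum())
    return 1.0 - ss_res / ss_tot


# -- graph metrics -----------------------------------------------------------

def oracle_graph_metrics(edges, nodes):
    """DG/NC/CC per node from an adjacency dict and BFS shortest paths."""
    adj = {n: set() for n in nodes}
    for a, b in edges:
        adj[a].add(b)
        adj[b].add(a)
    out = {}
    for node in nodes:
        deg = len(adj[node])
        nc = (sum(len(adj[nb]) for nb in adj[node]) / deg) if deg else float("nan")
        # BFS
        dist = {node: 0}
        queue = deque([node])
        while queue:
            cur = queue.popleft()
            for nb in adj[cur]:
                if nb not in dist:
                    dist[nb] = dist[cur] + 1
                    queue.append(nb)
        reachable = [d for n2, d in dist.items() if n2 != node]
        cc = (len(reachable) / sum(reachable)) if reachable else 0.0
        out[node] = {"DG": float(deg), "NC": nc, "CC": float(cc)}
    return out
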