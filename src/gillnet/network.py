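"""Per-site co-activity networks and their topology.

For each site, Spearman correlations between genus-level relative
activities are thresholded (|rho| > 0.4 by default) after BH-FDR control of
the correlation p-values; surviving pairs become signed undirected edges.
Isolated genera stay in the node set — they still carry activity.  Node
topology is summarized by degree (DG), neighborhood connectivity (NC, the
mean degree of a node's neighbors) and closeness centrality (CC, the
reciprocal mean shortest-path length to the nodes reachable from it).
Sparse, fragmented topology relative to other sites is the package's
operational dysbiosis signature.
"""
from __future__ import annotations

import dataclasses
import warnings
from typing import Mapping, Sequence

import networkx as nx
import numpy as np
import pandas as pd
import scipy.stats as sps

from .datatypes import (
    DataValidationError,
    FeatureTable,
    GillnetError,
    GroupTestResult,
)
from .preprocess import benjamini_hochberg, group_compare, to_relative_activity

__all__ = ["spearman_matrix", "build_network", "node_metrics",
           "compare_networks", "export_network", "read_edge_list",
           "CoactivityNetwork"]


@dataclasses.dataclass
class CoactivityNetwork:
    """Signed co-activity graph for one site."""

    site: str
    graph: nx.Graph
    threshold: float
    alpha: float
    excluded_constant: list = dataclasses.field(default_factory=list)

    @property
    def nodes(self) -> list:
        return list(self.graph.nodes)

    @property
    def n_edges(self) -> int:
        return self.graph.number_of_edges()

    def edge_table(self) -> pd.DataFrame:
        rows = [(u, v, d["rho"], d["sign"], d["p_adjusted"])
                for u, v, d in self.graph.edges(data=True)]
        return pd.DataFrame(rows, columns=["node_a", "node_b", "rho",
                                           "sign", "p_adjusted"])

    def edge_sign_counts(self) -> tuple[int, int]:
        signs = [d["sign"] for _, _, d in self.graph.edges(data=True)]
        return signs.count(1), signs.count(-1)


def spearman_matrix(site_table: FeatureTable) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Spearman rho and p between every genus pair at one site.

    rho is Pearson correlation of average ranks; p uses the t-distribution
    approximation.  Constant genera are excluded with a warning (their
    correlation is undefined).  Requires at least 4 samples.
    """
    if site_table.n_samples < 4:
        raise GillnetError("need at least 4 samples for site correlations")
    if site_table.n_features < 2:
        raise GillnetError("need at least 2 genera")
    X = site_table.values
    constant = [f for f, row in zip(site_table.feature_ids, X)
                if np.all(row == row[0])]
    if constant:
        warnings.warn(f"excluding {len(constant)} constant genus/genera "
                      "from the correlation matrix", stacklevel=2)
        site_table = site_table.select(
            features=[f for f in site_table.feature_ids if f not in set(constant)])
        X = site_table.values
    if site_table.n_features < 2:
        raise GillnetError("fewer than 2 non-constant genera")
    n = site_table.n_samples
    ranks = np.apply_along_axis(sps.rankdata, 1, X)
    rho = np.corrcoef(ranks)
    np.fill_diagonal(rho, 1.0)
    rho = np.clip(rho, -1.0, 1.0)
    # t approximation for the correlation p-value
    with np.errstate(divide="ignore", invalid="ignore"):
        t = rho * np.sqrt((n - 2) / np.maximum(1.0 - rho ** 2, 1e-300))
    p = 2.0 * sps.t.sf(np.abs(t), df=n - 2)
    np.fill_diagonal(p, 0.0)
    ids = site_table.feature_ids
    return (pd.DataFrame(rho, index=ids, columns=ids),
            pd.DataFrame(p, index=ids, columns=ids))


def build_network(rho: pd.DataFrame, p: pd.DataFrame,
                  threshold: float = 0.4, alpha: float = 0.05,
                  site: str = "", activity: Mapping | None = None,
                  phylum: Mapping | None = None) -> CoactivityNetwork:
    """Threshold a correlation matrix into a signed co-activity graph.

    BH-FDR is applied over all unique pairs with a defined correlation; an
    edge is kept iff |rho| > ``threshold`` (strict) and adjusted p < ``alpha``.
    Isolated nodes are retained.  ``activity`` and ``phylum`` attach node
    attributes when given.
    """
    ids = list(rho.index)
    if list(p.index) != ids or list(rho.columns) != ids:
        raise DataValidationError("rho and p matrices must share identical ids")
    n = len(ids)
    iu = np.triu_indices(n, k=1)
    rvals = rho.to_numpy()[iu]
    pvals = p.to_numpy()[iu]
    padj = benjamini_hochberg(pvals)
    graph = nx.Graph()
    order = sorted(range(n), key=lambda i: str(ids[i]))
    for i in order:
        graph.add_node(ids[i])
    for (i, j, r, q) in zip(iu[0], iu[1], rvals, padj):
        if np.isfinite(r) and abs(r) > threshold and np.isfinite(q) and q < alpha:
            graph.add_edge(ids[i], ids[j], rho=float(r),
                           sign=1 if r > 0 else -1, p_adjusted=float(q))
    if activity is not None:
        nx.set_node_attributes(
            graph, {k: float(activity[k]) for k in graph.nodes
                    if k in activity}, "activity")
    if phylum is not None:
        nx.set_node_attributes(
            graph, {k: str(phylum[k]) for k in graph.nodes
                    if k in phylum}, "phylum")
    return CoactivityNetwork(site=site, graph=graph, threshold=threshold,
                             alpha=alpha)


def node_metrics(network: CoactivityNetwork) -> pd.DataFrame:
    """DG, NC and CC per node.

    Isolated nodes: DG = 0, NC = NaN (undefined), CC = 0.  CC uses the
    within-component convention: the reciprocal of the mean shortest-path
    length to the nodes reachable from the node.
    """
    g = network.graph
    deg = dict(g.degree())
    cc = nx.closeness_centrality(g, wf_improved=False)
    rows = {}
    for node in g.nodes:
        d = deg[node]
        if d == 0:
            nc = np.nan
        else:
            nc = float(np.mean([deg[nb] for nb in g.neighbors(node)]))
        rows[node] = {"DG": float(d), "NC": nc, "CC": float(cc[node])}
    return pd.DataFrame.from_dict(rows, orient="index")[["DG", "NC", "CC"]]


def site_networks(table: FeatureTable, groups,
                  threshold: float = 0.4, alpha: float = 0.05,
                  min_samples: int = 4,
                  phylum: Mapping | None = None) -> dict[str, CoactivityNetwork]:
    """Build one network per site from a genus-level table.

    ``groups`` maps sample id -> site.  Sites with fewer than
    ``min_samples`` samples are skipped with a warning.  Node activity is
    the summed relative activity of the genus across the site's samples.
    """
    if isinstance(groups, dict):
        groups = pd.Series(groups)
    labels = groups.reindex(table.sample_ids)
    if labels.isna().any():
        raise DataValidationError("site label missing for some sample(s)")
    rel = table if table.is_relative else to_relative_activity(table)
    out: dict[str, CoactivityNetwork] = {}
    for site in sorted(set(map(str, labels))):
        samples = [s for s, lab in labels.items() if str(lab) == site]
        if len(samples) < min_samples:
            warnings.warn(f"site {site!r} has {len(samples)} sample(s) "
                          f"(< {min_samples}); skipping its network",
                          stacklevel=2)
            continue
        sub = rel.select(samples=samples)
        rho, p = spearman_matrix(sub)
        activity = sub.data.sum(axis=1).to_dict()
        out[site] = build_network(rho, p, threshold=threshold, alpha=alpha,
                                  site=site, activity=activity, phylum=phylum)
    return out


def compare_networks(networks: Mapping[str, CoactivityNetwork],
                     metrics: Sequence[str] = ("DG", "NC", "CC")):
    """Cross-site Kruskal-Wallis on node-level topology metrics plus a summary.

    Returns ``(tests, summary)`` where ``tests`` maps each metric to a
    :class:`GroupTestResult` (nodes are the observations, mirroring how the
    source networks are usually compared — a pseudo-replication caveat
    documented in the methods note) and ``summary`` is one row per site with
    node/edge counts, signed edge counts, the node-metric medians and the
    nodes carrying the most negative edges.
    """
    if len(networks) < 2:
        raise GillnetError("need at least 2 site networks to compare")
    per_site_metrics = {site: node_metrics(net)
                        for site, net in networks.items()}
    tests: dict[str, GroupTestResult] = {}
    for metric in metrics:
        by_group = {}
        for site, frame in per_site_metrics.items():
            vals = frame[metric].dropna().to_numpy()
            if metric != "DG":
                # NC/CC only defined on connected nodes
                vals = frame.loc[frame["DG"] > 0, metric].dropna().to_numpy()
            by_group[site] = vals
        usable = {s: v for s, v in by_group.items() if len(v) >= 2}
        skipped = sorted(set(by_group) - set(usable))
        if skipped:
            warnings.warn(f"site(s) with < 2 usable nodes excluded from "
                          f"{metric} comparison: {skipped}", stacklevel=2)
        if len(usable) >= 2:
            tests[metric] = group_compare(usable)

    rows = []
    for site in sorted(networks):
        net = networks[site]
        frame = per_site_metrics[site]
        pos, negedges = net.edge_sign_counts()
        neg_by_node = {
            node: sum(1 for _, _, d in net.graph.edges(node, data=True)
                      if d["sign"] < 0)
            for node in net.graph.nodes}
        max_neg = max(neg_by_node.values(), default=0)
        top_neg = sorted(n for n, c in neg_by_node.items()
                         if c == max_neg and c > 0)
        rows.append({
            "site": site,
            "n_nodes": net.graph.number_of_nodes(),
            "n_edges": net.n_edges,
            "positive_edges": pos,
            "negative_edges": negedges,
            "median_DG": float(frame["DG"].median()),
            "median_NC": float(frame["NC"].median()),
            "median_CC": float(frame["CC"].median()),
            "most_negative_nodes": ";".join(map(str, top_neg)),
        })
    summary = pd.DataFrame(rows).set_index("site")
    return tests, summary


def top_n_subgraph(network: CoactivityNetwork, n: int = 50) -> CoactivityNetwork:
    """Visualization/export filter: subgraph on the n most active nodes."""
    act = nx.get_node_attributes(network.graph, "activity")
    order = sorted(network.graph.nodes,
                   key=lambda node: (-act.get(node, 0.0), str(node)))
    keep = order[:n]
    sub = network.graph.subgraph(keep).copy()
    return CoactivityNetwork(site=network.site, graph=sub,
                             threshold=network.threshold, alpha=network.alpha)


def export_network(network: CoactivityNetwork, path, fmt: str = "edgelist") -> None:
    """Write the network as a TSV edge list or as GraphML with node attributes."""
    if fmt == "edgelist":
        network.edge_table().to_csv(path, sep="\t", index=False,
                                    float_format="%.12g")
    elif fmt == "graphml":
        graph = network.graph.copy()
        metrics = node_metrics(network)
        for node in graph.nodes:
            graph.nodes[node]["DG"] = float(metrics.loc[node, "DG"])
            nc = metrics.loc[node, "NC"]
            graph.nodes[node]["NC"] = float(nc) if np.isfinite(nc) else -1.0
            graph.nodes[node]["CC"] = float(metrics.loc[node, "CC"])
        nx.write_graphml(graph, path)
    else:
        raise ValueError(f"unknown export format: {fmt!r}")


def read_edge_list(path, site: str = "", threshold: float = 0.4,
                   alpha: float = 0.05) -> CoactivityNetwork:
    """Rebuild a network from an exported edge list (edges only)."""
    df = pd.read_csv(path, sep="\t")
    graph = nx.Graph()
    for _, row in df.iterrows():
        graph.add_edge(row["node_a"], row["node_b"], rho=float(row["rho"]),
                       sign=int(row["sign"]), p_adjusted=float(row["p_adjusted"]))
    return CoactivityNetwork(site=site, graph=graph, threshold=threshold,
                             alpha=alpha)
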