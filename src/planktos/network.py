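"""Correlation-based co-occurrence networks with null-model benchmarks.

A network is built by screening all OTU pairs for strong (|Spearman r|
above a threshold, 0.8 by default) and significant (p below 0.01 by the
t approximation) rank correlations across samples; each retained pair
becomes an undirected edge carrying the correlation's sign. Topology
(degree, betweenness, closeness, eigenvector centrality, clustering,
path length, modularity) is computed on the unsigned simple graph and
benchmarked against Erdős–Rényi G(n, m) random graphs with the same
node and edge counts. Louvain modules feed the Zi–Pi plane (within-
module degree z-score vs. participation coefficient), which classifies
nodes into module hubs, connectors, network hubs and peripherals;
keystone taxa are high-degree, low-betweenness nodes.
"""

from __future__ import annotations

import logging

import networkx as nx
import numpy as np
import pandas as pd
from networkx.algorithms.community import louvain_communities, modularity
from scipy import stats

from .data_model import OtuTable, SampleFrame

logger = logging.getLogger(__name__)

__all__ = ["network_prefilter", "correlation_screen", "node_topology",
           "detect_modules", "global_topology", "er_null_ensemble",
           "keystone_taxa", "zi_pi", "module_env_association",
           "spearman_pvalue"]


def network_prefilter(table: OtuTable, min_samples: int = 6,
                      min_reads: int = 20) -> OtuTable:
    """Keep OTUs present in more than ``min_samples`` samples with more
    than ``min_reads`` total reads (both strict inequalities)."""
    counts = table.counts
    occ = (counts > 0).sum(axis=1)
    keep = (occ > min_samples) & (counts.sum(axis=1) > min_reads)
    if not keep.any():
        raise ValueError("prevalence filter removed every OTU")
    logger.info("network_prefilter: %d of %d OTUs retained",
                int(keep.sum()), table.n_otus)
    return table.select_otus(counts.index[keep])


def spearman_pvalue(r: np.ndarray, n: int) -> np.ndarray:
    """Two-sided p for Spearman r via the t approximation
    t = r·sqrt((n−2)/(1−r²))."""
    r = np.clip(np.asarray(r, dtype=float), -1.0, 1.0)
    with np.errstate(divide="ignore", invalid="ignore"):
        t = r * np.sqrt((n - 2) / (1.0 - r ** 2))
    p = 2.0 * stats.t.sf(np.abs(t), df=n - 2)
    return np.where(np.abs(r) >= 1.0, 0.0, p)


def correlation_screen(table: OtuTable, r_threshold: float = 0.8,
                       p_threshold: float = 0.01,
                       classes: pd.DataFrame | None = None,
                       drop_isolated: bool = True) -> nx.Graph:
    """Screen all OTU pairs and build the co-occurrence graph.

    Edges require |Spearman r| strictly above ``r_threshold`` and p
    strictly below ``p_threshold``; the correlation sign is kept as an
    edge attribute. Constant OTU profiles have undefined correlations
    and are skipped with a log entry. Degree-zero nodes are dropped from
    the reported network by default (count logged). ``classes`` (from
    ``classify_otus``) attaches each node's abundance roll-up label.
    """
    n = table.n_samples
    if n < 4:
        raise ValueError("need at least 4 samples for the correlation screen")
    arr = table.counts.to_numpy().astype(float)
    const = arr.std(axis=1) == 0
    if const.any():
        logger.info("correlation_screen: %d constant OTU profiles skipped",
                    int(const.sum()))
    ids = np.asarray(table.otu_ids, dtype=object)
    use = ~const
    ranks = np.apply_along_axis(stats.rankdata, 1, arr[use])
    r = np.corrcoef(ranks)
    iu = np.triu_indices(len(r), k=1)
    rr = r[iu]
    pp = spearman_pvalue(rr, n)
    hit = (np.abs(rr) > r_threshold) & (pp < p_threshold)
    removed_by_p = int(((np.abs(rr) > r_threshold) & ~(pp < p_threshold)).sum())
    logger.info("correlation_screen: p<%g filter removed %d pairs beyond "
                "|r|>%g (0 expected at n=%d: the r rule dominates)",
                p_threshold, removed_by_p, r_threshold, n)
    g = nx.Graph()
    g.add_nodes_from(ids[use])
    kept_ids = ids[use]
    for i, j, rij, pij in zip(iu[0][hit], iu[1][hit], rr[hit], pp[hit]):
        g.add_edge(kept_ids[i], kept_ids[j], r=float(rij), p=float(pij),
                   sign=1 if rij > 0 else -1)
    if drop_isolated:
        isolated = list(nx.isolates(g))
        if isolated:
            logger.info("correlation_screen: dropping %d isolated nodes",
                        len(isolated))
        g.remove_nodes_from(isolated)
    if classes is not None:
        for node in g.nodes:
            if node in classes.index:
                g.nodes[node]["rollup"] = classes.loc[node, "rollup"]
    return g


def node_topology(net: nx.Graph) -> pd.DataFrame:
    """Degree, betweenness (unnormalized), closeness and eigenvector
    centrality per node, on the unweighted unsigned graph."""
    if net.number_of_nodes() == 0:
        raise ValueError("empty graph")
    deg = dict(net.degree())
    btw = nx.betweenness_centrality(net, normalized=False)
    clo = nx.closeness_centrality(net)
    try:
        eig = nx.eigenvector_centrality_numpy(net)
    except (nx.NetworkXException, TypeError):
        eig = {v: np.nan for v in net.nodes}
    return pd.DataFrame({"degree": deg, "betweenness": btw,
                         "closeness": clo, "eigenvector": eig})


def detect_modules(net: nx.Graph, seed: int = 0, resolution: float = 1.0,
                   major_size: int = 40) -> tuple[pd.Series, float]:
    """Louvain modules on the unsigned graph.

    Modules are labeled 0, 1, 2, … by descending size; the returned
    Series carries a ``major`` attribute listing modules with more than
    ``major_size`` nodes. Returns (labels, modularity Q).
    """
    if net.number_of_edges() == 0:
        raise ValueError("graph has no edges")
    comms = louvain_communities(net, seed=seed, resolution=resolution)
    comms = sorted(comms, key=len, reverse=True)
    q = modularity(net, comms, resolution=resolution)
    labels = {}
    for lab, members in enumerate(comms):
        for v in members:
            labels[v] = lab
    ser = pd.Series(labels, name="module")
    ser.attrs["major"] = [i for i, c in enumerate(comms) if len(c) > major_size]
    ser.attrs["sizes"] = [len(c) for c in comms]
    return ser, float(q)


def _power_law_r2(net: nx.Graph) -> float:
    """R² of the log–log OLS fit of degree-count vs degree."""
    degs = np.array([d for _, d in net.degree()])
    degs = degs[degs > 0]
    if degs.size == 0:
        return np.nan
    vals, counts = np.unique(degs, return_counts=True)
    if len(vals) < 3:
        return np.nan
    res = stats.linregress(np.log10(vals), np.log10(counts))
    return float(res.rvalue ** 2)


def global_topology(net: nx.Graph, seed: int = 0,
                    with_modularity: bool = True) -> dict:
    """Graph-level summary statistics.

    Average path length is computed over the largest connected
    component; modularity comes from Louvain; the power-law R² is the
    log–log OLS fit to the degree histogram.
    """
    if net.number_of_nodes() == 0:
        raise ValueError("empty graph")
    out: dict = {
        "n_nodes": net.number_of_nodes(),
        "n_edges": net.number_of_edges(),
        "avg_clustering": nx.average_clustering(net),
    }
    if net.number_of_nodes() > 1:
        lcc = net.subgraph(max(nx.connected_components(net), key=len))
        out["avg_path_length"] = (nx.average_shortest_path_length(lcc)
                                  if lcc.number_of_nodes() > 1 else np.nan)
    else:
        out["avg_path_length"] = np.nan
    if with_modularity and net.number_of_edges() > 0:
        mods, q = detect_modules(net, seed=seed)
        out["modularity"] = q
        out["module_sizes"] = mods.attrs["sizes"]
    pos = sum(1 for _, _, d in net.edges(data=True) if d.get("sign", 1) > 0)
    out["n_positive_edges"] = pos
    out["n_negative_edges"] = net.number_of_edges() - pos
    out["power_law_r2"] = _power_law_r2(net)
    return out


def er_null_ensemble(net: nx.Graph, n_random: int = 1000, seed: int = 0,
                     metrics: tuple = ("modularity", "avg_clustering",
                                       "avg_path_length")) -> pd.DataFrame:
    """Benchmark graph statistics against Erdős–Rényi G(n, m) nulls.

    Each null has exactly the observed node and edge counts. Returns one
    row per metric with the real value, null mean and sd, z-score and
    the empirical percentile of the real value in the ensemble; the raw
    null draws sit in ``attrs['null_values']``.
    """
    n = net.number_of_nodes()
    m = net.number_of_edges()
    if m < 1:
        raise ValueError("graph has no edges")
    if m > n * (n - 1) // 2:
        raise ValueError("more edges than pairs of nodes")
    real = global_topology(net, seed=seed,
                           with_modularity="modularity" in metrics)
    rng = np.random.default_rng(seed)
    draws = {k: np.empty(n_random) for k in metrics}
    for b in range(n_random):
        g = nx.gnm_random_graph(n, m, seed=int(rng.integers(2 ** 31)))
        if "modularity" in metrics:
            comms = louvain_communities(g, seed=int(rng.integers(2 ** 31)))
            draws["modularity"][b] = modularity(g, comms)
        if "avg_clustering" in metrics:
            draws["avg_clustering"][b] = nx.average_clustering(g)
        if "avg_path_length" in metrics:
            lcc = g.subgraph(max(nx.connected_components(g), key=len))
            draws["avg_path_length"][b] = (
                nx.average_shortest_path_length(lcc)
                if lcc.number_of_nodes() > 1 else np.nan)
    rows = []
    for k in metrics:
        vals = draws[k]
        mu, sd = float(np.nanmean(vals)), float(np.nanstd(vals, ddof=1))
        rv = float(real[k])
        rows.append({"metric": k, "real": rv, "null_mean": mu, "null_sd": sd,
                     "z": (rv - mu) / sd if sd > 0 else np.inf,
                     "percentile": float(100.0 * np.nanmean(vals < rv))})
    out = pd.DataFrame(rows).set_index("metric")
    out.attrs["null_values"] = draws
    out.attrs["n_random"] = n_random
    return out


def keystone_taxa(node_stats: pd.DataFrame,
                  classes: pd.DataFrame | None = None,
                  degree_min: int = 100,
                  betweenness_max: float = 5000) -> pd.DataFrame:
    """Keystone nodes: degree strictly above ``degree_min`` and raw
    betweenness strictly below ``betweenness_max``."""
    keep = (node_stats["degree"] > degree_min) & \
           (node_stats["betweenness"] < betweenness_max)
    out = node_stats[keep].copy()
    if classes is not None:
        out["rollup"] = classes["rollup"].reindex(out.index)
    return out


def zi_pi(net: nx.Graph, modules: pd.Series,
          z_threshold: float = 2.5, p_threshold: float = 0.62
          ) -> pd.DataFrame:
    """Within-module degree z-score (Zi) and participation coefficient (Pi).

    Zi standardizes a node's number of links to its own module against
    that module's mean and sd (z = 0 where the sd is 0); Pi = 1 − Σₛ
    (k_is/k_i)² measures how evenly a node's links spread over modules.
    Roles: module hub (z ≥ 2.5, P < 0.62), connector (P ≥ 0.62,
    z < 2.5), network hub (both), peripheral (neither). Isolated nodes
    are peripheral with a flag.
    """
    modules = modules.reindex(list(net.nodes))
    rows = []
    within_degree = {}
    for v in net.nodes:
        counts: dict = {}
        for u in net.neighbors(v):
            counts[modules[u]] = counts.get(modules[u], 0) + 1
        within_degree[v] = counts
    module_stats = {}
    for mod in modules.unique():
        members = modules.index[modules == mod]
        k_own = np.array([within_degree[v].get(mod, 0) for v in members],
                         dtype=float)
        module_stats[mod] = (k_own.mean(), k_own.std(ddof=0))
    for v in net.nodes:
        mod = modules[v]
        k_total = net.degree(v)
        counts = within_degree[v]
        mu, sd = module_stats[mod]
        z = (counts.get(mod, 0) - mu) / sd if sd > 0 else 0.0
        if k_total == 0:
            rows.append({"node": v, "module": mod, "z": np.nan, "P": np.nan,
                         "role": "peripheral", "isolated": True})
            continue
        p = 1.0 - sum((k / k_total) ** 2 for k in counts.values())
        if z >= z_threshold and p >= p_threshold:
            role = "network hub"
        elif z >= z_threshold:
            role = "module hub"
        elif p >= p_threshold:
            role = "connector"
        else:
            role = "peripheral"
        rows.append({"node": v, "module": mod, "z": float(z), "P": float(p),
                     "role": role, "isolated": False})
    return pd.DataFrame(rows).set_index("node")


def module_env_association(table: OtuTable, modules: pd.Series,
                           meta: SampleFrame, r_threshold: float = 0.8,
                           p_threshold: float = 0.01) -> pd.DataFrame:
    """Count, per (module, environmental variable), the module members
    whose abundance profile passes the Spearman screen against the
    variable (same thresholds as the OTU–OTU network)."""
    n = table.n_samples
    arr = table.counts.to_numpy().astype(float)
    out = {}
    for var in meta.env.columns:
        v = meta.env[var].reindex(table.sample_ids).to_numpy(dtype=float)
        if np.isnan(v).any() or np.std(v) == 0:
            logger.info("module_env_association: skipping %r "
                        "(constant or missing)", var)
            continue
        rho = np.array([stats.spearmanr(arr[i], v).statistic
                        if arr[i].std() > 0 else np.nan
                        for i in range(len(arr))])
        pv = spearman_pvalue(np.nan_to_num(rho), n)
        hit = (~np.isnan(rho)) & (np.abs(rho) > r_threshold) & (pv < p_threshold)
        hits = pd.Series(hit, index=table.counts.index)
        counts = hits.groupby(modules.reindex(table.counts.index)).sum()
        out[var] = counts.astype(int)
    return pd.DataFrame(out).fillna(0).astype(int)
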