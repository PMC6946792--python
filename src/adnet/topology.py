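"""Topological properties, module detection and node roles.

Conventions:

* harmonic geodesic distance GD = N_pairs / sum(1/d_ij); unreachable pairs
  contribute zero reciprocal, so disconnected graphs get a finite GD.
* average clustering counts nodes of degree < 2 as 0.
* modularity is Newman's Q, maximized by deterministic greedy agglomeration
  (igraph fast-greedy); leading-eigenvector is available as an alternative.
* node roles follow the Guimera-Amaral z-P scheme: within-module degree
  z-score and participation coefficient P, with module hubs at z > 2.5 and
  P <= 0.62.
* centralizations use Freeman's formulas (star-graph maxima).
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, asdict

import igraph as ig
import networkx as nx
import numpy as np
import pandas as pd
from scipy import stats
from scipy.sparse import csr_matrix
from scipy.sparse.csgraph import shortest_path

from .io_formats import AbundanceTable, SampleMetadata, ENV_PARAMS, PERFORMANCE_PARAMS

logger = logging.getLogger(__name__)


def _to_igraph(net: nx.Graph) -> tuple[ig.Graph, list]:
    nodes = list(net.nodes)
    index = {n: i for i, n in enumerate(nodes)}
    g = ig.Graph(n=len(nodes), edges=[(index[u], index[v]) for u, v in net.edges])
    return g, nodes


def _pairwise_distances(net: nx.Graph) -> np.ndarray:
    nodes = list(net.nodes)
    A = nx.to_scipy_sparse_array(net, nodelist=nodes, weight=None, format="csr")
    return shortest_path(csr_matrix(A), method="D", unweighted=True, directed=False)


def harmonic_geodesic(net: nx.Graph) -> float:
    """Harmonic mean shortest-path length over all node pairs."""
    n = net.number_of_nodes()
    if n < 2:
        raise ValueError("need at least 2 nodes")
    D = _pairwise_distances(net)
    d = D[np.triu_indices(n, 1)]
    finite = np.isfinite(d) & (d > 0)
    if not finite.any():
        raise ValueError("no finite-distance pair in the graph")
    return float(len(d) / (1.0 / d[finite]).sum())


def average_clustering(net: nx.Graph) -> float:
    g, _ = _to_igraph(net)
    return float(g.transitivity_avglocal_undirected(mode="zero"))


def detect_modules(
    net: nx.Graph,
    method: str = "greedy",
    seed: int | None = None,
    init_partition: dict | None = None,
) -> tuple[dict, float, int]:
    """Non-overlapping module partition maximizing Newman modularity.

    ``greedy`` (default) is deterministic agglomerative merging;
    ``leading_eigenvector`` is the spectral alternative.  When
    ``init_partition`` is given, greedy merging starts from that partition
    (so the returned Q never falls below the initial partition's Q).
    Isolated nodes become singleton modules.
    """
    if net.number_of_edges() == 0:
        part = {n: i for i, n in enumerate(net.nodes)}
        return part, 0.0, len(part)
    if init_partition is not None:
        return _greedy_from_partition(net, init_partition)
    g, nodes = _to_igraph(net)
    if method == "greedy":
        clustering = g.community_fastgreedy().as_clustering()
    elif method == "leading_eigenvector":
        clustering = g.community_leading_eigenvector()
    else:
        raise ValueError(f"unknown module detection method {method!r}")
    membership = clustering.membership
    part = {nodes[i]: int(m) for i, m in enumerate(membership)}
    q = modularity(net, part)
    return part, q, len(set(membership))


def modularity(net: nx.Graph, partition: dict) -> float:
    """Newman modularity Q = sum_m (e_mm - a_m^2) of a node partition."""
    m = net.number_of_edges()
    if m == 0:
        return 0.0
    comms: dict = {}
    for node, c in partition.items():
        comms.setdefault(c, set()).add(node)
    return float(nx.algorithms.community.modularity(net, list(comms.values())))


def _greedy_from_partition(net: nx.Graph, init: dict) -> tuple[dict, float, int]:
    """Greedy pairwise merging of the initial communities while Q improves.

    With e_ij the fraction of edges between communities i and j (e_ii within),
    Q = sum_i (e_ii - a_i^2) where a_i = e_ii + sum_{j!=i} e_ij / 2, and
    merging i, j changes Q by e_ij - 2 a_i a_j; merges are applied greedily
    while the best change is positive, so Q never drops below Q(init).
    """
    m = net.number_of_edges()
    comm_ids = sorted(set(init[n] for n in net.nodes), key=str)
    cid = {c: i for i, c in enumerate(comm_ids)}
    member = {n: cid[init[n]] for n in net.nodes}
    k = len(comm_ids)
    e = np.zeros((k, k))
    for u, v in net.edges:
        i, j = member[u], member[v]
        e[i, j] += 1
        if i != j:
            e[j, i] += 1
    e /= m
    a = np.diag(e) + (e.sum(axis=1) - np.diag(e)) / 2.0
    alive = list(range(k))
    while len(alive) > 1:
        best, best_dq = None, 1e-12
        for ii, i in enumerate(alive):
            for j in alive[ii + 1:]:
                if e[i, j] == 0:
                    continue
                dq = e[i, j] - 2.0 * a[i] * a[j]
                if dq > best_dq:
                    best, best_dq = (i, j), dq
        if best is None:
            break
        i, j = best
        for l in alive:
            if l not in (i, j):
                e[i, l] += e[j, l]
                e[l, i] = e[i, l]
        e[i, i] += e[j, j] + e[i, j]
        e[i, j] = e[j, i] = 0.0
        a[i] += a[j]
        alive.remove(j)
        member = {n: (i if c == j else c) for n, c in member.items()}
    part = {n: member[n] for n in net.nodes}
    return part, modularity(net, part), len(set(part.values()))


def powerlaw_fit(net: nx.Graph) -> tuple[float, float]:
    """R^2 and slope-significance p of the log-log OLS fit of the degree
    histogram (frequency ~ degree over nonzero-frequency degrees)."""
    degrees = np.array([d for _, d in net.degree()])
    degrees = degrees[degrees > 0]
    values, counts = np.unique(degrees, return_counts=True)
    if len(values) < 5:
        raise ValueError("need at least 5 distinct positive degree values")
    res = stats.linregress(np.log(values), np.log(counts))
    return float(res.rvalue**2), float(res.pvalue)


def _centralization(values: np.ndarray, theoretical_max: float) -> float:
    if theoretical_max <= 0:
        return 0.0
    return float((values.max() - values).sum() / theoretical_max)


@dataclass
class TopologySummary:
    n_nodes: int
    n_edges: int
    pct_positive_edges: float
    powerlaw_r2: float
    powerlaw_p: float
    avgK: float
    GD: float
    avgCC: float
    modularity: float
    n_modules: int
    centralization_degree: float
    centralization_betweenness: float
    centralization_closeness: float

    def as_dict(self) -> dict:
        return asdict(self)


def summarize(net: nx.Graph, module_method: str = "greedy") -> TopologySummary:
    """All Table-1-style topological properties of a signed simple graph.

    Edge signs are ignored except for the percent-positive column.
    """
    n, m = net.number_of_nodes(), net.number_of_edges()
    if m == 0:
        raise ValueError("network has no edges")
    signs = [d.get("sign", "positive") for _, _, d in net.edges(data=True)]
    pct_pos = 100.0 * sum(s == "positive" for s in signs) / m
    try:
        r2, pl_p = powerlaw_fit(net)
    except ValueError:
        r2, pl_p = np.nan, np.nan
    _, q, n_mod = detect_modules(net, method=module_method)

    deg = np.array([d for _, d in net.degree()], dtype=float)
    cent_deg = _centralization(deg, (n - 1.0) * (n - 2.0)) if n > 2 else 0.0
    btw = np.array(list(nx.betweenness_centrality(net, normalized=False).values()))
    cent_btw = (
        _centralization(btw, (n - 1.0) ** 2 * (n - 2.0) / 2.0) if n > 2 else 0.0
    )
    clo = np.array(list(nx.closeness_centrality(net).values()))
    cent_clo = (
        _centralization(clo, (n - 2.0) * (n - 1.0) / (2.0 * n - 3.0)) if n > 2 else 0.0
    )
    return TopologySummary(
        n_nodes=n, n_edges=m, pct_positive_edges=pct_pos,
        powerlaw_r2=r2, powerlaw_p=pl_p,
        avgK=2.0 * m / n, GD=harmonic_geodesic(net),
        avgCC=average_clustering(net), modularity=q, n_modules=n_mod,
        centralization_degree=cent_deg, centralization_betweenness=cent_btw,
        centralization_closeness=cent_clo,
    )


@dataclass
class NodeRole:
    node: object
    module: object
    z: float
    p: float
    role: str


def node_roles(
    net: nx.Graph,
    partition: dict,
    z_hub: float = 2.5,
    p_connector: float = 0.62,
) -> list[NodeRole]:
    """Classify nodes by within-module degree z-score and participation
    coefficient: module hub (z > z_hub, P <= p_connector), connector
    (P > p_connector only), network hub (both exceeded), else peripheral."""
    missing = [n for n in net.nodes if n not in partition]
    if missing:
        raise ValueError(f"partition does not cover nodes: {missing[:5]}")
    within = {}
    for n in net.nodes:
        within[n] = sum(1 for nb in net[n] if partition[nb] == partition[n])
    by_module: dict = {}
    for n in net.nodes:
        by_module.setdefault(partition[n], []).append(n)
    roles = []
    for n in net.nodes:
        members = by_module[partition[n]]
        kw = np.array([within[u] for u in members], dtype=float)
        sd = kw.std()
        z = 0.0 if sd == 0 else (within[n] - kw.mean()) / sd
        k = net.degree(n)
        if k == 0:
            p = 0.0
        else:
            per_mod: dict = {}
            for nb in net[n]:
                per_mod[partition[nb]] = per_mod.get(partition[nb], 0) + 1
            p = 1.0 - sum((c / k) ** 2 for c in per_mod.values())
        hub = z > z_hub
        conn = p > p_connector
        role = ("network hub" if hub and conn else
                "module hub" if hub else
                "connector" if conn else "peripheral")
        roles.append(NodeRole(node=n, module=partition[n], z=float(z), p=float(p),
                              role=role))
    return roles


def per_sample_subnetworks(net: nx.Graph, table: AbundanceTable) -> dict:
    """Induced subgraph per sample on the taxa present (abundance > 0)."""
    missing = [n for n in net.nodes if n not in table.data.index]
    if missing:
        raise ValueError(f"network nodes absent from the table: {missing[:5]}")
    out = {}
    for s in table.samples:
        present = set(table.data.index[table.data[s] > 0])
        sub = net.subgraph([n for n in net.nodes if n in present]).copy()
        if sub.number_of_nodes() == 0:
            logger.warning("sample %r shares no taxa with the network", s)
        out[s] = sub
    return out


def topology_vs_parameters(
    summaries: pd.DataFrame,
    metadata: SampleMetadata,
    parameters: tuple = ENV_PARAMS + PERFORMANCE_PARAMS,
    alpha: float = 0.05,
) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Spearman r and two-sided p between each per-sample topological
    property (rows of ``summaries`` indexed by sample) and each metadata
    parameter.  Constant properties yield NaN (masked)."""
    if len(summaries) < 5:
        raise ValueError("need at least 5 samples")
    samples = [s for s in summaries.index if s in metadata.df.index]
    r = pd.DataFrame(index=summaries.columns, columns=list(parameters), dtype=float)
    p = r.copy()
    for prop in summaries.columns:
        x = summaries.loc[samples, prop].to_numpy(dtype=float)
        for param in parameters:
            y = metadata.df.loc[samples, param].to_numpy(dtype=float)
            ok = np.isfinite(x) & np.isfinite(y)
            if ok.sum() < 5 or np.std(x[ok]) == 0 or np.std(y[ok]) == 0:
                continue
            res = stats.spearmanr(x[ok], y[ok])
            r.loc[prop, param] = res.statistic
            p.loc[prop, param] = res.pvalue
    return r, p
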