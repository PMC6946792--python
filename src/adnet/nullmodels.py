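"""Random-graph null models and between-taxa edge effect sizes.

The null ensemble is uniform G(n, m): simple labelled graphs with exactly
the empirical node and edge counts, edge positions fully randomized.  Each
empirical metric is compared against the ensemble mean and SD (z-score) and
against the ensemble rank (empirical p).  Effect sizes between taxon groups
(phyla or classes) are (observed - random mean) / random SD of the edge
count between the two label sets, with |effect| > 2 deemed significant.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import networkx as nx
import numpy as np
import pandas as pd

from . import topology

logger = logging.getLogger(__name__)

ENSEMBLE_METRICS = ("GD", "avgCC", "modularity")


@dataclass
class RandomEnsembleStats:
    n_nodes: int
    n_edges: int
    reps: int
    values: dict  # metric -> np.ndarray of per-replicate values
    seed: int | None = None

    def mean(self, metric: str) -> float:
        return float(np.mean(self.values[metric]))

    def sd(self, metric: str) -> float:
        return float(np.std(self.values[metric], ddof=1))

    def summary(self) -> pd.DataFrame:
        return pd.DataFrame({
            "metric": list(self.values),
            "mean": [self.mean(m) for m in self.values],
            "sd": [self.sd(m) for m in self.values],
        })


def _gnm(n_nodes: int, n_edges: int, rng: np.random.Generator) -> nx.Graph:
    """Uniform simple random graph with exactly n nodes and m edges."""
    max_edges = n_nodes * (n_nodes - 1) // 2
    picks = rng.choice(max_edges, size=n_edges, replace=False)
    # decode linear upper-triangle index -> (i, j), i < j
    g = nx.empty_graph(n_nodes)
    i = (
        n_nodes - 2
        - np.floor(np.sqrt(-8.0 * picks + 4 * n_nodes * (n_nodes - 1) - 7) / 2.0 - 0.5)
    ).astype(int)
    j = (picks + i + 1 - i * (2 * n_nodes - i - 1) // 2).astype(int)
    g.add_edges_from(zip(i.tolist(), j.tolist()))
    return g


def random_ensemble(
    n_nodes: int,
    n_edges: int,
    reps: int = 100,
    seed: int | None = None,
    metrics: tuple = ENSEMBLE_METRICS,
    keep_graphs: bool = True,
    nodes: list | None = None,
) -> tuple[RandomEnsembleStats, list]:
    """Generate ``reps`` uniform G(n, m) graphs and their metric values.

    ``nodes`` optionally relabels vertices (e.g. with the empirical taxon
    IDs) so that group-wise edge counting is possible downstream.
    """
    if reps < 2:
        raise ValueError("reps must be >= 2")
    max_edges = n_nodes * (n_nodes - 1) // 2
    if not 0 < n_edges <= max_edges:
        raise ValueError(f"cannot place {n_edges} simple edges on {n_nodes} nodes")
    if nodes is not None and len(nodes) != n_nodes:
        raise ValueError("nodes must have length n_nodes")
    rng = np.random.default_rng(seed)
    values = {m: np.empty(reps) for m in metrics}
    graphs = []
    for r in range(reps):
        g = _gnm(n_nodes, n_edges, rng)
        if "GD" in values:
            values["GD"][r] = topology.harmonic_geodesic(g)
        if "avgCC" in values:
            values["avgCC"][r] = topology.average_clustering(g)
        if "modularity" in values:
            _, q, _ = topology.detect_modules(g)
            values["modularity"][r] = q
        if keep_graphs:
            if nodes is not None:
                g = nx.relabel_nodes(g, dict(enumerate(nodes)))
            graphs.append(g)
    stats_ = RandomEnsembleStats(n_nodes=n_nodes, n_edges=n_edges, reps=reps,
                                 values=values, seed=seed)
    return stats_, graphs


def compare_to_random(
    empirical: topology.TopologySummary, ens: RandomEnsembleStats
) -> pd.DataFrame:
    """Per-metric z-score and two-sided empirical p of the observed network
    against its size-matched random ensemble."""
    if (empirical.n_nodes, empirical.n_edges) != (ens.n_nodes, ens.n_edges):
        raise ValueError(
            f"ensemble size ({ens.n_nodes}, {ens.n_edges}) does not match the "
            f"network ({empirical.n_nodes}, {empirical.n_edges})"
        )
    emp = empirical.as_dict()
    rows = []
    for metric, vals in ens.values.items():
        obs = float(emp[metric])
        mean, sd = float(np.mean(vals)), float(np.std(vals, ddof=1))
        if sd > 0:
            z = (obs - mean) / sd
        else:
            z = 0.0 if obs == mean else np.inf * np.sign(obs - mean)
        # two-sided rank p with the observation included in the ensemble
        more_extreme = np.sum(np.abs(vals - mean) >= abs(obs - mean) - 1e-15)
        p = min(1.0, (more_extreme + 1) / (len(vals) + 1))
        if not np.isfinite(z):
            p = 1.0 / len(vals)
        rows.append({"metric": metric, "observed": obs, "random_mean": mean,
                     "random_sd": sd, "z": z, "p": p,
                     "direction": "higher" if obs > mean else
                                  "lower" if obs < mean else "equal"})
    return pd.DataFrame(rows).set_index("metric")


def _count_group_edges(g: nx.Graph, grouping: dict, sign_channel: str = "all") -> dict:
    counts: dict = {}
    for u, v, d in g.edges(data=True):
        if sign_channel != "all" and d.get("sign", "positive") != sign_channel:
            continue
        gu, gv = grouping.get(u), grouping.get(v)
        if gu is None or gv is None:
            continue
        key = tuple(sorted((str(gu), str(gv))))
        counts[key] = counts.get(key, 0) + 1
    return counts


def group_effect_sizes(
    net: nx.Graph,
    grouping: dict,
    ensemble_graphs: list,
    sign_channel: str = "all",
    effect_threshold: float = 2.0,
) -> pd.DataFrame:
    """Effect size of the edge count between every pair of taxon groups.

    ``grouping`` maps each network node to a group (phylum or class label);
    ensemble graphs must carry the same node labels with randomized edge
    positions.  Effect size = (observed - random mean) / random SD; NA when
    the random SD is 0.
    """
    missing = [n for n in net.nodes if n not in grouping]
    if missing:
        raise ValueError(f"grouping does not cover nodes: {missing[:5]}")
    groups = sorted({str(g) for g in grouping.values()})
    empty = [g for g in groups
             if not any(str(grouping[n]) == g for n in net.nodes)]
    for g in empty:
        logger.warning("group %r has no nodes; skipped", g)
    observed = _count_group_edges(net, grouping, sign_channel)
    rand = [_count_group_edges(g, grouping, "all") for g in ensemble_graphs]
    pairs = sorted(set(observed) | {k for r in rand for k in r})
    rows = []
    for pair in pairs:
        obs = observed.get(pair, 0)
        vals = np.array([r.get(pair, 0) for r in rand], dtype=float)
        mean, sd = float(vals.mean()), float(vals.std(ddof=1))
        es = (obs - mean) / sd if sd > 0 else np.nan
        rows.append({
            "group_a": pair[0], "group_b": pair[1], "observed": obs,
            "random_mean": mean, "random_sd": sd, "effect_size": es,
            "significant": bool(np.isfinite(es) and abs(es) > effect_threshold),
        })
    return pd.DataFrame(rows)
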