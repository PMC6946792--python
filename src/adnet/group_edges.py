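"""Omission-score classification of edges as global vs group-specific.

For every network edge and every phase group, the omission score (OS) is the
Spearman correlation of the two taxa recomputed over the samples NOT in the
group.  The null is built by omitting 500 random sample sets of the same
size.  An edge is specific to a group when the omitted-group correlation
collapses (|OS| < |original rho|) and the nonparametric p — the fraction of
random omissions giving a smaller |OS| — is below 0.05.  Magnitudes are
compared sign-blind so that negative edges are classifiable.  Edges specific
to no group are global.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import networkx as nx
import numpy as np
import pandas as pd
from scipy import stats

from .io_formats import AbundanceTable

logger = logging.getLogger(__name__)


def _spearman_pair(x: np.ndarray, y: np.ndarray) -> float:
    if np.std(x) == 0 or np.std(y) == 0:
        return np.nan
    return float(stats.spearmanr(x, y).statistic)


def omission_score(table: AbundanceTable, edge: tuple, sample_subset) -> float:
    """Spearman rho of the edge's taxa over the samples not in the subset."""
    u, v = edge
    omit = set(sample_subset)
    keep = [s for s in table.samples if s not in omit]
    if len(keep) < 4:
        raise ValueError("fewer than 4 samples remain after omission")
    x = table.data.loc[u, keep].to_numpy(dtype=float)
    y = table.data.loc[v, keep].to_numpy(dtype=float)
    r = _spearman_pair(x, y)
    if np.isnan(r):
        logger.warning("edge %s: a taxon is constant after omitting %d samples",
                       edge, len(omit))
    return r


def _rank_rows(X: np.ndarray) -> np.ndarray:
    return stats.rankdata(X, axis=1)


def _edge_correlations(X: np.ndarray, ei: np.ndarray, ej: np.ndarray) -> np.ndarray:
    """Pearson correlation of rank-transformed rows for each edge (vectorized
    Spearman with average-rank ties).  Constant rows give NaN."""
    R = _rank_rows(X)
    R = R - R.mean(axis=1, keepdims=True)
    norm = np.sqrt((R**2).sum(axis=1))
    with np.errstate(invalid="ignore", divide="ignore"):
        num = (R[ei] * R[ej]).sum(axis=1)
        return num / (norm[ei] * norm[ej])


@dataclass
class EdgeGroupClassification:
    """Per (edge, group) omission-score record."""

    edge: tuple
    group: str
    original_rho: float
    omission_score: float
    ratio: float
    null_mean: float
    null_sd: float
    p: float
    group_specific: bool


def classify_edges(
    table: AbundanceTable,
    net: nx.Graph,
    groups: dict,
    n_random: int = 500,
    alpha: float = 0.05,
    seed: int | None = None,
) -> pd.DataFrame:
    """Classify every edge of ``net`` per sample group.

    ``groups`` maps group label -> sample IDs (the four phase groups in the
    digester design).  Returns one row per (edge, group) with the original
    rho, the group OS, OS/|rho| ratio, the random-omission null summary, the
    nonparametric p (#{|random OS| < |group OS|} / n_random) and the
    group-specific flag; plus a ``global`` column that is True for all rows
    of an edge flagged for no group.
    """
    if n_random < 100:
        raise ValueError("n_random must be >= 100")
    samples = list(table.samples)
    pos = {s: i for i, s in enumerate(samples)}
    covered = [s for g in groups.values() for s in g]
    if set(covered) - set(samples):
        raise ValueError("group samples absent from the table")
    for label, g in groups.items():
        if len(samples) - len(g) < 4:
            raise ValueError(f"group {label!r} leaves fewer than 4 samples")

    edges = [tuple(e) for e in net.edges]
    if not edges:
        return pd.DataFrame(columns=[
            "source", "target", "group", "original_rho", "omission_score",
            "ratio", "null_mean", "null_sd", "p", "group_specific", "global"])
    taxa_idx = {t: i for i, t in enumerate(table.data.index)}
    X = table.values()
    ei = np.array([taxa_idx[u] for u, _ in edges])
    ej = np.array([taxa_idx[v] for _, v in edges])

    original = _edge_correlations(X, ei, ej)
    rng = np.random.default_rng(seed)
    rows = []
    flagged_any = np.zeros(len(edges), dtype=bool)
    for label, members in groups.items():
        k = len(members)
        omit_mask = np.zeros(len(samples), dtype=bool)
        omit_mask[[pos[s] for s in members]] = True
        os_group = _edge_correlations(X[:, ~omit_mask], ei, ej)
        # shared random same-size omission sets across edges
        null_os = np.empty((n_random, len(edges)))
        for r in range(n_random):
            omit = rng.choice(len(samples), size=k, replace=False)
            mask = np.ones(len(samples), dtype=bool)
            mask[omit] = False
            null_os[r] = _edge_correlations(X[:, mask], ei, ej)
        abs_null = np.abs(null_os)
        abs_group = np.abs(os_group)
        with np.errstate(invalid="ignore"):
            p = np.nanmean(abs_null < abs_group[None, :], axis=0)
        specific = (abs_group < np.abs(original)) & (p < alpha)
        flagged_any |= np.where(np.isnan(p), False, specific)
        for e_idx, (u, v) in enumerate(edges):
            rows.append({
                "source": u, "target": v, "group": label,
                "original_rho": float(original[e_idx]),
                "omission_score": float(os_group[e_idx]),
                "ratio": float(abs_group[e_idx] / abs(original[e_idx]))
                if original[e_idx] else np.nan,
                "null_mean": float(np.nanmean(abs_null[:, e_idx])),
                "null_sd": float(np.nanstd(abs_null[:, e_idx])),
                "p": float(p[e_idx]),
                "group_specific": bool(specific[e_idx]),
            })
    df = pd.DataFrame(rows)
    edge_key = list(zip(df["source"], df["target"]))
    flagged = {e: f for e, f in zip(edges, flagged_any)}
    df["global"] = [not flagged[e] for e in edge_key]
    return df


def group_subnetwork(
    net: nx.Graph,
    classifications: pd.DataFrame,
    group: str,
    include_global: bool = False,
) -> nx.Graph:
    """Subnetwork of the edges specific to ``group`` (optionally plus the
    global edges), with their incident nodes."""
    sub = classifications[classifications["group"] == group]
    if sub.empty and group not in set(classifications["group"]):
        raise KeyError(f"group {group!r} not present in the classification")
    keep = sub[sub["group_specific"]]
    pairs = set(zip(keep["source"], keep["target"]))
    if include_global:
        glob = classifications[classifications["global"]]
        pairs |= set(zip(glob["source"], glob["target"]))
    g = nx.Graph()
    for u, v, d in net.edges(data=True):
        if (u, v) in pairs or (v, u) in pairs:
            g.add_edge(u, v, **d)
    for n in g.nodes:
        g.nodes[n].update(net.nodes[n])
    if g.number_of_edges() == 0:
        logger.warning("no edges are specific to group %r", group)
    return g
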