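"""Gene significance and Mantel / partial-Mantel analysis.

Gene significance (GS) of a taxon for a parameter is the squared Pearson
correlation of its abundance profile with that parameter across samples.
Two GS matrices are built (environmental parameters: total ammonia, acetate,
pH, VS load; performance parameters: biogas production, methane production,
VS removal), distances among taxa are derived from the GS row-vectors and
from network connectivity (|degree difference|), and their agreement is
tested by Mantel and partial Mantel permutation tests, overall and within
domain- and class-level taxon subsets.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import networkx as nx
import numpy as np
import pandas as pd
from scipy.spatial.distance import pdist, squareform
from skbio import DistanceMatrix

from .io_formats import (
    AbundanceTable,
    SampleMetadata,
    ENV_PARAMS,
    PERFORMANCE_PARAMS,
)

logger = logging.getLogger(__name__)


def gene_significance(table: AbundanceTable, parameter_vector) -> pd.Series:
    """GS = r^2 of each taxon's abundance with the parameter across samples.

    Constant taxa (or a constant parameter) yield NaN.
    """
    y = np.asarray(parameter_vector, dtype=float)
    if table.n_samples < 4:
        raise ValueError("need at least 4 samples")
    if y.shape[0] != table.n_samples:
        raise ValueError("parameter vector length does not match samples")
    if not np.isfinite(y).all():
        raise ValueError("parameter vector must be finite")
    X = table.values()
    xs = X.std(axis=1)
    ys = y.std()
    with np.errstate(invalid="ignore", divide="ignore"):
        r = ((X - X.mean(axis=1, keepdims=True)) @ (y - y.mean())) / (
            X.shape[1] * xs * ys
        )
    gs = r**2
    gs[(xs == 0)] = np.nan
    if ys == 0:
        gs[:] = np.nan
    return pd.Series(gs, index=table.data.index, name="GS")


def gs_matrix(
    table: AbundanceTable, metadata: SampleMetadata, parameters
) -> pd.DataFrame:
    """Taxon x parameter GS matrix (samples aligned on the metadata)."""
    sub = AbundanceTable(
        data=table.data[metadata.samples], taxonomy=table.taxonomy, kind=table.kind
    )
    cols = {p: gene_significance(sub, metadata.parameter(p).to_numpy())
            for p in parameters}
    return pd.DataFrame(cols)


def gs_distance(
    gs: pd.DataFrame, taxa_subset=None, metric: str = "euclidean"
) -> DistanceMatrix:
    """Distance between taxa's GS row-vectors (default Euclidean)."""
    sub = gs if taxa_subset is None else gs.loc[list(taxa_subset)]
    na = sub.isna().any(axis=1)
    if na.any():
        logger.warning("%d taxa with undefined GS dropped", int(na.sum()))
        sub = sub[~na]
    if len(sub) < 3:
        raise ValueError("need at least 3 taxa with defined GS")
    d = squareform(pdist(sub.to_numpy(dtype=float), metric=metric))
    return DistanceMatrix(d, ids=[str(t) for t in sub.index])


def connectivity_distance(net: nx.Graph, taxa_subset=None) -> DistanceMatrix:
    """|degree_i - degree_j| with degrees taken from the overall network,
    restricted to the given taxa."""
    taxa = list(net.nodes) if taxa_subset is None else list(taxa_subset)
    missing = [t for t in taxa if t not in net]
    if missing:
        raise ValueError(f"taxa not in the network: {missing[:5]}")
    k = np.array([net.degree(t) for t in taxa], dtype=float)
    d = np.abs(k[:, None] - k[None, :])
    return DistanceMatrix(d, ids=[str(t) for t in taxa])


@dataclass
class MantelResult:
    r: float
    p: float
    n_permutations: int
    n_taxa: int
    controlled: str | None = None
    subset: str | None = None


def _upper(m: np.ndarray) -> np.ndarray:
    return m[np.triu_indices(m.shape[0], 1)]


def _align(d1: DistanceMatrix, d2: DistanceMatrix) -> tuple[np.ndarray, np.ndarray]:
    if set(d1.ids) != set(d2.ids):
        raise ValueError("distance matrices cover different taxa")
    order = list(d1.ids)
    return d1.data, d2.filter(order).data


def mantel(
    d1: DistanceMatrix,
    d2: DistanceMatrix,
    n_permutations: int = 999,
    seed: int | None = None,
    method: str = "pearson",
) -> MantelResult:
    """Mantel test: correlation of the upper triangles of two distance
    matrices, one-sided (greater) permutation p over simultaneous row/column
    permutations of one matrix; p = (#{r_perm >= r_obs} + 1)/(n_perm + 1)."""
    a, b = _align(d1, d2)
    if a.shape != b.shape:
        raise ValueError("distance matrix size mismatch")
    if method == "spearman":
        from scipy.stats import rankdata
        a = squareform(rankdata(_upper(a)))
        b = squareform(rankdata(_upper(b)))
    x = _upper(a)
    rng = np.random.default_rng(seed)
    n = a.shape[0]
    y = _upper(b)
    r_obs = _pearson(x, y)
    if np.isnan(r_obs):
        logger.warning("Mantel statistic undefined (a distance matrix is constant)")
        return MantelResult(r=np.nan, p=np.nan, n_permutations=n_permutations,
                            n_taxa=n)
    count = 0
    for _ in range(n_permutations):
        perm = rng.permutation(n)
        yp = _upper(b[np.ix_(perm, perm)])
        if _pearson(x, yp) >= r_obs - 1e-15:
            count += 1
    p = (count + 1) / (n_permutations + 1)
    return MantelResult(r=float(r_obs), p=float(p), n_permutations=n_permutations,
                        n_taxa=n)


def _pearson(x: np.ndarray, y: np.ndarray) -> float:
    xc = x - x.mean()
    yc = y - y.mean()
    den = np.sqrt((xc**2).sum() * (yc**2).sum())
    if den == 0:
        return np.nan
    return float((xc * yc).sum() / den)


def partial_mantel(
    d1: DistanceMatrix,
    d2: DistanceMatrix,
    d_control: DistanceMatrix,
    n_permutations: int = 999,
    seed: int | None = None,
) -> MantelResult:
    """Partial Mantel test: correlation of the residuals of d1 and d2 after
    regressing each (upper triangle) on the control distances; permutation
    of one residual vector's underlying matrix for the one-sided p."""
    a, b = _align(d1, d2)
    _, c = _align(d1, d_control)
    x, y, z = _upper(a), _upper(b), _upper(c)
    if z.std() == 0:
        logger.warning("control matrix is constant; falling back to plain Mantel")
        return mantel(d1, d2, n_permutations=n_permutations, seed=seed)

    def residuals(v, w):
        beta = np.cov(v, w)[0, 1] / np.var(w)
        return v - (v.mean() + beta * (w - w.mean()))

    r_obs = _pearson(residuals(x, z), residuals(y, z))
    n = a.shape[0]
    if np.isnan(r_obs):
        logger.warning("partial Mantel statistic undefined (constant residuals)")
        return MantelResult(r=np.nan, p=np.nan, n_permutations=n_permutations,
                            n_taxa=n, controlled="control")
    rng = np.random.default_rng(seed)
    rx = residuals(x, z)
    count = 0
    for _ in range(n_permutations):
        perm = rng.permutation(n)
        yp = _upper(b[np.ix_(perm, perm)])
        zp = _upper(c)  # control kept fixed; d2 rows/cols permuted
        if _pearson(rx, residuals(yp, zp)) >= r_obs - 1e-15:
            count += 1
    p = (count + 1) / (n_permutations + 1)
    return MantelResult(r=float(r_obs), p=float(p), n_permutations=n_permutations,
                        n_taxa=n, controlled="control")


def taxon_subsets(net: nx.Graph, taxonomy: pd.DataFrame, min_nodes: int = 3) -> dict:
    """All / Archaea / Bacteria / per-class node subsets of the network with
    at least ``min_nodes`` members."""
    nodes = [n for n in net.nodes if n in taxonomy.index]
    subsets = {"All": list(nodes)}
    for domain in ("Archaea", "Bacteria"):
        sub = [n for n in nodes if taxonomy.loc[n, "domain"] == domain]
        if len(sub) >= min_nodes:
            subsets[domain] = sub
    for cls, grp in taxonomy.loc[nodes].groupby("class"):
        if cls == "unclassified":
            continue
        if len(grp) >= min_nodes:
            subsets[str(cls)] = list(grp.index)
    return subsets


def table2_analysis(
    net: nx.Graph,
    table: AbundanceTable,
    metadata: SampleMetadata,
    taxonomy: pd.DataFrame | None = None,
    n_permutations: int = 999,
    seed: int | None = None,
    min_nodes: int = 3,
) -> pd.DataFrame:
    """Mantel triple per taxon subset: connectivity distance vs GS of the
    environmental set, vs GS of the performance set, and vs GS of the
    performance set with the environmental GS distances controlled."""
    taxonomy = table.taxonomy if taxonomy is None else taxonomy
    gs_env = gs_matrix(table, metadata, ENV_PARAMS)
    gs_perf = gs_matrix(table, metadata, PERFORMANCE_PARAMS)
    rows = []
    for label, taxa in taxon_subsets(net, taxonomy, min_nodes=min_nodes).items():
        taxa = [t for t in taxa if t in gs_env.index]
        defined = [
            t for t in taxa
            if not (gs_env.loc[t].isna().any() or gs_perf.loc[t].isna().any())
        ]
        if len(defined) < min_nodes:
            logger.info("subset %r skipped: %d usable taxa", label, len(defined))
            rows.append({"subset": label, "n_taxa": len(defined),
                         "skipped": True})
            continue
        d_conn = connectivity_distance(net, defined)
        d_env = gs_distance(gs_env, defined)
        d_perf = gs_distance(gs_perf, defined)
        m_env = mantel(d_conn, d_env, n_permutations, seed=seed)
        m_perf = mantel(d_conn, d_perf, n_permutations, seed=seed)
        m_part = partial_mantel(d_conn, d_perf, d_env, n_permutations, seed=seed)
        rows.append({
            "subset": label, "n_taxa": len(defined), "skipped": False,
            "r_env": m_env.r, "p_env": m_env.p,
            "r_perf": m_perf.r, "p_perf": m_perf.p,
            "r_perf_env_controlled": m_part.r, "p_perf_env_controlled": m_part.p,
        })
    return pd.DataFrame(rows).set_index("subset")
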