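"""Tables, taxonomy, diversity summaries and network serialization.

Abundance tables are taxon-by-sample matrices: integer read counts for 16S
OTU data, or non-negative real signal intensities for functional-gene-array
derived organism abundances.  Taxonomy uses a 7-rank semicolon convention
(domain;phylum;class;order;family;genus;species) with explicit
``unclassified`` placeholders so that class-level subsets can always be
formed.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from pathlib import Path
from typing import Mapping, Sequence

import networkx as nx
import numpy as np
import pandas as pd
from scipy.spatial.distance import pdist, squareform
from skbio import DistanceMatrix

logger = logging.getLogger(__name__)

RANKS = ("domain", "phylum", "class", "order", "family", "genus", "species")
UNCLASSIFIED = "unclassified"

#: metadata columns holding environmental parameters
ENV_PARAMS = ("total_ammonia", "acetate", "ph", "vs_load")
#: metadata columns holding digester performance parameters
PERFORMANCE_PARAMS = ("biogas_production", "methane_production", "vs_removal")

PHASE_GROUPS = ("C 45-76", "T 45-76", "C 80-97", "T 80-97")


def parse_taxonomy(s: str) -> dict[str, str]:
    """Split a semicolon taxonomy string into the 7 canonical ranks.

    Missing or empty trailing ranks become ``unclassified``.
    """
    parts = [p.strip() for p in str(s).split(";")]
    out = {}
    for i, rank in enumerate(RANKS):
        out[rank] = parts[i] if i < len(parts) and parts[i] else UNCLASSIFIED
    return out


def taxonomy_string(ranks: Mapping[str, str]) -> str:
    return ";".join(ranks.get(r, UNCLASSIFIED) for r in RANKS)


@dataclass
class AbundanceTable:
    """Taxon x sample abundance matrix with per-taxon taxonomy.

    Parameters
    ----------
    data:
        DataFrame indexed by taxon ID, columns are sample IDs.  Values are
        non-negative; integer-valued when ``kind == "count"``.
    taxonomy:
        DataFrame indexed like ``data`` with the 7 rank columns.
    kind:
        ``"count"`` for rarefiable read counts, ``"signal"`` for
        gene-array-derived relative abundances.
    """

    data: pd.DataFrame
    taxonomy: pd.DataFrame = None
    kind: str = "count"

    def __post_init__(self):
        if self.kind not in ("count", "signal"):
            raise ValueError(f"kind must be 'count' or 'signal', got {self.kind!r}")
        if self.data.index.duplicated().any():
            dups = self.data.index[self.data.index.duplicated()].unique().tolist()
            raise ValueError(f"duplicate taxon IDs: {dups}")
        if self.data.columns.duplicated().any():
            dups = self.data.columns[self.data.columns.duplicated()].unique().tolist()
            raise ValueError(f"duplicate sample IDs: {dups}")
        vals = self.data.to_numpy()
        if not np.issubdtype(vals.dtype, np.number):
            raise ValueError("abundance values must be numeric")
        if np.isnan(vals).any():
            i, j = np.argwhere(np.isnan(vals))[0]
            raise ValueError(
                f"non-numeric cell at taxon {self.data.index[i]!r}, "
                f"sample {self.data.columns[j]!r}"
            )
        if (vals < 0).any():
            i, j = np.argwhere(vals < 0)[0]
            raise ValueError(
                f"negative value {vals[i, j]} at taxon {self.data.index[i]!r}, "
                f"sample {self.data.columns[j]!r}"
            )
        if self.kind == "count" and not np.allclose(vals, np.round(vals)):
            raise ValueError("count tables must hold integer values")
        if self.taxonomy is None:
            self.taxonomy = pd.DataFrame(
                UNCLASSIFIED, index=self.data.index, columns=list(RANKS)
            )
        else:
            self.taxonomy = self.taxonomy.reindex(self.data.index).fillna(UNCLASSIFIED)

    @property
    def taxon_ids(self) -> list:
        return list(self.data.index)

    @property
    def samples(self) -> list:
        return list(self.data.columns)

    @property
    def n_taxa(self) -> int:
        return self.data.shape[0]

    @property
    def n_samples(self) -> int:
        return self.data.shape[1]

    def values(self) -> np.ndarray:
        return self.data.to_numpy(dtype=float)

    def relative(self) -> pd.DataFrame:
        """Per-sample relative abundances (columns sum to 1)."""
        totals = self.data.sum(axis=0)
        if (totals <= 0).any():
            bad = totals.index[totals <= 0].tolist()
            raise ValueError(f"all-zero samples: {bad}")
        return self.data / totals

    def write(self, path) -> None:
        df = self.data.copy()
        df.insert(0, "taxonomy", [taxonomy_string(r) for _, r in self.taxonomy.iterrows()])
        df.to_csv(path, sep="\t", index_label="taxon_id")


@dataclass
class SampleMetadata:
    """Per-sample design, environmental and performance variables."""

    df: pd.DataFrame  # indexed by sample_id

    REQUIRED = ("digester_id", "group", "day") + ENV_PARAMS + PERFORMANCE_PARAMS

    def __post_init__(self):
        if self.df.index.duplicated().any():
            raise ValueError("duplicate sample IDs in metadata")
        missing = [c for c in self.REQUIRED if c not in self.df.columns]
        if missing:
            raise ValueError(f"metadata missing columns: {missing}")
        bad_group = set(self.df["group"]) - {"control", "treatment"}
        if bad_group:
            raise ValueError(f"unknown groups: {bad_group}")
        num = self.df[list(ENV_PARAMS + PERFORMANCE_PARAMS)].to_numpy(dtype=float)
        if not np.isfinite(num).all():
            raise ValueError("env/performance values must be finite")
        if "phase_group" not in self.df.columns:
            self.df = self.df.assign(phase_group=[
                derive_phase_group(g, d) for g, d in zip(self.df["group"], self.df["day"])
            ])

    @property
    def samples(self) -> list:
        return list(self.df.index)

    def parameter(self, name: str) -> pd.Series:
        return self.df[name].astype(float)

    def phase_groups(self) -> dict[str, list]:
        """Map phase group label -> list of sample IDs."""
        return {g: list(sub.index) for g, sub in self.df.groupby("phase_group", sort=False)}

    def write(self, path) -> None:
        self.df.to_csv(path, sep="\t", index_label="sample_id")


def derive_phase_group(group: str, day: int) -> str:
    prefix = "C" if group == "control" else "T"
    if 45 <= day <= 76:
        return f"{prefix} 45-76"
    if 80 <= day <= 97:
        return f"{prefix} 80-97"
    raise ValueError(f"day {day} outside the phase windows 45-76 / 80-97")


def read_abundance_table(path, kind: str = "count") -> AbundanceTable:
    """Read a tab-delimited taxon x sample table.

    First column is the taxon ID; an optional ``taxonomy`` column carries
    semicolon rank strings; every other column is a sample.  Lines starting
    with ``#`` are ignored.
    """
    df = pd.read_csv(path, sep="\t", comment="#", dtype=str)
    if df.shape[1] < 2:
        raise ValueError(f"{path}: need a taxon column plus at least one sample")
    taxon_col = df.columns[0]
    ids = df[taxon_col]
    if ids.duplicated().any():
        raise ValueError(f"duplicate taxon {ids[ids.duplicated()].iloc[0]!r} in {path}")
    df = df.set_index(taxon_col)
    taxonomy = None
    if "taxonomy" in df.columns:
        taxonomy = pd.DataFrame(
            [parse_taxonomy(s) for s in df["taxonomy"]], index=df.index
        )
        df = df.drop(columns="taxonomy")
    df.index.name = None
    try:
        data = df.astype(float)
    except ValueError:
        for col in df.columns:
            bad = pd.to_numeric(df[col], errors="coerce").isna() & df[col].notna()
            if bad.any():
                raise ValueError(
                    f"non-numeric cell {df[col][bad].iloc[0]!r} at taxon "
                    f"{df.index[bad][0]!r}, sample {col!r}"
                ) from None
        raise
    return AbundanceTable(data=data, taxonomy=taxonomy, kind=kind)


def read_metadata(path) -> SampleMetadata:
    df = pd.read_csv(path, sep="\t", comment="#", index_col=0)
    return SampleMetadata(df=df)


def rarefy(table: AbundanceTable, depth: int, seed: int | None = None) -> AbundanceTable:
    """Subsample each sample to exactly ``depth`` reads without replacement.

    Samples with fewer than ``depth`` total reads are dropped with a warning.
    """
    if table.kind != "count":
        raise ValueError("rarefaction requires a count table")
    depth = int(depth)
    if depth <= 0:
        raise ValueError("rarefaction depth must be >= 1")
    rng = np.random.default_rng(seed)
    kept, cols = [], []
    for s in table.samples:
        counts = table.data[s].to_numpy(dtype=np.int64)
        total = int(counts.sum())
        if total < depth:
            logger.warning("sample %r dropped: total %d < depth %d", s, total, depth)
            continue
        # multivariate hypergeometric == sampling reads without replacement
        kept.append(rng.multivariate_hypergeometric(counts, depth))
        cols.append(s)
    if not cols:
        raise ValueError("no sample reaches the rarefaction depth")
    data = pd.DataFrame(np.column_stack(kept), index=table.data.index, columns=cols)
    return AbundanceTable(data=data, taxonomy=table.taxonomy.copy(), kind="count")


def aggregate_gene_signals(
    gene_table: pd.DataFrame, gene_to_organism: Mapping[str, str]
) -> AbundanceTable:
    """Average functional-gene signal intensities per organism.

    ``gene_table`` is gene x sample; each gene maps to at most one organism.
    An organism's abundance in a sample is the arithmetic mean of its genes'
    signals there.  Unmapped genes are excluded (count logged).
    """
    if not gene_to_organism:
        raise ValueError("empty gene-to-organism mapping")
    mapped = [g for g in gene_table.index if g in gene_to_organism]
    n_excluded = gene_table.shape[0] - len(mapped)
    if n_excluded:
        logger.info("%d genes absent from the mapping were excluded", n_excluded)
    if not mapped:
        raise ValueError("no gene in the table is present in the mapping")
    sub = gene_table.loc[mapped].astype(float)
    org = pd.Series({g: gene_to_organism[g] for g in mapped}, name="organism")
    out = sub.groupby(org).mean()
    out.index.name = None
    return AbundanceTable(data=out, kind="signal")


def inverse_simpson(table: AbundanceTable, sample) -> float:
    """Effective number of taxa, 1 / sum(p_i^2), for one sample."""
    if sample not in table.data.columns:
        raise KeyError(f"sample {sample!r} not in table")
    x = table.data[sample].to_numpy(dtype=float)
    total = x.sum()
    if total <= 0:
        raise ValueError(f"sample {sample!r} is all zero")
    p = x / total
    return float(1.0 / np.sum(p**2))


def bray_curtis(table: AbundanceTable) -> DistanceMatrix:
    """Sample x sample Bray-Curtis dissimilarity matrix."""
    if table.n_samples < 2:
        raise ValueError("need at least 2 samples")
    X = table.values().T  # samples x taxa
    sums = X.sum(axis=1)
    if (sums <= 0).sum() >= 2:
        raise ValueError("Bray-Curtis undefined between two all-zero samples")
    d = squareform(pdist(X, metric="braycurtis"))
    return DistanceMatrix(d, ids=[str(s) for s in table.samples])


# ---------------------------------------------------------------------------
# network serialization
# ---------------------------------------------------------------------------

_EDGE_COLUMNS = ("source", "target", "rho", "sign", "q")


def write_network(net: nx.Graph, path, format: str = "graphml") -> None:
    """Write a signed association network.

    ``edgelist`` is a TSV of (source, target, rho, sign, q); ``graphml``
    additionally carries node taxonomy, module and role attributes and
    round-trips the graph exactly.
    """
    path = Path(path)
    if format == "graphml":
        g = net.copy()
        for _, attrs in g.nodes(data=True):
            for k, v in list(attrs.items()):
                if v is None:
                    del attrs[k]
        nx.write_graphml(g, path)
    elif format == "edgelist":
        rows = [
            {
                "source": u,
                "target": v,
                "rho": d.get("rho", np.nan),
                "sign": d.get("sign", ""),
                "q": d.get("q", np.nan),
            }
            for u, v, d in net.edges(data=True)
        ]
        pd.DataFrame(rows, columns=_EDGE_COLUMNS).to_csv(path, sep="\t", index=False)
    else:
        raise ValueError(f"unsupported network format {format!r}")


def read_network(path, format: str = "graphml") -> nx.Graph:
    path = Path(path)
    if format == "graphml":
        g = nx.read_graphml(path)
        return nx.relabel_nodes(g, {n: str(n) for n in g.nodes})
    if format == "edgelist":
        df = pd.read_csv(path, sep="\t", dtype={"source": str, "target": str})
        g = nx.Graph()
        for row in df.itertuples(index=False):
            g.add_edge(row.source, row.target, rho=float(row.rho), sign=row.sign,
                       q=float(row.q))
        return g
    raise ValueError(f"unsupported network format {format!r}")
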