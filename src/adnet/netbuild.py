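"""Association-network construction.

Pipeline order follows standard molecular-ecological-network practice:
prevalence filtering, all-pairs Spearman correlation, Benjamini-Hochberg
FDR adjustment, then a random-matrix-theory scan that picks the smallest
|rho| cutoff at which the thresholded correlation matrix's
nearest-neighbour eigenvalue spacing distribution (NNSD) turns Poisson
(uncorrelated, modular signal) rather than Gaussian-orthogonal-ensemble
(correlated noise).  Edges require BOTH q <= q_cutoff and |rho| >= cutoff.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import networkx as nx
import numpy as np
import pandas as pd
from scipy import stats
from scipy.interpolate import UnivariateSpline

from .io_formats import AbundanceTable

logger = logging.getLogger(__name__)


def prevalence_filter(table: AbundanceTable, min_samples: float = 9) -> AbundanceTable:
    """Keep taxa detected (nonzero) in strictly more than ``min_samples``
    samples.  A ``min_samples`` in (0, 1) is read as a fraction of samples."""
    if min_samples <= 0:
        raise ValueError("min_samples must be positive")
    thr = min_samples * table.n_samples if min_samples < 1 else min_samples
    present = (table.data > 0).sum(axis=1)
    keep = present > thr
    if keep.sum() < 2:
        raise ValueError("fewer than 2 taxa pass the prevalence filter")
    return AbundanceTable(
        data=table.data.loc[keep].copy(),
        taxonomy=table.taxonomy.loc[keep].copy(),
        kind=table.kind,
    )


@dataclass
class CorrelationSet:
    """All-pairs Spearman correlations with BH-adjusted p values.

    ``valid`` marks taxa that are non-constant across samples; rows/columns
    of constant taxa hold NaN and are excluded from the FDR adjustment and
    from network construction.
    """

    taxa: list
    rho: np.ndarray
    p_raw: np.ndarray
    q: np.ndarray
    valid: np.ndarray

    @property
    def n_taxa(self) -> int:
        return len(self.taxa)

    def valid_rho(self) -> np.ndarray:
        idx = np.where(self.valid)[0]
        return self.rho[np.ix_(idx, idx)]


def bh_adjust(p_values) -> np.ndarray:
    """Benjamini-Hochberg step-up adjustment.

    q_(i) = min_{j >= i} (m * p_(j) / j), capped at 1, in the input order.
    """
    p = np.asarray(p_values, dtype=float)
    if p.size and (np.nanmin(p) < 0 or np.nanmax(p) > 1):
        raise ValueError("p values must lie in [0, 1]")
    q = np.full_like(p, np.nan)
    ok = ~np.isnan(p)
    if ok.any():
        q[ok] = stats.false_discovery_control(p[ok], method="bh")
    return q


def spearman_all_pairs(table: AbundanceTable) -> CorrelationSet:
    """Spearman rho (average ranks for ties) and two-sided p for every taxon
    pair, with BH-adjusted q values over the defined pairs."""
    if table.n_samples < 4:
        raise ValueError("need at least 4 samples for pairwise Spearman")
    X = table.values()
    valid = X.std(axis=1) > 0
    n_const = int((~valid).sum())
    if n_const:
        logger.warning("%d constant taxa excluded from correlation", n_const)
    n = table.n_taxa
    rho = np.full((n, n), np.nan)
    p = np.full((n, n), np.nan)
    idx = np.where(valid)[0]
    if len(idx) >= 2:
        r, pv = stats.spearmanr(X[idx].T)
        r = np.atleast_2d(r)
        pv = np.atleast_2d(pv)
        rho[np.ix_(idx, idx)] = r
        p[np.ix_(idx, idx)] = pv
    np.fill_diagonal(rho, 1.0)
    np.fill_diagonal(p, 0.0)

    iu = np.triu_indices(n, 1)
    q = np.full((n, n), np.nan)
    qv = bh_adjust(p[iu])
    q[iu] = qv
    q.T[iu] = qv
    np.fill_diagonal(q, 0.0)
    return CorrelationSet(taxa=list(table.taxon_ids), rho=rho, p_raw=p, q=q,
                          valid=valid)


# ---------------------------------------------------------------------------
# random-matrix-theory threshold scan
# ---------------------------------------------------------------------------

@dataclass
class ThresholdScan:
    """Record of the NNSD scan: one row per candidate cutoff with the
    chi-square goodness-of-fit statistics against the Poisson form e^(-s)
    and the GOE Wigner surmise (pi/2) s exp(-pi s^2 / 4)."""

    records: pd.DataFrame
    chosen_cutoff: float
    alpha: float

    def write(self, path) -> None:
        df = self.records.copy()
        df["chosen"] = df["cutoff"] == self.chosen_cutoff
        df.to_csv(path, sep="\t", index=False)


def _unfold(eigs: np.ndarray, method: str = "spline") -> np.ndarray:
    """Map eigenvalues to uniform density via a smoothed cumulative
    spectral function; returns unfolded values (mean spacing ~ 1)."""
    n = len(eigs)
    cum = np.arange(1, n + 1, dtype=float)
    if method == "spline":
        # cubic smoothing of the empirical cumulative spectral density
        spl = UnivariateSpline(eigs, cum, k=3, s=float(n))
        return spl(eigs)
    if method == "gaussian":
        sigma = 2.0 * (eigs[-1] - eigs[0]) / max(n - 1, 1)
        return stats.norm.cdf((eigs[:, None] - eigs[None, :]) / sigma).sum(axis=1)
    raise ValueError(f"unknown unfolding method {method!r}")


def _nnsd_gof(spacings: np.ndarray) -> tuple[float, float, float, float]:
    """Chi-square goodness of fit of spacings against Poisson and GOE using
    equal-probability bins; returns (chi2_P, p_P, chi2_G, p_G)."""
    s = spacings[spacings >= 0]
    m = s.mean()
    if m <= 0:
        # all spacings zero: a point mass, neither Poisson nor GOE;
        # treated by the caller via the degenerate-spectrum path
        return np.inf, 0.0, np.inf, 0.0
    s = s / m
    k = int(max(5, min(20, s.size // 5)))
    qs = np.linspace(0, 1, k + 1)[1:-1]
    out = []
    for name in ("poisson", "goe"):
        if name == "poisson":
            edges = -np.log1p(-qs)
        else:
            edges = np.sqrt(-4.0 * np.log1p(-qs) / np.pi)
        counts, _ = np.histogram(s, bins=np.concatenate(([0.0], edges, [np.inf])))
        expected = s.size / k
        chi2 = float(((counts - expected) ** 2 / expected).sum())
        p = float(stats.chi2.sf(chi2, k - 1))
        out.extend([chi2, p])
    return tuple(out)


def rmt_threshold(
    corr: CorrelationSet,
    scan_start: float = 0.30,
    scan_stop: float = 0.99,
    step: float = 0.01,
    alpha: float = 0.05,
    min_spacings: int = 10,
    unfolding: str = "spline",
) -> ThresholdScan:
    """Scan |rho| cutoffs and pick the smallest at which the NNSD of the
    thresholded correlation matrix is consistent with the Poisson form
    (p > alpha) and inconsistent with the GOE Wigner surmise (p < alpha).

    Degenerate eigenvalues (repeated to 8 decimals, e.g. the unit eigenvalues
    of fully isolated taxa) are collapsed before unfolding; a spectrum left
    with fewer than ``min_spacings`` spacings is fully modular/diagonal and
    is scored Poisson-consistent.
    """
    R = corr.valid_rho()
    if R.shape[0] < 2:
        raise ValueError("need at least 2 non-constant taxa")
    cutoffs = np.round(np.arange(scan_start, scan_stop + step / 2, step), 10)
    rows = []
    chosen = None
    for s in cutoffs:
        M = np.where(np.abs(R) >= s, R, 0.0)
        np.fill_diagonal(M, 1.0)
        eigs = np.linalg.eigvalsh(M)
        uniq = np.unique(np.round(eigs, 8))
        if len(uniq) - 1 < min_spacings:
            poisson_ok, goe_rejected = True, True
            chi2_p = p_p = chi2_g = p_g = np.nan
        else:
            unfolded = np.sort(_unfold(uniq, method=unfolding))
            spacings = np.diff(unfolded)
            chi2_p, p_p, chi2_g, p_g = _nnsd_gof(spacings)
            poisson_ok = p_p > alpha
            goe_rejected = p_g < alpha
        decision = bool(poisson_ok and goe_rejected)
        rows.append({
            "cutoff": float(s), "n_eigenvalues": len(uniq),
            "poisson_chi2": chi2_p, "poisson_p": p_p,
            "goe_chi2": chi2_g, "goe_p": p_g, "poisson_consistent": decision,
        })
        if decision and chosen is None:
            chosen = float(s)
            break
    records = pd.DataFrame(rows)
    if chosen is None:
        raise ValueError(
            "no cutoff in the scan range yields a Poisson NNSD; widen the scan"
        )
    return ThresholdScan(records=records, chosen_cutoff=chosen, alpha=alpha)


def build_network(
    corr: CorrelationSet,
    q_cutoff: float = 0.001,
    rho_cutoff: float = 0.86,
    taxonomy: pd.DataFrame | None = None,
) -> nx.Graph:
    """Signed association network: edge (i, j) iff q <= q_cutoff and
    |rho| >= rho_cutoff.  Taxa left with degree 0 are not nodes."""
    for name, c in (("q_cutoff", q_cutoff), ("rho_cutoff", rho_cutoff)):
        if not 0 < c <= 1:
            raise ValueError(f"{name} must be in (0, 1]")
    g = nx.Graph(q_cutoff=q_cutoff, rho_cutoff=rho_cutoff)
    n = corr.n_taxa
    iu, ju = np.triu_indices(n, 1)
    ok = (
        ~np.isnan(corr.rho[iu, ju])
        & (corr.q[iu, ju] <= q_cutoff)
        & (np.abs(corr.rho[iu, ju]) >= rho_cutoff)
    )
    for i, j in zip(iu[ok], ju[ok]):
        r = float(corr.rho[i, j])
        g.add_edge(
            corr.taxa[i], corr.taxa[j],
            rho=r, sign="positive" if r > 0 else "negative",
            q=float(corr.q[i, j]),
        )
    if taxonomy is not None:
        for node in g.nodes:
            if node in taxonomy.index:
                ranks = taxonomy.loc[node]
                g.nodes[node]["taxonomy"] = ";".join(str(x) for x in ranks)
                g.nodes[node]["domain"] = str(ranks.get("domain", "unclassified"))
    return g
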