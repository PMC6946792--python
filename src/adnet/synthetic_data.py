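"""Synthetic digester communities with known correlation structure.

The generator emulates the study design the downstream analysis assumes:
66 samples (2 feeding groups x 3 replicate digesters x 11 sampling days),
compositional counts at a fixed library size, planted correlation modules
among taxa, module couplings active only in one phase group, and digester
performance parameters linearly driven by designated archaeal taxa.

The latent model is log-normal -> multinomial: module members share a
Gaussian factor, ``z_i = sqrt(rho) f_m + sqrt(1-rho) eps_i``, so the latent
pairwise correlation within a module is ``rho`` (Spearman slightly lower by
the Gaussian rank-correlation identity, and attenuated further by counting
noise).  Background taxa are independent.  Counts are drawn per sample by a
single multinomial of size ``library_size`` over the exponentiated latent
abundances, which reproduces the compositional closure of amplicon data.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field, asdict

import numpy as np
import pandas as pd

from .io_formats import (
    RANKS,
    AbundanceTable,
    SampleMetadata,
    derive_phase_group,
)

SAMPLING_DAYS = (45, 62, 66, 69, 73, 76, 80, 83, 87, 90, 97)

_ARCHAEAL_CLASSES = ("Methanobacteria", "Methanomicrobia", "Methanococci", "Thermoprotei")
_BACTERIAL_CLASSES = ("Clostridia", "Bacteroidia", "Bacilli", "Anaerolineae",
                      "Actinobacteria", "Gammaproteobacteria")


@dataclass
class PlantedTruth:
    """Ground truth of a generated community."""

    module_assignments: dict  # taxon -> module label or "background"
    planted_edges: list       # [(u, v, sign, target_rho), ...] with u < v
    group_specific_edges: dict  # (u, v) -> phase group label
    performance_driver_taxa: list
    driver_coefficients: dict  # taxon -> beta weight
    performance_noise_sd: float
    seed: int | None = None

    def planted_pairs(self) -> set:
        return {(u, v) for u, v, _, _ in self.planted_edges}

    def global_pairs(self) -> set:
        return self.planted_pairs() - set(self.group_specific_edges)

    def to_json(self, path) -> None:
        d = asdict(self)
        d["planted_edges"] = [list(e) for e in self.planted_edges]
        d["group_specific_edges"] = {f"{u}\t{v}": g for (u, v), g in
                                     self.group_specific_edges.items()}
        with open(path, "w") as fh:
            json.dump(d, fh, indent=1)

    @classmethod
    def from_json(cls, path) -> "PlantedTruth":
        with open(path) as fh:
            d = json.load(fh)
        d["planted_edges"] = [tuple(e) for e in d["planted_edges"]]
        d["group_specific_edges"] = {tuple(k.split("\t")): g for k, g in
                                     d["group_specific_edges"].items()}
        return cls(**d)


def _design() -> pd.DataFrame:
    rows = []
    for group, prefix in (("control", "C"), ("treatment", "T")):
        for dig in (1, 2, 3):
            for day in SAMPLING_DAYS:
                sid = f"{prefix}{dig}_d{day}"
                rows.append({
                    "sample_id": sid, "digester_id": f"{prefix}{dig}",
                    "group": group, "day": day,
                    "phase_group": derive_phase_group(group, day),
                })
    return pd.DataFrame(rows).set_index("sample_id")


def _taxonomy_frame(taxa, modules, group_labels, rng) -> pd.DataFrame:
    """Assign domains/classes: module 1 is archaeal (methanogen-like), the
    rest bacterial; ~20% of background taxa are archaeal."""
    rows = []
    for t in taxa:
        m = modules[t]
        if m == "module_1":
            domain = "Archaea"
            cls = _ARCHAEAL_CLASSES[rng.integers(len(_ARCHAEAL_CLASSES))]
        elif m == "background" and rng.random() < 0.2:
            domain = "Archaea"
            cls = _ARCHAEAL_CLASSES[rng.integers(len(_ARCHAEAL_CLASSES))]
        else:
            domain = "Bacteria"
            cls = _BACTERIAL_CLASSES[rng.integers(len(_BACTERIAL_CLASSES))]
        row = {r: "unclassified" for r in RANKS}
        row.update(domain=domain, phylum="unclassified", **{"class": cls},
                   genus=f"g_{t}")
        rows.append(row)
    return pd.DataFrame(rows, index=list(taxa))[list(RANKS)]


def generate_community(
    n_taxa: int = 100,
    n_samples: int = 66,
    n_modules: int = 4,
    within_module_rho: float = 0.9,
    noise_sd: float = 0.1,
    sparsity: float = 0.6,
    library_size: int = 11558,
    mu_sd: float = 0.5,
    group_specific_modules: dict | None = None,
    seed: int | None = None,
) -> tuple[AbundanceTable, PlantedTruth]:
    """Generate a count table with planted correlation modules.

    Parameters
    ----------
    within_module_rho:
        Latent pairwise correlation among members of a module; must be in
        [0, 1).
    sparsity:
        Fraction of taxa left as independent background.
    group_specific_modules:
        Phase-group label -> module size; members of these modules share
        their factor only within that phase group's samples.  Default plants
        one 4-taxon module each in "T 45-76" and "T 80-97".
    library_size:
        Multinomial depth per sample (the study's rarefaction depth).
    """
    rho = float(within_module_rho)
    if not 0.0 <= rho < 1.0:
        raise ValueError("within_module_rho must be in [0, 1)")
    if n_modules < 1:
        raise ValueError("n_modules must be >= 1")
    if not 0.0 <= sparsity < 1.0:
        raise ValueError("sparsity must be in [0, 1)")
    if group_specific_modules is None:
        group_specific_modules = {"T 45-76": 4, "T 80-97": 4}

    design = _design()
    if n_samples != len(design):
        # allow smaller designs by truncation, keeping group balance
        if n_samples > len(design):
            raise ValueError(f"design supports at most {len(design)} samples")
        design = design.iloc[np.linspace(0, len(design) - 1, n_samples).astype(int)]
    samples = list(design.index)
    ns = len(samples)

    rng = np.random.default_rng(seed)
    taxa = [f"OTU_{i+1}" for i in range(n_taxa)]

    n_gs = sum(group_specific_modules.values())
    n_planted = int(round((1 - sparsity) * n_taxa))
    if n_planted < n_gs + 2 * n_modules:
        raise ValueError("not enough planted taxa for the requested modules")
    n_ordinary = n_planted - n_gs
    # the archaeal driver module (module_1) gets ~40% of the planted taxa so
    # the per-domain Mantel contrasts have comparable power; the rest split
    # evenly over the remaining bacterial modules
    first = max(2, int(round(0.4 * n_ordinary))) if n_modules > 1 else n_ordinary
    rest = n_ordinary - first
    sizes = [first] + [rest // (n_modules - 1)] * (n_modules - 1) if n_modules > 1 else [first]
    for i in range(1, 1 + (rest % (n_modules - 1) if n_modules > 1 else 0)):
        sizes[i] += 1

    modules: dict[str, str] = {t: "background" for t in taxa}
    pos = 0
    module_members: dict[str, list] = {}
    for m, size in enumerate(sizes, start=1):
        label = f"module_{m}"
        members = taxa[pos:pos + size]
        pos += size
        module_members[label] = members
        for t in members:
            modules[t] = label
    gs_members: dict[str, list] = {}
    for g, size in group_specific_modules.items():
        label = f"group::{g}"
        members = taxa[pos:pos + size]
        pos += size
        gs_members[g] = members
        module_members[label] = members
        for t in members:
            modules[t] = label

    # latent standard-normal matrix (taxa x samples); member i of a module
    # loads on the module factor with loading lambda_i spread around
    # sqrt(rho), so pairwise latent correlations are lambda_i*lambda_j with
    # median ~ rho and node degrees downstream vary with the loading
    z = rng.standard_normal((n_taxa, ns))
    loadings = {}
    for label, members in module_members.items():
        idx = [taxa.index(t) for t in members]
        f = rng.standard_normal(ns)
        lam = np.clip(
            np.sqrt(rho) * rng.uniform(0.65, 1.05, size=len(members)), 0.0, 0.999
        )
        for t, l in zip(members, lam):
            loadings[t] = float(l)
        if label.startswith("group::"):
            g = label.split("::", 1)[1]
            mask = (design["phase_group"] == g).to_numpy()
        else:
            mask = np.ones(ns, dtype=bool)
        cols = np.where(mask)[0]
        z[np.ix_(idx, cols)] = (
            lam[:, None] * f[mask][None, :]
            + np.sqrt(1.0 - lam[:, None] ** 2) * z[np.ix_(idx, cols)]
        )
    if noise_sd > 0:
        z = (z + noise_sd * rng.standard_normal(z.shape)) / np.sqrt(1 + noise_sd**2)

    mu = rng.normal(0.0, mu_sd, size=n_taxa)
    log_abund = mu[:, None] + z
    weights = np.exp(log_abund)
    weights /= weights.sum(axis=0, keepdims=True)
    counts = np.column_stack([
        rng.multinomial(library_size, weights[:, j]) for j in range(ns)
    ])

    taxonomy = _taxonomy_frame(taxa, modules, gs_members, rng)
    table = AbundanceTable(
        data=pd.DataFrame(counts, index=taxa, columns=samples),
        taxonomy=taxonomy, kind="count",
    )

    planted_edges = []
    group_specific_edges = {}
    for label, members in module_members.items():
        for i, u in enumerate(members):
            for v in members[i + 1:]:
                planted_edges.append(
                    (u, v, 1, round(loadings[u] * loadings[v], 6)))
                if label.startswith("group::"):
                    group_specific_edges[(u, v)] = label.split("::", 1)[1]

    # performance is driven by the archaeal module's latent factor, proxied
    # by a loading-weighted combination of its members' abundances: taxa with
    # larger loadings get both higher network degree and higher GS
    drivers = module_members.get("module_1", [])
    wsum = sum(loadings[t] for t in drivers) or 1.0
    truth = PlantedTruth(
        module_assignments=modules,
        planted_edges=planted_edges,
        group_specific_edges=group_specific_edges,
        performance_driver_taxa=list(drivers),
        driver_coefficients={t: loadings[t] / wsum for t in drivers},
        performance_noise_sd=0.35,
        seed=seed,
    )
    return table, truth


# realistic operating scales for the generated metadata; GS and the Mantel
# statistics are invariant to these affine placements
_PERF_SCALES = {"biogas_production": (3.0, 0.4), "methane_production": (1.8, 0.25),
                "vs_removal": (55.0, 4.0)}
_ENV_BASE = {"total_ammonia": (1.8, (2.2, 2.8), 0.08),
             "acetate": (0.5, (0.8, 1.1), 0.05),
             "ph": (7.2, (7.2, 7.2), 0.05)}


def generate_metadata(
    table: AbundanceTable,
    truth: PlantedTruth,
    effect_size_beta: float = 1.0,
    olr_step: tuple[float, float] = (1.3, 1.5),
    control_olr: float = 1.0,
    seed: int | None = None,
) -> SampleMetadata:
    """Derive metadata whose performance columns are driven by the truth's
    driver taxa and whose environmental columns follow the loading-rate step.

    Performance parameter = base + amp * (beta * d + eps) where ``d`` is the
    mean standardized relative abundance of the driver taxa across samples
    and eps ~ N(0, truth.performance_noise_sd).  Environmental parameters in
    the treatment group step between the two phase windows
    (``olr_step[0]`` -> ``olr_step[1]`` for VS load); controls stay flat.
    """
    if not truth.performance_driver_taxa:
        raise ValueError("truth has no performance driver taxa")
    rng = np.random.default_rng(seed)
    design = _design().loc[list(table.samples)]
    rel = table.relative()
    drivers = [t for t in truth.performance_driver_taxa if t in rel.index]
    D = rel.loc[drivers].to_numpy(dtype=float)
    Dz = (D - D.mean(axis=1, keepdims=True)) / np.where(
        D.std(axis=1, keepdims=True) > 0, D.std(axis=1, keepdims=True), 1.0)
    w = np.array([truth.driver_coefficients.get(t, 0.0) for t in drivers])
    d = (w[:, None] * Dz).sum(axis=0)
    if d.std() > 0:
        d = d / d.std()

    df = design.copy()
    treat = (df["group"] == "treatment").to_numpy()
    late = (df["day"] >= 80).to_numpy()

    noise = truth.performance_noise_sd
    for name, (base, amp) in _PERF_SCALES.items():
        eps = rng.normal(0.0, noise, size=len(df))
        df[name] = base + amp * (effect_size_beta * d + eps)

    vs = np.full(len(df), control_olr, dtype=float)
    vs[treat & ~late] = olr_step[0]
    vs[treat & late] = olr_step[1]
    df["vs_load"] = vs + rng.normal(0.0, 0.03, size=len(df))
    for name, (ctrl, (lo, hi), sd) in _ENV_BASE.items():
        x = np.full(len(df), ctrl, dtype=float)
        x[treat & ~late] = lo
        x[treat & late] = hi
        df[name] = x + rng.normal(0.0, sd, size=len(df))

    return SampleMetadata(df=df)
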