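"""End-to-end pipeline: ingest/synthesize -> filter -> correlate -> threshold
-> network -> topology -> null models -> group-specific edges -> GS/Mantel.

A single YAML config drives every stage; each stochastic stage has its own
seed so re-running a config reproduces byte-identical outputs.
"""

from __future__ import annotations

import hashlib
import json
import logging
from dataclasses import dataclass, field, asdict
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from . import gs_mantel, group_edges, netbuild, nullmodels, synthetic_data, topology
from .io_formats import (
    AbundanceTable,
    SampleMetadata,
    read_abundance_table,
    read_metadata,
    write_network,
)

logger = logging.getLogger(__name__)


@dataclass
class RunConfig:
    """Configuration of a full pipeline run."""

    out_dir: str = "adnet_run"
    abundance: str | None = None       # path to a taxon x sample TSV
    metadata: str | None = None        # path to a sample metadata TSV
    synth: dict | None = None          # or generator parameters
    min_prevalence: float = 9
    fdr_cutoff: float = 0.001
    rmt_scan: tuple = (0.30, 0.99, 0.01)
    rho_cutoff: float | None = None    # overrides the RMT scan when set
    null_reps: int = 100
    omission_permutations: int = 500
    mantel_permutations: int = 999
    seeds: dict = field(default_factory=lambda: {
        "synth": 1, "metadata": 2, "null": 3, "omission": 4, "mantel": 5,
    })

    def validate(self) -> None:
        if self.abundance is None and self.synth is None:
            raise ValueError("config needs either an abundance path or a synth block")
        if self.abundance is not None and self.metadata is None:
            raise ValueError("an abundance path requires a metadata path")
        if not 0 < self.fdr_cutoff <= 1:
            raise ValueError("fdr_cutoff must be in (0, 1]")

    @classmethod
    def from_yaml(cls, path) -> "RunConfig":
        with open(path) as fh:
            raw = yaml.safe_load(fh) or {}
        cfg = cls(**raw)
        if isinstance(cfg.rmt_scan, (list, tuple)):
            cfg.rmt_scan = tuple(float(x) for x in cfg.rmt_scan)
        return cfg

    def to_yaml(self, path) -> None:
        d = asdict(self)
        d["rmt_scan"] = list(self.rmt_scan)
        with open(path, "w") as fh:
            yaml.safe_dump(d, fh, sort_keys=True)

    def digest(self) -> str:
        d = asdict(self)
        d["rmt_scan"] = list(self.rmt_scan)
        d.pop("out_dir", None)  # the hash covers the analysis, not its location
        return hashlib.sha256(
            json.dumps(d, sort_keys=True).encode()
        ).hexdigest()[:12]


def _load_inputs(cfg: RunConfig):
    if cfg.abundance is not None:
        table = read_abundance_table(cfg.abundance, kind="count")
        meta = read_metadata(cfg.metadata)
        truth = None
    else:
        params = dict(cfg.synth or {})
        beta = params.pop("effect_size_beta", 1.0)
        table, truth = synthetic_data.generate_community(
            seed=cfg.seeds.get("synth", 1), **params
        )
        meta = synthetic_data.generate_metadata(
            table, truth, effect_size_beta=beta,
            seed=cfg.seeds.get("metadata", 2),
        )
    return table, meta, truth


def run_pipeline(config: RunConfig) -> dict:
    """Execute every stage and write TSV/GraphML/JSON artifacts.

    Returns the run report (also written as ``report.json``).
    """
    config.validate()
    out = Path(config.out_dir)
    out.mkdir(parents=True, exist_ok=True)
    report: dict = {"config_hash": config.digest(), "stages": {}}
    config.to_yaml(out / "config.yaml")

    def stage(name):
        logger.info("stage: %s", name)
        report["stages"][name] = {}
        return report["stages"][name]

    try:
        rec = stage("ingest")
        table, meta, truth = _load_inputs(config)
        table.write(out / "abundance.tsv")
        meta.write(out / "metadata.tsv")
        if truth is not None:
            truth.to_json(out / "truth.json")
        rec.update(n_taxa=table.n_taxa, n_samples=table.n_samples)

        rec = stage("filter")
        filtered = netbuild.prevalence_filter(table, config.min_prevalence)
        rec.update(n_taxa=filtered.n_taxa, min_prevalence=config.min_prevalence)

        rec = stage("correlate")
        corr = netbuild.spearman_all_pairs(filtered)
        rec.update(n_valid_taxa=int(corr.valid.sum()))

        rec = stage("threshold")
        if config.rho_cutoff is not None:
            cutoff = float(config.rho_cutoff)
            rec.update(rho_cutoff=cutoff, source="config")
        else:
            lo, hi, step = config.rmt_scan
            scan = netbuild.rmt_threshold(corr, lo, hi, step)
            scan.write(out / "rmt_scan.tsv")
            cutoff = scan.chosen_cutoff
            rec.update(rho_cutoff=cutoff, source="rmt")

        rec = stage("network")
        net = netbuild.build_network(
            corr, q_cutoff=config.fdr_cutoff, rho_cutoff=cutoff,
            taxonomy=filtered.taxonomy,
        )
        if net.number_of_edges() == 0:
            raise ValueError("no edge passes the q and rho cutoffs")
        part, q, n_mod = topology.detect_modules(net)
        for n in net.nodes:
            net.nodes[n]["module"] = int(part[n])
        roles = topology.node_roles(net, part)
        for r in roles:
            net.nodes[r.node]["role"] = r.role
        write_network(net, out / "network.graphml", "graphml")
        write_network(net, out / "network_edges.tsv", "edgelist")
        summary = topology.summarize(net)
        pd.DataFrame([summary.as_dict()]).to_csv(
            out / "topology.tsv", sep="\t", index=False)
        rec.update(n_nodes=net.number_of_nodes(), n_edges=net.number_of_edges(),
                   modularity=q, n_modules=n_mod)

        rec = stage("null_models")
        ens, graphs = nullmodels.random_ensemble(
            summary.n_nodes, summary.n_edges, reps=config.null_reps,
            seed=config.seeds.get("null", 3), nodes=list(net.nodes),
        )
        cmp_df = nullmodels.compare_to_random(summary, ens)
        cmp_df.to_csv(out / "null_comparison.tsv", sep="\t")
        grouping = {n: net.nodes[n].get("domain", "unclassified") for n in net.nodes}
        es = nullmodels.group_effect_sizes(net, grouping, graphs)
        es.to_csv(out / "effect_sizes.tsv", sep="\t", index=False)
        rec.update({m: {"z": float(cmp_df.loc[m, "z"]),
                        "p": float(cmp_df.loc[m, "p"])}
                    for m in cmp_df.index})

        rec = stage("group_edges")
        cls = group_edges.classify_edges(
            filtered, net, meta.phase_groups(),
            n_random=config.omission_permutations,
            seed=config.seeds.get("omission", 4),
        )
        cls.to_csv(out / "edges_classified.tsv", sep="\t", index=False)
        per_edge = cls.groupby(["source", "target"])["group_specific"].any()
        rec.update(n_edges=int(len(per_edge)),
                   n_group_specific=int(per_edge.sum()),
                   n_global=int((~per_edge).sum()))

        rec = stage("gs_mantel")
        t2 = gs_mantel.table2_analysis(
            net, filtered, meta,
            n_permutations=config.mantel_permutations,
            seed=config.seeds.get("mantel", 5),
        )
        t2.to_csv(out / "mantel.tsv", sep="\t")
        rec.update(n_subsets=int(len(t2)))
    except Exception as err:
        name = list(report["stages"])[-1] if report["stages"] else "setup"
        raise RuntimeError(f"pipeline failed at stage {name!r}: {err}") from err

    report["cutoffs"] = {
        "min_prevalence": config.min_prevalence,
        "fdr": config.fdr_cutoff,
        "rho": cutoff,
        "null_reps": config.null_reps,
        "omission_permutations": config.omission_permutations,
        "mantel_permutations": config.mantel_permutations,
    }
    with open(out / "report.json", "w") as fh:
        json.dump(report, fh, indent=1, sort_keys=True)
    return report
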