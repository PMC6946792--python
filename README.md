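# adnet

Association-network analysis of anaerobic-digester (AD) microbiomes.

Anaerobic digestion converts organic waste to biogas through a chain of
microbial guilds — hydrolytic and fermentative bacteria, syntrophic
acetogens, and methanogenic archaea. `adnet` infers putative interactions
among these taxa from time-series abundance tables (16S OTU counts and
functional-gene-array organism signals) and asks whether the *structure* of
the interaction network, rather than individual abundances, tracks digester
performance (biogas and methane production, volatile-solids removal).

The pipeline:

1. **Network inference** — taxa present in more than a minimum number of
   samples are correlated pairwise (Spearman ρ, average-rank ties); p values
   are Benjamini–Hochberg adjusted; an edge requires both `q ≤ 0.001` and
   `|ρ| ≥ s*`, where the cutoff `s*` is chosen by a random-matrix-theory
   scan: the smallest cutoff at which the nearest-neighbour spacing
   distribution (NNSD) of the thresholded correlation matrix's unfolded
   eigenvalues follows the Poisson form `e^(−d)` (modular signal) rather
   than the Gaussian-orthogonal-ensemble Wigner surmise (correlated noise).
2. **Topology** — node/edge counts, percent positive edges, power-law R² of
   the degree histogram, average connectivity `avgK = 2E/N`, harmonic
   geodesic distance `GD = N_pairs / Σ 1/d_ij` (unreachable pairs contribute
   zero reciprocal), average clustering, greedy-agglomeration modularity Q,
   Freeman centralizations, and Guimerà–Amaral z–P node roles (module hubs:
   `z > 2.5`, `P ≤ 0.62` — candidate keystone taxa).
3. **Null models** — 100 uniform simple random graphs with the empirical
   node and edge counts; per-metric z-scores and empirical p; between-taxa
   edge effect sizes `(observed − mean)/SD`, significant above 2.
4. **Group-specific edges** — for each of the four phase groups
   (C 45-76, T 45-76, C 80-97, T 80-97) the omission score (OS) is each
   edge's ρ recomputed without that group's samples; 500 random same-size
   omissions give a nonparametric p; edges with `|OS| < |ρ|` and `p < 0.05`
   are group specific, the rest global.
5. **Gene significance and Mantel tests** — GS is the squared Pearson
   correlation of a taxon's abundance with an environmental (total ammonia,
   acetate, pH, VS load) or performance (biogas, methane, VS removal)
   parameter. Euclidean distances among GS row-vectors are compared with
   connectivity distances `|k_i − k_j|` by one-sided Mantel and partial
   Mantel permutation tests, overall and per domain/class.
6. **Synthetic communities** — a log-normal → multinomial generator with
   planted correlation modules, phase-group-specific couplings and
   performance parameters driven by designated archaeal taxa provides
   ground truth for every stage.

## Worked example

```sh
adnet synth --n-taxa 100 --seed 1 --out-dir demo
adnet build --abundance demo/abundance.tsv --out demo/net.graphml
adnet topo  --in demo/net.graphml --out demo/topo.tsv
adnet groups --in demo/net.graphml --abundance demo/abundance.tsv \
             --meta demo/metadata.tsv --seed 7 --out demo/edges.tsv
adnet mantel --in demo/net.graphml --abundance demo/abundance.tsv \
             --meta demo/metadata.tsv --seed 7 --out demo/mantel.tsv
```

prints (abridged):

```
RMT cutoff: 0.31
30 nodes, 88 edges -> demo/net.graphml
avgK 5.867   GD 4.230   avgCC 0.795   modularity 0.520 (4 modules)
18 group-specific, 70 global edges -> demo/edges.tsv

subset    n_taxa  r_perf  p_perf  r_perf_env_controlled  p_perf_env_controlled
All           30   0.758   0.001                  0.759                  0.001
Archaea       13   0.431   0.008                  0.437                  0.008
Bacteria      17   0.034   0.283                  0.028                  0.307
```

The RMT scan lands at 0.31 — just above this design's noise bulk — and the
network recovers the planted modules. The Mantel table shows the planted
contrast: performance parameters were generated from the archaeal module's
taxa, so archaeal connectivity correlates with performance GS even when the
environmental GS is controlled (r = 0.44, p = 0.008), while the bacterial
subset stays at the null.

The full pipeline (all stages, one YAML config, per-stage seeds,
byte-reproducible outputs) runs with `adnet run --config run.yaml`.

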