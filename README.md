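# interolog

Homology-transfer (interolog) inference of a protein–protein interaction
(PPI) network for a de novo transcriptome, with full topological
characterization and matched random-graph null models.

## The problem

For a non-model organism with no sequenced genome, gene interactions
cannot be looked up — but they can be *transferred*: if two proteins are
known to interact in a well-studied reference species, and both have
clear homologs among the assembled transcripts (unigenes), the
interaction is inferred between those unigenes (the "interolog"
principle). This package implements that chain for RNA-seq assemblies,
plus the transcript-facing bookkeeping around it and the network
analysis downstream of it:

1. **Read cleaning** — trim 3′ adapter contamination (exact
   adapter-prefix match, ≥ 8 nt), then drop reads whose fraction of
   unknown (N) bases is strictly greater than 5%.
2. **Unigene selection** — per assembled gene cluster, keep the
   transcript maximizing *length × isoform percent*; expression is
   reported in TPM, `TPM_i = (c_i/l_i) / Σ_j(c_j/l_j) × 10⁶`.
3. **Coding-sequence calls** — six-frame longest-ORF scan
   (ATG → in-frame stop, stop included), applied to unigenes longer
   than 300 bp; assembly quality summarized as mean length and N50.
4. **Homology transfer** — TBLASTN-style hit tables (protein query vs
   translated unigene) are filtered at *E* < 10⁻⁶, identity > 50% and
   query coverage > 80% (all strict); each reference protein is
   assigned its best unigene (lowest E-value, then highest bitscore);
   reference edges with both endpoints assigned become unigene edges,
   merged across species into a simple undirected graph.
5. **Topology** — degree distribution `P(k) = N(k)/N` with a log-log
   least-squares power-law fit `P(k) = a·k^(−γ)`; average
   nearest-neighbor degree `k_nn,i = (1/k_i) Σ_j a_ij k_j` (degree
   correlation); clustering `C_i = 2e_i/(k_i(k_i−1))`, its curve
   `C(k)` and network average `C`; average shortest path length `L`
   over all pairs of the giant component.
6. **Null models** — Erdős–Rényi, Watts–Strogatz and Barabási–Albert
   graphs with *exactly* the observed node and edge counts, for the
   small-world / scale-free comparison of `C` and `L`.

A synthetic-data module generates every input with retained ground
truth — heavy-tailed reference interactomes, ortholog maps, hit tables
with boundary-value decoys, isoform tables, defective reads — so the
entire chain is testable without any external download.

## Worked example

```python
from interolog import (ScenarioConfig, generate_ortholog_scenario, filter_hits,
                       assign_orthologs, transfer_interactions, graph_from_edges,
                       topology_summary)

cfg = ScenarioConfig(n_reference_proteins=300, n_unigenes=450,
                     ortholog_fraction=0.8, n_species=2, reference_model="BA",
                     reference_edges=900, decoy_rate=0.3, seed=42)
scenario = generate_ortholog_scenario(cfg)
assignments = [assign_orthologs(filter_hits(h), sp)
               for sp, h in scenario.hits.items()]
edges = transfer_interactions(assignments, scenario.reference_edges)
print("recovered ground truth exactly:", edges == scenario.truth.expected_edges)

summary = topology_summary(graph_from_edges(edges))
print(f"components: {summary.n_components}  "
      f"giant: {summary.giant_nodes} nodes / {summary.giant_edges} edges")
print(f"C = {summary.clustering:.4f}   L = {summary.avg_path_length:.3f}")
fit = summary.power_law
print(f"P(k) ~ {fit.prefactor:.3f} * k^-{fit.exponent:.3f}")
```

prints

```
recovered ground truth exactly: True
components: 1  giant: 240 nodes / 1080 edges
C = 0.1176   L = 2.577
P(k) ~ 0.236 * k^-0.961
```

Despite 30% decoy hits sitting exactly on each filter boundary, the
strict thresholds recover the ground-truth edge set exactly. The
transferred network inherits the heavy-tailed degree distribution of
its preferential-attachment reference (shallow fitted exponent at this
small size), and its clustering is far above the Erdős–Rényi
expectation `2E/(N(N−1)) ≈ 0.038` for its size — the small-world
signature the null-model table quantifies.

The same stages are available as a CLI (`interolog simulate`,
`clean-reads`, `select-unigenes`, `orfs`, `map-orthologs`, `build-net`,
`topology`, `null-models`, `run-all`); `run-all` consumes a YAML config
and writes a JSON run report with every threshold, seed and output
checksum.

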