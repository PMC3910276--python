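# Methods

## Homology-transfer model

The network inference assumes that interactions are conserved between
orthologs (the interolog assumption): a reference-species interaction
(A, B) is transferred to the unigene pair (u, v) when A's best filtered
homolog is u and B's is v. Three per-hit filters gate the evidence,
all strict inequalities: E-value < 1e-6, percent identity > 50, query
coverage > 80 (query = reference protein, TBLASTN direction). Query
coverage is taken from a `qcovs` column when the hit table supplies
one, else computed per hit as 100·(qend − qstart + 1)/qlen; multiple
hits of one protein to different regions of one unigene are not merged
before the coverage test — filtering is per hit.

Assignment is best-hit per reference protein: lowest E-value, then
highest bitscore, then lexicographically smallest unigene id. The map
is deliberately many-to-one — several reference proteins may share a
unigene, mirroring paralog collapse in de novo assemblies — and no
reciprocal-best-hit constraint is applied. Transferred edges are
undirected; self-pairs (both endpoints mapping to the same unigene)
are dropped, and duplicates within and across reference species
collapse to a single edge. STRING-like confidence scores are read but
not filtered by default (`min_score=0`); a configurable minimum is
available.

## Transcript rules

* **Read cleaning.** 3′ adapters are removed by exact suffix/prefix
  match with a minimum overlap of 8 nt, before the N-content test; a
  read is then dropped iff its N fraction is strictly greater than
  `max_unknown_fraction` (default 0.05, so 5 N in 100 nt survives and
  6 N does not). A mean-quality cutoff exists but is off by default:
  "low-quality" has no canonical definition at this stage and we do
  not invent a threshold.
* **Unigene selection.** Per gene, the transcript maximizing
  length × isoform percent wins; ties go to the longer transcript,
  then the smaller transcript id. TPM is the standard length-
  normalized unit; an all-zero count table yields all-zero TPM.
* **ORF calls.** All six frames are scanned; an ORF is ATG to the
  first in-frame stop, stop included, coordinates 1-based inclusive on
  the forward strand even for minus-strand calls (unambiguous
  reporting). Complete ORFs always outrank open (stop-less) ATG-to-end
  stretches, which are reported only when no complete ORF exists.
  Ties are broken forward strand first, then smallest start; a
  consequence is that when equal-length ORFs exist on both strands the
  call is not strand-symmetric — each orientation reports its own
  forward ORF. The 300 bp unigene filter is strict (a 300 bp sequence
  is excluded).
* **N50.** Scanning lengths in descending order, the first length at
  which the cumulative sum reaches half the total.

## Topology metrics

All metrics are computed on the giant component (ties in component
size broken by edge count, then smallest member id). Per-node values
are evaluated directly from adjacency sets:

* `P(k) = N(k)/N` over observed degrees; the power-law fit is an
  unweighted, unbinned ordinary least squares of log10 P(k) on log10 k
  over degrees with nonzero counts — no binning, no maximum-likelihood
  estimator, no x_min search. Note that on finite scale-free graphs
  this estimator is biased shallow: the singleton tail degrees all sit
  at P(k) = 1/N and flatten the slope, so a preferential-attachment
  graph with theoretical exponent 3 fits at γ ≈ 2.0 for N = 10⁴
  (replicate-calibrated band 1.8–2.3 in the tests). The fit reproduces
  exact power-law inputs to < 1e-10 relative error.
* `k_nn,i = (1/k_i) Σ_j a_ij k_j` for nodes with k ≥ 1; the curves
  k_nn(k) and C(k) are arithmetic means per degree, unbinned.
* `C_i = 2e_i/(k_i(k_i−1))` for k ≥ 2. Nodes with k < 2 are assigned
  C_i = 0 and **included** in the network average by default
  (`include_low_degree=False` excludes them); inclusion is what makes
  very sparse interactomes report C in the 10⁻³ range.
* `L` is the mean number of **edges** on the shortest path over all
  unordered pairs, by BFS from every node. (Counting intermediate
  nodes instead would shift every distance by one and is not the
  convention under which published L values of ~5 for sparse
  1900-node networks are plausible.) Disconnected input is an error;
  callers reduce to a component first.

Tests verify all of these against deliberately naive oracles —
triple-loop triangle counting, dense Floyd–Warshall distances, direct
summation — with exact equality on hundreds of random graphs.

## Null models

ER/WS/BA comparisons require "same N, same E". ER samples exactly E
edges uniformly. WS builds a ring lattice with even κ = 2·⌊E/N⌋ (≥ 2),
rewires each lattice edge with probability `p_rewire` (default 0.1,
configurable and echoed in output — no canonical value exists), then
tops up / removes random edges to exactly E; BA runs preferential
attachment with m = max(1, round(E/N)) and adjusts the same way. The
adjustment is what makes an exact-E match possible at all for WS/BA.
At `p_rewire = 0` the pre-adjustment WS base equals the ring lattice,
whose clustering has the closed form 3(κ−2)/(4(κ−1)) — checked
exactly. The ER ensemble's mean clustering approaches the density
2E/(N(N−1)) — checked within Monte-Carlo error. L on a disconnected
replicate is computed on that replicate's giant component. Replicate
seeds derive deterministically from one master seed.

## Synthetic data: what it emulates, and what it does not

The generator emulates the *structure* of each real input: BA
reference interactomes reproduce heavy-tailed degree distributions;
hit tables contain exactly one all-filters-passing hit per true
ortholog pair plus decoys that each violate exactly one filter at its
boundary value (E = 1e-5, identity = 50.0, coverage = 80.0), which
pins the strict-inequality semantics; isoform percents are derived
from per-gene counts and sum to 100; reads carry planted >5% N content
and ≥ 8 nt 3′ adapter prefixes with provenance labels. Scenario
defaults (200 reference proteins, 300 unigenes, 80% ortholog coverage,
2 species, 800 reference edges, 30% decoy rate) are sized so that a
scenario runs in well under a second while the transferred network
still has a giant component worth analyzing; the acceptance script
scales the reference to 1887 proteins / 7634 interactions, a realistic
giant-component size for a plant interactome projection.

Not modelled: sequence evolution (hit scores are drawn from simple
distributions, not alignments), read error profiles and quality-score
distributions (qualities are constant Phred 40), and real proteome
redundancy. Passing tests therefore demonstrate the *logic* of
filtering, assignment, transfer and topology — not robustness to
biological noise sources the generator does not contain.

## Numerical choices and degenerate inputs

* All randomness flows through `numpy.random.SeedSequence`-derived
  generators; fixed seed ⇒ byte-identical outputs.
* Power-law fit requires ≥ 2 positive degrees, else a ValueError.
* `average_shortest_path` of a < 2-node component is an error;
  `topology_summary` reports L = 0 for a single-node giant component.
* Empty filtered hit tables yield empty assignments; empty edge sets
  yield empty graphs.
* TPM of an all-zero count table is all zeros by definition, not NaN.
* Tie-breaks (unigene selection, ortholog assignment, ORF calls,
  giant-component choice) are all total orders, so every output is
  permutation-invariant and reproducible.

## Known limitations

* Interaction transfer inherits every bias of the reference
  interactomes; no attempt is made to score transferred edges.
* The unbinned OLS power-law fit is a descriptive convention, not a
  statistically efficient estimator; no goodness-of-fit test is run.
* One unigene may represent several reference proteins of the same
  species; conflicts are resolved by best-hit only.
* WS null parameters beyond (N, E, p_rewire) are not tuned to any
  particular published table; see the null-model section.
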