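# Methods

This note records the models, conventions and numerical choices behind
`richclubnet`, in enough detail to reproduce or audit any number the
package prints.

## Network model and conventions

The single input is a binary directed adjacency matrix with region
labels: `a[i, j] = 1` means region *i* projects to region *j*
(rows = source; a `transpose` flag accepts column-source files).
Self-connections are forbidden and entries must be 0/1. Total degree is
always k = k_in + k_out. Networks are pruned before analysis by
removing regions lacking at least one afferent and one efferent; the
default applies the rule iteratively until it is stable (a single-pass
variant is available, since published matrices do not always state
which was used). Unreachable ordered pairs carry infinite distance and
are excluded from mean path length; on the strongly connected matrices
this analysis targets the distinction is moot.

Reciprocity is the fraction of directed edges whose opposite edge also
exists, i.e. 2 · (#mutual dyads) / |E|.

## Null models

Both nulls are Markov chains of double-edge swaps
(a→b, c→d) ⇒ (a→d, c→b), rejecting self-loops, duplicate edges and
swaps touching fewer than four distinct nodes; size, density and the
exact in- and out-degree sequences are conserved on every member, which
the test suite asserts member by member.

- **Randomization** accepts every legal swap. Default 10 swap attempts
  per edge; at this length the chain's reciprocity and clustering are
  already at their stationary values on macaque-scale inputs (e.g.
  reciprocity falls from ~0.51 to ~0.13).
- **Latticization** additionally requires that the swapped edges do not
  move further (in sum) from the matrix diagonal under a node ordering
  drawn at random per instantiation; a stricter per-edge variant is
  available. Because this acceptance rule is a greedy descent rather
  than an ergodic chain, it converges far more slowly: on a 60-node
  Watts–Strogatz test graph mean directed clustering of the latticized
  ensemble was 0.26 at 10 swaps/edge, 0.57 at 100 and 0.64 (the ring
  value) at 300. The default is therefore 100 swaps/edge for this null
  only. ω and lattice-referenced motif z-scores are sensitive to this
  choice; the ensemble metadata records it.

Ensembles are seeded by a splitmix64-style derivation of per-member
sub-seeds from one master seed, so they are reproducible and trivially
resumable or parallelizable.

## Small-world metrics

Per-node directed clustering follows Fagiolo:
t_i = ½[(A+Aᵀ)³]_ii and C_i = t_i / (k_i(k_i−1) − 2k_i↔), where k_i↔
counts reciprocal neighbors; nodes with fewer than two neighbors get 0.
L is the mean finite off-diagonal hop distance; global efficiency the
mean of 1/d over ordered pairs; local efficiency of *i* the global
efficiency of the subgraph induced on the union of i's in- and
out-neighbors. γ, λ, σ are referenced to the randomized ensemble and
ω = ⟨L_rand⟩/L − C/⟨C_latt⟩ mixes both nulls; ensemble sizes default to
100 per model.

## Directed modularity

Q = (1/m) Σ_ij [a_ij − k_i^out k_j^in/m] δ(c_i, c_j). Because δ is
symmetric, optimization works on S = (B+Bᵀ)/2 with
B_ij = a_ij − k_i^out k_j^in/m: recursive spectral bisection on the
leading eigenvector of the row-sum-corrected restriction S^(g), each
split refined by greedy single-node flips of the bisection vector, then
a final pass moving single nodes between any modules while Q improves.
Eigenvector entries at exactly zero join the larger side; the seed only
resolves exact degeneracies and the sweep order of the final pass, so
runs are deterministic given the seed. On an 8-node two-clique fixture
the result matches exhaustive search over all 4140 partitions.
Participation coefficients and within-module z-scores use total degree
(in+out variants exist but are not default); singleton modules get
z = 0 with a warning.

## Centrality

Betweenness uses Brandes accumulation (networkx) over directed shortest
paths; closeness is the average of in- and out-closeness (inverse mean
distance), with a harmonic-mean fallback when pairs are unreachable;
vulnerability is E_glob(G) − E_glob(G−i) with the deleted-network
efficiency over (N−1)(N−2) ordered pairs, so peripheral deletions can
score negative (retained, not clipped). Dynamical importance is
(λ_max − λ_max^(−i))/λ_max on the dominant adjacency eigenvalue,
computed by power iteration (tolerance 1e−10, at most 1e5 iterations);
a converged Rayleigh quotient is accepted only if its residual is below
1e−8, otherwise a dense eigendecomposition is used (this guards against
plateaus on reducible or periodic matrices). The source material words
this measure in terms of the largest eigen*vector*; the cited
definition is on the eigen*value*, which is what is implemented. The
global score counts, per node, the measures in which it reaches the
90th percentile (midpoint interpolation; ties at the threshold
included).

## Rich-club detection

Φ(k) is the ordered-pair density of the subgraph induced by nodes with
total degree > k. The sweep runs from the lowest degree to the
second-highest; k values with fewer than two qualifying nodes are
dropped. Because the null conserves every node's degrees, the >k node
set is identical in every member, and the null Φ(k) reduces to edge
counts inside a fixed set — computed for all k at once from a histogram
of per-edge min(k_i, k_j). One-sided p-values use the add-one
correction p = (1 + #{Φ_null ≥ Φ}) / (1 + n_null); this keeps p
strictly positive, at the cost that no k can pass FDR unless the
ensemble is large enough for the step-up threshold (with 100 nulls and
a 100-point sweep, nothing can survive q = 0.05 — the sweep warns below
1000 members). Benjamini–Hochberg FDR at q = 0.05 is applied across the
sweep via statsmodels. Surviving k values are collapsed into unique
node sets, ordered innermost first and labeled by the largest
(innermost) defining k. k-core decomposition uses total degree within
the surviving subgraph; subshell ranks record the removal order at the
first k whose core is empty, with ties inside one pruning pass sharing
a rank.

## Motif analysis

The 13 connected 3-node isomorphism classes are ordered by edge count
(each direction counted), then by the lexicographically sorted per-node
(out-degree, in-degree) signature. This puts the three *apex* classes —
one node adjacent to two mutually unconnected nodes — at 4 (apex sends
one single edge besides a reciprocal tie), 6 (apex receives it) and 9
(both ties reciprocal), and the reciprocal triangle at 13.
`motif_library()` returns the full id → pattern table, including the
standard triad-census names (021D … 300), so the numbering is auditable
against any motif reference. Counting is induced-subgraph counting:
each connected triple contributes to exactly one class, enumerated once
from its first linked dyad; class counts are cross-checked in the tests
against both a 64-pattern brute-force classifier and the networkx
triadic census. Apex ratios divide a node's apex occupancies by its
participations over the chosen classes (0 when it participates in
none). The largest-star search restricts to the center's reciprocal
neighbors and greedily builds an independent set in ascending-degree
order with 20 seeded random-order restarts; on fixtures up to 12 nodes
it matches exhaustive maximum-independent-set search, but it remains a
heuristic and individual star sizes should be read as lower bounds.

## Shortest-path analytics

All statistics weight every distinct shortest path once. Per source,
BFS yields σ(s, v) (path counts) and a reverse pass yields suffix
counts h(v) = [v admissible target] + Σ h over DAG successors; per-edge
usage is σ(s, u)·h(v) summed over sources, and totals, node usage and
entry/exit events follow the same scheme — all exact, with enumeration
oracles in the test suite. Rich-club participation restricts to paths
with both endpoints outside the club and counts "touching" on
intermediates only; the touching and traveling fractions are computed
by complement, re-running the DP with club nodes (or club→club edges)
removed and keeping only pairs whose restricted distance equals the
full-graph distance. Positional degree profiles come from closed-form
products of distance-resolved count matrices rather than path
enumeration — mathematically identical to enumerating and binning, with
no memory ceiling. Flow asymmetry counts every crossing of the club
boundary along a path (a first/last-crossing variant is a switch), and
per-node significance is a two-sided add-one empirical p against the
randomized ensemble, reported uncorrected at 0.01. Communication cost
multiplies each edge's usage by the Euclidean distance between its
endpoint centroids (units taken as given, typically mm), restricted to
the coordinate-covered subnetwork; class comparisons use one-sided
Wilcoxon rank-sum tests (exact method below 20 observations per group).

## Synthetic study conditions

The generator's defaults emulate the macaque cortical regime: 242
nodes, 5 equal modules with within/between block densities 0.191/0.037
(overall density ≈ 0.07), reciprocity 0.507, an exponential degree tail
(floored at a small propensity so no region is near-isolated, as in
pruned empirical matrices), and a 15-member planted club at internal
density 0.65 spanning all five modules, with module-clustered 3D
coordinates so club edges (which cross modules) are long. Reciprocity
is exact in expectation by dyad-level sampling: a connected dyad is
mutual with probability ρ = r/(2−r).

Two structural choices make recovery well-posed:

- **Core–periphery club wiring.** A connector third of the club
  (spread one per module) is reciprocally tied to every member, while
  the top-degree satellite members are only sparsely interlinked
  directly. With i.i.d. dense club wiring, the highest-degree *subsets*
  of the club are themselves significantly denser than the
  degree-preserving null, so "the innermost significant level" would
  systematically be a sub-club fragment; concentrating internal wiring
  on the connectors removes that enrichment gradient, making the
  planted set the unique innermost detectable level. This also mirrors
  the empirical observation that a club's very top hubs are not
  mutually saturated.
- **Calibrated degree bands.** Expected total degrees are set as
  multiples of the mean background degree (satellites ≈ 3.1–3.35×,
  connectors ≈ 2.5–2.65× with their larger internal contribution
  subtracted), then the background block is rescaled to restore overall
  density. The three bands (background tail < connectors < satellites)
  hold across network sizes.

Setting `rc_density = within_density` disables the club wiring while
keeping the high-degree band — the matched null case used for
false-positive testing. `plant_flow_bias` converts one club member into
a path sink (or source) by re-pointing its outgoing (incoming) feeder
edges into the club, a configuration maximally atypical under
degree-preserving rewiring.

What the generator does **not** reproduce: the empirical matrix's exact
degree sequence and region identities, overlapping parcellations,
spatially decaying connection probabilities (distance enters only
through module geometry), and any weighted or quantitative projection
strength. Passing recovery tests therefore demonstrates that the
machinery detects the planted structure under realistic global
statistics, not that it would reach the same decisions on any
particular empirical matrix.

## Problem sizes and tolerances in the shipped checks

The test suite validates oracles on ≤6-node digraphs (1000 random
instances), runs recovery on 12 macaque-scale seeds with 300-member
nulls (requiring Jaccard ≥ 0.8 between the innermost level and the
planted club on at least 10), bounds false-positive club detections at
2 of 20 randomized inputs with 200-member nulls, requires mean
adjusted-Rand module agreement ≥ 0.9 over 6 seeds, and checks flow-bias
detection on 8 seeds with 200-member nulls (biased members flagged at
p < 0.01 in ≥ 90% of node–seed pairs, unbiased in ≤ 10% — the add-one
two-sided p-value floor of 2/201 makes a per-seed "no false flag
anywhere" requirement unattainable by construction). The acceptance
script runs the full pipeline at 500/100/100/200 ensemble sizes.

## Known limitations

- Latticization quality depends on the swap budget; the shipped default
  is a measured compromise, not a proven optimum.
- The spectral modularity optimizer is deterministic and fast but not
  globally optimal on large graphs; module compositions at the margins
  can differ between equally scoring partitions.
- Star sizes are heuristic lower bounds (exact only on small fixtures).
- Rich-club p-value resolution is 1/(n_null+1); FDR-corrected sweeps
  need ensembles of roughly a thousand members or more.
- Euclidean edge lengths underestimate curved fiber trajectories, so
  communication-cost shares are lower bounds with respect to wiring
  length.
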