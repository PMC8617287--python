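# Methods

This note documents the models and procedures implemented in `netmedkit`,
the conventions chosen where several were defensible, and what the synthetic
benchmarks do and do not demonstrate.

## Network model

A heterogeneous network holds four node kinds (gene, protein, drug,
disease) and six edge kinds (ppi, drug_target, gene_disease,
drug_indication, gene_protein, disease_hierarchy). Identifiers follow the
`{namespace}.{identifier}` convention (`uniprot.P51587`); inputs must arrive
pre-mapped — no identifier-mapping service is included. All edge kinds are
undirected except `disease_hierarchy`, which points child → parent; at most
one edge of a given kind exists per unordered node pair, duplicates collapse
to the first occurrence with a logged warning, and self-loops are rejected.
Drug nodes may carry a `groups` attribute (`approved`, `other`,
`approved|other`); PPI edges carry `evidence` ∈ {experimental, predicted}.
All algorithms run on the *experimental* PPI layer by default — predicted
interactions are retained in the data model but excluded from mining and
ranking. Gene–disease associations may carry a `score` attribute; no
algorithm consumes it.

GraphML serialisation declares one `<key>` per attribute name and writes
`edgedefault="undirected"` with `directed="true"` on hierarchy edges; the
reader validates the schema and preserves unknown attributes verbatim.
Round-trips through GraphML and through TSV node/edge tables are exact
(tested property-style), which is what makes the pipeline's byte-level
reproducibility meaningful.

## Module mining

**Hub penalty.** The interactome's degree distribution is heavy-tailed, and
unweighted shortest paths route through hubs, diluting disease specificity.
Edge weights are the affine blend w(u,v) = (1 − λ) + λ·(deg u + deg v)/(2·d̄)
with d̄ the mean degree; λ = 0 recovers unit weights, λ = 1 weights an edge
purely by its endpoints' relative degree. The form is scale-free in network
size, and on a regular graph every weight is 1 for any λ.

**Steiner tree heuristic.** Trees connecting the terminals (seed proteins)
are built by shortest-path insertion: start from one terminal, repeatedly
attach the nearest unconnected terminal along a minimum-weight shortest
path, then prune non-terminal leaves. This classical heuristic guarantees
cost ≤ 2·(1 − 1/ℓ)·optimum for ℓ terminals, which the tests verify against
an exhaustive optimum on all instances up to 12 nodes.

**Multi-tree aggregation.** Minimum Steiner trees are typically non-unique;
aggregating several stabilises the extracted mechanism. Tree *i* shuffles
the terminal insertion order with an RNG seeded by `(random_seed, component,
i)`, so the first k trees are identical regardless of `n_trees`. Acceptance
is *streaming*: a tree is kept iff its cost exceeds the best cost seen so
far by at most `tolerance` (default 0), and acceptance is never revoked when
a later tree improves the best. The streaming rule was chosen over
retroactive filtering so that increasing `n_trees` can only grow the module
(a monotonicity property the tests assert). Seeds spanning several
components are mined per component with a warning, yielding a module with
one component per seed group rather than a hard failure, because downstream
ranking still has use for the union. Defaults: `n_trees=10`,
`hub_penalty=0`, `tolerance=0`.

**Greedy connectivity-significance expansion.** For a candidate of degree k
with k_s links into the current module of size s₀ in an N-node network, the
significance is the hypergeometric upper tail
p = Σ_{j=k_s}^{min(k,s₀)} C(s₀,j)·C(N−s₀,k−j)/C(N,k), computed via
`scipy.stats.hypergeom.sf` (the tests cross-check against exact `Fraction`
enumeration to 1e-12). Each iteration scores only the nodes adjacent to the
module — a node with k_s = 0 has p = 1 and can never win — adds the best
one and recomputes. Ties break deterministically by (smaller p, larger k_s,
smaller k, lexicographic id). The seed weight α (default 1) counts links to
seeds and the seeds' contribution to s₀ and N α-fold; with α = 1 the
weighting is inert. The module may be disconnected; the component count is
recorded. The function-level `connectivity_pvalue` accepts α as a pure
count-scaling convenience (s₀ → α·s₀, N → N + (α−1)·s₀); the per-link
weighting necessarily lives in the expansion loop, which passes pre-weighted
counts.

## Drug ranking

Both rankers operate on the *ranking graph*: experimental PPI edges plus
drug–target edges, unit weights; genes and diseases never enter. With
`approved_only`, non-approved drugs are dropped from the graph before
propagation.

**TrustRank.** t = d·W·t + (1 − d)·t₀ with W the column-normalised
adjacency, t₀ uniform over the seed proteins, damping d = 0.85 by default.
Columns of isolated nodes (degree 0) redistribute their mass to t₀. Power
iteration stops when the L1 change falls below `tolerance` (default 1e-6)
or after `max_iterations` (default 100; non-convergence logs a warning and
returns the last iterate). With no isolated nodes the trust vector sums to
1 at the fixed point. Higher damping propagates trust further from the
seeds (more explorative); d = 0 leaves all mass on the seeds and returns an
empty drug list.

**Seed-restricted closeness.** The default is harmonic:
C(v) = Σ_{s reachable} 1/d(v,s) with unweighted shortest-path distances.
Harmonic closeness was chosen because unreachable seeds contribute 0
without special-casing while preserving the intended ordering (drugs nearer
the module score higher). The classical form |S_reach|/Σd is available via
`variant="classic"`. Distances are unweighted: the hub penalty is a
module-mining concept and is not applied to ranking.

**Candidates, filtering, ties.** Direct mode admits only drugs with a
target among the seeds; indirect mode admits every drug in the seeds'
component (exactly those that can score > 0), so direct ⊆ indirect always.
Zero-score drugs are excluded; ties break lexicographically by drug id so
ranks 1..n are unique and reproducible. `exclude_seed_targeting` drops
drugs *all* of whose targets are seeds (useful when prioritising drugs for
a module while ignoring trivial seed hits) and re-ranks.

## Statistical validation

All three methods report an empirical p-value p = r/n, where r counts null
draws whose statistic *strictly exceeds* the observation among n
permutations (default 1000), reported as "< 1/n" when r = 0 (e.g. "<
0.001"). Strict exceedance is the primary convention; a `strict=False`
switch counts ties as exceedances for a conservative variant. The
(r+1)/(n+1) estimator is deliberately not used, to keep the reporting
convention exact.

- **Drug lists**: the observed list's DCG = Σ d_i/log₂(i+1) (or plain
  overlap Σ d_i, which ignores ranks) is compared against random ordered
  lists of the same length sampled without replacement from a pool —
  by default all drug nodes of the network.
- **Modules**: the observed module's precision (reference drugs targeting
  the module / all drugs targeting it; 0 when untargeted) or raw
  intersection size is compared against *mock modules* matching the
  observed module's component sizes. Mocks grow each component from a
  uniform start node by uniformly chosen boundary neighbours, keeping
  components mutually non-adjacent so the induced subgraph matches the
  component count exactly; dead ends retry (≤ 100). This sampler is simple
  and connected by construction but is *not* exactly uniform over connected
  k-sets on irregular graphs (growth favours high-boundary regions); on
  vertex-transitive graphs it is uniform, which the exactness tests exploit.
- **Joint**: for the observed and each mock module, the full ranking
  pipeline runs with the module members as seeds and list precisions are
  compared, so both pipeline stages enter the null.

The gene-set overlap test is the one-sided hypergeometric tail
P(X ≥ |A∩B|) with X ~ Hypergeom(N, |A|, |B|); the universe N defaults to
the number of gene nodes in the loaded network and should be overridden
when a different background is appropriate.

Null calibration is tested empirically: with reference drugs assigned
uniformly at random, all three methods produce approximately uniform
p-values (Kolmogorov–Smirnov distance < 0.1 over 200 replicates of 200
permutations). Because exceedance is strict, heavily discrete statistics
bias p downward under ties; the calibration tests therefore use settings
where the statistic is near-continuous (DCG for lists; precision with
variable numbers of targeting drugs for modules), which is also the regime
of realistic networks with hundreds of drugs.

## Synthetic benchmarks

The generator emulates the structural features the algorithms rely on, not
any real database's content. A Barabási–Albert preferential-attachment
graph (default 1000 proteins, 2 edges per new node) supplies the heavy-
tailed, connected interactome (so the hub penalty is exercisable); each
protein is encoded by exactly one gene (a many-to-many map is supported by
the model but kept one-to-one here for legible ground truth). A connected
module (default 20 proteins) is grown by a boundary random walk; a fraction
(default 0.5) of its genes receive gene–disease edges and become the
recoverable seeds. True drugs (default 10) are approved, target 3 module
proteins each and carry an indication edge; decoys (default 50) target only
non-module proteins.

What passing these benchmarks shows: the pipeline recovers planted
structure significantly above degree-matched chance, ranks module-targeting
drugs above decoys (median true-drug rank ≈ 5 vs ≈ 35 at defaults), and its
validation p-values are both calibrated under the null and significant on
planted truth. What it does not show: performance on real interactomes,
whose modules are denser and noisier than random-walk plants, whose
drug–target layer is biased toward well-studied proteins, and whose
gene–disease annotations are incomplete. In particular, random-walk-planted
modules in a BA(m=2) graph are internally tree-like, so absolute recovery
is modest: at the default settings greedy expansion recovers on average
≈ 30% of the hidden module members (the regression tests bound the mean at
> 20% over 10 generator seeds); the meaningful claim is the significance
against the degree-matched null, not the absolute fraction.

## Numerical and degenerate-input conventions

- Hypergeometric tails are clamped to (0, 1]; k_s = 0 returns exactly 1.
- Steiner terminals in several components raise a connectivity error
  listing the unreachable terminals (MuST catches this per component).
- Seeds absent from the PPI layer are dropped with a warning; an empty
  mapped seed set is an error, as is a seedless ranking graph.
- Genes encoding no protein are reported as dropped during seed mapping.
- Empty drug pools, pools smaller than the ranked list, zero permutations
  and oversized mock-module specs raise typed errors rather than returning
  degenerate statistics.
- Problem sizes in the test suite: oracle equivalence uses exhaustive
  enumeration for all N ≤ 25 plus a 1500-point random grid up to N = 60
  (tolerance 1e-12), 200 random graphs for the ranking oracles (1e-10), and
  25 exhaustively solved Steiner instances of ≤ 12 nodes; calibration runs
  on 50-protein / 150-drug toys; recovery checks use the default
  1000-protein benchmark.

## Known limitations

- Drug–target edges carry no activation/inhibition semantics; ranking
  treats all targets alike.
- The mock-module sampler's growth bias (above) makes module p-values
  approximate on strongly irregular graphs; matched size and component
  count are exact by construction.
- No failed-drug (negative-control) reference lists; validation measures
  concordance with indicated drugs only.
- The disease hierarchy is assumed acyclic (child → parent); cycles would
  terminate traversal but are not diagnosed.
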