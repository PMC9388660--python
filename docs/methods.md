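# Methods

## Model and procedure

The analysis treats the interactome as an undirected simple graph G
over gene symbols and asks which genes are over-represented across the
2-hop ego neighborhoods ("communities") of a seed list S. Stages, with
their defaults:

1. **Evidence collapse and filter.** Evidence rows (interactor pair,
   organisms, publication, experimental system) are kept when both
   organisms equal the target taxon (default 9606) and the pair is not
   a self-loop; identical (pair, publication, system) tuples count
   once. An edge survives when it has ≥ `min_publications` (2) distinct
   publications **or** ≥ `min_methods` (2) distinct experimental
   systems — a disjunction, read literally from the filtering rule the
   analysis implements. "Methods" are counted as distinct experimental
   system strings (not system types); both physical and genetic
   evidence count by default, with a switch to restrict to physical.
2. **Cell-type restriction.** A gene is "present" in the cell type when
   its atlas value strictly exceeds `min_level` (default 0) in at least
   one target cluster — the most permissive reading, with the threshold
   exposed. The graph is the induced subgraph on present genes.
3. **Membership.** community(s) = nodes at unweighted shortest-path
   distance ≤ `radius` (2) from s, s included (distance 0 qualifies,
   and the later seed-restoration step presumes seeds appear in
   results). membership_number(g) = |{s ∈ S ∩ V : d(s, g) ≤ r}|;
   proportion divides by C = |S ∩ V|. Seeds absent from the filtered
   graph induce no community and are excluded from C but reported and
   later restored. Genes never reached are stored sparsely (absent, not
   zero).
4. **Null model.** `replicates` (1000) random seed sets of size C are
   drawn uniformly *without replacement from the filtered graph's node
   set* — the space in which the observed statistic lives (a
   user-supplied universe is accepted for sensitivity analysis). Per
   node, the mean and sample standard deviation (divisor R − 1;
   replicates are a sample from the null) of membership proportion are
   recorded; nodes never reached in a replicate contribute 0, and every
   node gets an entry. Under this sampling the number of seeds inside a
   node's ball of size m is Hypergeometric(N, m, C), so the proportion
   has mean m/N and variance (1/C)(m/N)(1 − m/N)(N − C)/(N − 1);
   `closed_form_null` exposes these exact moments and the test suite
   holds the simulation to them (and to `scipy.stats.hypergeom`).
5. **Filters and expansion.** Fold enrichment = observed proportion /
   max(null mean, 1/(R·C)); the floor is the smallest nonzero
   proportion resolvable at R replicates, avoiding division by zero
   while preserving rank order. A gene is retained when its proportion
   is ≥ mean + `sd_multiplier` (3) × SD (the ≥ keeps a gene exactly at
   the threshold, since the exclusion rule drops genes *below* it) and
   its membership number is ≥ `min_membership` (2). Input seed genes
   not retained are appended with their raw statistics and a
   `is_restored_seed` flag — restored to the list, not to the passing
   statistics.
6. **Composite score.** Per retained gene, three raw variables —
   connectivity (the fold enrichment), expression (mean abundance over
   target clusters), relative enrichment ((target mean + ε)/(off-target
   mean + ε), ε defaulting to 10⁻⁶ of the atlas maximum) — are each
   divided by their maximum over the scored set and summed, giving a
   composite in [0, 3]; a zero category maximum normalizes to zeros
   with a warning. Ties in the ranking break alphabetically. Genes
   restored only by the expansion step are excluded from scoring unless
   `include_restored_seeds` is set; genes missing from the atlas score
   0 in the two expression categories and are flagged.

## Implementation shape

The three fit-shaped computations are scikit-learn estimators —
`NullModel` (fit: graph → per-node null moments), `ConvergenceAnalyzer`
(fit: graph + seeds → convergence table), and `CompositeScorer`
(fit learns category maxima; transform normalizes and sums) — with
`get_params`/`set_params` and trailing-underscore fitted attributes, so
they compose with sklearn tooling. Graph/file primitives and list
overlap are plain functions; the spec-level operations are thin
wrappers either way. The Monte Carlo loop is a single sparse
matrix product (replicate-sampling indicator × node-ball incidence),
which makes an interactome-scale run (4,400 nodes, 10,000 edges, 470
seeds, R = 1000) finish in seconds on one CPU.

## Synthetic data: what it emulates, and what it does not

* `generate_interaction_table` emulates evidence multiplicity: each
  sampled pair gets one base row, a second-publication row with
  probability `p_second_pub`, a second-method row with
  `p_second_method`, and off-taxon contamination with `p_off_taxon`. It
  returns the exact ground-truth set of pairs that survive the default
  filter, so filter correctness is testable bit-for-bit.
* `generate_atlas` draws log-normal baselines (σ = 0.5 by default, a
  realistic dispersion for mean-expression summaries) and multiplies
  designated genes' target-cluster values by a known factor.
* `generate_planted_convergence` wires `n_hubs` hub nodes to every
  seed — **and to nothing else** — over an Erdős–Rényi background
  (p = 0.02 at n = 200: mean background degree ≈ 4, sparse enough that
  convergence on all 20 seeds cannot arise by chance). Hubs carry no
  background edges by design: a hub with random extra edges would
  promote each of its neighbors to full membership (any neighbor of a
  hub is within 2 hops of every seed), contaminating the ground-truth
  labels. A configuration-model background (same degree sequence) is
  available for stress tests.

None of the generators reproduce real interactome degree distributions,
atlas cluster structure, or symbol semantics; passing tests demonstrate
correctness of the computation under the stated statistical structure,
not biological validity on real BioGRID/Dropviz releases. Real-data
headline counts (node/edge totals, retained-gene counts) are
database-version-dependent, which is why every pipeline run writes its
intermediate tables and manifest: auditability substitutes for exact
count reproduction.

## Hub recovery: what "recovered" means

The planted-hub recovery check ranks genes by fold enrichment within
the pipeline's *discovery output* — the retained set minus the input
seeds. Both restrictions are substantive. Seeds are inputs, not
discoveries, and every seed trivially reaches proportion 1.0 through
seed–hub–seed paths while owning a smaller ego ball (hence higher fold
enrichment) than the hubs themselves, so an unrestricted ranking can
never place the hubs first. Restricting to the retained set matters
because sparse-ball background nodes that catch two seeds by luck post
large fold enrichments — and are exactly what the 3-SD filter exists to
remove. Under this definition both hubs land in the top 5 in ≥ 95% of
independent generations at the documented generator settings
(n = 200, 20 seeds, 2 hubs, p = 0.02, R = 500).

## Numerical and degenerate-input choices

* Symbols are upper-cased everywhere on read (human symbols are
  upper-case; mouse-cased lists then match by symbol).
* Unparseable evidence rows are skipped and counted, never fatal;
  malformed atlas cells (negative, non-numeric, duplicate labels) are
  fatal with coordinates.
* A single-node graph defines null variance 0 (the 0/0 finite-
  population factor).
* On complete graphs simulation and closed form agree exactly
  (mean 1, SD 0) — a degenerate-exactness check in the suite.
* All randomness flows through explicit integer seeds
  (`numpy.random.default_rng`); no global RNG state. Identical seeds
  give bit-identical outputs end to end, independent of `--threads`
  (all computation is single-threaded).
* Problem sizes in the test suite (graphs of 25–200 nodes for property
  tests, one 4,400-node feasibility run, R = 500–1000) were chosen as
  the smallest instances at which the asymptotic statements — oracle
  agreement within Monte Carlo error, ≥ 95% hub recovery — are
  comfortably observable.

## Known limitations

* "Community" is strictly the fixed-radius ego definition; no
  modularity or label-propagation detection, no edge weights or signs.
* The null randomizes seed identity, not network topology; a
  degree-preserving rewiring null would answer a different question and
  is out of scope.
* No statistical significance is attached to list overlaps (raw counts
  only) and no multiple-testing correction is applied to the SD rule,
  matching the procedure the package implements.
* Cross-species comparison relies on a user-supplied symbol map;
  orthology inference is deliberately not performed.
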