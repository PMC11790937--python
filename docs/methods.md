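# Methods

## Model and estimator

All statistics operate on a cells × genes matrix binarised at strictly
positive evidence (entry 1 iff count > 0; no configurable cutoff). The
n-point model-free interaction (MFI) of a tuple (G₁…Gₙ), conditioned on a
blanket state, is

I = Σ_{s∈{0,1}ⁿ} (−1)^{n−|s|} ln p(G = s | blanket),

estimated by plugging in the empirical joint frequencies of the 2ⁿ states
among the conditioned cells. The estimate is *undefined* whenever any joint
state is unobserved: no pseudocounts are added by default, because the
log-linear contrast is only model-free on the observed support (an additive
pseudocount option exists for exploration only). Natural-log scale is used
throughout so that the MFI of a tuple T equals the coupling J_T of a {0,1}
energy model p(x) ∝ exp(Σ_T J_T Π_{i∈T} x_i) with the remaining genes
clamped to zero; a log₂ convenience value is reported alongside. The
equality is verified symbolically against `synthetic_data.exact_mfi_from_model`,
which enumerates all 2ⁿ state probabilities (capped at 20 genes — larger
models are refused rather than approximately sampled, to keep the oracle
exact).

## Dependency graph and Markov blankets

Conditioning on the full gene set is statistically hopeless, so each tuple
is conditioned only on its Markov blanket in a learnt dependency graph:

1. **Stable PC skeleton.** Starting from the complete graph, edges are
   tested level-by-level with a likelihood-ratio G² test (2·ΣO·ln(O/E)
   summed over conditioning strata; a stratum with a zero margin
   contributes no statistic and no degrees of freedom). Removals are
   applied only after a level completes, so the output is independent of
   gene order. The default significance threshold is α = 0.05,
   uncorrected — a *larger* α is the conservative direction here, since
   extra edges only enlarge blankets. Conditioning sets are capped at 3
   genes by default (configurable); an uncapped search is intractable at
   the 1000-gene scale the tool targets.
2. **Orientation.** Unshielded triples are oriented as colliders by the
   majority rule over all qualifying separating sets; Meek rules R1–R3
   propagate orientations (R4 is only needed with background knowledge,
   which never arises here). Orientations that would reverse an existing
   edge or close a directed cycle are skipped.
3. **Score-based refinement.** The CPDAG is extended to a DAG (Dor–Tarsi,
   with a topological-order fallback for non-extendable finite-sample
   patterns) and improved by BDeu hill-climbing (equivalent sample size 1)
   over add/delete/reverse moves, scanned in a fixed lexicographic order
   with first-improvement; the search may add edges the PC stage missed.
   Seeded random restarts perturb the start DAG; the best DAG's CPDAG is
   returned. Greedy search with restarts was chosen as a transparent,
   deterministic stand-in for sampling-based structure search: the graph
   is never interpreted causally, it only has to be *conservative enough*
   that blankets are not too small.

Blankets are computed on the CPDAG treating every undirected edge as both
orientations (parents ∪ children ∪ spouses), so the blanket is a superset
of the blanket in every DAG of the equivalence class — erring on the side
of conditioning on too much. For a tuple, the admissible conditioning sets
are the union blanket and, through the factorised form of the estimator,
any single member's blanket minus the tuple; the set retaining the most
cells is used (ties: fewer genes, then lexicographic). A `genes_to_one`
list pins chosen blanket genes at 1 instead of 0.

**Candidate tuples.** Order 2: all pairs. Orders 3–5: cliques in the
mutual-blanket graph (edge iff each gene is in the other's blanket) —
Markov-disconnected tuples have vanishing interactions. Orders 6–7: each
retained 5-/6-tuple extended by one blanket gene. A per-order candidate cap
with deterministic priority guards against clique explosions.

## Bootstrap and the λ filter

Uncertainty is quantified by resampling the full cell set with replacement
and re-applying the conditioning in every resample (1000 resamples by
default). Because the estimate depends on the data only through the 2ⁿ
conditioned joint-state counts, the resampled counts follow a multinomial
over those categories plus one "unconditioned" lump; the implementation
samples that multinomial directly, which is distributionally identical to
resampling cells and orders of magnitude faster. Resamples with an
unobserved joint state are undefined and are excluded from the sign-flip
fraction λ's denominator (the treatment of undefined resamples is a
package decision; both inclusive and exclusive conventions are defensible).
Fewer than 100 defined resamples flags the estimate unstable. An
interaction is retained when λ < 0.05 — deliberately more permissive than
requiring the 95% percentile interval to exclude zero.

## d-tuple statistics

For each retained interaction, all 2ⁿ joint states are evaluated on that
interaction's conditioned cells: with per-gene means μ_i computed there,
the state count Φ_s is Binomial(N, π_s) under independence, with
π_s = Π_i(s_iμ_i + (1−s_i)(1−μ_i)). States with positive log₂(φ_s/(π_s·N))
get exact upper-tail p-values (scipy's binomial survival function, which
the tests check against exact-rational summation to 12 significant
digits). All candidates from one run form a single Benjamini–Yekutieli
family — the conservative scoping, valid under arbitrary dependence.
Defaults: q < 0.05, log₂FC > 3 (eightfold), minimum member cells 0. φ and
μ are counted on the conditioned subset (consistent with the null's N),
while a d-tuple's *member cells* are counted on the full matrix, ignoring
the blanket state. States with π_s = 0 (a degenerate μ ∈ {0,1}) are
skipped. Only positive deviations are tested; depleted tuples are out of
scope.

## States

The cells × d-tuples boolean matrix is clustered column-wise by Dice
dissimilarity d(X,Y) = 1 − 2|X∧Y|/(|X|+|Y|) (not a metric) with average
linkage by default (the linkage flavour is a genuinely open choice and is
configurable; complete and single are also supported). Candidate cut
heights are 0 plus the finite set of merge heights — the induced partition
is piecewise constant in between. Each candidate partition is scored by
Newman's weighted modularity on the complete d-tuple graph with edge
weight 1 − d (the *similarity*: clustering co-occurring d-tuples requires
similarity weighting, and the literal alternative reading — weighting by
dissimilarity — is available via the override). Ties, including the
degenerate zero-total-weight graph where Q = 0 for every partition, go to
the smallest height, i.e. the finest partition. A cell belongs to every
state one of whose d-tuples it carries; projection to a new dataset is by
exact joint-state match of each d-tuple's genes, with no re-estimation.

## Annotation scoring

Enrichment of an annotation label in a state uses the exact hypergeometric
upper tail P(X ≥ q) (depletion: lower tail; optionally a two-sided Fisher
exact test with the conventional pmf-summation definition), BH-corrected
across all state × label pairs and exported as −log₁₀(q). Differential
expression (state-vs-other, or state-vs-state after removing co-labelled
cells) is a two-sided Wilcoxon rank-sum test on log1p counts-per-10k
values with BH correction; fold changes compare group means on the
normalised scale with ε = 1e−9. Default filters: q < 0.05,
|log₂FC| > 0.25, minimum 3 cells per group. Marker matching reports a
label when ≥ 3 of its markers are upregulated, ranked by hit count then
hit fraction. Exact numerical parity with any specific external DE
implementation is a non-goal.

## Synthetic data: what it emulates, and what it does not

* `sample_energy_model` — exact-enumeration sampling of {0,1} energy
  models; the ground truth for coupling recovery.
* `sample_bayes_net` — ancestral sampling of binary Bayesian networks; the
  ground truth for structure learning.
* `null_independent` — independent Bernoulli columns; the global null for
  false-discovery calibration.
* `plant_dtuple` — rewrites the target genes' sub-vectors of eligible
  cells from the mixture t·δ_s + (1−t)·Q with t = fold·π_s, where Q is the
  product of adjusted marginals (μ_i − t·s_i)/(1−t) restricted to non-target
  states. This hits the target frequency exactly in expectation and
  preserves marginal means up to the (small) renormalisation of Q; fold < 1
  depletes, fold = 0 removes. `plant_disjoint_pair` combines planting and
  removal to produce two d-tuples with *exactly* disjoint member-cell sets
  — with only two d-tuples, a modularity cut can separate them only at
  zero between-weight, so exact disjointness is constructed rather than
  hoped for. A side effect worth knowing: disjointness anti-correlates the
  two gene blocks, and at generous background rates the scan (correctly)
  finds the induced mixed dependencies; the planted-recovery study
  therefore uses sparse backgrounds (mean 0.15, a typical single-cell
  expression rate), where those side signals stay below the eightfold
  filter.

The generators produce the binary structure the method consumes and
nothing else: no count-level overdispersion, dropout gradients, library
size variation or batch effects. Passing tests demonstrate correctness of
the statistics under the stated models, not robustness to every artefact
of real droplet data.

## Problem sizes and defaults used in the shipped studies

The calibration and recovery studies run at the sizes their claims state:
100 replicates of 100,000 cells × 2 genes for the null interaction; 100
replicates of 10,000 cells × 15 genes (means evenly spaced in 0.1–0.5)
for false-discovery control; 50,000 cells for sampled coupling recovery on
≤ 5-gene models; 10,000 cells × 6 genes for two-group planted recovery.
Pipeline defaults mirror the method's printed defaults: 1000 HVGs (variance
of log1p counts-per-10k, user genes kept first regardless of variability),
PC α 0.05, conditioning cap 3, 1000 bootstrap resamples, λ < 0.05, BY FDR
0.05, log₂FC > 3, minimum member cells 0, average linkage, modularity-
maximising cut. QC is off by default ("agnostic" mode — only an explicit
exclusion list is applied); expression mode adds minimum-count and
mitochondrial-fraction filters (prefix "mt-", case-insensitive).

## Known limitations

* Greedy BDeu refinement finds local optima; a missing-edge repair can
  leave a redundant extra edge that the first-improvement order cannot
  delete without reorientation. Blanket conservativeness bounds the
  damage (too-large blankets cost power, not validity).
* The majority-rule collider search re-tests subsets up to the
  conditioning cap; on dense graphs this is the most expensive PC step.
* Undefined estimates (unobserved joint states) are reported, not rescued;
  at high orders and sparse genes this limits the reach of 6–7-point
  scans, which is a statistical property of the estimator, not an
  implementation artefact.
* `fcluster`-based cutting is global; per-branch cutting is not
  implemented.
* The CSV reader materialises dense matrices; very large datasets should
  arrive as MTX and be gene-selected early.
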