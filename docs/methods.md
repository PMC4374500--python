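# Methods

## Model and assumptions

The discovery method treats a gene set M on a PPI network as a unit
whose per-sample *activity* is the sum of member expression values
scaled by 1/√|M| (so that, for independent standardised genes, the
activity variance does not grow with module size). Its central
assumption is that module activity within a phenotype group is
approximately Gaussian; with that, the separability of the two groups
reduces to the overlap of two fitted normal densities, the
*discriminative area* disa(M) ∈ [0, 1].

The greedy seed-growth search is a local optimiser: it never removes a
member, evaluates only the current neighbour set, and is therefore
sensitive to seed choice — which is why many seeds are grown and the
survivors filtered (disa ≤ 0.2) and re-ranked by prior knowledge.
Because grown modules are fitted to the discovery data, the pathway
similarity score, not disa, selects the final biomarker: modules whose
enriched pathways resemble the disease background set are preferred as
more likely to generalise.

## Gaussian overlap: numerics

For σ_N = σ_C the densities cross once, midway between the means, and
disa = 2·Φ(−|μ_N − μ_C| / 2σ). Otherwise the log-density equality is a
quadratic Ax² + Bx + C = 0 with A = 1/(2σ_b²) − 1/(2σ_a²) < 0 for
σ_a < σ_b, whose discriminant is strictly positive, giving two real
crossings x₁ < x₂; between them the narrower density dominates, so

disa = Φ_b(x₂) − Φ_b(x₁) + Φ_a(x₁) + (1 − Φ_a(x₂)),

with a = narrow, b = wide. σ differences below 1e−12 (relative) are
routed to the equal-σ branch to avoid ill-conditioned root arithmetic,
results are clamped to [0, 1], and a quadrature fallback guards the
(never observed) non-finite case. The closed form agrees with adaptive
quadrature of min(φ₁, φ₂) to ~1e−15 over μ ∈ [−10, 10], σ ∈ [0.1, 5].

Group fits use the sample mean and the n−1 sample SD. A group with zero
activity variance cannot be fitted; such candidates are skipped during
growth rather than aborting the search.

## Greedy growth: termination and determinism

The literal stopping rule — stop when disa(M) < δ, default δ = 0.001 —
need not trigger for weak seeds, so three guards are added, each
configurable: stop when the neighbour set is empty, when no candidate
strictly lowers disa (`require_improvement`, default on; with it the
accepted disa sequence is strictly decreasing), and at a size cap
(default 50). Setting `require_improvement=False` and a large cap
recovers the bare rule. Candidate ties within 1e−12 of the minimum are
broken lexicographically by gene ID, making growth fully deterministic.
Growth is pure-forward: members are never revisited or removed. Module
activity is computed on z-scored expression (configurable), and no
direction constraint ties added genes to the seed's t-statistic sign.

## Statistical choices

- **Z-score**: conventional (x − x̄)/σ per gene across all retained
  samples, sample SD (n−1, `ddof` configurable). Constant rows are an
  error. Sign conventions are immaterial downstream (the t-test, disa
  and the classifier are symmetric under joint negation).
- **Seed tests**: Welch's unequal-variance t-test by default
  (`equal_var` switch for the pooled test); two-sided. Genes with zero
  variance in both groups get p = 1 with a warning. BH adjustment is
  applied across all tested genes; the seed threshold is adjusted
  p < 0.01. Seed counts are data-dependent output, not a target.
- **Enrichment**: upper-tail hypergeometric P(X ≥ s) with the analysis
  network's gene set as the population; pathways are intersected with
  the universe before testing, s = 0 gives p = 1 exactly. The MF
  threshold is BH-adjusted p < 0.05 (the threshold and raw-p mode are
  configurable; any defensible choice only reorders borderline modules).
- **Similarity**: sim(PS₁, PS₂) averages, over both directions, each
  pathway's best Jaccard match in the other collection; it is symmetric
  and equals 1 iff the collections match pairwise. An empty MF scores 0
  (with a warning) so poorly annotated modules rank last. The disease
  background is intersected with the universe (configurable).
- **Classifier**: linear-kernel SVM with fixed C = 1.0 (recorded in the
  report), stratified k-fold CV (default k = 10) seeded explicitly; AUC
  is the midrank Mann–Whitney statistic on pooled held-out decision
  scores. Label noise flips ⌈f·n_train⌉ training labels per fold,
  repetitions default to 100; reports give mean, SD, a normal 95%
  interval (±1.96·SD/√reps) and empirical 2.5/97.5 percentiles, since
  the notion of "confidence interval" is otherwise underdetermined.

## Synthetic benchmark generator

`SyntheticSpec` defaults define the study conditions used throughout
the tests: 300 genes, 60 samples per group, a planted module of 10
genes each shifted by 1.5 SD in cases, an Erdős–Rényi background graph
with edge probability 0.02 (mean degree ≈ 6, of the order of curated
PPI networks), 30 catalogue pathways of 10–40 genes, and a
disease-background (DMF) subset of ⌈20%⌉ of the catalogue, half of
whose pathways are forced to contain ≥ 50% planted genes (their size is
capped at twice the planted set so the guarantee is feasible). The
planted genes get a random spanning tree plus ~30% of internal pairs as
edges, so they are connected by construction. Everything is a
deterministic function of `rng_seed`.

The planted-module activity is exactly Gaussian per group with a
standardised mean gap effect·√k ≈ 4.7, predicting disa ≈ 2Φ(−2.37) ≈
0.018 — a direct check on the whole activity/overlap chain.

What the generator does **not** emulate: heavy-tailed or heteroskedastic
microarray noise, gene–gene correlation outside the planted module,
batch effects, scale-free degree distributions, probe-level artefacts,
or annotation bias in pathway catalogues. Passing tests therefore
demonstrate correctness of the algorithms and calibration under the
stated model, not performance on real cohort data.

## Problem sizes in tests and the acceptance script

Oracle-agreement checks use 200 random parameter sets (overlap), every
universe size up to 25 (hypergeometric), 100 random collection pairs
(similarity) and 50 random 20-node instances (greedy). Simulation
checks use 20 independent pipeline runs at the default conditions for
recovery and for the null control, and 100 repetitions per noise
fraction for the label-noise decay. These sizes give stable medians and
rates while keeping a full run in the order of half a minute.

## Known limitations

- Greedy growth finds a local optimum; no backtracking or annealing.
- The Gaussian-activity assumption can be poor for small modules of
  strongly non-normal genes; disa is then a heuristic ranking score.
- The disa ≤ 0.2 filter and δ = 0.001 are inherited defaults; on data
  with weaker effects they may pass nothing (the pipeline exits with a
  distinct empty-result condition rather than guessing).
- Pathway-set similarity treats pathways as flat gene sets; no
  ontology-graph or expression-weighted similarity.
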