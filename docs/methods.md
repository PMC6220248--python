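# Methods

## Scope and data model

The pipeline starts at the weighted adjacency matrix: a subject is an N×N
symmetric, non-negative matrix with zero diagonal over a fixed region table
(the bundled default is the 83-region Desikan–Killiany + subcortical
parcellation: 41 regions per hemisphere, one brainstem node). How the
weights were produced (streamline count, fiber density, …) is deliberately
not modeled; the analysis is invariant to any monotone rescaling of the
weights because only the rank order of edges survives top-K binarization.
Files carrying region names are reconciled by name, never by position, and
readers reject — rather than repair — asymmetry beyond 1e-9, negative
weights and non-zero diagonals.

## Thresholding and the entropy criterion

Binarization keeps the K strongest edges of each subject, with ties at the
cut broken deterministically by ascending lexicographic node-pair order so
runs are reproducible. K is selected at cohort level: for each candidate K,
p(i,j) is the fraction of subjects whose binarized network contains edge
{i,j}, and the cohort entropy is the sum over all pairs of the binary
entropy of p(i,j), in bits. The null ensemble at each K holds `n_random`
networks (default 500), each produced by degree-preserving double-edge
swaps applied to one uniformly drawn subject's network; the optimum
maximizes H_null − H_actual, ties toward smaller K for parsimony.

Two choices here are documented interpretations rather than forced by the
problem. First, the entropy of the cohort's edge-occurrence probabilities
is computed as a sum of independent per-pair Bernoulli entropies — the
direct reading of "the probability that edges occur, for all node pairs" —
rather than normalizing the probabilities into a single distribution over
pairs; the argmax of the difference is unaffected by the log base, and the
per-pair form has the clean interpretation of total cohort edge
uncertainty in bits. Second, the rewiring effort is ceil(10·|E|) attempted
swaps (skipping any swap that would create a self-loop or multi-edge),
a standard mixing budget; it is configurable, and graphs with no feasible
swap (e.g. a triangle) are returned unchanged. The swap loop is seeded by
a numpy Generator so the entire scan is bit-reproducible.

The automatic K grid covers mean degrees 2–20 (K ∈ [83, 830] at N = 83),
clipped in the pipeline to the sparsest subject's positive-edge count.

## Network measures

* **CPL**: mean shortest-path hop count over all reachable unordered pairs;
  unreachable pairs are excluded rather than treated as infinite, which
  keeps the measure finite on fragmenting rewirings.
* **GCC**: the default (`average_local`) is the mean nodal clustering
  coefficient with degree-<2 nodes contributing 0; `transitivity`
  (3·triangles/triples) is also provided. The two disagree on most graphs
  and both circulate under the same name, so the choice is recorded in
  every result row.
* **BET**: unnormalized Brandes betweenness for undirected graphs, each
  unordered pair counted once, endpoints excluded.
* **SMW**: (GCC_act/GCC_rand)/(CPL_act/CPL_rand), where the rand terms are
  means over `n_random` degree-preserving rewirings of the subject's own
  network (the standard small-world σ construction; a shared cohort-level
  ensemble would be the alternative reading and is intentionally not the
  default). GCC_rand = 0 makes the ratio undefined; it is returned as NaN
  with a warning, never as a silent infinity. A degenerate-column guard
  downstream then drops the constant SMW column if every subject is
  affected.

Graph algorithms are delegated to networkx; the test suite checks them
against hand-rolled exhaustive oracles (Floyd–Warshall, explicit
shortest-path enumeration, direct triple counting) on all graphs up to 7
nodes, so the delegation is verified, not assumed.

## Association stage

Design: age, sex (male = 1, female = 0 — only the sex coefficient's sign
depends on this coding), CPL, GCC, SMW, then one BET column per region in
region-table order — 88 candidates at N = 83. Predictors **and** response
are z-scored (sample SD, n−1), so reported coefficients are standardized
βs; zero-variance columns are dropped with a warning before
standardization.

Selection runs L1-penalized least squares (scikit-learn coordinate
descent) over a log-spaced penalty path with seeded K-fold
cross-validation (default 10 folds). The default penalty is the **one-SE
rule** (largest penalty within one standard error of the CV-minimum MSE);
the CV-minimum is available as `penalty_rule="min"`. The one-SE default is
deliberate: with 88 candidates and ~50 subjects, refitting OLS on
CV-min-selected terms and reading nominal p-values is badly anti-
conservative (post-selection inference), and in simulations under the
global null the CV-min rule flags spurious node terms in roughly half of
cohorts at p < 0.01, while the one-SE rule keeps the false-flag run rate
near zero and still recovers strong planted effects essentially always at
n = 200. The one-SE choice is also what the reference R workflow
(`cv.glmnet`) extracts by default. The nominal p-values of the final OLS
remain post-selection quantities and are flagged at a fixed p < 0.01
without multiplicity correction, mirroring the analysis the package
implements; the null-cohort simulations in the test suite are the honest
statement of the procedure's operating characteristics.

Order of operations: selection on all subjects → OLS (selected terms, age
and sex forced in even when unselected) → a **single** Cook's-distance
pass removing subjects with D > 3 × mean(D) → one refit on the survivors.
Cook's distance needs a fitted regression to be defined, which is why
removal follows the first fit rather than preceding selection. The refit
reuses the cohort-level standardization (columns are not re-scaled after
removal), keeping βs comparable before and after filtering.

Cronbach's α uses the classical item-variance form with sample variances
(n−1): α = k/(k−1) · (1 − Σ var(itemᵢ)/var(Σ items)).

## Synthetic cohort generator

The generator produces the statistical structure the analysis assumes,
with every planted quantity recorded:

* **Backbone**: `backbone_edges` (default 343, matching the operating
  point of the analysis; mean degree ≈ 8.3 at N = 83) node pairs drawn
  uniformly at random, resampled until connected, carrying log-normal
  weights (median `backbone_weight_mean` = 100, log-SD 0.6 — right-skewed,
  strictly positive, like tract-strength distributions).
* **Subjects**: each backbone weight × an independent log-normal factor
  (log-SD `subject_noise_sd` = 0.3), plus `n_noise_edges` = 60 idiosyncratic
  weak edges (median 20, log-SD 0.6) off the backbone. Noise edges sit
  mostly below the backbone weight range, so top-K binarization near the
  backbone size recovers mostly backbone edges while leaving genuine
  subject variability — which is what gives the entropy criterion a
  non-trivial optimum.
* **Effect mechanism**: per subject, a latent z ~ N(0,1) scales every edge
  incident to each effect node v by exp(γ_v·z). This moves v's betweenness
  rank after binarization (stronger incident edges survive the cut and
  carry more shortest paths) without touching the rest of the degree
  sequence in expectation, and supports signed γ per node (default: one
  node at +0.8, one at −0.8).
* **Trait scale**: 12 items, each a discretized equicorrelated latent
  normal (pairwise r = 0.262) whose shared component carries
  `beta_trait`·z (default 2.0, giving a latent trait–z correlation ≈ 0.8);
  categories 0–4 with fixed marginal probabilities (0.1, 0.2, 0.4, 0.2,
  0.1). By the Spearman–Brown prophecy, k = 12 items at r = 0.262 give
  α = 0.810; the generator's empirical α on large cohorts lands within a
  few hundredths of that (discretization attenuates the latent
  correlation slightly). Item sums are linearly rescaled at cohort level
  to hit mean 23.5 and SD 7.5 exactly in-sample — cohort-level rescaling
  was chosen over fixed population constants because the discretized
  sum's SD has no closed form and the calibration targets are cohort
  moments.
* **Covariates**: age uniform on [20, 65], sex Bernoulli with P(male) =
  33/51. Neither influences the trait in the generative model, so their
  coefficients are pure null checks downstream.

What the generator does **not** emulate: spatial embedding and distance-
dependent connectivity, hemispheric symmetry of the backbone, realistic
degree heterogeneity (hubs), head-motion artifacts, or any direct age/sex
effect on connectivity or trait. Passing recovery tests therefore show the
pipeline does what it claims on data satisfying its own assumptions — not
that those assumptions hold in real tractography.

## Numerical and reproducibility choices

* All randomness flows through numpy Generators; the pipeline derives one
  sub-seed per stage from a master seed via `SeedSequence.spawn`, so
  changing one stage's ensemble size cannot perturb another stage's draws.
  Repeated runs at the same seed are byte-identical.
* Entropy uses 0·log 0 = 0; probabilities are validated into [0, 1].
* Binarization ties are broken lexicographically (documented above);
  without ties, edge sets are nested in K.
* OLS is solved by statsmodels and asserted against the residual-df
  identity n − p − 1 on every fit; the LASSO path uses tolerance 1e-7 and
  a high iteration cap so KKT residuals are small enough to audit.
* Default problem sizes in tests and the acceptance script (cohorts of
  10–51 subjects at 20–83 nodes, null ensembles of 3–100, 5–50 Monte-Carlo
  repetitions) were chosen so the full suite completes in minutes on one
  CPU while keeping each Monte-Carlo bound comfortably away from its
  threshold.

## Known limitations

* The final p-values are post-selection; the package controls the
  *procedure-level* false-flag rate by its conservative penalty default
  and quantifies it by simulation, but does not implement formal selective
  inference.
* CPL on graphs that fragment under rewiring averages over fewer pairs;
  comparing CPL across graphs with very different reachable-pair counts
  is not meaningful.
* The edge-occurrence entropy treats pairs as independent Bernoullis; any
  dependence between edges (shared degree constraints) is ignored by the
  criterion, as in the per-pair reading it implements.
* `rewire_degree_preserving` guarantees degree preservation and
  reproducibility but, like all fixed-budget double-edge-swap samplers,
  does not guarantee uniform sampling of the degree-constrained graph
  space.
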