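# Methods

This note records the statistical model, the algorithmic choices and
their defaults, and the known limitations of the implementation.

## 1. Data model and assumptions

Three layers, ordered by causal precedence:

1. **Genome** — additive minor-allele dosages in {0, 1, 2}; exogenous
   (nothing in the other layers can cause a germline genotype).
2. **Metabolome** — positive abundances, analyzed on the log scale,
   assumed approximately multivariate normal after transformation.
3. **Risk factor** — triglycerides, measured longitudinally, analyzed
   as winsorised log values; a sink (no metabolite is its descendant).

Inference assumes a linear-Gaussian structural equation model (SEM)
over the transformed metabolites: faithfulness (conditional
independences in the distribution correspond to d-separations in the
generating DAG), causal sufficiency *up to* the measured covariates,
and valid instruments (relevance via the first-stage F gate; the
exclusion restriction is tested per edge rather than assumed).

## 2. Preprocessing

- Metabolites: natural log then per-column z-score
  (`log_standardize`, default), or Blom rank-inverse-normal
  (`rank_inverse_normal`, offset 3/8) for heavy-tailed panels.
  Non-positive values under the log transform are a hard error, not
  silently dropped.
- Risk factor: winsorised at the 1st/99th percentiles (linear
  interpolation between order statistics) then log-transformed;
  bounds are recorded per visit. Standardization happens within each
  visit's analysis sample.
- Metabolites missing in more than 20% of samples are dropped
  (`max_missing_frac`); remaining missingness is handled by listwise
  deletion within each statistical test.

## 3. Genomic instruments

- **LD reduction.** Pairwise `r²` of dosage vectors; average-linkage
  hierarchical clustering on `1 − r²`, dendrogram cut at
  `1 − r2_threshold` (default threshold 0.80). Each cluster's proxy is
  the member with the least missingness, ties broken by the higher
  minor-allele frequency, then lexicographic id. This keeps one
  representative per LD block and makes downstream scans approximately
  independent across proxies.
- **Scores.** Per metabolite, a marginal scan (simple regression of
  the standardized metabolite on standardized dosage, t-distributed
  p-values) selects proxies with `p < 5×10⁻⁸`, capped at 20 members by
  ascending p; the weighted allele score uses the marginal betas as
  weights and is standardized.
- **Exclusivity filter (default on).** A proxy associated with several
  metabolites — typically because a metabolite→metabolite effect
  transmits its parent's genetic signal — is assigned only to the
  metabolite where its marginal p is smallest (a Steiger-style
  specificity rule). Without this, downstream metabolites' scores
  absorb their parents' SNPs and the exclusion restriction fails,
  producing spurious orientation conflicts.
- **Strength.** First-stage `R²` and `F = R²(n−2)/(1−R²)`; instruments
  with `F < 10` are flagged weak and excluded from orientation.

## 4. Network discovery

- **CI test.** Partial correlation through the precision matrix of the
  covariance submatrix (Cholesky-based; exact collinearity raises a
  "singular conditioning design" error), then the Fisher z statistic
  `√(n − |S| − 3)·atanh(r)` against the standard normal. `α = 0.001`
  is the only tuning parameter.
- **Stage 1.** Edge `x – y` is kept iff `x ⊥̸ y` given *all* other
  metabolites. On a faithful linear-Gaussian system this returns the
  moral graph of the generating DAG (skeleton plus spouse edges). It
  requires `n > p + 3`; a Ledoit–Wolf shrinkage covariance is
  available (`shrinkage=True`) for wider-than-tall panels.
- **Stage 2 (default on).** PC-style pruning: for each surviving edge,
  search conditioning subsets of the current neighborhoods up to
  `max_order = 3`; the first separating subset removes the edge and is
  recorded for collider orientation. Disabling stage 2 keeps the
  literal full-conditional topology.
- **Orientation**, in order of precedence:
  1. *Instruments.* For edge `x – y` with usable instrument `G_x`:
     `G_x` marginally associated with `y` (`p < α`) **and**
     `G_x ⊥ y | x` (`p ≥ α`) supports `x → y`. Evidence in both
     directions marks the edge as a conflict.
  2. *Colliders.* Unshielded triples `x – z – y` with `z` outside the
     recorded separating set of `(x, y)` are oriented `x → z ← y`,
     but only when both edges are still fully undirected —
     instrument-derived orientations are never overturned by a sepset
     miss, which is the weaker signal.
  3. *Meek rules R1–R4*, iterated to closure.
  The directed subgraph is kept acyclic throughout (an orientation
  closing a cycle is refused and logged), instrument nodes always have
  in-degree 0, and every decision is logged with its provenance.
  Traversals are lexicographic, so results are independent of column
  order.

## 5. Risk-factor integration

- **Direct effects.** Markov-boundary selection against the
  standardized log outcome: forward inclusion of the candidate with
  the smallest conditional p below `α`, backward elimination at `≥ α`,
  iterated to a fixed point. Measured covariates (e.g. BMI) can be
  appended to every conditioning set (`adjust_selection`); by default
  selection is unadjusted and a covariate-adjusted p-value is reported
  alongside as a sensitivity column.
- **Indirect effects.** Metabolites with a directed path into a direct
  metabolite. Only confidently directed edges establish ancestry;
  undirected or conflicted edges do not.
- **Quantification.** With the risk factor attached as a sink, each
  node is regressed on its graph parents (OLS); total effects are
  `((I − B)⁻¹ − I)`, equivalent to the sum over directed paths of
  coefficient products. All variables standardized, so effects are SD
  units. SEs from a nonparametric sample bootstrap (`n_boot = 200`)
  on the *fixed* graph — graph-selection uncertainty is deliberately
  not propagated.
- **Visits.** Later visits re-test the baseline direct set within that
  visit's samples (full re-discovery by flag); visits with fewer than
  100 samples are skipped with a warning.

## 6. The simulator

Defaults mirror the cohort dimensions the package targets: 2479
samples, 122 metabolites, five visits with attrition
2479/1920/1629/1398/700, ~2000 LD blocks (4000 SNPs), 9 direct parents
with effects drawn from ±[0.07, 0.17] SD, per-metabolite genetic
effect 0.3, shared confounder 0.2.

Design choices worth knowing:

- **Genotypes** are noisy copies of one latent haplotype pair per LD
  block (per-allele flip probability 0.01), giving high within-block
  and near-zero between-block `r²`. The MAF is drawn per block
  (uniform on [0.1, 0.4]); within-block copying makes a per-SNP MAF
  draw incompatible with the copy structure.
- **Outcome scale.** The per-visit noise SD is chosen so that
  `Var(log y) = 1` in population (floored at 0.05), which makes the
  planted direct coefficients effects in outcome-SD units — the scale
  on which results are reported. Per-visit attenuation is a knob
  (default 1.0: persistent effects).
- What it does **not** emulate: realistic allele-frequency spectra or
  recombination maps, nonlinear or non-Gaussian metabolite dynamics,
  informative (non-random) attrition, batch effects, or pleiotropy
  beyond the optional one-block-two-metabolites knob.

## 7. Numerical choices

- All regressions and partial correlations use dense linear algebra
  (`lstsq`, Cholesky) on covariance submatrices; the Stage-1 screen
  computes one covariance and reuses submatrices per test.
- Every random draw flows from a single `numpy` Generator seed; run
  artifacts contain no wall-clock information, so identical
  configuration and seed reproduce a run directory bit for bit.
- A full default-size run (2479 × 122, 2000 proxies) completes in
  roughly 3–4 minutes on one CPU, dominated by the bootstrap.

## 8. Known limitations and honest failures

- **Null-selection empty-set rate.** Forward selection at `α = 0.001`
  over 122 independent candidates selects at least one noise variable
  with probability `1 − (1−α)^122 ≈ 11.5%` per dataset; the observed
  empty-set rate on pure-noise outcomes is ~87–89%. The acceptance
  test asserting a ≥ 95% empty-set rate therefore fails by design of
  the selector: it controls the per-test level, not the family-wise
  error. Adding a multiplicity correction would change the published
  operating characteristics of the method, so it is not done silently;
  the per-edge test itself is calibrated (null rejection rate
  statistically indistinguishable from `α`).
- Orientation accuracy depends on instrument strength; at the default
  genetic effect (first-stage `R² ≈ 0.08`) about 90% of true edge
  directions are recovered at n = 5000, with conflicts rare but
  reported rather than suppressed.
- Bootstrap SEs condition on the estimated graph; intervals are
  anti-conservative where the structure itself is uncertain.
- Listwise deletion assumes missingness completely at random within
  each test.
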