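# Methods

## The model

`mitosel` models the joint behaviour of mitochondrial heteroplasmy and a
per-cell disease phenotype.  Each observation is a (cell, clone, mutation)
record carrying a variant allele frequency v ∈ [0, 1] and the cell's scalar
disease-relevance score n.  Conditional on the clone's parameters the score
is a two-part mixture: with probability π it is an exact zero (the mutation
does not feed into the phenotype), otherwise it is Gaussian with mean
a·v + b and variance σ².  The slope a is the clone's *selection pressure*:
it measures how strongly higher heteroplasmy of the clone's mutations
translates into a more disease-like cell state.  Its Beta prior restricts
it to (0, 1); selection below baseline therefore appears as a near zero
rather than as a negative coefficient, and interpretation of sub-baseline
selection is left to the analyst.

Assumptions worth keeping in mind:

* **Exact-zero rule.**  A record belongs to the point-mass component if and
  only if its score equals 0.0 exactly.  A continuous Gaussian hits zero
  with probability zero, so the rule is unambiguous, and the synthetic-data
  generator emits exact zeros.  Real score pipelines that z-normalize
  scores rarely produce exact zeros; users who want zero-inflation on real
  data must encode "non-contributing" observations as exact zeros
  themselves.  This convention is deliberate and documented rather than
  hidden behind a tolerance.
* **Sum restriction.**  Zero-score records carry no Gaussian term, so every
  sum in the conditionals of a, b and σ² runs over the nonzero-score
  records only.  Including exact zeros would inject spurious −b residuals
  and bias the baseline.
* **Grouping.**  Parameters are indexed per clone, pooling all cells
  assigned to the clone (one (π, a, b) per clone, one shared σ² per
  dataset).  A per-(cell, clone) grouping and, implicitly through it, finer
  σ² structure are available via `per_cell_groups`; the pooled default is
  what the reported clone-level coefficients mean.
* **Score replication.**  Phenotype scores are per cell; the likelihood
  indexes them per mutation record.  `assemble_observations` replicates the
  cell's scalar score across its mutation records — the convention for
  integrating per-cell scores such as scDRS output.

## Inference

π and σ² admit conjugate Gibbs updates:

* π | data ~ Beta(α + Z, β + K − Z), with Z the number of exact-zero scores
  among the group's K records.
* σ² | rest ~ Inv-Gamma(κ + N₁/2, θ + ½·Σ(n − a·v − b)²), summing over all
  N₁ nonzero records; with N₁ = 0 the update degenerates to a prior draw.
  This update follows from standard Normal–Inverse-Gamma conjugacy and was
  validated against a brute-force grid posterior before being trusted.

a and b are updated by Metropolis–Hastings on their unnormalized log
conditionals:

* **a**: by default a Gaussian random walk on logit(a) with the Jacobian
  a(1−a) folded into the acceptance ratio, so the chain targets the
  conditional on the original scale.  An independence proposal
  a′ ~ Beta(c/2, c/2) (concentration c = `step_a`) with the full Hastings
  ratio is available as `beta-independence`.  Whenever a proposal is
  asymmetric the Hastings correction is included — dropping it would make
  the chain target the wrong distribution.
* **b**: symmetric Gaussian random walk N(b, τ²).  The b conditional is in
  fact exactly Gaussian (completing the square gives variance
  (K₁/σ² + 1/σ_b²)⁻¹); the MH treatment is retained by design and is tested
  against that closed form, which doubles as a strong correctness oracle.

The latent zero indicators are never sampled: they are identified by the
exact-zero rule, which is what makes the Beta update's zero count a fixed
statistic of the data.

**Step-size adaptation.**  Both MH step sizes are tuned during burn-in
only: every 50 iterations the step is multiplied by
exp(rate − 0.44), clipped to [10⁻⁴, 50], targeting the classic ~0.44
acceptance rate for one-dimensional walks.  Adaptation is frozen at the end
of burn-in, so the retained draws come from a fixed, valid MH kernel.
Without adaptation a fixed logit step is far too coarse at large record
counts, where the conditional of a can have a standard deviation of ~10⁻³.

**Initialization.**  `data-driven` (default): π₀ is the observed zero
fraction clamped to (0.01, 0.99); (a₀, b₀) come from least squares on the
nonzero records, clamped into support; σ²₀ is the residual variance.
`prior-draw` starts every chain from independent prior draws and exists to
make PSRF checks honest (overdispersed starts).  Chains use seeds
`seed, seed+1, …`; every result is bitwise reproducible from the
configuration.

**Defaults.**  n_iter = 5000, burn_in = 2000, thin = 1, n_chains = 4;
priors Beta(2,2) on π and a, N(0, 1) on b, Inv-Gamma(2, 0.5) on σ².  These
are weakly informative at the record counts of interest (10³–10⁵ per
clone), where the likelihood dominates.

## Summaries and diagnostics

Posterior summaries pool draws across chains: mean, median, SD and the
central 95% credible interval per parameter.  The per-cell selection
pressure is defined as the posterior mean a of the cell's clone — the only
clone-to-cell map the model provides.  PSRF is the classic Gelman–Rubin
statistic on whole post-burn-in chains (a split-chain variant is a flag);
ESS uses Geyer's initial-monotone truncation and is capped at the retained
draw count (a perfectly antithetic chain reports exactly n).  Acceptance
rates are reported per kernel per clone.

## The synthetic-data generator

The generator mirrors the model exactly: VAFs uniform on (0, 1), a
Bernoulli(1 − π) contribution indicator, Gaussian scores on the line
a·v + b with s.d. σ for contributing records and exact zeros otherwise.
Each simulated cell carries one clonal population; multi-clone datasets
assign cells to clones round-robin.  Because generator and model share one
density, passing recovery tests demonstrates the *inference machinery* is
correct and calibrated — it says nothing about model misspecification on
real data, where VAFs are read-count-quantized, coverage is uneven, scores
are z-normalized, and clone assignments carry errors.  None of those
features are simulated.

Experiment settings, including choices the underlying study conditions
leave open (made once, recorded here):

* **Recovery:** three clones at a = 0.1/0.3/0.9, π = 0.3, σ = 0.1,
  b = (−0.2, 0, 0.2), 300 cells per clone × 200 mutations, 4 chains × 5000
  iterations.  Pass criterion: posterior means within ±0.05 and 3 posterior
  SDs of truth.
* **MAE vs. cells:** one clone, 200 mutations per sample, cell counts
  50–500, 10 replicates, b redrawn from Uniform(−0.5, 0.5) per replicate,
  σ = 0.1.  The generating π is 0.1: with the conjugate π posterior the
  expected MAE is ≈ √(2/π_const)·√(p(1−p)/K) with K = 200·cells, and
  p ≈ 0.1 is the value consistent with the reference curve's endpoints
  (≈0.0025 at 50 cells, <0.0015 at 500); a generating value of 0.3 would
  put the 50-cell endpoint near 0.0037.  This calibration is analytic, done
  before any experiment was run.  These fits use 2 chains × 2000
  iterations: π's conjugate chain is i.i.d. given the data, so the MAE is
  data-limited, not chain-length-limited.
* **MAE vs. clones:** clone counts 1–6, each clone a distinct π (evenly
  spaced on [0.2, 0.8]; midpoint 0.5 for a single clone) and a distinct b;
  a = 0.3 throughout.  Each clonal population is simulated as its own
  sample of 100 cells, so adding clones adds structure without shrinking
  any clone's data.  Under a fixed *total* cell budget the conjugate MAE
  must grow like √m, which would contradict the stability this experiment
  is meant to demonstrate; the constant per-clone design is the regime in
  which stability is the correct expectation (analytic max/min ratio ≈1.25
  from the π(1−π) spread alone).
* **Prior robustness:** one three-clone dataset (recovery settings, 100
  cells/clone), five prior configurations — Beta(2,2), Beta(1,5), Beta(5,1)
  on both π and a, and σ_b² ∈ {0.5, 2} (the "N(0, 0.5)/N(0, 2)" widths are
  read as variances) — 4 chains from prior-draw starts, 4000 iterations.
  Pass criterion: every PSRF < 1.1.

Experiment problem sizes (iteration counts, cells per clone) are the
package's own scale choices; all are recorded in the emitted tables and
config snapshots so any run is self-describing.

## Numerical notes and edge cases

* Log-conditionals are defined up to additive constants; MH uses
  differences only, so constants are dropped deterministically.
* a at the closed boundary {0, 1} evaluates to −∞ under any non-flat Beta
  prior (under the flat prior the likelihood term alone is returned).
* Chains are serialized with 17 significant digits, which round-trips IEEE
  doubles bitwise.
* A group with no nonzero records falls back to prior-mean initialization
  for (a, b) and contributes nothing to the σ² update.
* A proposal that underflows to exactly 0 or 1 on the probability scale is
  rejected outright (it has zero posterior density).

## Known limitations

* The (0, 1) support of a cannot express counter-selection as a sign; it
  compresses it against the lower boundary.
* One shared σ² per dataset is an approximation when clones differ strongly
  in score noise; use per-cell grouping as a finer-grained workaround.
* The exact-zero convention makes the zero-inflation component inert on
  data whose scores are never exactly zero; π then simply recovers the
  prior unless zeros are encoded upstream.
* PSRF and ESS are whole-chain, non-rank-normalized variants; pathologies
  that only rank-based diagnostics catch will be missed.
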