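# mitosel

Bayesian inference of **clone-specific selection pressure** from single-cell
mitochondrial variant data.

Single-cell experiments increasingly yield, for each cell, (i) the variant
allele frequencies (VAFs) of its mitochondrial DNA mutations, (ii) an
assignment of the cell to a mitochondrial clone, and (iii) a scalar
disease-relevance score (e.g. an scDRS-style polygenic score computed from
the cell's transcriptome).  `mitosel` asks the quantitative question these
three layers pose together: *are cells carrying a particular mitochondrial
clone preferentially found in disease-like transcriptional states?*  It is
aimed at computational biologists who already have variant calls, clone
assignments and cell scores, and want a calibrated, uncertainty-aware
estimate of each clone's selection pressure rather than a post-hoc
association test.

## Model

For mutation *k* of clone *c* in cell *s*, let *v* ∈ [0, 1] be the VAF and
*n* the cell's disease score.  Scores are zero-inflated Gaussian:

```
n | v  ~  π · δ₀(n)  +  (1 − π) · N(n | a·v + b, σ²)
```

* **π** — zero-inflation probability: the chance the mutation contributes
  nothing to the score (exact zero).
* **a** — selection pressure: the slope linking heteroplasmy to the disease
  score; a Beta prior keeps it in (0, 1), so larger values mean the clone is
  enriched in high-score (more disease-like) cells.
* **b** — the clone's baseline score contribution (Normal prior, mean 0).
* **σ²** — shared residual variance (Inverse-Gamma prior).

Priors: π ~ Beta(α, β), a ~ Beta(α_a, β_a), b ~ N(0, σ_b²),
σ² ~ Inv-Gamma(κ, θ).  Inference is MH-within-Gibbs: π and σ² have conjugate
updates (Beta–Bernoulli and Normal–Inverse-Gamma over the nonzero-score
records); a and b are updated by Metropolis–Hastings (logit-scale random
walk with Jacobian correction for a, Gaussian random walk for b), with step
sizes tuned during burn-in only.  Convergence is monitored with the
Gelman–Rubin PSRF and autocorrelation-based effective sample sizes.

## Worked example

Simulate three clones with low/medium/high selection (a = 0.1, 0.3, 0.9,
π = 0.3, σ = 0.1) and re-infer them:

```sh
mitosel simulate --cells 300 --mutations 100 --clones 3 \
    --a 0.1,0.3,0.9 --pi 0.3 --b -0.2,0,0.2 --seed 7 --out-dir sim
mitosel fit sim/observations.csv --out-dir fit --chains 4 --seed 11
```

The fit log reports the MH acceptance rates (≈0.4 after burn-in tuning),
and `fit/summary.csv` holds the posterior summaries.  The selection rows:

```
 group parameter     mean   median       sd    ci_lo    ci_hi
clone1         a 0.099947 0.099996 0.004127 0.092084 0.107903
clone2         a 0.300173 0.300139 0.004184 0.292159 0.308635
clone3         a 0.896795 0.896874 0.004094 0.888424 0.904575
```

Each posterior mean sits within one posterior SD of its generating truth,
and `fit/diagnostics.csv` shows a maximum PSRF of 1.025 across all
parameters and four chains — the chains have mixed.  `fit/` also contains
the full thinned chains (`chains_*.csv`), per-cell selection pressures
(`cell_pressure.csv`, the posterior mean a of each cell's clone), and a
`run_config.json` snapshot sufficient to reproduce the run.

Real data enter either as the same long-format table
(`cell,clone,mutation,vaf,score`) or via
`mitosel.assemble_observations(vaf_matrix, clone_map, score_map)`, which
replicates each cell's scalar score across its mutation records.

## Evaluation experiments

`mitosel benchmark {recovery,mae-cells,mae-clones,prior-robustness}` runs
the synthetic evaluation suite: posterior recovery at the three selection
levels, accuracy of the zero-inflation estimate as cell counts grow from
50 to 500 (200 mutations per sample, 10 replicates) and as clone counts
grow from 1 to 6, and PSRF under symmetric, left-skewed and right-skewed
Beta priors plus two Normal prior widths.  See `docs/methods.md` for the
generative settings and design rationale.

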