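# Methods

## Data model and replicate reconstruction

The experimental unit is a disinfection protocol (NaOCl % v/v, H₂O₂ %,
immersion minutes) applied to replicates of 5 seeds, so each replicate's
contamination percentage lies on the lattice {0, 20, 40, 60, 80, 100}.
Published summaries give mean ± SE over 3 replicates; the SE convention
is sample SD (n−1 divisor) divided by √n — the convention that exactly
reproduces every printed SE in the packaged table (e.g. {60, 80, 100} →
SD 20 → SE 11.55), where the population-SD variant does not.

Reconstruction enumerates all C(6+3−1, 3) = 56 replicate multisets and
accepts those matching the printed values to half a printed ULP
(|Δmean| ≤ 0.05, |ΔSE| ≤ 0.005). On the packaged 19-row experiment every
row has exactly one match; ambiguity and infeasibility are surfaced as
distinct errors carrying the offending treatment and, for ambiguity, all
candidates. This inversion is exact bookkeeping, not inference: it adds
no information beyond the printed table.

## GRNN

Prediction is the Gaussian-kernel weighted mean of stored training
targets (a Nadaraya–Watson estimator with a single spread σ). Numerical
choices:

- **Normalization** — per-feature min-max to [0,1] fitted on training
  inputs only. Without it the H₂O₂ axis (0–30) would dominate the
  Euclidean distance over time (0–20) and NaOCl (0–15). A feature that
  is constant in training maps to 0 with a warning rather than an error.
- **Kernel weights** — computed with the per-query maximum exponent
  subtracted, so the nearest point's weight is exactly 1 and the
  estimator degrades gracefully to nearest-neighbor as σ → 0 instead of
  dividing 0 by 0. If the weight sum still vanishes the nearest
  neighbor's target is returned.
- **Spread selection** — leave-one-out RMSE over a grid of 30 log-spaced
  values in [0.02, 2.0] (normalized units); ties break toward the larger
  (smoother) σ. On the replicate-level packaged data this selects
  σ ≈ 0.185. A profile of held-out skill against fixed σ shows the LOO
  choice coincides with the σ maximizing test-set R², i.e. the selector
  is not the binding constraint on skill.
- **Targets** stay on the 0–100 % scale, so RMSEs read directly in
  contamination points.

Predictions are convex combinations of training targets and therefore
bounded by the observed range — the model can never extrapolate to
negative or >100 % contamination, at the cost of underestimating how
good (or bad) unobserved extreme protocols might be.

## Evaluation protocol

Replicate-level modeling (57 points) is the default; treatment-mean
modeling (19 points) is a config option. The train/test split is seeded
and stratified by treatment: at least one replicate of every treatment
remains in training, so the model never predicts a wholly unseen
protocol. When every treatment has a single observation (mean-level
mode) the constraint is vacuous and the split falls back to a plain
random partition.

A single 80/20 split of 57 points is noisy, so headline metrics are
medians over 10 splits derived from one master seed (split seeds
master+101…+110; GA seed master+202; simulation seed master+303 — one
flag regenerates everything). Typical values on the packaged data:
median train R² ≈ 0.93, median test R² ≈ 0.90, median test RMSE ≈ 13
points, MBE negative (the many contamination-free treatments pull kernel
averages down). The test-set ceiling is set by within-treatment binomial
noise: a held-out replicate is predicted essentially from the mean of
its two siblings, so e.g. holding 80 out of {20, 60, 80} leaves an
unavoidable 40-point error. Individual seeds reach test R² ≈ 0.94.

## Genetic algorithm

Minimization over the experimental envelope (NaOCl ∈ [0,15], H₂O₂ ∈
[0,30], time ∈ [0,20]) with the classic operator stack: roulette-wheel
selection, two-point crossover (fraction 0.6 of non-elite offspring),
per-gene uniform mutation (rate 0.05), population 200, 1000 generations,
2 elites. Details that were genuinely open and how they were resolved:

- Roulette selection needs nonnegative bigger-is-better fitness;
  minimization uses fitness = 100 − objective, exploiting the known
  percentage scale. Fitness is clipped at 0; if an entire population
  clips to 0 the selector falls back to uniform probabilities (only
  reachable with non-percentage objectives).
- Crossover cut points are drawn from {0,…,L} inclusive and may
  coincide; on a 3-gene chromosome this keeps single-gene and two-gene
  exchanges both reachable, where interior-only cuts would degenerate.
- Elitism (2 of 200) guarantees a non-increasing best-objective track;
  there is no early stopping — the run is exactly the configured number
  of generations.
- Mutation resamples within bounds, so every chromosome is feasible by
  construction and no clamping is needed.

On the packaged data the fitted surface has a broad plateau of exactly
zero training targets (all protocols with ≥ 5 % NaOCl and ≥ 10 min), so
the minimum is not unique: different seeds return different coordinates
on that plateau (typically high NaOCl, long immersion, negligible H₂O₂)
while the predicted contamination at the optimum — the quantity of
interest — is stably 0 % after rounding.

## Synthetic surface

The simulator draws each replicate's contaminated-seed count from
Binomial(5, p) with first-order kill kinetics
`p = p₀·exp(−(α·NaOCl + β·H₂O₂)·timeᵞ)`. Defaults p₀ = 1 (untreated
control fully contaminated), α = 0.035 per %·min, β = 0.0005 per %·min,
γ = 1 were fixed by eye against the packaged experiment's qualitative
pattern — NaOCl at 5 % clears contamination by ~15 min while 30 % H₂O₂
still leaves ~75 % — giving a potency ratio of ~70×. The surface is a
test harness, not a biological claim: it omits replicate-level
overdispersion, any NaOCl×H₂O₂ interaction, and non-monotone effects
(e.g. disinfectant damage), so passing the recovery check shows the
pipeline recovers a monotone binomial surface, not that it would model
any real experiment correctly.

The end-to-end check simulates the 19-treatment layout, fits the GRNN,
runs the GA, and requires the *true* contamination probability at the
returned optimum to be within 0.02 of the minimum over the search box
(evaluated on a 25³ grid). Analysis drivers use a reduced GA
(population ~100, ~200 generations) for this check; the monotone surface
makes the optimum easy enough that full-scale settings change nothing.

## Known limitations

- The reconstruction step assumes the printed rounding conventions
  (1 dp mean, 2 dp SE) and exactly 3×5 seeds; other designs need the
  tolerances re-derived.
- Contamination is the single objective; seed viability and germination
  are outside the model, so the "optimal" protocol may be harsher than
  a grower would choose.
- With 57 observations on 19 support points, the GRNN is a smoother,
  not a mechanistic model; its plateau at 0 % reflects absence of
  observed contamination, not a guarantee of sterility.
- Published fit statistics for this kind of experiment depend on the
  (usually unreported) split and spread; this package therefore reports
  median-over-seeds metrics with all seeds recorded rather than a single
  favorable split.
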